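# Methods

`idpens` implements the analysis stack commonly applied to conformational
ensembles of intrinsically disordered proteins (IDPs) — here modeled on a
56-residue disordered fragment that can carry a covalently attached or
non-covalently bound small-molecule ligand: per-frame structural
descriptors, free-energy surfaces and state populations, geometric
protein–ligand interaction classification, t-SNE conformational clustering
with dual-space silhouette model selection, blocking-analysis error bars,
and maximum-entropy reweighting against experimental observables.  A
synthetic-ensemble generator provides controlled ground truth so every
stage is testable end to end without external trajectory data.

## Helical order parameter S_alpha

S_alpha measures how many seven-residue segments of a chain resemble an
ideal alpha-helix (phi = −57°, psi = −47°).  For each of the N = n_res − 6
consecutive windows the Cα coordinates are optimally superposed (Kabsch, no
reflection) onto a seven-residue ideal-helix template, and the window
contributes

    (1 − x^8) / (1 − x^12),   x = RMSD_α / r0,   r0 = 1.0 Å.

A near-ideal window (RMSD < 0.5 Å) contributes ≈ 1, RMSD = 1.1 Å
contributes ≈ 0.5, RMSD > 3 Å contributes ≈ 0.  S_alpha therefore ranges
from 0 (no helical content) to n_res − 6 (50 for a 56-residue chain).

Numerical choices:

* The summand is evaluated in the factored form (1 + x⁴)/(1 + x⁴ + x⁸),
  which is identical away from x = 1 and analytically removes the
  singularity there (limit 2/3).  It is smooth, monotone decreasing, and
  bounded in (0, 1].
* Window RMSD uses per-window optimal superposition, making S_alpha
  invariant under global rigid motion.
* Near-zero RMSD values are recomputed from explicit rotation residuals
  because the Kabsch trace formula cancels catastrophically there.

## Radius of gyration and helical fraction

Rg is mass-weighted over protein heavy atoms by default (a Cα-only switch
is exposed); the convention is a documented choice, as trajectory-analysis
tools differ.  The helical fraction is a transparent dihedral criterion —
*not* DSSP: a residue is helical iff phi ∈ (−100°, −30°), psi ∈ (−77°,
−17°) and it belongs to a run of ≥ 4 consecutive such residues; chain
termini without a full phi/psi pair are excluded from the denominator.  The
window widths (±~30–35° around the ideal helix) and the 4-residue run
mirror the geometry of a minimal helical turn.

## Free-energy surfaces and the helical globule

2-D surfaces over (S_alpha, Rg) are weighted histograms converted to
F = −ln p in kT units (kT = 1; temperature absorbed), shifted so the
occupied minimum is 0; empty bins are masked.  Default 40 × 40 bins
(config-exposed).  The helical-globule population p_Glob counts frames with
S_alpha > 6.0 **and** Rg < 1.3 nm, both strictly — boundary frames are
excluded by a literal reading of the definition.

## Interaction geometry

All cutoffs are inclusive (≤), reading "within" inclusively; boundary tests
document the convention.  Classes:

* contact — any heavy–heavy pair within 6.0 Å; a frame is "bound" when at
  least one protein–ligand heavy-atom pair is within 6.0 Å.
* hydrophobic — protein C to ligand C or Cl within 4.0 Å.
* hydrogen bond — donor-hydrogen to heavy acceptor ≤ 3.5 Å and
  donor–hydrogen–acceptor angle > 150°; the distance is measured
  hydrogen→acceptor as the definition reads (a donor-heavy variant exists
  behind a flag).  Donors are N/O/S with an attached hydrogen, acceptors
  all N/O/S; same-residue pairs are excluded.
* aromatic stacking — with ring-centroid separation R, inter-normal angle
  θ and protein-normal-to-centroid-vector angle φ: parallel when R < 6.5 Å,
  θ < 60°, φ < 45°; T-stacked when R < 7.5 Å, θ > 75°, φ < 45°.  Ring
  normals are best-fit plane normals (smallest principal axis — robust to
  puckering); normal sign is arbitrary, so θ and φ are folded to [0°, 90°]
  with absolute dot products, the only domain on which the ranges are
  well-posed.

Intramolecular residue–residue contact maps use the same 6.0 Å heavy-atom
rule excluding sequence neighbors |i−j| ≤ 2 (configurable; the exclusion
width is a documented choice).  Profile similarity between subensembles is
reported as squared Pearson correlation r² (one of two plausible
conventions; labeled as such).  Populations are weighted frame fractions.

## t-SNE conformational clustering

Input is the all-to-all Cα RMSD matrix of the merged (optionally
downsampled, default 5000 frames per source) ensemble; merged sources must
share the Cα atom count, so chemically different systems are compared on
the shared backbone.  The pipeline follows the standard exact t-SNE:

1. Per-point Gaussian bandwidths σ_i found by bisection so each conditional
   distribution's entropy matches log2(perplexity) within 1e−5 bits.
2. Joints p_ij = (p(j|i) + p(i|j)) / 2n — symmetric, summing to 1.
3. 2-D embedding minimizing KL(P‖Q) with a Student-t kernel for Q by
   momentum gradient descent.  Defaults (field-standard, config-exposed):
   1000 iterations, learning rate 200, momentum 0.5→0.8 at iteration 250,
   early exaggeration ×12 for 250 iterations, Gaussian init σ = 1e−4.
   Exact (non-accelerated) gradients: the target regime is n ≤ 10⁴.
4. k-means (scikit-learn, seeded k-means++ restarts, best inertia)
   partitions the embedding into N clusters.
5. Model selection over a (perplexity × N) grid by the integrated
   silhouette S_i = S_ld × S_hd, where S_ld is the mean silhouette under
   embedding Euclidean distance and S_hd under the original RMSD metric —
   the high-dimensional check guards against trusting a poor embedding.

The silhouette uses the standard normalization s_i = (b_i − a_i) /
max(a_i, b_i), the only form consistent with the stated [−1, 1] range;
singleton clusters score 0.  S_i multiplies the two space-level means (a
per-point-product variant exists behind a flag).  Two negative means would
multiply to a positive S_i; that pathological case is flagged with a
warning.  KL is computed over the joint distributions (symmetric P makes
index-order variants equivalent).

## Blocking-analysis errors

Statistical errors on ensemble averages use Flyvbjerg–Petersen reblocking:
block means are formed by recursively averaging adjacent pairs (block
sizes 1, 2, 4, …), the SE of the mean is estimated at every level together
with its own uncertainty SE/√(2(n_b − 1)), and the first level whose SE
agrees with the next level within the latter's uncertainty is selected
(plateau criterion).  If no plateau is found the largest-SE level is
reported and flagged unconverged.  Weighted series are blocked by carrying
per-block weight and weight×value sums, so reweighted ensembles get
consistent error bars.  On iid data this reduces to the naive SE; on AR(1)
data it recovers the analytic √((1+ρ)/(1−ρ)) effective-sample-size
inflation (both verified in the suite).  A stationary AR(1) generator is
provided as a test fixture; synthetic ensembles themselves are
i.i.d.-style, so their blocking errors are conservative.

## Maximum-entropy reweighting

Frame weights take the Gibbs form w_i ∝ w0_i·exp(−Σ_j λ_j s_ij); λ
minimizes the convex dual ln Z + λ·m + (θ/2)Σ_j σ_j²λ_j² (L-BFGS-B with
analytic gradient), i.e. restraints are satisfied within a Gaussian slack
scaled by the confidence parameter θ: θ→0 enforces them exactly, large θ
keeps the prior.  This is the established maximum-entropy/BME formulation
with fixed per-observable uncertainties.  The Kish ratio
(Σw)²/(n Σw²) — the effective retained-sample fraction — is monotone in θ,
so a target Kish ratio (e.g. 0.101, ≈10% of frames retained) is matched by
bisection on log θ to within 0.005.  Cross-validation restrains one
observable subset and reports RMSE on the held-out remainder.  Per-frame
observables (e.g. predicted chemical shifts) are upstream inputs; no
predictor is bundled.

## Synthetic-ensemble generator

The generator emulates the *statistical* structure of enhanced-sampling
IDP ensembles, not their physics:

* Poly-alanine backbone (N, H, CA, C, O) with fixed ideal bond
  lengths/angles (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å); dihedrals are
  the only degrees of freedom.  Internal unit is nm; Å constants are
  converted once.
* Per-residue helix/coil states from a two-state Markov chain: propensity
  p_i (scalar, per-residue array, or the two-helical-region profile
  mimicking a chain with two partially helical segments) and cooperativity
  c interpolating the conditional toward the previous state.
* Helical residues draw phi/psi from (−57, −47) ± 5° Gaussian noise —
  small enough that windows stay below the 0.5 Å knee of the S_alpha
  summand; coil residues from a broad basin phi ~ U(−180, −30),
  psi ~ U(60, 180) ∪ U(−180, −150), kept outside the helix dihedral
  window.  Narrow coil ranges can be configured to produce structurally
  tight non-helical families (used for planted-family clustering tests).
* Frames are generated independently by pivot-move Metropolis Monte Carlo
  at kT = 1 under a hard-core excluded-volume floor (0.24 nm between heavy
  atoms ≥ 2 residues apart) plus an optional harmonic Rg bias
  k(Rg − Rg_target)².  Emitted frames always respect the floor; an
  unreachable Rg target raises a diagnostic after bounded attempts.
  Default 10 sweeps (n_res pivot attempts each) per frame.
* The pseudo-ligand (two linker carbons, a six-carbon aromatic ring with a
  para chlorine, two hydroxyl donors, a carbonyl acceptor — echoing a
  chlorohydrin-like covalent adduct) is tethered to a chosen residue's Cα
  with sampled linker dihedrals, resampled to avoid overlap.  The topology
  gains ring-group, donor/acceptor and hydrophobic annotations.
* Pseudo-observables: value(f, r) = baseline + δ·[residue r helical in
  frame f] + N(0, σ), defaults (52.0, 2.6, 0.3) chosen to resemble Cα
  chemical shifts in ppm (random-coil baseline, helical downfield offset).
  "Experimental" targets are noiseless means under a recorded ground-truth
  weight vector, optionally tilted by exp(β·frame helicity) to create
  non-trivial reweighting problems.

What the generator does **not** emulate: real force-field energetics,
side-chain chemistry, solvent, kinetics (frames are exchangeable, not a
time series), and sequence-specific propensities of any real protein.
Passing tests therefore demonstrate the correctness of the analysis
machinery on ensembles with known truth, not the physics of any particular
system.

## Problem sizes and determinism

The test suite and the acceptance checks run at desk scale as the
package's own choice of study conditions: planted-family clustering uses
200 + 200 frames (two well-separated families: compact-helical vs a tight
extended ribbon), blocking checks use 2¹⁵-point series, reweighting
recovery 200-frame problems, interaction-oracle equivalence 100 random
annotated frames.  Every stochastic component is driven by an explicit
seed; identical configuration (including seed) reproduces ensembles,
embeddings and tables bitwise.  The pipeline derives per-stage seeds from
one global seed and stamps every output with a configuration hash.

## Known limitations

* The dihedral helicity criterion is a DSSP stand-in; absolute helical
  fractions differ from DSSP-based values.
* Exact t-SNE is O(n²) per iteration; beyond ~10⁴ frames an accelerated
  implementation would be needed.
* The maximum-entropy θ-convention follows the standard Gaussian-slack
  dual; other implementations parameterize confidence differently, so θ
  values are not directly transferable (matched Kish ratios are).
* The Rg-biased sampler targets the mean; very tight Rg targets combined
  with high helicity can be slow to equilibrate at few Monte Carlo sweeps.
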