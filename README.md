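# idpens

Analysis toolkit for conformational ensembles of intrinsically disordered
proteins (IDPs), built around the workflow used to characterize disordered
transcription-factor fragments interacting with small-molecule ligands:

* **Per-frame descriptors** — the helical order parameter S_alpha (a
  smoothed count of seven-residue segments resembling an ideal α-helix,
  summing (1 − x⁸)/(1 − x¹²) with x = RMSD_α/r₀, r₀ = 1 Å over all
  windows), mass-weighted radius of gyration, and a dihedral-run helical
  fraction.
* **Ensemble statistics** — free-energy surfaces F = −ln p over
  (S_alpha, Rg), helical-globule populations p_Glob (S_alpha > 6,
  Rg < 1.3 nm), and Flyvbjerg–Petersen blocking error bars with optimal
  block selection.
* **Interaction geometry** — protein–ligand contacts (6.0 Å),
  hydrophobic contacts (4.0 Å C–C/C–Cl), hydrogen bonds (3.5 Å, > 150°),
  and parallel/T aromatic stacking (R, θ, φ ring descriptors), aggregated
  into per-residue population profiles and r² profile comparisons.
* **Conformational clustering** — exact t-SNE on the all-to-all Cα RMSD
  matrix with perplexity-calibrated Gaussian conditionals, k-means
  partitioning of the embedding, and model selection by the integrated
  silhouette S_i = S_ld × S_hd evaluated in both the embedding and the
  original RMSD metric.
* **Maximum-entropy reweighting** — Gibbs-form frame weights fitted
  against experimental observable targets with Gaussian slack, Kish-ratio
  targeted regularization (bisection on θ), and held-out cross-validation
  RMSE.
* **Synthetic ensembles** — a dihedral-space Monte Carlo generator with
  controllable helical propensity, compaction, an attachable pseudo-ligand
  and coupled pseudo-observables, providing ground truth for every stage.

Audience: computational structural biologists analyzing MD ensembles of
disordered proteins (with or without bound ligands) who need reproducible,
statistically honest ensemble summaries.

See `docs/methods.md` for model details, conventions and limitations.

## Worked example

```python
import idpens as ip

# A 56-residue chain with two helix-prone regions and a covalently
# tethered pseudo-ligand at residue index 13 (author numbering 404).
cfg = ip.GeneratorConfig(
    n_frames=50, helix_propensity=ip.two_region_profile(),
    helix_cooperativity=0.9, ligand_site=13,
    mc_sweeps_per_frame=5, seed=42)
ens, truth = ip.sample_ensemble(cfg)

d = ip.frame_descriptors(ens)
print("mean S_alpha", round(d.salpha.mean(), 2))       # 20.87
print("mean Rg (nm)", round(d.rg.mean(), 3))           # 2.509

s = ip.subensemble_summary(ens, d)
print("HF", round(s.helix_fraction, 3),
      "+-", round(s.helix_fraction_se, 3))             # 0.461 +- 0.043
print("BF", ip.bound_fraction(ens))                    # 1.0

prof = ip.interaction_profile(ens)
print("top contact residue", prof.populations["contact"].idxmax())  # 403
```

The ensemble averages S_alpha ≈ 21 of a possible 50 (partially helical)
with an expanded mean Rg of 2.5 nm; the dihedral helix fraction is
0.461 ± 0.043 (blocking SE).  The covalently tethered ligand is within
6 Å of the chain in every frame (bound fraction 1.0), and the residue in
closest contact is a neighbor of the attachment site.

The same analyses run from the shell:

```bash
idpens synth --n-frames 50 --two-region --ligand-site 13 --seed 42 --out demo
idpens descriptors demo.pdb demo.topology.json --out demo.descriptors.tsv
idpens cluster a=demo.pdb:demo.topology.json --seed 1 --out-prefix demo
idpens run config.yaml            # full config-driven pipeline
```

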