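"""Synthetic conformational-ensemble generator.

Emulates the statistical structure of enhanced-sampling ensembles of a
56-residue intrinsically disordered chain: region-specific helical
propensity, tunable compaction (harmonic Rg bias), an optionally attached
small-molecule pseudo-ligand (aromatic ring, chlorine, hydroxyl donors,
carbonyl acceptor), and per-frame pseudo-observables linearly coupled to
local helicity.  Frames are an i.i.d.-style sample produced by
dihedral-space Monte Carlo (pivot moves, Metropolis at kT = 1, hard-core
excluded volume), not a time series.

Chemistry is deliberately minimal: a poly-alanine backbone (N, H, CA, C, O)
with ideal bond geometry; dihedrals are the only degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import _geometry as geom
from .io import Ensemble, ObservableTable, Topology
from .order_parameters import radius_of_gyration

A_PER_NM = geom.ANGSTROM_PER_NM

# excluded-volume floor between heavy atoms >= 2 residues apart (nm)
CLASH_FLOOR_NM = 0.24
CLASH_PENALTY = 1e3            # kT per clashing pair

HELIX_PHI_PSI = (-57.0, -47.0)
HELIX_NOISE_DEG = 5.0

_ATOMS_PER_RES = 5             # N, H, CA, C, O
_OFF = {"N": 0, "H": 1, "CA": 2, "C": 3, "O": 4}


class GeneratorError(RuntimeError):
    """Raised when the sampler cannot satisfy its constraints."""


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic ensemble.

    ``helix_propensity`` is a scalar or per-residue array of helix
    probabilities; ``helix_cooperativity`` in [0, 1) makes helix/coil runs
    sticky (0 = independent residues).  When ``rg_target`` (nm) is set, a
    harmonic bias ``rg_force_constant * (Rg - rg_target)**2`` (kT/nm^2) acts
    on the protein heavy-atom Rg.  ``observable_model`` is
    (coil baseline, helix offset delta, noise sigma) for the pseudo
    chemical-shift generator; ``truth_weight_beta`` tilts the recorded
    ground-truth frame weights by exp(beta * frame helicity).
    """

    n_residues: int = 56
    helix_propensity: float | np.ndarray = 0.3
    helix_cooperativity: float = 0.6
    rg_target: float | None = None
    rg_force_constant: float = 0.0
    n_frames: int = 100
    mc_sweeps_per_frame: int = 10
    seed: int = 0
    ligand_site: int | None = None
    observable_model: tuple[float, float, float] = (52.0, 2.6, 0.3)
    truth_weight_beta: float = 0.0
    first_residue_number: int = 391
    # coil-basin dihedral ranges; None selects the broad default basin
    # (phi U(-180,-30), psi U(60,180) U(-180,-150)).  Narrow ranges produce
    # structurally tight non-helical families (e.g. an extended ribbon).
    coil_phi_range: tuple[float, float] | None = None
    coil_psi_range: tuple[float, float] | None = None

    def propensity_profile(self) -> np.ndarray:
        p = np.asarray(self.helix_propensity, dtype=float)
        if p.ndim == 0:
            p = np.full(self.n_residues, float(p))
        if p.shape[0] != self.n_residues:
            raise ValueError("helix_propensity length != n_residues")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("helix_propensity must lie in [0, 1]")
        return p

    def validate(self) -> None:
        self.propensity_profile()
        if not 0.0 <= self.helix_cooperativity < 1.0:
            raise ValueError("helix_cooperativity must be in [0, 1)")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.rg_target is not None and self.rg_target <= 0:
            raise ValueError("rg_target must be positive")
        if self.ligand_site is not None and not (
                0 <= self.ligand_site < self.n_residues):
            raise ValueError("ligand_site out of range")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated ensemble."""

    config: GeneratorConfig
    states: np.ndarray                 # (n_frames, n_residues) 0/1 helix
    rg: np.ndarray                     # (n_frames,) nm
    truth_weights: np.ndarray          # (n_frames,) sums to 1
    true_mean_observables: np.ndarray | None = None
    ligand_atoms: list[int] = field(default_factory=list)


def two_region_profile(n_residues: int = 56, base: float = 0.15,
                       region_propensity: float = 0.9,
                       regions=((4, 16), (36, 50))) -> np.ndarray:
    """Propensity profile with two helix-prone segments on a low baseline,
    mimicking a chain with two partially helical regions."""
    p = np.full(n_residues, base)
    for lo, hi in regions:
        p[lo:hi] = region_propensity
    return p


# ---------------------------------------------------------------------------
# Topology and reference structures
# ---------------------------------------------------------------------------

def backbone_topology(n_residues: int, first_residue_number: int = 391) -> Topology:
    """Poly-alanine backbone topology: N, H, CA, C, O per residue."""
    names, elements, atom_res = [], [], []
    donor = []
    acceptor = []
    hydrophobic = []
    hlinks: dict[int, list[int]] = {}
    for r in range(n_residues):
        for nm in ("N", "H", "CA", "C", "O"):
            names.append(nm)
            elements.append("H" if nm == "H" else nm[0])
            atom_res.append(r)
            donor.append(nm == "N")
            acceptor.append(nm in ("N", "O"))
            hydrophobic.append(nm in ("CA", "C"))
        base = r * _ATOMS_PER_RES
        hlinks[base + _OFF["N"]] = [base + _OFF["H"]]
    return Topology(
        residue_numbers=[first_residue_number + r for r in range(n_residues)],
        residue_names=["ALA"] * n_residues,
        atom_names=names,
        atom_residue=np.array(atom_res),
        elements=elements,
        donor=np.array(donor),
        acceptor=np.array(acceptor),
        hydrophobic=np.array(hydrophobic),
        hydrogen_links=hlinks,
    )


def _coords_from_backbone(bb: dict[str, np.ndarray]) -> np.ndarray:
    """Interleave builder output into topology atom order, Angstrom -> nm."""
    n_res = bb["N"].shape[0]
    out = np.empty((n_res * _ATOMS_PER_RES, 3))
    for nm, off in _OFF.items():
        out[off::_ATOMS_PER_RES] = bb[nm]
    return out / A_PER_NM


def _build_frame(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    return _coords_from_backbone(geom.build_backbone(phi, psi))


def build_ideal_helix(n_residues: int,
                      first_residue_number: int = 391) -> Ensemble:
    """Single-frame ensemble of an ideal alpha-helix (phi -57, psi -47)."""
    if n_residues < 7:
        raise ValueError("need >= 7 residues for a complete helical window")
    coords = _build_frame(np.full(n_residues, HELIX_PHI_PSI[0]),
                          np.full(n_residues, HELIX_PHI_PSI[1]))
    top = backbone_topology(n_residues, first_residue_number)
    return Ensemble(top, coords[None], provenance="ideal-helix")


def build_extended_chain(n_residues: int,
                         first_residue_number: int = 391) -> Ensemble:
    """Single-frame ensemble of an extended chain (phi -120, psi +120)."""
    if n_residues < 7:
        raise ValueError("need >= 7 residues for a complete helical window")
    coords = _build_frame(np.full(n_residues, -120.0),
                          np.full(n_residues, 120.0))
    top = backbone_topology(n_residues, first_residue_number)
    return Ensemble(top, coords[None], provenance="extended-chain")


# ---------------------------------------------------------------------------
# Dihedral sampling
# ---------------------------------------------------------------------------

def _sample_states(p: np.ndarray, coop: float, rng) -> np.ndarray:
    """Two-state helix/coil Markov chain along the sequence.

    At cooperativity 0 residues are independent Bernoulli(p_i); higher
    cooperativity interpolates the conditional toward repeating the previous
    state, preserving roughly the marginal propensity.
    """
    n = p.shape[0]
    s = np.zeros(n, dtype=int)
    s[0] = rng.random() < p[0]
    for i in range(1, n):
        cond = (1 - coop) * p[i] + coop * s[i - 1]
        s[i] = rng.random() < cond
    return s


def _sample_dihedrals(states: np.ndarray, rng,
                      coil: tuple | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    n = states.shape[0]
    phi = np.empty(n)
    psi = np.empty(n)
    hel = states.astype(bool)
    nh = int(hel.sum())
    phi[hel] = HELIX_PHI_PSI[0] + rng.normal(0, HELIX_NOISE_DEG, nh)
    psi[hel] = HELIX_PHI_PSI[1] + rng.normal(0, HELIX_NOISE_DEG, nh)
    nc = n - nh
    phi_range, psi_range = coil if coil is not None else (None, None)
    if phi_range is not None:
        phi[~hel] = rng.uniform(phi_range[0], phi_range[1], nc)
    else:
        phi[~hel] = rng.uniform(-180.0, -30.0, nc)
    if psi_range is not None:
        psi[~hel] = rng.uniform(psi_range[0], psi_range[1], nc)
    else:
        # coil psi basin: (60, 180) united with (-180, -150), area-weighted
        u = rng.uniform(0.0, 150.0, nc)
        psi[~hel] = np.where(u < 120.0, 60.0 + u, -180.0 + (u - 120.0))
    return phi, psi


def _resample_residue(state: int, rng, coil: tuple | None = None
                      ) -> tuple[float, float]:
    ph, ps = _sample_dihedrals(np.array([state]), rng, coil)
    return float(ph[0]), float(ps[0])


# ---------------------------------------------------------------------------
# Monte Carlo machinery
# ---------------------------------------------------------------------------

def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    u = axis / np.linalg.norm(axis)
    t = np.deg2rad(angle_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


class _ChainMC:
    """Pivot-move Metropolis sampler for one backbone frame (nm units)."""

    def __init__(self, config: GeneratorConfig, topology: Topology):
        self.cfg = config
        heavy = topology.heavy
        self.heavy_ids = np.nonzero(heavy)[0]
        self.masses = topology.masses[self.heavy_ids]
        res = topology.atom_residue[self.heavy_ids]
        self.excl = np.abs(res[:, None] - res[None, :]) < 2
        np.fill_diagonal(self.excl, True)

    def energy(self, coords: np.ndarray) -> float:
        xyz = coords[self.heavy_ids]
        d = cdist(xyz, xyz)
        n_clash = int((((d < CLASH_FLOOR_NM) & ~self.excl)).sum()) // 2
        e = CLASH_PENALTY * n_clash
        if self.cfg.rg_target is not None and self.cfg.rg_force_constant > 0:
            rg = radius_of_gyration(xyz, self.masses)
            e += self.cfg.rg_force_constant * (rg - self.cfg.rg_target) ** 2
        return e

    def n_clashes(self, coords: np.ndarray) -> int:
        xyz = coords[self.heavy_ids]
        d = cdist(xyz, xyz)
        return int((((d < CLASH_FLOOR_NM) & ~self.excl)).sum()) // 2

    @staticmethod
    def _pivot(coords: np.ndarray, res: int, dphi: float, dpsi: float) -> None:
        """Apply pivot rotations for residue *res* in place."""
        base = res * _ATOMS_PER_RES
        n_atoms = coords.shape[0]
        down = np.arange(base + _ATOMS_PER_RES, n_atoms)
        if res > 0 and dphi != 0.0:
            N = coords[base + _OFF["N"]]
            CA = coords[base + _OFF["CA"]]
            R = _rotation(CA - N, dphi)
            sel = np.concatenate(([base + _OFF["C"], base + _OFF["O"]], down))
            coords[sel] = (coords[sel] - CA) @ R.T + CA
        if dpsi != 0.0:
            CA = coords[base + _OFF["CA"]]
            C = coords[base + _OFF["C"]]
            R = _rotation(C - CA, dpsi)
            sel = np.concatenate(([base + _OFF["O"]], down))
            coords[sel] = (coords[sel] - C) @ R.T + C

    def sample_frame(self, states: np.ndarray, rng) -> np.ndarray:
        cfg = self.cfg
        n_res = cfg.n_residues
        coil = (cfg.coil_phi_range, cfg.coil_psi_range)
        phi, psi = _sample_dihedrals(states, rng, coil)
        coords = _build_frame(phi, psi)
        # resolve initial hard-core overlaps greedily
        for _ in range(200 * n_res):
            nc = self.n_clashes(coords)
            if nc == 0:
                break
            k = int(rng.integers(0, n_res))
            ph, ps = _resample_residue(states[k], rng, coil)
            trial = coords.copy()
            self._pivot(trial, k, ph - phi[k], ps - psi[k])
            if self.n_clashes(trial) <= nc:
                coords = trial
                phi[k], psi[k] = ph, ps
        else:
            raise GeneratorError("could not resolve steric clashes")
        e = self.energy(coords)
        for _ in range(cfg.mc_sweeps_per_frame):
            for _ in range(n_res):
                k = int(rng.integers(0, n_res))
                ph, ps = _resample_residue(states[k], rng, coil)
                trial = coords.copy()
                self._pivot(trial, k, ph - phi[k], ps - psi[k])
                et = self.energy(trial)
                if et <= e or rng.random() < np.exp(e - et):
                    coords, e = trial, et
                    phi[k], psi[k] = ph, ps
        if self.n_clashes(coords) > 0:
            # final frames must respect the excluded-volume floor
            for _ in range(100 * n_res):
                k = int(rng.integers(0, n_res))
                ph, ps = _resample_residue(states[k], rng, coil)
                trial = coords.copy()
                self._pivot(trial, k, ph - phi[k], ps - psi[k])
                if self.n_clashes(trial) <= self.n_clashes(coords):
                    coords = trial
                    phi[k], psi[k] = ph, ps
                if self.n_clashes(coords) == 0:
                    break
            else:
                raise GeneratorError(
                    "rg_target appears unreachable without steric clashes")
        return coords


def sample_ensemble(config: GeneratorConfig) -> tuple[Ensemble, SyntheticTruth]:
    """Generate an ensemble of independent frames under *config*.

    Identical config (including seed) gives bitwise-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.propensity_profile()
    top = backbone_topology(config.n_residues, config.first_residue_number)
    mc = _ChainMC(config, top)
    frames = np.empty((config.n_frames, top.n_atoms, 3))
    states = np.empty((config.n_frames, config.n_residues), dtype=int)
    rg = np.empty(config.n_frames)
    for f in range(config.n_frames):
        states[f] = _sample_states(p, config.helix_cooperativity, rng)
        frames[f] = mc.sample_frame(states[f], rng)
        rg[f] = radius_of_gyration(frames[f][mc.heavy_ids], mc.masses)
    helicity = states.mean(axis=1)
    logw = config.truth_weight_beta * helicity
    w = np.exp(logw - logw.max())
    w /= w.sum()
    ensemble = Ensemble(top, frames, provenance=f"synthetic(seed={config.seed})")
    truth = SyntheticTruth(config=config, states=states, rg=rg, truth_weights=w)
    if config.ligand_site is not None:
        ensemble, truth = attach_pseudo_ligand(
            ensemble, config.ligand_site, int(rng.integers(2 ** 31)), truth)
    return ensemble, truth


# ---------------------------------------------------------------------------
# Pseudo-ligand
# ---------------------------------------------------------------------------

_LIG_NAMES = ["CL1", "CL2", "CR1", "CR2", "CR3", "CR4", "CR5", "CR6",
              "CLX", "OH1", "HO1", "OH2", "HO2", "CC1", "OC1"]
_LIG_ELEMENTS = ["C", "C", "C", "C", "C", "C", "C", "C",
                 "CL", "O", "H", "O", "H", "C", "O"]


def _ligand_coords(site_N: np.ndarray, site_CA: np.ndarray, site_C: np.ndarray,
                   rng) -> np.ndarray:
    """Build the pseudo-ligand in Angstrom from the site backbone frame.

    Moieties: two linker carbons, a 6-carbon aromatic ring (para chlorine),
    hydroxyl donors on each linker carbon's oxygen, and a carbonyl acceptor
    branch.  Linker dihedrals are sampled; ring geometry is rigid.
    """
    tor = lambda: float(rng.uniform(-180.0, 180.0))
    pa = geom.place_atom
    CL1 = pa(site_C, site_N, site_CA, 1.53, 110.0, tor())
    # substituents sharing a tetrahedral center get staggered +-120 offsets
    t1 = tor()
    CL2 = pa(site_N, site_CA, CL1, 1.53, 111.0, t1)
    OH1 = pa(site_N, site_CA, CL1, 1.43, 109.0, t1 + 120.0)
    CC1 = pa(site_N, site_CA, CL1, 1.52, 109.0, t1 - 120.0)
    HO1 = pa(site_CA, CL1, OH1, 0.96, 108.0, tor())
    OC1 = pa(site_CA, CL1, CC1, 1.23, 120.0, tor())
    t2 = tor()
    CR1 = pa(site_CA, CL1, CL2, 1.50, 111.0, t2)
    OH2 = pa(site_CA, CL1, CL2, 1.43, 109.0, t2 + 120.0)
    HO2 = pa(CL1, CL2, OH2, 0.96, 108.0, tor())
    CR2 = pa(CL1, CL2, CR1, 1.39, 120.0, tor())
    CR3 = pa(CL2, CR1, CR2, 1.39, 120.0, 180.0)
    CR4 = pa(CR1, CR2, CR3, 1.39, 120.0, 0.0)
    CR5 = pa(CR2, CR3, CR4, 1.39, 120.0, 0.0)
    CR6 = pa(CR3, CR4, CR5, 1.39, 120.0, 0.0)
    CLX = pa(CR2, CR3, CR4, 1.74, 120.0, 180.0)
    order = {"CL1": CL1, "CL2": CL2, "CR1": CR1, "CR2": CR2, "CR3": CR3,
             "CR4": CR4, "CR5": CR5, "CR6": CR6, "CLX": CLX, "OH1": OH1,
             "HO1": HO1, "OH2": OH2, "HO2": HO2, "CC1": CC1, "OC1": OC1}
    return np.stack([order[nm] for nm in _LIG_NAMES])


def attach_pseudo_ligand(ensemble: Ensemble, site: int, seed: int,
                         truth: SyntheticTruth | None = None
                         ) -> tuple[Ensemble, SyntheticTruth | None]:
    """Tether the pseudo-ligand to residue *site*'s C-alpha in every frame.

    Linker dihedrals are resampled (bounded attempts) to avoid hard-core
    overlap with the protein; the placement maximizing the minimum
    protein-ligand heavy-atom distance is kept if none is overlap-free.
    """
    top = ensemble.topology
    if not 0 <= site < top.n_residues:
        raise ValueError(f"ligand site {site} out of range")
    if top.ligand_atoms:
        raise ValueError("ensemble already carries a ligand")
    rng = np.random.default_rng(seed)

    n_prot = top.n_atoms
    lig_res = top.n_residues
    new_top = Topology(
        residue_numbers=list(top.residue_numbers) + [top.residue_numbers[-1] + 1],
        residue_names=list(top.residue_names) + ["LIG"],
        atom_names=list(top.atom_names) + _LIG_NAMES,
        atom_residue=np.concatenate([top.atom_residue,
                                     np.full(len(_LIG_NAMES), lig_res)]),
        elements=list(top.elements) + _LIG_ELEMENTS,
        donor=np.concatenate([top.donor,
                              np.array([nm in ("OH1", "OH2") for nm in _LIG_NAMES])]),
        acceptor=np.concatenate([top.acceptor,
                                 np.array([e == "O" for e in _LIG_ELEMENTS])]),
        hydrophobic=np.concatenate([top.hydrophobic,
                                    np.array([e in ("C", "CL")
                                              for e in _LIG_ELEMENTS])]),
        hydrogen_links={**top.hydrogen_links,
                        n_prot + _LIG_NAMES.index("OH1"):
                            [n_prot + _LIG_NAMES.index("HO1")],
                        n_prot + _LIG_NAMES.index("OH2"):
                            [n_prot + _LIG_NAMES.index("HO2")]},
        ring_groups={**top.ring_groups,
                     "LIG_ring": [n_prot + _LIG_NAMES.index(nm)
                                  for nm in ("CR1", "CR2", "CR3",
                                             "CR4", "CR5", "CR6")]},
        ligand_atoms=list(top.ligand_atoms) + list(range(n_prot,
                                                         n_prot + len(_LIG_NAMES))),
    )

    prot_heavy = np.nonzero(top.heavy)[0]
    near = np.abs(top.atom_residue[prot_heavy] - site) <= 1
    check_ids = prot_heavy[~near]
    lig_heavy_local = np.array([e != "H" for e in _LIG_ELEMENTS])

    base = site * _ATOMS_PER_RES
    coords = np.empty((ensemble.n_frames, new_top.n_atoms, 3))
    coords[:, :n_prot] = ensemble.coordinates
    for f in range(ensemble.n_frames):
        xyz_a = ensemble.coordinates[f] * A_PER_NM
        best, best_score = None, -np.inf
        for _ in range(200):
            lig = _ligand_coords(xyz_a[base + _OFF["N"]],
                                 xyz_a[base + _OFF["CA"]],
                                 xyz_a[base + _OFF["C"]], rng) / A_PER_NM
            d = cdist(lig[lig_heavy_local], ensemble.coordinates[f][check_ids])
            dmin = float(d.min()) if d.size else np.inf
            if dmin > best_score:
                best, best_score = lig, dmin
            if dmin >= CLASH_FLOOR_NM:
                break
        coords[f, n_prot:] = best
    out = Ensemble(new_top, coords, frame_weights=ensemble.frame_weights,
                   provenance=ensemble.provenance + "+ligand")
    if truth is not None:
        truth.ligand_atoms = list(new_top.ligand_atoms)
    return out, truth


# ---------------------------------------------------------------------------
# Pseudo-observables
# ---------------------------------------------------------------------------

def synth_observables(ensemble: Ensemble, truth: SyntheticTruth,
                      seed: int) -> ObservableTable:
    """Per-frame, per-residue pseudo chemical shifts.

    value(f, r) = baseline + delta * helical(f, r) + N(0, sigma).  The
    "experimental" targets are the noiseless per-residue means under the
    ground-truth weight vector recorded in *truth*.
    """
    baseline, delta, sigma = truth.config.observable_model
    rng = np.random.default_rng(seed)
    clean = baseline + delta * truth.states.astype(float)
    noise = rng.normal(0.0, sigma, clean.shape) if sigma > 0 else 0.0
    values = clean + noise
    targets = truth.truth_weights @ clean
    truth.true_mean_observables = targets
    sig = np.full(clean.shape[1], max(sigma, 0.1))
    labels = [f"CS_{n}" for n in ensemble.topology.residue_numbers
              [:truth.states.shape[1]]]
    return ObservableTable(values, targets, sig, labels)


# ---------------------------------------------------------------------------
# Random annotated frames (geometry-oracle fixtures)
# ---------------------------------------------------------------------------

def random_interaction_ensemble(n_frames: int, seed: int,
                                box_nm: float = 1.5) -> Ensemble:
    """Random annotated frames exercising every interaction class.

    A 3-residue pseudo-protein (polar atoms with hydrogens, one aromatic
    ring) and a pseudo-ligand (aromatic ring, chlorine, hydroxyl, carbonyl)
    are scattered uniformly in a box; hydrogens sit 0.1 nm from their heavy
    atom.  Geometrically meaningless but annotation-complete.
    """
    names = ["C1", "N1", "H1", "O1",                      # res 0, polar
             "CG", "CD1", "CD2", "CE1", "CE2", "CZ",      # res 1, ring
             "C2", "OG", "HG", "SD"]                      # res 2
    elements = ["C", "N", "H", "O",
                "C", "C", "C", "C", "C", "C",
                "C", "O", "H", "S"]
    atom_res = [0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 2, 2, 2, 2]
    lig_names = ["LC1", "LC2", "LC3", "LC4", "LC5", "LC6",
                 "LCL", "LO1", "LH1", "LO2", "LC7"]
    lig_elements = ["C", "C", "C", "C", "C", "C", "CL", "O", "H", "O", "C"]
    n_prot = len(names)
    all_names = names + lig_names
    all_elements = elements + lig_elements
    all_res = atom_res + [3] * len(lig_names)
    donor = [False] * len(all_names)
    acceptor = [False] * len(all_names)
    hydrophobic = [e in ("C", "CL") for e in all_elements]
    hlinks = {}
    for heavy, hyd in (("N1", "H1"), ("OG", "HG"), ("LO1", "LH1")):
        i, j = all_names.index(heavy), all_names.index(hyd)
        donor[i] = True
        hlinks[i] = [j]
    for nm in ("N1", "O1", "OG", "SD", "LO1", "LO2"):
        acceptor[all_names.index(nm)] = True
    top = Topology(
        residue_numbers=[391, 392, 393, 394],
        residue_names=["GLN", "PHE", "SER", "LIG"],
        atom_names=all_names,
        atom_residue=np.array(all_res),
        elements=all_elements,
        donor=np.array(donor),
        acceptor=np.array(acceptor),
        hydrophobic=np.array(hydrophobic),
        hydrogen_links=hlinks,
        ring_groups={"PHE_ring": [all_names.index(n) for n in
                                  ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
                     "LIG_ring": [all_names.index(n) for n in
                                  ("LC1", "LC2", "LC3", "LC4", "LC5", "LC6")]},
        ligand_atoms=list(range(n_prot, len(all_names))),
    )
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box_nm, size=(n_frames, top.n_atoms, 3))
    # planar-ish hexagons so ring normals are well defined
    hexagon = 0.14 * np.stack([[np.cos(a), np.sin(a), 0.0]
                               for a in np.linspace(0, 2 * np.pi, 6,
                                                    endpoint=False)])
    for ring in top.ring_groups.values():
        center = coords[:, ring[0], :][:, None, :]
        for f in range(n_frames):
            R = geom.random_rotation(rng)
            coords[f, ring] = center[f] + hexagon @ R.T
    for heavy, hyds in hlinks.items():
        for h in hyds:
            direction = rng.normal(size=(n_frames, 3))
            direction /= np.linalg.norm(direction, axis=1, keepdims=True)
            coords[:, h] = coords[:, heavy] + 0.1 * direction
    return Ensemble(top, coords, provenance=f"random-interactions(seed={seed})")
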