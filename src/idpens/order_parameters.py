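"""Per-frame scalar descriptors of helicity and compaction.

The helical order parameter S_alpha counts, in a smoothed way, how many
seven-residue segments of a chain resemble an ideal alpha-helix
(phi = -57 deg, psi = -47 deg).  Each window contributes

    (1 - x^8) / (1 - x^12),   x = RMSD_alpha / r0,  r0 = 1.0 Angstrom,

where RMSD_alpha is the C-alpha RMSD of the window onto the ideal-helix
template after optimal (Kabsch) superposition.  A near-ideal window
(RMSD < 0.5 A) contributes ~1, RMSD = 1.1 A contributes ~0.5, and
RMSD > 3 A contributes ~0, so S_alpha of an n-residue chain ranges from 0
(fully disordered) to n - 6 (fully helical): 50 for a 56-residue construct.

Also provided: mass-weighted radius of gyration and a transparent
dihedral-run helical-fraction criterion standing in for a secondary
structure assignment (this is NOT DSSP; see docs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from . import _geometry as geom
from .io import Ensemble, EmptySelectionError, select_atoms

WINDOW = 7          # residues per S_alpha segment, fixed by definition
R0_NM = 0.10        # r0 = 1.0 Angstrom, in nm

# Dihedral window (degrees) declaring a residue helical, centered near
# (-57, -47); a run of >= 4 consecutive helical residues is required.
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-77.0, -17.0)
MIN_HELIX_RUN = 4


@dataclass
class SalphaConfig:
    """Parameters of the S_alpha order parameter (defaults are canonical)."""
    r0_nm: float = R0_NM
    window: int = WINDOW
    exponents: tuple[int, int] = (8, 12)

    def __post_init__(self):
        if self.r0_nm <= 0:
            raise ValueError("r0 must be positive")
        if self.window != WINDOW or self.exponents != (8, 12):
            raise ValueError("the 7-residue window and 8/12 exponents are "
                             "fixed by the order-parameter definition")


@dataclass
class FrameDescriptors:
    """Per-frame descriptor block for one ensemble."""
    salpha: np.ndarray                 # (n_frames,)
    rg: np.ndarray                     # (n_frames,) nm
    helical_fraction: np.ndarray       # (n_frames,)
    residue_helicity: np.ndarray       # (n_frames, n_residues) 0/1, NaN at termini
    frame_weights: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"salpha": self.salpha, "rg_nm": self.rg,
                             "helical_fraction": self.helical_fraction})


@lru_cache(maxsize=8)
def _ideal_helix_template(window: int = WINDOW) -> np.ndarray:
    """C-alpha coordinates (nm) of an ideal-helix window, centered."""
    bb = geom.build_backbone(np.full(window, -57.0), np.full(window, -47.0))
    ca = bb["CA"] / geom.ANGSTROM_PER_NM
    return ca - ca.mean(axis=0)


def salpha_term(rmsd: float | np.ndarray, r0: float = 1.0):
    """The per-window summand (1 - x^8)/(1 - x^12) with x = rmsd/r0.

    Evaluated in the factored form (1 + x^4)/(1 + x^4 + x^8), which is the
    same rational function with the removable singularity at x = 1
    eliminated analytically (value 2/3 there).  Monotone decreasing from 1
    at x = 0 toward 0.
    """
    rmsd = np.asarray(rmsd, dtype=float)
    if np.any(rmsd < 0) or r0 <= 0:
        raise ValueError("rmsd must be nonnegative and r0 positive")
    x4 = (rmsd / r0) ** 4
    out = (1.0 + x4) / (1.0 + x4 + x4 * x4)
    return float(out) if out.ndim == 0 else out


def salpha(ca_coords: np.ndarray, config: SalphaConfig | None = None) -> float:
    """S_alpha of one frame given its C-alpha coordinates (n_residues, 3) nm."""
    cfg = config or SalphaConfig()
    ca = np.asarray(ca_coords, dtype=float)
    n_res = ca.shape[0]
    if n_res < cfg.window:
        raise ValueError(f"need >= {cfg.window} residues for one window")
    if not np.isfinite(ca).all():
        raise ValueError("missing/non-finite C-alpha coordinates")
    template = _ideal_helix_template(cfg.window)
    windows = np.stack([ca[i:i + cfg.window] for i in range(n_res - cfg.window + 1)])
    rmsd_nm = geom.kabsch_rmsd_many(template, windows)
    return float(salpha_term(rmsd_nm, cfg.r0_nm).sum())


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration (nm) of the given atoms."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need >= 2 atoms for a radius of gyration")
    m = np.asarray(masses, dtype=float)
    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    d2 = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt((m * d2).sum() / m.sum()))


def _helicity_from_dihedrals(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Per-residue helicity indicator; NaN where phi or psi is undefined."""
    ok = np.isfinite(phi) & np.isfinite(psi)
    in_window = (ok
                 & (phi > HELIX_PHI[0]) & (phi < HELIX_PHI[1])
                 & (psi > HELIX_PSI[0]) & (psi < HELIX_PSI[1]))
    helical = np.zeros(phi.shape[0])
    run = 0
    for i in range(phi.shape[0] + 1):
        if i < phi.shape[0] and in_window[i]:
            run += 1
        else:
            if run >= MIN_HELIX_RUN:
                helical[i - run:i] = 1.0
            run = 0
    helical[~ok] = np.nan
    return helical


def helical_fraction(N: np.ndarray, CA: np.ndarray,
                     C: np.ndarray) -> tuple[float, np.ndarray]:
    """Fraction of assignable residues in helical dihedral runs (>= 4 long).

    Chain termini lacking a full phi/psi pair are excluded from the
    denominator.  Returns (fraction, per-residue indicators with NaN at
    termini).
    """
    phi, psi = geom.backbone_dihedrals(N, CA, C)
    ind = _helicity_from_dihedrals(phi, psi)
    assignable = np.isfinite(ind)
    if not assignable.any():
        raise ValueError("no residue has a complete phi/psi pair")
    return float(np.nansum(ind) / assignable.sum()), ind


def _backbone_ids(ensemble: Ensemble, name: str) -> np.ndarray:
    ids = select_atoms(ensemble, atom_names={name}, ligand=False)
    top = ensemble.topology
    protein_res = top.protein_residue_indices()
    if ids.size != protein_res.size:
        missing = set(protein_res.tolist()) - set(top.atom_residue[ids].tolist())
        raise ValueError(f"residues missing backbone atom {name}: {sorted(missing)}")
    return ids


def frame_descriptors(ensemble: Ensemble, rg_selection: str = "heavy",
                      config: SalphaConfig | None = None) -> FrameDescriptors:
    """S_alpha, Rg and helical fraction for every frame of an ensemble.

    ``rg_selection`` is ``"heavy"`` (mass-weighted protein heavy atoms,
    default) or ``"ca"`` (C-alpha only).
    """
    top = ensemble.topology
    ca_ids = _backbone_ids(ensemble, "CA")
    n_ids = _backbone_ids(ensemble, "N")
    c_ids = _backbone_ids(ensemble, "C")
    if rg_selection == "ca":
        rg_ids = ca_ids
    elif rg_selection == "heavy":
        rg_ids = select_atoms(ensemble, heavy_only=True, ligand=False)
    else:
        raise ValueError("rg_selection must be 'heavy' or 'ca'")
    masses = top.masses[rg_ids]

    n_frames = ensemble.n_frames
    sal = np.empty(n_frames)
    rg = np.empty(n_frames)
    hf = np.empty(n_frames)
    res_h = np.empty((n_frames, ca_ids.size))
    for f in range(n_frames):
        xyz = ensemble.coordinates[f]
        sal[f] = salpha(xyz[ca_ids], config)
        rg[f] = radius_of_gyration(xyz[rg_ids], masses)
        hf[f], res_h[f] = helical_fraction(xyz[n_ids], xyz[ca_ids], xyz[c_ids])
    return FrameDescriptors(salpha=sal, rg=rg, helical_fraction=hf,
                            residue_helicity=res_h,
                            frame_weights=ensemble.frame_weights)
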