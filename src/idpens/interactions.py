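"""Geometric classification of protein-ligand and intramolecular
interactions.

Classes and their (inclusive) cutoffs:

* contact            any heavy-heavy pair within 6.0 A
* hydrophobic        protein C to ligand C or Cl within 4.0 A
* hydrogen bond      donor-hydrogen to acceptor within 3.5 A and
                     donor-hydrogen-acceptor angle > 150 deg
* parallel stacking  ring-centroid separation R < 6.5 A, inter-normal angle
                     theta < 60 deg, normal-to-centroid angle phi < 45 deg
* T stacking         R < 7.5 A, theta > 75 deg, phi < 45 deg

Ring normals carry an arbitrary sign, so theta and phi are folded to
[0, 90] deg via absolute dot products.  All classifications are invariant
under global rigid motion of a frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .io import Ensemble, Topology

NM = 0.1   # nm per Angstrom


@dataclass(frozen=True)
class InteractionCutoffs:
    """All cutoffs in nm / degrees; defaults are the canonical values."""
    contact: float = 6.0 * NM
    hydrophobic: float = 4.0 * NM
    hbond_distance: float = 3.5 * NM
    hbond_angle: float = 150.0
    parallel_r: float = 6.5 * NM
    parallel_theta: float = 60.0
    t_stack_r: float = 7.5 * NM
    t_stack_theta: float = 75.0
    stack_phi: float = 45.0


DEFAULT_CUTOFFS = InteractionCutoffs()


@dataclass
class RingGeometry:
    """Pairwise aromatic ring geometry (angles folded to [0, 90] deg)."""
    centroid_a: np.ndarray
    centroid_b: np.ndarray
    normal_a: np.ndarray
    normal_b: np.ndarray
    r: float            # centroid separation, nm
    theta: float        # inter-normal angle, deg
    phi: float          # angle between normal_a and the centroid vector, deg


@dataclass
class InteractionProfile:
    """Per-residue interaction populations for one (sub)ensemble."""
    residue_numbers: list[int]
    populations: pd.DataFrame   # columns: contact, hydrophobic, hbond, parallel, t_stack
    n_frames: int
    label: str = ""


def _pair_within(xa: np.ndarray, xb: np.ndarray, cutoff: float) -> bool:
    if xa.size == 0 or xb.size == 0:
        return False
    return bool((cdist(xa, xb) <= cutoff).any())


def residue_contact(frame: np.ndarray, topology: Topology, residue: int,
                    partner_atoms: np.ndarray,
                    cutoff: float = DEFAULT_CUTOFFS.contact) -> bool:
    """True iff any heavy atom of *residue* is within *cutoff* of any heavy
    partner atom (inclusive)."""
    heavy = topology.heavy
    res_ids = np.nonzero((topology.atom_residue == residue) & heavy)[0]
    partner_atoms = np.asarray(partner_atoms)
    partner_atoms = partner_atoms[heavy[partner_atoms]]
    if res_ids.size == 0 or partner_atoms.size == 0:
        raise ValueError("contact test requires non-empty heavy atom sets")
    return _pair_within(frame[res_ids], frame[partner_atoms], cutoff)


def bound_frames(ensemble: Ensemble,
                 cutoff: float = DEFAULT_CUTOFFS.contact) -> np.ndarray:
    """Per-frame flag: at least one protein-ligand heavy-atom pair within
    the contact cutoff."""
    top = ensemble.topology
    lig = top.ligand_mask & top.heavy
    prot = ~top.ligand_mask & top.heavy
    if not lig.any():
        raise ValueError("ensemble has no ligand heavy atoms")
    li, pi = np.nonzero(lig)[0], np.nonzero(prot)[0]
    out = np.empty(ensemble.n_frames, dtype=bool)
    for f in range(ensemble.n_frames):
        out[f] = _pair_within(ensemble.coordinates[f][li],
                              ensemble.coordinates[f][pi], cutoff)
    return out


def bound_fraction(ensemble: Ensemble,
                   cutoff: float = DEFAULT_CUTOFFS.contact) -> float:
    """Weighted share of bound frames."""
    flags = bound_frames(ensemble, cutoff)
    return float(ensemble.frame_weights @ flags)


def hydrophobic_contact(frame: np.ndarray, topology: Topology, residue: int,
                        ligand_atoms: np.ndarray | None = None,
                        cutoff: float = DEFAULT_CUTOFFS.hydrophobic) -> bool:
    """True iff a protein carbon of *residue* is within *cutoff* of a ligand
    carbon or chlorine."""
    elements = np.array(topology.elements)
    res_c = np.nonzero((topology.atom_residue == residue)
                       & (elements == "C"))[0]
    if ligand_atoms is None:
        ligand_atoms = np.nonzero(topology.ligand_mask)[0]
    ligand_atoms = np.asarray(ligand_atoms)
    lig_ccl = ligand_atoms[np.isin(elements[ligand_atoms], ("C", "CL"))]
    return _pair_within(frame[res_c], frame[lig_ccl], cutoff)


def hydrogen_bonds(frame: np.ndarray, topology: Topology,
                   donors: np.ndarray | None = None,
                   acceptors: np.ndarray | None = None,
                   cutoffs: InteractionCutoffs = DEFAULT_CUTOFFS
                   ) -> list[tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triples satisfying the H-bond
    criterion; donor and acceptor in the same residue are excluded."""
    if donors is None:
        donors = np.nonzero(topology.donor)[0]
    if acceptors is None:
        acceptors = np.nonzero(topology.acceptor)[0]
    out = []
    for d in np.asarray(donors):
        hyds = topology.hydrogen_links.get(int(d), [])
        if not hyds:
            raise ValueError(f"donor atom {d} has no attached hydrogen")
        for h in hyds:
            for a in np.asarray(acceptors):
                if a == d or (topology.atom_residue[a]
                              == topology.atom_residue[d]):
                    continue
                ha = frame[a] - frame[h]
                dist = np.linalg.norm(ha)
                if dist > cutoffs.hbond_distance:
                    continue
                hd = frame[d] - frame[h]
                cosang = np.dot(hd, ha) / (np.linalg.norm(hd) * dist)
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if angle > cutoffs.hbond_angle:
                    out.append((int(d), int(h), int(a)))
    return out


def ring_geometry(frame: np.ndarray, ring_a: np.ndarray,
                  ring_b: np.ndarray) -> RingGeometry:
    """Centroids, best-fit plane normals (smallest principal axis), and the
    folded R/theta/phi descriptors for a ring pair.  ``ring_a`` is the
    protein ring whose normal defines phi."""
    def centroid_normal(ids):
        xyz = frame[np.asarray(ids)]
        c = xyz.mean(axis=0)
        centered = xyz - c
        _, s, vt = np.linalg.svd(centered)
        if s[1] < 1e-10:
            raise ValueError("degenerate (collinear) ring atoms")
        return c, vt[2]

    ca, na = centroid_normal(ring_a)
    cb, nb = centroid_normal(ring_b)
    rvec = cb - ca
    r = float(np.linalg.norm(rvec))
    theta = float(np.degrees(np.arccos(np.clip(abs(np.dot(na, nb)), 0, 1))))
    if r < 1e-12:
        phi = 0.0
    else:
        phi = float(np.degrees(np.arccos(
            np.clip(abs(np.dot(na, rvec / r)), 0, 1))))
    return RingGeometry(ca, cb, na, nb, r, theta, phi)


def classify_stacking(geometry: RingGeometry,
                      cutoffs: InteractionCutoffs = DEFAULT_CUTOFFS) -> str:
    """'parallel', 't_stack', or 'none'.  The two classes are mutually
    exclusive (theta cannot be < 60 and > 75 simultaneously)."""
    if (geometry.r < cutoffs.parallel_r
            and geometry.theta < cutoffs.parallel_theta
            and geometry.phi < cutoffs.stack_phi):
        return "parallel"
    if (geometry.r < cutoffs.t_stack_r
            and geometry.theta > cutoffs.t_stack_theta
            and geometry.phi < cutoffs.stack_phi):
        return "t_stack"
    return "none"


CLASSES = ("contact", "hydrophobic", "hbond", "parallel", "t_stack")


def interaction_profile(ensemble: Ensemble,
                        reference_atoms: np.ndarray | None = None,
                        frame_subset: np.ndarray | None = None,
                        cutoffs: InteractionCutoffs = DEFAULT_CUTOFFS,
                        label: str = "") -> InteractionProfile:
    """Per-residue populations of each interaction class against a reference
    group (default: the ligand) over a weighted frame subset.

    Stacking classes are evaluated between every protein ring group and
    every reference-group ring; the population is booked to the residue
    holding the protein ring.  H-bond populations are booked to the protein
    residue of the donor or acceptor partner.
    """
    top = ensemble.topology
    if reference_atoms is None:
        reference_atoms = np.nonzero(top.ligand_mask)[0]
    reference_atoms = np.asarray(reference_atoms)
    if reference_atoms.size == 0:
        raise ValueError("empty reference group")
    if frame_subset is None:
        frame_subset = np.arange(ensemble.n_frames)
    frame_subset = np.asarray(frame_subset)
    if frame_subset.size == 0:
        raise ValueError("empty frame subset")
    w = ensemble.frame_weights[frame_subset]
    w = w / w.sum()

    elements = np.array(top.elements)
    heavy = top.heavy
    ref_set = set(reference_atoms.tolist())
    ref_heavy = reference_atoms[heavy[reference_atoms]]
    ref_ccl = reference_atoms[np.isin(elements[reference_atoms], ("C", "CL"))]
    ref_donors = [d for d in np.nonzero(top.donor)[0] if d in ref_set]
    ref_acceptors = [a for a in np.nonzero(top.acceptor)[0] if a in ref_set]
    ref_rings = [ids for ids in top.ring_groups.values()
                 if set(ids) <= ref_set]

    prot_res = [r for r in top.protein_residue_indices()
                if not any(a in ref_set
                           for a in np.nonzero(top.atom_residue == r)[0])]
    res_heavy = {r: np.nonzero((top.atom_residue == r) & heavy)[0]
                 for r in prot_res}
    res_c = {r: np.nonzero((top.atom_residue == r) & (elements == "C"))[0]
             for r in prot_res}
    res_rings = {r: [ids for ids in top.ring_groups.values()
                     if not set(ids) <= ref_set
                     and top.atom_residue[ids[0]] == r]
                 for r in prot_res}

    pop = {cls: np.zeros(len(prot_res)) for cls in CLASSES}
    for fi, f in enumerate(frame_subset):
        xyz = ensemble.coordinates[f]
        hb = hydrogen_bonds(xyz, top, cutoffs=cutoffs)
        hb_res = set()
        for d, _, a in hb:
            if d in ref_set and a not in ref_set:
                hb_res.add(int(top.atom_residue[a]))
            elif a in ref_set and d not in ref_set:
                hb_res.add(int(top.atom_residue[d]))
        for ri, r in enumerate(prot_res):
            if _pair_within(xyz[res_heavy[r]], xyz[ref_heavy], cutoffs.contact):
                pop["contact"][ri] += w[fi]
            if _pair_within(xyz[res_c[r]], xyz[ref_ccl], cutoffs.hydrophobic):
                pop["hydrophobic"][ri] += w[fi]
            if r in hb_res:
                pop["hbond"][ri] += w[fi]
            kinds = set()
            for pring in res_rings[r]:
                for lring in ref_rings:
                    kinds.add(classify_stacking(
                        ring_geometry(xyz, pring, lring), cutoffs))
            if "parallel" in kinds:
                pop["parallel"][ri] += w[fi]
            if "t_stack" in kinds:
                pop["t_stack"][ri] += w[fi]
    df = pd.DataFrame(pop, index=[top.residue_numbers[r] for r in prot_res])
    return InteractionProfile(
        residue_numbers=[top.residue_numbers[r] for r in prot_res],
        populations=df, n_frames=int(frame_subset.size), label=label)


def profile_r2(profile_a: InteractionProfile, profile_b: InteractionProfile,
               interaction_class: str = "contact") -> float:
    """Squared Pearson correlation between two per-residue population
    vectors; NaN (with a warning) when either vector has zero variance."""
    a = profile_a.populations[interaction_class].to_numpy()
    b = profile_b.populations[interaction_class].to_numpy()
    if a.shape != b.shape:
        raise ValueError("profiles have different residue support")
    if np.std(a) == 0 or np.std(b) == 0:
        import warnings
        warnings.warn("zero-variance profile; r^2 undefined", stacklevel=2)
        return float("nan")
    return float(pearsonr(a, b).statistic ** 2)


def contact_map(ensemble: Ensemble, frame_subset: np.ndarray | None = None,
                cutoff: float = DEFAULT_CUTOFFS.contact,
                exclude_neighbors: int = 2) -> pd.DataFrame:
    """Intramolecular residue-residue contact populations (heavy-atom 6 A
    rule), excluding sequence neighbors |i - j| <= exclude_neighbors."""
    top = ensemble.topology
    if frame_subset is None:
        frame_subset = np.arange(ensemble.n_frames)
    frame_subset = np.asarray(frame_subset)
    w = ensemble.frame_weights[frame_subset]
    w = w / w.sum()
    res = top.protein_residue_indices()
    res_heavy = {r: np.nonzero((top.atom_residue == r) & top.heavy)[0]
                 for r in res}
    n = res.size
    pop = np.zeros((n, n))
    for fi, f in enumerate(frame_subset):
        xyz = ensemble.coordinates[f]
        for i in range(n):
            for j in range(i + 1, n):
                if abs(int(res[i]) - int(res[j])) <= exclude_neighbors:
                    continue
                if _pair_within(xyz[res_heavy[res[i]]],
                                xyz[res_heavy[res[j]]], cutoff):
                    pop[i, j] += w[fi]
                    pop[j, i] += w[fi]
    labels = [top.residue_numbers[r] for r in res]
    return pd.DataFrame(pop, index=labels, columns=labels)
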