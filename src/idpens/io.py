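"""Core data model and file I/O for conformational ensembles.

An :class:`Ensemble` couples a frames x atoms x 3 coordinate block (nm) with
a :class:`Topology` carrying the chemical annotations the coordinates cannot
supply: elements, hydrogen-bond donor/acceptor flags, hydrophobic flags, and
aromatic ring atom groups (including ligand moieties).  The topology is a
sidecar file (JSON), never inferred from PDB heuristics.

On-disk formats are plain text: multi-model PDB (one MODEL per frame),
JSON topology descriptor, and delimited observable/report tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "CL": 35.45,
}

NM_PER_ANGSTROM = 0.1


class TopologyError(ValueError):
    """Raised when a topology annotation is inconsistent."""


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


class EmptySelectionError(ValueError):
    """Raised (or caught by callers) when an atom selection matches nothing."""


@dataclass
class Topology:
    """Residue/atom annotations for one molecular system.

    ``residue_numbers`` are author-facing (e.g. AR 391-446); all internal
    indexing is 0-based positional.  ``hydrogen_links[i]`` lists the hydrogen
    atom ids attached to heavy atom i (needed for donor geometry).
    """

    residue_numbers: list[int]
    residue_names: list[str]
    atom_names: list[str]
    atom_residue: np.ndarray          # (n_atoms,) internal residue index
    elements: list[str]               # upper-case element symbols
    donor: np.ndarray                 # (n_atoms,) bool
    acceptor: np.ndarray              # (n_atoms,) bool
    hydrophobic: np.ndarray           # (n_atoms,) bool
    hydrogen_links: dict[int, list[int]] = field(default_factory=dict)
    ring_groups: dict[str, list[int]] = field(default_factory=dict)
    ligand_atoms: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.atom_residue = np.asarray(self.atom_residue, dtype=int)
        self.donor = np.asarray(self.donor, dtype=bool)
        self.acceptor = np.asarray(self.acceptor, dtype=bool)
        self.hydrophobic = np.asarray(self.hydrophobic, dtype=bool)
        self.validate()

    # -- derived views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)

    @property
    def heavy(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[e] for e in self.elements])

    @property
    def ligand_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_atoms, dtype=bool)
        mask[list(self.ligand_atoms)] = True
        return mask

    def protein_residue_indices(self) -> np.ndarray:
        """Residue indices holding at least one non-ligand atom."""
        lig = self.ligand_mask
        return np.unique(self.atom_residue[~lig])

    def validate(self) -> None:
        n = self.n_atoms
        if not (len(self.elements) == n and self.atom_residue.shape[0] == n):
            raise TopologyError("atom annotation arrays disagree in length")
        if self.atom_residue.size and (
                self.atom_residue.min() < 0
                or self.atom_residue.max() >= self.n_residues):
            raise TopologyError("atom residue index out of range")
        heavy = self.heavy
        for i in np.nonzero(self.donor)[0]:
            if self.elements[i] not in ("N", "O", "S"):
                raise TopologyError(f"donor atom {i} is not N/O/S")
            if not self.hydrogen_links.get(int(i)):
                raise TopologyError(f"donor atom {i} has no attached hydrogen")
        for i in np.nonzero(self.acceptor)[0]:
            if self.elements[i] not in ("N", "O", "S"):
                raise TopologyError(f"acceptor atom {i} is not N/O/S")
        for name, ids in self.ring_groups.items():
            if len(ids) < 3:
                raise TopologyError(f"ring group {name!r} has < 3 atoms")
            if not all(heavy[j] for j in ids):
                raise TopologyError(f"ring group {name!r} contains hydrogen")


@dataclass
class Ensemble:
    """A conformational ensemble: shared topology, per-frame coordinates (nm),
    and normalized per-frame weights (uniform unless reweighted)."""

    topology: Topology
    coordinates: np.ndarray           # (n_frames, n_atoms, 3) nm
    frame_weights: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError("coordinate block does not match topology")
        if self.frame_weights is None:
            self.frame_weights = np.full(self.n_frames, 1.0 / self.n_frames)
        else:
            w = np.asarray(self.frame_weights, dtype=float)
            if w.shape != (self.n_frames,) or (w < 0).any():
                raise ValueError("frame_weights must be nonnegative per frame")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("frame_weights must sum to 1")
            self.frame_weights = w

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def subset(self, frames: np.ndarray, renormalize: bool = True) -> "Ensemble":
        frames = np.asarray(frames)
        w = self.frame_weights[frames]
        if renormalize:
            w = w / w.sum()
        return replace(self, coordinates=self.coordinates[frames],
                       frame_weights=w)

    def with_weights(self, weights: np.ndarray) -> "Ensemble":
        return replace(self, frame_weights=np.asarray(weights, dtype=float))


@dataclass
class ObservableTable:
    """Per-frame observables with experimental targets and uncertainties."""

    values: np.ndarray                # (n_frames, n_obs)
    targets: np.ndarray               # (n_obs,)
    uncertainties: np.ndarray         # (n_obs,) > 0
    labels: list[str]

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.targets = np.asarray(self.targets, dtype=float)
        self.uncertainties = np.asarray(self.uncertainties, dtype=float)
        n_obs = self.values.shape[1]
        if not (self.targets.shape[0] == n_obs
                and self.uncertainties.shape[0] == n_obs
                and len(self.labels) == n_obs):
            raise ValueError("observable table columns disagree")
        if (self.uncertainties <= 0).any():
            raise ValueError("uncertainties must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def subset(self, columns: np.ndarray) -> "ObservableTable":
        columns = np.asarray(columns)
        return ObservableTable(self.values[:, columns], self.targets[columns],
                               self.uncertainties[columns],
                               [self.labels[int(c)] for c in columns])


# ---------------------------------------------------------------------------
# Topology descriptor (JSON sidecar)
# ---------------------------------------------------------------------------

def write_topology(topology: Topology, path) -> None:
    doc = {
        "residue_numbers": list(map(int, topology.residue_numbers)),
        "residue_names": list(topology.residue_names),
        "atom_names": list(topology.atom_names),
        "atom_residue": topology.atom_residue.tolist(),
        "elements": list(topology.elements),
        "donor": topology.donor.astype(int).tolist(),
        "acceptor": topology.acceptor.astype(int).tolist(),
        "hydrophobic": topology.hydrophobic.astype(int).tolist(),
        "hydrogen_links": {str(k): v for k, v in topology.hydrogen_links.items()},
        "ring_groups": topology.ring_groups,
        "ligand_atoms": list(map(int, topology.ligand_atoms)),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_topology(path) -> Topology:
    with open(path) as fh:
        doc = json.load(fh)
    return Topology(
        residue_numbers=doc["residue_numbers"],
        residue_names=doc["residue_names"],
        atom_names=doc["atom_names"],
        atom_residue=np.array(doc["atom_residue"]),
        elements=doc["elements"],
        donor=np.array(doc["donor"], dtype=bool),
        acceptor=np.array(doc["acceptor"], dtype=bool),
        hydrophobic=np.array(doc["hydrophobic"], dtype=bool),
        hydrogen_links={int(k): v for k, v in doc["hydrogen_links"].items()},
        ring_groups=doc["ring_groups"],
        ligand_atoms=doc["ligand_atoms"],
    )


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------

def write_multimodel_pdb(ensemble: Ensemble, path) -> None:
    """One MODEL per frame; ligand atoms as HETATM LIG records."""
    top = ensemble.topology
    lig = top.ligand_mask
    with open(path, "w") as fh:
        for m in range(ensemble.n_frames):
            fh.write(f"MODEL     {m + 1:4d}\n")
            xyz = ensemble.coordinates[m] / NM_PER_ANGSTROM
            for a in range(top.n_atoms):
                ri = int(top.atom_residue[a])
                rec = "HETATM" if lig[a] else "ATOM  "
                name = top.atom_names[a]
                # PDB atom-name column convention: 1-letter elements indented
                name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
                elem = top.elements[a]
                fh.write(
                    f"{rec}{a + 1:5d} {name_field}"
                    f" {top.residue_names[ri][:3]:>3s} A"
                    f"{top.residue_numbers[ri]:4d}    "
                    f"{xyz[a, 0]:8.3f}{xyz[a, 1]:8.3f}{xyz[a, 2]:8.3f}"
                    f"  1.00  0.00          {elem:>2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_multimodel_pdb(path, topology_path) -> Ensemble:
    """Read a multi-model PDB against its sidecar topology.

    Coordinates are converted Angstrom -> nm; every model must carry exactly
    the topology's atom count in topology order.
    """
    topology = read_topology(topology_path)
    frames: list[np.ndarray] = []
    current: list[list[float]] | None = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                current = []
            elif line.startswith(("ATOM", "HETATM")):
                if current is None:     # single-model file without MODEL card
                    current = []
                current.append([float(line[30:38]), float(line[38:46]),
                                float(line[46:54])])
            elif line.startswith("ENDMDL"):
                frames.append(np.array(current))
                current = None
    if current:
        frames.append(np.array(current))
    if not frames:
        raise FormatError(f"no coordinate models found in {path}")
    n_atoms = {f.shape[0] for f in frames}
    if len(n_atoms) != 1:
        raise FormatError(
            f"models with unequal atom counts in {path}: {sorted(n_atoms)}")
    if frames[0].shape[0] != topology.n_atoms:
        raise FormatError(
            f"model atom count {frames[0].shape[0]} does not match topology "
            f"({topology.n_atoms})")
    coords = np.stack(frames) * NM_PER_ANGSTROM
    return Ensemble(topology=topology, coordinates=coords, provenance=str(path))


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

def select_atoms(ensemble_or_topology, residue_range: tuple[int, int] | None = None,
                 atom_names: set[str] | None = None, heavy_only: bool = False,
                 ligand: bool | None = None) -> np.ndarray:
    """Stable ordered atom-id selection.

    ``residue_range`` is an inclusive (lo, hi) pair of author-facing residue
    numbers.  ``ligand=True/False`` restricts to ligand / protein atoms.
    Raises :class:`EmptySelectionError` when nothing matches.
    """
    top = getattr(ensemble_or_topology, "topology", ensemble_or_topology)
    mask = np.ones(top.n_atoms, dtype=bool)
    if residue_range is not None:
        lo, hi = residue_range
        numbers = np.array([top.residue_numbers[i] for i in top.atom_residue])
        mask &= (numbers >= lo) & (numbers <= hi)
    if atom_names is not None:
        names = set(atom_names)
        mask &= np.array([n in names for n in top.atom_names])
    if heavy_only:
        mask &= top.heavy
    if ligand is not None:
        mask &= top.ligand_mask if ligand else ~top.ligand_mask
    ids = np.nonzero(mask)[0]
    if ids.size == 0:
        raise EmptySelectionError("selection matched no atoms")
    return ids


# ---------------------------------------------------------------------------
# Observable tables and reports
# ---------------------------------------------------------------------------

def write_observables(table: ObservableTable, path) -> None:
    df = pd.DataFrame(table.values, columns=table.labels)
    header = pd.DataFrame([table.targets, table.uncertainties],
                          columns=table.labels,
                          index=["#target", "#uncertainty"])
    pd.concat([header, df]).to_csv(path, index_label="frame")


def read_observables(path) -> ObservableTable:
    df = pd.read_csv(path, index_col=0)
    targets = df.loc["#target"].to_numpy(dtype=float)
    sigma = df.loc["#uncertainty"].to_numpy(dtype=float)
    values = df.drop(index=["#target", "#uncertainty"]).to_numpy(dtype=float)
    return ObservableTable(values, targets, sigma, list(df.columns))


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(results: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write an analysis table as delimited text with '#'-prefixed metadata
    lines (seed, version, config hash) that round-trip losslessly."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        results.to_csv(fh, index=False, sep="\t", lineterminator="\n")


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
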