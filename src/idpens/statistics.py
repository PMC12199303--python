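"""Ensemble statistics: free-energy surfaces, helical-globule populations,
blocking-analysis error bars, and subensemble summaries.

Free energies are relative, in units of kT (the temperature is absorbed:
F = -ln p, shifted so the occupied minimum is 0).  Statistical errors on
ensemble averages use Flyvbjerg-Petersen reblocking: block means are formed
by recursively averaging adjacent pairs, the standard error is estimated at
every blocking level together with its own uncertainty, and the first level
where the estimate plateaus within that uncertainty is selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .interactions import bound_frames
from .io import Ensemble
from .order_parameters import FrameDescriptors


@dataclass
class FreeEnergySurface:
    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray      # (nx, ny), NaN in empty bins
    counts: np.ndarray           # weighted probability mass per bin
    occupied: np.ndarray         # bool mask


@dataclass(frozen=True)
class GlobuleCriterion:
    """Helical-globule definition: compact, substantially helical frames.
    Both inequalities are strict."""
    salpha_min: float = 6.0
    rg_max_nm: float = 1.3


@dataclass
class BlockingResult:
    block_sizes: np.ndarray
    se_estimates: np.ndarray
    se_uncertainties: np.ndarray
    optimal_index: int
    se: float
    converged: bool = True


@dataclass
class SubensembleSummary:
    population: float
    population_se: float
    bound_fraction: float | None
    bound_fraction_se: float | None
    globule_population: float
    globule_population_se: float
    helix_fraction: float
    helix_fraction_se: float


def fes2d(x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None,
          bins: int | tuple[int, int] = 40,
          ranges=None) -> FreeEnergySurface:
    """Weighted 2-D free-energy surface F = -ln p with min(F) = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    counts, xe, ye = np.histogram2d(x, y, bins=bins, range=ranges,
                                    weights=weights)
    total = counts.sum()
    if total <= 0:
        raise ValueError("no weight in histogram")
    p = counts / total
    occupied = p > 0
    F = np.full_like(p, np.nan)
    F[occupied] = -np.log(p[occupied])
    F[occupied] -= np.nanmin(F[occupied])
    return FreeEnergySurface(xe, ye, F, p, occupied)


def _block_se(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Weighted SE of the mean from block means plus its own uncertainty."""
    nb = values.shape[0]
    W = weights.sum()
    mean = float((weights * values).sum() / W)
    var = ((weights ** 2) * (values - mean) ** 2).sum() / W ** 2
    se = float(np.sqrt(var * nb / max(nb - 1, 1)))
    return se, se / np.sqrt(2.0 * max(nb - 1, 1))


def blocking_error(series: np.ndarray,
                   weights: np.ndarray | None = None) -> BlockingResult:
    """Flyvbjerg-Petersen reblocking SE of the (weighted) series mean.

    Adjacent blocks are pair-averaged up the ladder (block sizes 1, 2, 4,
    ...); the optimal level is the first whose SE estimate agrees with the
    next level within the latter's uncertainty (plateau criterion).  If no
    plateau is found the most conservative (largest-SE) level is reported
    with ``converged=False``.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    if n < 8:
        raise ValueError("blocking needs a series of length >= 8")
    if weights is None:
        weights = np.ones(n)
    else:
        weights = np.asarray(weights, dtype=float)
    wx = weights * series
    w = weights.copy()

    sizes, ses, dses = [], [], []
    block = 1
    while w.shape[0] >= 4:
        means = wx / w
        se, dse = _block_se(means, w)
        sizes.append(block)
        ses.append(se)
        dses.append(dse)
        m = (w.shape[0] // 2) * 2
        wx = wx[:m:2] + wx[1:m:2]
        w = w[:m:2] + w[1:m:2]
        block *= 2
    sizes = np.array(sizes)
    ses = np.array(ses)
    dses = np.array(dses)

    opt = None
    for k in range(len(ses) - 1):
        if abs(ses[k + 1] - ses[k]) <= dses[k + 1]:
            opt = k
            break
    converged = opt is not None
    if opt is None:
        opt = int(np.argmax(ses))
    return BlockingResult(sizes, ses, dses, int(opt), float(ses[opt]),
                          converged)


def globule_population(descriptors: FrameDescriptors,
                       weights: np.ndarray | None = None,
                       criterion: GlobuleCriterion = GlobuleCriterion()
                       ) -> tuple[float, float]:
    """Weighted helical-globule population p_Glob with its blocking SE."""
    ind = ((descriptors.salpha > criterion.salpha_min)
           & (descriptors.rg < criterion.rg_max_nm)).astype(float)
    if weights is None:
        weights = (descriptors.frame_weights
                   if descriptors.frame_weights is not None
                   else np.full(ind.shape[0], 1.0 / ind.shape[0]))
    p = float(np.asarray(weights) @ ind / np.sum(weights))
    se = blocking_error(ind, weights).se if ind.shape[0] >= 8 else float("nan")
    return p, se


def ar1_series(n: int, rho: float, seed: int) -> np.ndarray:
    """Stationary AR(1) series with unit marginal variance (blocking
    fixture)."""
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, np.sqrt(1.0 - rho ** 2), n)
    x = np.empty(n)
    x[0] = rng.normal()
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    return x


def subensemble_summary(ensemble: Ensemble, descriptors: FrameDescriptors,
                        frame_subset: np.ndarray | None = None,
                        has_ligand: bool | None = None,
                        criterion: GlobuleCriterion = GlobuleCriterion()
                        ) -> SubensembleSummary:
    """Population p, bound fraction BF, helical-globule population p_Glob,
    and helix fraction HF of a frame subset, each with a blocking SE.

    p is the subset's weight share of the whole ensemble; the other three
    are weighted averages within the subset.
    """
    w_all = ensemble.frame_weights
    if frame_subset is None:
        frame_subset = np.arange(ensemble.n_frames)
    frame_subset = np.asarray(frame_subset)
    if frame_subset.size == 0:
        raise ValueError("empty frame subset")
    member = np.zeros(ensemble.n_frames)
    member[frame_subset] = 1.0
    p = float(w_all @ member)
    p_se = (blocking_error(member, w_all).se
            if ensemble.n_frames >= 8 else float("nan"))

    w_sub = w_all[frame_subset]
    if has_ligand is None:
        has_ligand = bool(ensemble.topology.ligand_atoms)
    bf = bf_se = None
    if has_ligand:
        flags = bound_frames(ensemble.subset(frame_subset)).astype(float)
        bf = float(w_sub @ flags / w_sub.sum())
        bf_se = (blocking_error(flags, w_sub).se
                 if flags.shape[0] >= 8 else float("nan"))

    sub_desc = FrameDescriptors(
        salpha=descriptors.salpha[frame_subset],
        rg=descriptors.rg[frame_subset],
        helical_fraction=descriptors.helical_fraction[frame_subset],
        residue_helicity=descriptors.residue_helicity[frame_subset],
        frame_weights=w_sub / w_sub.sum())
    pg, pg_se = globule_population(sub_desc, criterion=criterion)
    hf_series = sub_desc.helical_fraction
    hf = float(w_sub @ hf_series / w_sub.sum())
    hf_se = (blocking_error(hf_series, w_sub).se
             if hf_series.shape[0] >= 8 else float("nan"))
    return SubensembleSummary(p, p_se, bf, bf_se, pg, pg_se, hf, hf_se)
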