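"""t-SNE-based conformational clustering with dual-space silhouette model
selection.

Protocol: the all-to-all C-alpha RMSD matrix of a (merged, optionally
downsampled) ensemble is converted to perplexity-calibrated Gaussian
conditionals p(j|i), symmetrized to joints p_ij = (p(j|i) + p(i|j))/(2n),
and embedded in 2-D by gradient-descent minimization of KL(P||Q) with a
Student-t kernel for Q (exact t-SNE; the regime of interest is n <= 10^4).
k-means partitions the embedding; clustering quality is scored by the mean
silhouette in the embedding (S_ld), the mean silhouette under the original
RMSD metric (S_hd), and the integrated score S_i = S_ld * S_hd.  A
hyperparameter scan over (perplexity, N) selects the argmax-S_i model under
a cluster-count constraint.

The silhouette uses the standard normalization s_i = (b_i - a_i) /
max(a_i, b_i), the form consistent with the stated [-1, 1] range;
singleton clusters score 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import _geometry as geom
from .interactions import interaction_profile, profile_r2
from .io import Ensemble, select_atoms
from .order_parameters import frame_descriptors
from .statistics import subensemble_summary


@dataclass
class DistanceMatrix:
    """Symmetric pairwise C-alpha RMSD matrix (nm) with frame provenance."""
    values: np.ndarray
    sources: np.ndarray          # per-frame source label (str)
    frame_indices: np.ndarray    # per-frame original index in its source

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(v) > 1e-9).any() or (v < 0).any():
            raise ValueError("distance matrix must be nonnegative with zero "
                             "diagonal")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ConditionalModel:
    sigma: np.ndarray            # per-point Gaussian bandwidth
    conditional: np.ndarray      # p(j|i), rows sum to 1
    joint: np.ndarray            # p_ij, symmetric, sums to 1
    perplexity: float
    entropy_bits: np.ndarray     # per-row entropy of p(.|i)


@dataclass
class Embedding:
    coordinates: np.ndarray      # (n, 2)
    kl: float
    kl_trace: np.ndarray
    seed: int


@dataclass
class ClusterModel:
    labels: np.ndarray
    n_clusters: int
    perplexity: float
    embedding: Embedding
    silhouette_ld: float
    silhouette_hd: float
    integrated_score: float
    per_point_ld: np.ndarray = field(repr=False, default=None)
    per_point_hd: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def rmsd_matrix(ensembles: list[Ensemble] | Ensemble,
                labels: list[str] | None = None) -> DistanceMatrix:
    """All-to-all C-alpha RMSD (Kabsch superposition, no reflection) over
    the merged frame set of one or more ensembles.

    All ensembles must expose the same number of C-alpha atoms (merges of
    chemically different systems must be restricted to the shared backbone
    by the caller).
    """
    if isinstance(ensembles, Ensemble):
        ensembles = [ensembles]
    if labels is None:
        labels = [e.provenance or f"ensemble{i}"
                  for i, e in enumerate(ensembles)]
    cas, sources, indices = [], [], []
    for lab, ens in zip(labels, ensembles):
        ids = select_atoms(ens, atom_names={"CA"}, ligand=False)
        cas.append(ens.coordinates[:, ids])
        sources.extend([lab] * ens.n_frames)
        indices.extend(range(ens.n_frames))
    n_ca = {c.shape[1] for c in cas}
    if len(n_ca) != 1:
        raise ValueError(f"merged ensembles have unequal C-alpha counts: "
                         f"{sorted(n_ca)}")
    X = np.concatenate(cas)
    X = X - X.mean(axis=1, keepdims=True)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n - 1):
        D[i, i + 1:] = geom.kabsch_rmsd_many(X[i], X[i + 1:])
    D = D + D.T
    return DistanceMatrix(D, np.array(sources), np.array(indices))


def downsample(ensemble: Ensemble, target: int = 5000, seed: int = 0,
               mode: str = "stride") -> tuple[Ensemble, np.ndarray]:
    """Evenly strided (default) or seeded-uniform frame subset of size
    *target*; returns (subset ensemble, selected frame indices)."""
    n = ensemble.n_frames
    if target > n:
        raise ValueError(f"cannot downsample {n} frames to {target}")
    if mode == "stride":
        idx = np.linspace(0, n - 1, target).round().astype(int)
        idx = np.unique(idx)
    elif mode == "random":
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=target, replace=False))
    else:
        raise ValueError("mode must be 'stride' or 'random'")
    return ensemble.subset(idx), idx


# ---------------------------------------------------------------------------
# Perplexity-calibrated conditionals
# ---------------------------------------------------------------------------

def _row_conditional(d2: np.ndarray, beta: float) -> np.ndarray:
    """Conditional distribution for one point at precision beta = 1/(2 s^2)."""
    p = np.exp(-(d2 - d2.min()) * beta)
    return p / p.sum()


def _row_entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def calibrate_conditionals(distances: DistanceMatrix, perplexity: float,
                           tol_bits: float = 1e-5,
                           max_iter: int = 200) -> ConditionalModel:
    """Per-point bandwidths by bisection so each row entropy matches
    log2(perplexity) within *tol_bits*."""
    n = distances.n
    if not 1.0 < perplexity < n:
        raise ValueError("perplexity must lie in (1, n)")
    target = np.log2(perplexity)
    D2 = distances.values ** 2
    P = np.zeros((n, n))
    sigma = np.empty(n)
    entropy = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        d2 = D2[i, idx != i]
        lo, hi = 0.0, np.inf
        beta = 1.0 / max(np.median(d2), 1e-12)
        for _ in range(max_iter):
            p = _row_conditional(d2, beta)
            h = _row_entropy_bits(p)
            if abs(h - target) < tol_bits:
                break
            if h > target:      # too flat -> sharpen
                lo = beta
                beta = beta * 2.0 if np.isinf(hi) else 0.5 * (beta + hi)
            else:
                hi = beta
                beta = 0.5 * (beta + lo)
        P[i, idx != i] = p
        sigma[i] = np.sqrt(1.0 / (2.0 * beta)) if beta > 0 else np.inf
        entropy[i] = h
    joint = (P + P.T) / (2.0 * n)
    return ConditionalModel(sigma, P, joint, perplexity, entropy)


# ---------------------------------------------------------------------------
# Exact t-SNE gradient descent
# ---------------------------------------------------------------------------

def tsne_embed(model: ConditionalModel, seed: int = 0, n_iter: int = 1000,
               learning_rate: float = 200.0,
               momentum: tuple[float, float] = (0.5, 0.8),
               momentum_switch: int = 250,
               early_exaggeration: float = 12.0,
               exaggeration_iter: int = 250) -> Embedding:
    """Minimize KL(P||Q) by momentum gradient descent (exact gradient)."""
    P = model.joint
    n = P.shape[0]
    rng = np.random.default_rng(seed)
    Y = rng.normal(0.0, 1e-4, size=(n, 2))
    V = np.zeros_like(Y)
    trace = np.empty(n_iter)
    eps = 1e-12
    for it in range(n_iter):
        Peff = P * early_exaggeration if it < exaggeration_iter else P
        diff = Y[:, None, :] - Y[None, :, :]
        d2 = (diff ** 2).sum(axis=-1)
        W = 1.0 / (1.0 + d2)
        np.fill_diagonal(W, 0.0)
        Q = W / max(W.sum(), eps)
        PQ = (Peff - Q) * W
        grad = 4.0 * (PQ[:, :, None] * diff).sum(axis=1)
        mom = momentum[0] if it < momentum_switch else momentum[1]
        V = mom * V - learning_rate * grad
        Y = Y + V
        Y = Y - Y.mean(axis=0)
        mask = (P > 0) & (Q > 0)
        kl = float((P[mask] * np.log(P[mask] / Q[mask])).sum())
        if not np.isfinite(kl):
            raise RuntimeError(f"t-SNE diverged at iteration {it}")
        trace[it] = kl
    return Embedding(Y, float(trace[-1]), trace, seed)


# ---------------------------------------------------------------------------
# Partitioning and silhouettes
# ---------------------------------------------------------------------------

def kmeans_partition(embedding: Embedding | np.ndarray, n_clusters: int,
                     seed: int = 0, restarts: int = 10) -> np.ndarray:
    """Best-inertia k-means labels over seeded k-means++ restarts."""
    Y = embedding.coordinates if isinstance(embedding, Embedding) else embedding
    if n_clusters < 2 or n_clusters > Y.shape[0]:
        raise ValueError("need 2 <= N <= n points")
    if np.unique(Y, axis=0).shape[0] < n_clusters:
        raise ValueError("fewer distinct points than clusters")
    km = KMeans(n_clusters=n_clusters, n_init=restarts, random_state=seed)
    return km.fit_predict(Y)


def silhouette_from_distances(labels: np.ndarray,
                              distances: np.ndarray
                              ) -> tuple[np.ndarray, float]:
    """Per-point and mean silhouette s_i = (b_i - a_i)/max(a_i, b_i) from a
    precomputed distance matrix; singleton clusters score 0."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    n = labels.shape[0]
    s = np.zeros(n)
    masks = {c: labels == c for c in uniq}
    sizes = {c: int(m.sum()) for c, m in masks.items()}
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            s[i] = 0.0
            continue
        row = distances[i]
        a = row[masks[c]].sum() / (sizes[c] - 1)
        b = min(row[masks[o]].mean() for o in uniq if o != c)
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return s, float(s.mean())


def _euclidean(Y: np.ndarray) -> np.ndarray:
    d2 = ((Y[:, None, :] - Y[None, :, :]) ** 2).sum(-1)
    return np.sqrt(np.clip(d2, 0.0, None))


def integrated_silhouette(labels: np.ndarray, embedding: Embedding | np.ndarray,
                          distances: DistanceMatrix
                          ) -> tuple[float, float, float]:
    """(S_ld, S_hd, S_i): mean silhouettes in the embedding and under the
    original RMSD metric, and their product.

    Note both means negative would multiply to a positive S_i; such models
    are flagged with a warning and should be rejected on the individual
    scores.
    """
    Y = embedding.coordinates if isinstance(embedding, Embedding) else embedding
    _, s_ld = silhouette_from_distances(labels, _euclidean(Y))
    _, s_hd = silhouette_from_distances(labels, distances.values)
    if s_ld < 0 and s_hd < 0:
        warnings.warn("both silhouettes negative: integrated score positive "
                      "but the clustering is poor", stacklevel=2)
    return s_ld, s_hd, s_ld * s_hd


def cluster_model(distances: DistanceMatrix, perplexity: float,
                  n_clusters: int, seed: int = 0,
                  tsne_kwargs: dict | None = None,
                  restarts: int = 10) -> ClusterModel:
    """Run the full protocol once: calibrate, embed, partition, score."""
    model = calibrate_conditionals(distances, perplexity)
    emb = tsne_embed(model, seed=seed, **(tsne_kwargs or {}))
    labels = kmeans_partition(emb, n_clusters, seed=seed, restarts=restarts)
    pp_ld, s_ld = silhouette_from_distances(labels, _euclidean(emb.coordinates))
    pp_hd, s_hd = silhouette_from_distances(labels, distances.values)
    return ClusterModel(labels, n_clusters, perplexity, emb, s_ld, s_hd,
                        s_ld * s_hd, pp_ld, pp_hd)


def hyperparameter_scan(distances: DistanceMatrix,
                        perplexities: list[float],
                        n_clusters_values: list[int],
                        seed: int = 0,
                        tsne_kwargs: dict | None = None
                        ) -> tuple[ClusterModel, pd.DataFrame]:
    """Scan (perplexity x N), returning the argmax-S_i model and the full
    score table.  Embeddings are shared across N at fixed perplexity."""
    if not perplexities or not n_clusters_values:
        raise ValueError("perplexity and N grids must be non-empty")
    rows = []
    best = None
    for perp in perplexities:
        model = calibrate_conditionals(distances, perp)
        emb = tsne_embed(model, seed=seed, **(tsne_kwargs or {}))
        for N in n_clusters_values:
            labels = kmeans_partition(emb, N, seed=seed)
            pp_ld, s_ld = silhouette_from_distances(labels,
                                                    _euclidean(emb.coordinates))
            pp_hd, s_hd = silhouette_from_distances(labels, distances.values)
            cm = ClusterModel(labels, N, perp, emb, s_ld, s_hd, s_ld * s_hd,
                              pp_ld, pp_hd)
            rows.append({"perplexity": perp, "n_clusters": N,
                         "silhouette_ld": s_ld, "silhouette_hd": s_hd,
                         "integrated_score": cm.integrated_score})
            if best is None or cm.integrated_score > best.integrated_score:
                best = cm
    return best, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-cluster reports
# ---------------------------------------------------------------------------

def cluster_report(ensembles: dict[str, Ensemble], model: ClusterModel,
                   distances: DistanceMatrix) -> pd.DataFrame:
    """Per-cluster, per-source summary table (columns Cluster, source, p,
    BF, p_Glob, HF with blocking SEs).

    Rows where a source has no frames in a cluster carry the explicit
    absence marker '-'.  'merged' rows aggregate all sources; p is the
    cluster's share within each source (and of the merged set).
    """
    desc = {lab: frame_descriptors(ens) for lab, ens in ensembles.items()}
    rows = []
    for cluster in range(model.n_clusters):
        in_cluster = model.labels == cluster
        merged_p = float(in_cluster.mean())
        # merged-set aggregates, weighting every frame equally
        agg = {"p": merged_p, "BF": [], "p_Glob": [], "HF": []}
        for lab, ens in ensembles.items():
            sel = in_cluster & (distances.sources == lab)
            frames = distances.frame_indices[sel]
            if frames.size == 0:
                rows.append({"Cluster": cluster + 1, "source": lab,
                             "p": "-", "BF": "-", "p_Glob": "-", "HF": "-"})
                continue
            summ = subensemble_summary(ens, desc[lab], frames)
            src_total = int((distances.sources == lab).sum())
            p_src = frames.size / src_total
            rows.append({
                "Cluster": cluster + 1, "source": lab,
                "p": round(p_src, 4),
                "BF": (round(summ.bound_fraction, 4)
                       if summ.bound_fraction is not None else "-"),
                "p_Glob": round(summ.globule_population, 4),
                "HF": round(summ.helix_fraction, 4),
            })
            agg["BF"].append((summ.bound_fraction, frames.size))
            agg["p_Glob"].append((summ.globule_population, frames.size))
            agg["HF"].append((summ.helix_fraction, frames.size))

        def pool(pairs):
            pairs = [(v, n) for v, n in pairs if v is not None]
            if not pairs:
                return "-"
            tot = sum(n for _, n in pairs)
            return round(sum(v * n for v, n in pairs) / tot, 4)

        rows.append({"Cluster": cluster + 1, "source": "merged",
                     "p": round(merged_p, 4), "BF": pool(agg["BF"]),
                     "p_Glob": pool(agg["p_Glob"]), "HF": pool(agg["HF"])})
    return pd.DataFrame(rows)


def cluster_profile_r2(ensembles: dict[str, Ensemble], model: ClusterModel,
                       distances: DistanceMatrix,
                       interaction_class: str = "contact") -> pd.DataFrame:
    """Pairwise r^2 between per-source interaction profiles within each
    cluster (sources must carry a ligand/reference group)."""
    rows = []
    labs = list(ensembles)
    for cluster in range(model.n_clusters):
        in_cluster = model.labels == cluster
        profs = {}
        for lab in labs:
            sel = in_cluster & (distances.sources == lab)
            frames = distances.frame_indices[sel]
            if frames.size:
                profs[lab] = interaction_profile(ensembles[lab],
                                                 frame_subset=frames,
                                                 label=f"{lab}/c{cluster + 1}")
        for i, la in enumerate(labs):
            for lb in labs[i + 1:]:
                r2 = (profile_r2(profs[la], profs[lb], interaction_class)
                      if la in profs and lb in profs else float("nan"))
                rows.append({"Cluster": cluster + 1, "source_a": la,
                             "source_b": lb, "class": interaction_class,
                             "r2": r2})
    return pd.DataFrame(rows)
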