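"""Subsampled consensus clustering for behavioural stratification.

Pipeline: standardize features -> Euclidean distances -> locally scaled
Gaussian affinity network over a K x alpha hyper-parameter grid (default
5 x 6 = 30 combinations) -> nested subsampled spectral clustering
aggregated into a consensus matrix per grid point -> the grid point with
the highest mean silhouette width (on consensus dissimilarity) wins ->
the whole selection is repeated over random 80% subsamples of the cohort
and the outer co-clustering proportions define the final consensus
matrix, cut by average-linkage hierarchical clustering into C subgroups.

Cluster-number candidates are ranked by the eigengap of the normalized
graph Laplacian and by an eigenvector rotation cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.cluster.vq import kmeans2
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "StratifyConfig",
    "SimilarityNetwork",
    "ConsensusMatrix",
    "ClusterSolution",
    "standardize",
    "euclidean_distance",
    "affinity_network",
    "spectral_cluster",
    "bootstrap_consensus",
    "silhouette_width",
    "select_best_grid",
    "subsample_consensus",
    "estimate_num_clusters",
]


@dataclass
class StratifyConfig:
    """Hyper-parameters of the consensus-clustering pipeline."""

    k_grid: tuple = (10, 15, 20, 25, 30)
    alpha_grid: tuple = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    n_bootstrap: int = 1000       # inner resamples per grid point
    n_repeats: int = 1000         # outer 80%-subsample repeats
    subsample_fraction: float = 0.8
    inner_subsample: float = 0.8
    candidate_c: tuple = (2, 3, 5)
    linkage_method: str = "average"
    silhouette_basis: str = "consensus"   # or "euclidean"
    seed: int = 0

    def __post_init__(self):
        if not self.k_grid or not self.alpha_grid:
            raise ValueError("k_grid and alpha_grid must be non-empty")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if not (0 < self.inner_subsample <= 1):
            raise ValueError("inner_subsample must lie in (0, 1]")
        if self.n_bootstrap < 1 or self.n_repeats < 1:
            raise ValueError("n_bootstrap and n_repeats must be >= 1")
        if self.silhouette_basis not in ("consensus", "euclidean"):
            raise ValueError("silhouette_basis must be consensus or euclidean")

    @property
    def grid_size(self) -> int:
        return len(self.k_grid) * len(self.alpha_grid)


@dataclass
class SimilarityNetwork:
    weights: np.ndarray
    k_used: int
    alpha_used: float


@dataclass
class ConsensusMatrix:
    """Pairwise co-clustering proportions over resamples."""

    co_cluster: np.ndarray   # proportions in [0, 1]
    co_sampled: np.ndarray   # counts of joint inclusion

    @property
    def dissimilarity(self) -> np.ndarray:
        d = 1.0 - self.co_cluster
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class ClusterSolution:
    labels: np.ndarray       # 1..C per subject
    c_used: int
    mean_silhouette: float
    provenance: list = field(default_factory=list)


def _weights(W) -> np.ndarray:
    return W.weights if isinstance(W, SimilarityNetwork) else np.asarray(W, float)


def standardize(features):
    """Scale each feature to mean 0, sample SD 1 (ddof=1).

    Accepts an array or a DataFrame (returned as the same type).
    """
    is_df = isinstance(features, pd.DataFrame)
    X = features.to_numpy(dtype=float) if is_df else np.asarray(features, float)
    if np.isnan(X).any():
        raise ValueError("missing values are not accepted")
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = (list(features.columns[bad]) if is_df else bad.tolist())
        raise ValueError(f"constant feature(s): {names}")
    Z = (X - X.mean(axis=0)) / sd
    if is_df:
        return pd.DataFrame(Z, index=features.index, columns=features.columns)
    return Z


def euclidean_distance(features) -> np.ndarray:
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, float)
    return squareform(pdist(X, metric="euclidean"))


def affinity_network(dist: np.ndarray, k: int, alpha: float) -> SimilarityNetwork:
    """Locally scaled Gaussian similarity kernel.

    W(i,j) = exp(-d(i,j)^2 / (2 (alpha * eps(i,j))^2)) with the local
    scale eps(i,j) = (mean d(i, K nearest) + mean d(j, K nearest) +
    d(i,j)) / 3. Larger K densifies the network; larger alpha retains
    weaker edges.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if not (1 <= k < n):
        raise ValueError(f"K must lie in [1, {n - 1}], got {k}")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    d = (d + d.T) / 2.0
    d_off = d + np.diag(np.full(n, np.inf))
    knn_mean = np.sort(d_off, axis=1)[:, :k].mean(axis=1)
    eps = (knn_mean[:, None] + knn_mean[None, :] + d) / 3.0
    sigma = alpha * eps
    zero_scale = (sigma <= 0) & (d > 0)
    if np.any(zero_scale):
        raise ValueError("zero local scale with nonzero distance")
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    W[d == 0] = 1.0
    W = (W + W.T) / 2.0
    return SimilarityNetwork(weights=W, k_used=k, alpha_used=alpha)


def _spectral_embedding(W: np.ndarray, n_components: int) -> np.ndarray:
    """First eigenvectors of the symmetric normalized graph Laplacian."""
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    deg = W.sum(axis=1)
    deg[deg <= 0] = 1e-12
    dinv = 1.0 / np.sqrt(deg)
    L = -(W * dinv[:, None]) * dinv[None, :]
    np.fill_diagonal(L, 1.0)
    _, vecs = eigh(L, subset_by_index=(0, n_components - 1))
    return vecs


def spectral_cluster(W, n_clusters: int, rng=None, n_init: int = 3) -> np.ndarray:
    """Normalized spectral clustering of a similarity network.

    Embeds with the C smallest Laplacian eigenvectors (row-normalized)
    and runs k-means with ``n_init`` seeded restarts; deterministic for
    a fixed generator state. Returns labels 1..C.
    """
    W = _weights(W)
    n = W.shape[0]
    if not (2 <= n_clusters < n):
        raise ValueError(f"C must lie in [2, {n - 1}], got {n_clusters}")
    rng = np.random.default_rng(rng)
    U = _spectral_embedding(W, n_clusters)
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = U / norms

    best_labels, best_inertia = None, np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # kmeans2 warns on empty clusters
        for _ in range(n_init):
            seed = int(rng.integers(0, 2**31 - 1))
            centroids, labels = kmeans2(U, n_clusters, minit="++", seed=seed)
            if np.unique(labels).size < n_clusters:
                continue
            inertia = ((U - centroids[labels]) ** 2).sum()
            if inertia < best_inertia:
                best_inertia, best_labels = inertia, labels
    if best_labels is None:
        # degenerate embedding: split deterministically on the Fiedler axis
        ranks = np.argsort(np.argsort(U[:, -1], kind="stable"), kind="stable")
        best_labels = (ranks * n_clusters) // n
    return best_labels.astype(int) + 1


def _cut_consensus(diss: np.ndarray, n_clusters: int, method: str) -> np.ndarray:
    Z = linkage(squareform(diss, checks=False), method=method)
    # cut_tree guarantees exactly n_clusters even with tied merge heights
    return cut_tree(Z, n_clusters=n_clusters).ravel() + 1


def bootstrap_consensus(W, n_clusters: int, n_bootstrap: int,
                        inner_subsample: float = 0.8, rng=None,
                        linkage_method: str = "average",
                        ) -> tuple[ConsensusMatrix, np.ndarray]:
    """Resampled spectral clustering aggregated into a consensus matrix.

    Each resample draws ``inner_subsample`` of the subjects without
    replacement, spectrally clusters the induced sub-network and
    records co-memberships. co_cluster(i,j) is the fraction of
    resamples containing both i and j that cluster them together;
    never-co-sampled pairs are reported and treated as 0. Final labels
    come from average-linkage hierarchical clustering of 1 - co_cluster.
    """
    W = _weights(W)
    n = W.shape[0]
    rng = np.random.default_rng(rng)
    m = int(round(inner_subsample * n))
    m = min(max(m, n_clusters + 1), n)
    co = np.zeros((n, n))
    counts = np.zeros((n, n))
    for _ in range(n_bootstrap):
        if m == n:
            idx = np.arange(n)
        else:
            idx = np.sort(rng.choice(n, size=m, replace=False))
        labels = spectral_cluster(W[np.ix_(idx, idx)], n_clusters, rng)
        same = labels[:, None] == labels[None, :]
        block = np.ix_(idx, idx)
        co[block] += same
        counts[block] += 1.0
    never = (counts == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        warnings.warn(
            f"{int(never.sum()) // 2} subject pair(s) never co-sampled; "
            "their consensus proportion is treated as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(counts > 0, co / np.maximum(counts, 1), 0.0)
    consensus = ConsensusMatrix(co_cluster=prop, co_sampled=counts)
    final = _cut_consensus(consensus.dissimilarity, n_clusters, linkage_method)
    return consensus, final


def silhouette_width(labels: np.ndarray, dissimilarity: np.ndarray) -> float:
    """Mean silhouette width s(i) = (b - a) / max(a, b).

    a is the mean dissimilarity to the subject's own cluster (excluding
    itself), b the smallest mean dissimilarity to any other cluster.
    Singleton clusters score 0, as do points with a = b = 0.
    """
    labels = np.asarray(labels)
    D = np.asarray(dissimilarity, dtype=float)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least two clusters")
    if uniq.size >= labels.size:
        raise ValueError("silhouette undefined with all-singleton clustering")
    n = labels.size
    # mean dissimilarity from every point to every cluster
    sums = np.stack([D[:, labels == c].sum(axis=1) for c in uniq], axis=1)
    sizes = np.array([(labels == c).sum() for c in uniq])
    own = np.searchsorted(uniq, labels)
    s = np.zeros(n)
    for i in range(n):
        k = own[i]
        if sizes[k] == 1:
            continue
        a = sums[i, k] / (sizes[k] - 1)
        other = np.delete(sums[i] / sizes, k)
        b = other.min()
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def select_best_grid(features=None, n_clusters: int = 2,
                     config: StratifyConfig | None = None,
                     dist: np.ndarray | None = None, rng=None,
                     ) -> tuple[ClusterSolution, ConsensusMatrix]:
    """Evaluate every (K, alpha) grid point, keep the best silhouette.

    Runs :func:`bootstrap_consensus` for each of the |K| x |alpha|
    combinations and retains the solution with the highest mean
    silhouette width on consensus dissimilarity. Ties break toward
    smaller K, then smaller alpha.
    """
    config = config or StratifyConfig()
    if dist is None:
        if features is None:
            raise ValueError("provide features or a distance matrix")
        dist = euclidean_distance(standardize(features))
    rng = np.random.default_rng(config.seed if rng is None else rng)
    best = None
    best_consensus = None
    provenance = []
    for k in sorted(config.k_grid):
        for alpha in sorted(config.alpha_grid):
            try:
                W = affinity_network(dist, k, alpha)
                consensus, labels = bootstrap_consensus(
                    W, n_clusters, config.n_bootstrap,
                    inner_subsample=config.inner_subsample, rng=rng,
                    linkage_method=config.linkage_method)
                basis = (consensus.dissimilarity
                         if config.silhouette_basis == "consensus" else dist)
                sil = silhouette_width(labels, basis)
            except ValueError as err:
                raise ValueError(f"grid point K={k}, alpha={alpha}: {err}") from err
            provenance.append({"K": k, "alpha": alpha, "silhouette": sil})
            if best is None or sil > best.mean_silhouette:
                best = ClusterSolution(labels=labels, c_used=n_clusters,
                                       mean_silhouette=sil,
                                       provenance=[{"K": k, "alpha": alpha}])
                best_consensus = consensus
    best.provenance.extend(provenance)
    return best, best_consensus


def subsample_consensus(features, n_clusters: int,
                        config: StratifyConfig | None = None,
                        ) -> tuple[ConsensusMatrix, ClusterSolution]:
    """Outer consensus over repeated 80% subsamples of the cohort.

    Each repeat runs the full grid selection on a random subsample;
    winning labels accumulate into the outer consensus matrix, which is
    cut by average-linkage hierarchical clustering into the final
    subgroups.
    """
    config = config or StratifyConfig()
    X = standardize(features)
    D = euclidean_distance(X)
    n = D.shape[0]
    m = int(round(config.subsample_fraction * n))
    m = min(max(m, n_clusters + 1), n)
    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(config.n_repeats + 1)]
    sampler = streams[-1]

    co = np.zeros((n, n))
    counts = np.zeros((n, n))
    provenance = []
    for rep in range(config.n_repeats):
        idx = (np.arange(n) if m == n
               else np.sort(sampler.choice(n, size=m, replace=False)))
        sol, _ = select_best_grid(n_clusters=n_clusters, config=config,
                                  dist=D[np.ix_(idx, idx)], rng=streams[rep])
        same = sol.labels[:, None] == sol.labels[None, :]
        block = np.ix_(idx, idx)
        co[block] += same
        counts[block] += 1.0
        chosen = sol.provenance[0]
        provenance.append({"repeat": rep, "K": chosen["K"],
                           "alpha": chosen["alpha"],
                           "silhouette": sol.mean_silhouette})
    if np.any(np.diag(counts) == 0):
        missing = np.flatnonzero(np.diag(counts) == 0)
        raise RuntimeError(
            f"subject(s) {missing.tolist()} never sampled across repeats; "
            "increase n_repeats")
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(counts > 0, co / np.maximum(counts, 1), 0.0)
    consensus = ConsensusMatrix(co_cluster=prop, co_sampled=counts)
    labels = _cut_consensus(consensus.dissimilarity, n_clusters,
                            config.linkage_method)
    basis = (consensus.dissimilarity
             if config.silhouette_basis == "consensus" else D)
    sil = silhouette_width(labels, basis)
    solution = ClusterSolution(labels=labels, c_used=n_clusters,
                               mean_silhouette=sil, provenance=provenance)
    return consensus, solution


def _align_to_indicators(U: np.ndarray, max_iter: int = 30) -> np.ndarray:
    """Rotate a row-normalized spectral embedding toward the nearest
    cluster-indicator matrix (alternating assignment / Procrustes)."""
    n, k = U.shape
    # deterministic greedy init: spread starting rows far apart
    R = np.zeros((k, k))
    R[:, 0] = U[n // 2]
    score = np.zeros(n)
    for j in range(1, k):
        score += np.abs(U @ R[:, j - 1])
        R[:, j] = U[int(np.argmin(score))]
    last = 0.0
    for _ in range(max_iter):
        Q = U @ R
        X = np.zeros_like(Q)
        X[np.arange(n), Q.argmax(axis=1)] = 1.0
        P, s, Vt = np.linalg.svd(U.T @ X)
        obj = s.sum()
        R = P @ Vt
        if abs(obj - last) < 1e-10:
            break
        last = obj
    return U @ R


def estimate_num_clusters(W, candidates=range(2, 11)) -> dict:
    """Best and second-best cluster numbers by two spectral criteria.

    Eigengap: C maximizing lambda_{C+1} - lambda_C of the symmetric
    normalized Laplacian (eigenvalues ascending). Rotation cost: C
    minimizing the row-concentration cost of the squared spectral
    embedding (how far the first C eigenvectors are from cluster
    indicator vectors). Returns ``{"eigengap": (best, second),
    "rotation_cost": (best, second)}``.
    """
    W = _weights(W)
    n = W.shape[0]
    candidates = sorted(candidates)
    if candidates[0] < 2 or candidates[-1] > n - 1:
        raise ValueError(f"candidates must lie in [2, {n - 1}]")
    Wz = W.copy()
    np.fill_diagonal(Wz, 0.0)
    deg = Wz.sum(axis=1)
    deg[deg <= 0] = 1e-12
    dinv = 1.0 / np.sqrt(deg)
    L = -(Wz * dinv[:, None]) * dinv[None, :]
    np.fill_diagonal(L, 1.0)
    vals, vecs = eigh(L)

    gaps = {c: vals[c] - vals[c - 1] for c in candidates}
    by_gap = sorted(candidates, key=lambda c: (-gaps[c], c))

    costs = {}
    for c in candidates:
        U = vecs[:, :c]
        norms = np.linalg.norm(U, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        M = _align_to_indicators(U / norms) ** 2
        mx = M.max(axis=1)
        mx[mx == 0] = 1.0
        costs[c] = float((M.sum(axis=1) / mx).sum())
    by_cost = sorted(candidates, key=lambda c: (costs[c], c))

    return {
        "eigengap": (by_gap[0], by_gap[1] if len(by_gap) > 1 else by_gap[0]),
        "rotation_cost": (by_cost[0], by_cost[1] if len(by_cost) > 1 else by_cost[0]),
        "eigengaps": gaps,
        "rotation_costs": costs,
    }
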