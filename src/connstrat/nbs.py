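"""Network Based Statistic: cluster-based inference on connectome edges.

Steps: (i) a mass-univariate general linear model at every edge,
(ii) retention of edges whose one-sided p-value beats an edge-level
threshold (the NBS threshold, typically 0.05 / 0.01 / 0.001),
(iii) extraction of connected components among supra-threshold edges,
and (iv) a max-statistic permutation null on component strength (sum of
edge t-values) giving each component a family-wise error corrected
p-value.

Permutation uses the Freedman-Lane scheme by default: residuals of the
reduced (covariate-only) model are permuted, preserving exchangeability
when nuisance covariates (head motion, age, sex, SES) are confounded
with the grouping of interest. Raw label shuffling is available via
``perm_scheme="labels"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .connectome import edge_index, possible_edge_count

__all__ = [
    "NBSConfig",
    "EdgeStatMap",
    "NBSComponent",
    "build_design",
    "fit_edgewise_glm",
    "suprathreshold_edges",
    "extract_components",
    "permutation_fwer",
    "run_nbs",
]

SES_ORDINAL = {"I-II": 1, "III": 2, "IV-V": 3}


@dataclass
class NBSConfig:
    p_nbs_threshold: float = 0.01
    n_perm: int = 1000
    tail: str = "greater"            # direction of the tested contrast
    component_statistic: str = "strength"   # or "extent"
    perm_scheme: str = "freedman-lane"      # or "labels"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.p_nbs_threshold < 1):
            raise ValueError("p_nbs_threshold must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.tail not in ("greater", "less"):
            raise ValueError("tail must be 'greater' or 'less'")
        if self.component_statistic not in ("strength", "extent"):
            raise ValueError("component_statistic must be strength or extent")
        if self.perm_scheme not in ("freedman-lane", "labels"):
            raise ValueError("perm_scheme must be freedman-lane or labels")


@dataclass
class EdgeStatMap:
    t_values: np.ndarray     # EdgeIndex order
    df_resid: int
    n_nodes: int


@dataclass
class NBSComponent:
    edges: list               # (i, j) node pairs, i < j
    nodes: np.ndarray
    strength: float           # sum of edge t-values
    extent: int               # edge count
    p_fwer: float | None = None
    nodal_degree_percent: dict = field(default_factory=dict)
    edge_t: np.ndarray | None = None


def _stack_to_edges(stack: np.ndarray) -> tuple[np.ndarray, int]:
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("stack must have shape (n_subjects, N, N)")
    n_nodes = stack.shape[1]
    iu, ju = edge_index(n_nodes)
    return stack[:, iu, ju], n_nodes


def build_design(metadata: pd.DataFrame, group_col: str,
                 covariates: tuple = ("mean_fd", "sex_female", "age", "ses"),
                 interaction_col: str | None = None,
                 ) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, group indicator, covariates, and an
    optional group x second-factor interaction.

    The group column may be any two-level variable; the indicator is 1
    for the lexicographically first level, so a positive contrast tests
    first-level > second-level. SES given as strings is mapped to the
    ordinal coding I-II = 1, III = 2, IV-V = 3.
    """
    missing = [c for c in (group_col, *covariates) if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata lacks column(s) {missing}")
    levels = sorted(metadata[group_col].unique())
    if len(levels) != 2:
        raise ValueError(f"{group_col!r} must have exactly two levels")
    g = (metadata[group_col] == levels[0]).to_numpy(float)
    cols = [np.ones(len(metadata)), g]
    names = ["intercept", f"{group_col}[{levels[0]}]"]
    for c in covariates:
        v = metadata[c]
        if v.dtype == object:
            v = v.map(SES_ORDINAL)
            if v.isna().any():
                raise ValueError(f"column {c!r} has unmapped categories")
        cols.append(v.to_numpy(float))
        names.append(c)
    if interaction_col is not None:
        lv2 = sorted(metadata[interaction_col].unique())
        if len(lv2) != 2:
            raise ValueError(f"{interaction_col!r} must have two levels")
        b = (metadata[interaction_col] == lv2[0]).to_numpy(float)
        cols.extend([b, g * b])
        names.extend([f"{interaction_col}[{lv2[0]}]",
                      f"{group_col}x{interaction_col}"])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


def _glm_t(Y: np.ndarray, X: np.ndarray, col: int,
           pinv: np.ndarray | None = None,
           var_factor: float | None = None) -> np.ndarray:
    """Vectorized per-edge OLS t-statistics for one coefficient."""
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more subjects ({n}) than parameters ({p})")
    if pinv is None:
        pinv = np.linalg.pinv(X)
    if var_factor is None:
        var_factor = np.linalg.inv(X.T @ X)[col, col]
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / (n - p)
    # degenerate edges (numerically zero residual variance) get t = 0
    scale = np.maximum((Y ** 2).mean(axis=0), 1.0)
    ok = sigma2 > 1e-12 * scale
    se = np.sqrt(sigma2 * var_factor)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ok, beta[col] / np.where(ok, se, 1.0), 0.0)
    return t


def fit_edgewise_glm(stack: np.ndarray, design: np.ndarray,
                     contrast_col: int) -> EdgeStatMap:
    """OLS at every edge; t = estimate / SE with df = n - p.

    Degenerate edges (zero residual variance) get t = 0.
    """
    Y, n_nodes = _stack_to_edges(stack)
    X = np.asarray(design, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("design rows must match number of subjects")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    t = _glm_t(Y, X, contrast_col)
    return EdgeStatMap(t_values=t, df_resid=X.shape[0] - X.shape[1],
                       n_nodes=n_nodes)


def suprathreshold_edges(statmap: EdgeStatMap, p_nbs_threshold: float,
                         tail: str = "greater") -> np.ndarray:
    """Boolean mask of edges beating the one-sided edge-level threshold."""
    crit = stats.t.ppf(1.0 - p_nbs_threshold, statmap.df_resid)
    t = statmap.t_values if tail == "greater" else -statmap.t_values
    return t >= crit


def extract_components(edge_mask: np.ndarray, n_nodes: int,
                       t_values: np.ndarray | None = None,
                       ) -> list[NBSComponent]:
    """Maximal connected components of the supra-threshold graph.

    Strength sums edge t-values (signed as supplied); extent counts
    edges; isolated nodes are ignored. Components are returned sorted
    by decreasing strength magnitude.
    """
    edge_mask = np.asarray(edge_mask, dtype=bool)
    if edge_mask.size != possible_edge_count(n_nodes):
        raise ValueError("edge mask length does not match node count")
    iu, ju = edge_index(n_nodes)
    ei, ej = iu[edge_mask], ju[edge_mask]
    if t_values is None:
        tv = np.ones(edge_mask.size)
    else:
        tv = np.asarray(t_values, dtype=float)
    et = tv[edge_mask]
    if ei.size == 0:
        return []
    adj = coo_matrix((np.ones(ei.size), (ei, ej)), shape=(n_nodes, n_nodes))
    n_comp, labels = connected_components(adj, directed=False)
    comps = []
    for c in range(n_comp):
        nodes = np.flatnonzero(labels == c)
        if nodes.size < 2:
            continue
        in_comp = np.isin(ei, nodes)
        if not in_comp.any():
            continue
        edges = list(zip(ei[in_comp].tolist(), ej[in_comp].tolist()))
        comp_t = et[in_comp]
        extent = len(edges)
        deg: dict[int, int] = {}
        for a, b in edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        pct = {node: 100.0 * d / extent for node, d in deg.items()}
        comps.append(NBSComponent(edges=edges, nodes=nodes,
                                  strength=float(comp_t.sum()), extent=extent,
                                  nodal_degree_percent=pct, edge_t=comp_t))
    comps.sort(key=lambda c: -abs(c.strength))
    return comps


def _component_stat(comp: NBSComponent, statistic: str) -> float:
    return abs(comp.strength) if statistic == "strength" else float(comp.extent)


def _max_null_stat(keep: np.ndarray, tvals: np.ndarray, iu, ju,
                   n_nodes: int, statistic: str) -> float:
    """Maximum component statistic of one (permuted) edge map."""
    ei, ej = iu[keep], ju[keep]
    if ei.size == 0:
        return 0.0
    adj = coo_matrix((np.ones(ei.size), (ei, ej)), shape=(n_nodes, n_nodes))
    _, labels = connected_components(adj, directed=False)
    comp_ids = labels[ei]
    if statistic == "strength":
        sums = np.bincount(comp_ids, weights=np.abs(tvals[keep]))
    else:
        sums = np.bincount(comp_ids)
    return float(sums.max())


def permutation_fwer(stack: np.ndarray, design: np.ndarray, contrast_col: int,
                     config: NBSConfig, rng=None) -> list[NBSComponent]:
    """Observed components with max-statistic permutation FWER p-values.

    p_fwer = (1 + #{permutation max >= observed}) / (1 + n_perm), the
    add-one estimator, bounded below by 1/(n_perm + 1).
    """
    Y, n_nodes = _stack_to_edges(stack)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(config.seed if rng is None else rng)
    iu, ju = edge_index(n_nodes)
    crit = stats.t.ppf(1.0 - config.p_nbs_threshold, n - p)
    sign = 1.0 if config.tail == "greater" else -1.0

    pinvX = np.linalg.pinv(X)
    var_factor = np.linalg.inv(X.T @ X)[contrast_col, contrast_col]
    t_obs = _glm_t(Y, X, contrast_col, pinvX, var_factor)
    comps = extract_components(sign * t_obs >= crit, n_nodes, t_values=t_obs)

    # reduced model for Freedman-Lane residual permutation
    Z = np.delete(X, contrast_col, axis=1)
    hatZ = Z @ np.linalg.pinv(Z)
    fitted = hatZ @ Y
    resid = Y - fitted

    exceed = np.zeros(len(comps))
    obs_stats = np.array([_component_stat(c, config.component_statistic)
                          for c in comps])
    for _ in range(config.n_perm):
        perm = rng.permutation(n)
        if config.perm_scheme == "freedman-lane":
            Yp = fitted + resid[perm]
            tp = _glm_t(Yp, X, contrast_col, pinvX, var_factor)
        else:
            Xp = X.copy()
            Xp[:, contrast_col] = X[perm, contrast_col]
            tp = _glm_t(Y, Xp, contrast_col)
        null_max = _max_null_stat(sign * tp >= crit, tp, iu, ju, n_nodes,
                                  config.component_statistic)
        exceed += null_max >= obs_stats
    for comp, k in zip(comps, exceed):
        comp.p_fwer = (1.0 + k) / (1.0 + config.n_perm)
    return comps


def run_nbs(stack: np.ndarray, metadata: pd.DataFrame, group_col: str,
            covariates: tuple = ("mean_fd", "sex_female", "age", "ses"),
            config: NBSConfig | None = None,
            interaction_col: str | None = None) -> dict:
    """Both one-sided contrasts (and optionally the interaction) with
    permutation FWER p-values.

    Returns a report dict keyed by contrast name; each entry holds the
    component list, the tested coefficient and the settings used.
    """
    config = config or NBSConfig()
    if len(metadata) != np.asarray(stack).shape[0]:
        raise ValueError("metadata rows must align with the connectome stack")
    X, names = build_design(metadata, group_col, covariates,
                            interaction_col=interaction_col)
    contrast_col = names.index(
        f"{group_col}x{interaction_col}") if interaction_col else 1
    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(2)]
    report = {"design_columns": names, "settings": {
        "p_nbs_threshold": config.p_nbs_threshold, "n_perm": config.n_perm,
        "component_statistic": config.component_statistic,
        "perm_scheme": config.perm_scheme, "seed": config.seed}}
    for tail, rng, label in (("greater", streams[0], "positive"),
                             ("less", streams[1], "negative")):
        cfg = NBSConfig(p_nbs_threshold=config.p_nbs_threshold,
                        n_perm=config.n_perm, tail=tail,
                        component_statistic=config.component_statistic,
                        perm_scheme=config.perm_scheme, seed=config.seed)
        comps = permutation_fwer(stack, X, contrast_col, cfg, rng=rng)
        report[label] = {"tested_coefficient": names[contrast_col],
                         "tail": tail, "components": comps}
    return report
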