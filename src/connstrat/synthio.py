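"""Synthetic cohorts with known ground truth.

Generates (i) behavioural feature tables with two planted latent
subgroups, (ii) per-subject Fisher-z connectome stacks carrying a
planted connected edge component whose mean differs between groups,
(iii) band-limited regional time series with block covariance, and
(iv) node-to-network partitions. Every generator is deterministic
given its seed.

Default cohort conditions mirror a very-preterm (VPT) / full-term (FT)
adult follow-up cohort: n = 156, 13 standardized behavioural features,
an 85/71 subgroup split, higher in-scanner head motion (framewise
displacement, FD) in the VPT group, age around 30 years, and a 3-level
ordinal socio-economic status (SES).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "PlantedComponentSpec",
    "CANONICAL_NETWORKS",
    "gen_cohort",
    "gen_connectome_stack",
    "gen_timeseries",
    "gen_partition",
]

CANONICAL_NETWORKS = (
    "visual", "somatomotor", "dorsal_attention", "ventral_attention",
    "limbic", "frontoparietal", "default_mode", "subcortical",
)

#: per-group covariate distributions: (VPT, FT)
_DEFAULT_COVARIATES = {
    "age_mean": (30.9, 28.9),       # years
    "age_sd": (3.5, 3.0),
    "female_prop": (0.40, 0.54),
    "ses_probs": ((0.52, 0.36, 0.12), (0.47, 0.34, 0.19)),  # ordinal 1..3
    "fd_median": (0.15, 0.12),      # mm, log-normal medians
    "fd_sigma": (0.35, 0.35),
}


@dataclass
class CohortSpec:
    """Conditions for a synthetic behavioural cohort."""

    n_subjects: int = 156
    n_features: int = 13
    subgroup_fraction: float = 85 / 156
    feature_effects: np.ndarray | None = None  # per-feature Cohen's d
    group_fraction: float = 85 / 156           # proportion labelled VPT
    covariate_model: dict = field(default_factory=lambda: dict(_DEFAULT_COVARIATES))
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0 or self.n_features <= 0:
            raise ValueError("n_subjects and n_features must be positive")
        if not (0 < self.subgroup_fraction < 1):
            raise ValueError("subgroup_fraction must lie in (0, 1)")
        if not (0 < self.group_fraction < 1):
            raise ValueError("group_fraction must lie in (0, 1)")
        if self.feature_effects is None:
            self.feature_effects = np.zeros(self.n_features)
        self.feature_effects = np.asarray(self.feature_effects, dtype=float)
        if self.feature_effects.shape != (self.n_features,):
            raise ValueError("feature_effects must have one entry per feature")
        if not np.all(np.isfinite(self.feature_effects)):
            raise ValueError("feature_effects must be finite")


@dataclass
class PlantedComponentSpec:
    """A connected set of edges carrying an additive group effect."""

    n_nodes: int = 60
    n_edges_planted: int = 80
    anchor_nodes: int = 3
    delta: float = 0.3          # group mean difference on planted edges, z units
    edge_noise_sd: float = 0.2  # between-subject SD of each edge, z units
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        max_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if not (1 <= self.n_edges_planted <= max_edges):
            raise ValueError(
                f"n_edges_planted must lie in [1, {max_edges}]")
        if self.anchor_nodes < 1:
            raise ValueError("need at least one anchor node")
        if self.edge_noise_sd <= 0:
            raise ValueError("edge_noise_sd must be positive")


def gen_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Draw a cohort: (metadata, feature matrix, true subgroup labels).

    Features are per-subgroup Gaussian with unit variance; subgroup 1
    means are shifted by ``feature_effects`` (standardized mean
    difference d). Metadata carries group (VPT/FT), age, sex, ordinal
    SES and group-specific log-normal FD. Subgroup membership is
    independent of clinical group, matching a cohort where the
    data-driven split does not track birth status.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    n_sub1 = int(round(n * spec.subgroup_fraction))
    n_sub1 = min(max(n_sub1, 1), n - 1)
    subgroup = np.zeros(n, dtype=int)
    subgroup[rng.choice(n, size=n_sub1, replace=False)] = 1

    n_vpt = min(max(int(round(n * spec.group_fraction)), 1), n - 1)
    group = np.full(n, "FT", dtype=object)
    group[rng.choice(n, size=n_vpt, replace=False)] = "VPT"

    features = rng.standard_normal((n, spec.n_features))
    features[subgroup == 1] += spec.feature_effects

    cm = spec.covariate_model
    gidx = (group == "FT").astype(int)  # 0 = VPT, 1 = FT
    age = rng.normal(np.take(cm["age_mean"], gidx),
                     np.take(cm["age_sd"], gidx))
    sex = (rng.random(n) < np.take(cm["female_prop"], gidx)).astype(int)
    ses = np.empty(n, dtype=int)
    for g, probs in zip((0, 1), cm["ses_probs"]):
        mask = gidx == g
        ses[mask] = rng.choice([1, 2, 3], size=mask.sum(), p=probs)
    fd = np.exp(rng.normal(np.log(np.take(cm["fd_median"], gidx)),
                           np.take(cm["fd_sigma"], gidx)))

    metadata = pd.DataFrame({
        "subject_id": [f"sub-{i:04d}" for i in range(n)],
        "group": group,
        "age": age,
        "sex_female": sex,
        "ses": ses,
        "mean_fd": fd,
    })
    return metadata, features, subgroup


def _grow_connected_edges(rng: np.random.Generator, n_nodes: int,
                          n_edges: int, anchor_nodes: int) -> list[tuple[int, int]]:
    """Random breadth-first expansion from anchor seeds.

    Keeps the planted edge set connected in topological space: every
    new edge touches at least one already-visited node, and new nodes
    enter via an edge to the visited set.
    """
    anchors = rng.choice(n_nodes, size=min(anchor_nodes, n_nodes), replace=False)
    visited = [int(anchors[0])]
    edges: set[tuple[int, int]] = set()
    # chain the anchors together first so all seeds share one component
    for a in anchors[1:]:
        u = int(rng.choice(visited))
        edges.add((min(u, int(a)), max(u, int(a))))
        visited.append(int(a))
    unvisited = [v for v in range(n_nodes) if v not in set(visited)]
    rng.shuffle(unvisited)
    while len(edges) < n_edges:
        # prefer expansion while new nodes remain, else densify
        if unvisited and rng.random() < 0.7:
            v = unvisited.pop()
            u = int(rng.choice(visited))
            edges.add((min(u, v), max(u, v)))
            visited.append(v)
        else:
            u, v = rng.choice(visited, size=2, replace=False)
            u, v = int(u), int(v)
            if u == v:
                continue
            e = (min(u, v), max(u, v))
            if e in edges:
                # fall back to expansion if densification saturates
                if unvisited:
                    w = unvisited.pop()
                    a = int(rng.choice(visited))
                    edges.add((min(a, w), max(a, w)))
                    visited.append(w)
                continue
            edges.add(e)
    return sorted(edges)


def gen_connectome_stack(metadata: pd.DataFrame, spec: PlantedComponentSpec,
                         group_col: str = "group",
                         ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Per-subject symmetric z-matrices with a planted group effect.

    Returns ``(stack, true_edges)`` where ``stack`` has shape
    (n_subjects, n_nodes, n_nodes). Edge baselines are U(0.2, 0.6)
    z-units (plausible retained Fisher-z weights); on planted edges the
    first group (sorted label order) is shifted by +delta/2 and the
    second by -delta/2, so the between-group mean difference is delta.
    All other edges are exchangeable between groups.
    """
    if group_col not in metadata.columns:
        raise ValueError(f"metadata lacks group column {group_col!r}")
    rng = np.random.default_rng(spec.seed)
    n_subjects = len(metadata)
    n = spec.n_nodes
    true_edges = _grow_connected_edges(rng, n, spec.n_edges_planted,
                                       spec.anchor_nodes)

    levels = sorted(metadata[group_col].unique())
    if len(levels) != 2:
        raise ValueError("group column must have exactly two levels")
    sign = np.where(metadata[group_col].to_numpy() == levels[0], 0.5, -0.5)

    iu, ju = np.triu_indices(n, k=1)
    n_edges = iu.size
    baseline = rng.uniform(0.2, 0.6, size=n_edges)
    values = baseline + rng.normal(0.0, spec.edge_noise_sd,
                                   size=(n_subjects, n_edges))
    edge_pos = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(iu, ju))}
    planted_idx = np.array([edge_pos[e] for e in true_edges])
    values[:, planted_idx] += spec.delta * sign[:, None]

    stack = np.zeros((n_subjects, n, n))
    stack[:, iu, ju] = values
    stack[:, ju, iu] = values
    return stack, true_edges


def gen_timeseries(n_subjects: int, n_nodes: int, n_timepoints: int = 256,
                   tr_seconds: float = 2.0,
                   partition: np.ndarray | None = None,
                   within_r: float = 0.5, between_r: float = 0.1,
                   seed: int = 0) -> np.ndarray:
    """Band-limited Gaussian series with block covariance.

    ``partition`` assigns each node to a block (e.g. an intrinsic
    network); same-block node pairs share correlation ``within_r``,
    different blocks ``between_r``. Returns an array of shape
    (n_subjects, n_timepoints, n_nodes). Defaults follow an
    eight-minute resting acquisition (256 volumes at TR = 2 s).
    """
    if n_timepoints < 8:
        raise ValueError("need at least 8 time points")
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    rng = np.random.default_rng(seed)
    if partition is None:
        partition = np.zeros(n_nodes, dtype=int)
    partition = np.asarray(partition)
    if partition.shape != (n_nodes,):
        raise ValueError("partition must assign every node")
    same = partition[:, None] == partition[None, :]
    cov = np.where(same, within_r, between_r)
    np.fill_diagonal(cov, 1.0)
    # ensure positive definiteness for strong block structure
    w, v = np.linalg.eigh(cov)
    chol = v @ np.diag(np.sqrt(np.clip(w, 1e-10, None)))
    raw = rng.standard_normal((n_subjects, n_timepoints, n_nodes))
    return raw @ chol.T


def gen_partition(n_nodes: int, n_networks: int = 8, seed: int = 0,
                  subcortical_size: int | None = None) -> np.ndarray:
    """Random node-to-network assignment using every label at least once.

    With 8 networks the canonical labels are the seven cortical
    intrinsic connectivity networks plus "subcortical";
    ``subcortical_size`` forces that network to an exact node count
    (e.g. 16 of 374 regions).
    """
    if n_networks > n_nodes:
        raise ValueError("more networks than nodes")
    if n_networks < 1:
        raise ValueError("need at least one network")
    rng = np.random.default_rng(seed)
    if n_networks == 8:
        names = list(CANONICAL_NETWORKS)
    else:
        names = [f"network_{k + 1}" for k in range(n_networks)]

    labels = np.empty(n_nodes, dtype=object)
    order = rng.permutation(n_nodes)
    pos = 0
    if subcortical_size is not None:
        if "subcortical" not in names:
            raise ValueError("subcortical_size requires the 8-network labels")
        if subcortical_size < 1 or subcortical_size > n_nodes - (n_networks - 1):
            raise ValueError("subcortical_size infeasible")
        labels[order[:subcortical_size]] = "subcortical"
        pos = subcortical_size
        rest = [nm for nm in names if nm != "subcortical"]
    else:
        rest = names
    # one node per remaining label guarantees coverage, rest uniform
    for nm in rest:
        labels[order[pos]] = nm
        pos += 1
    remaining = order[pos:]
    labels[remaining] = rng.choice(rest, size=remaining.size)
    return labels
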