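"""Group comparisons of behavioural and demographic variables.

Continuous measures: Mann-Whitney/Wilcoxon rank-sum with the
rank-biserial correlation r = 2U/(n1 n2) - 1 as effect size (positive
means the first sample tends larger). Categorical measures: chi-square,
or Fisher's exact for sparse 2x2 tables, with Cramer's V. Families of
p-values are corrected by Benjamini-Hochberg FDR, and covariate-adjusted
sensitivity tests use Freedman-Lane permutation of reduced-model
residuals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ranksum_test",
    "categorical_test",
    "bh_fdr",
    "adjusted_perm_test",
    "interaction_behaviour_test",
    "compare_groups",
]


def ranksum_test(x, y, use_continuity: bool = False):
    """Rank-sum test with rank-biserial effect size.

    Returns ``(U, two-sided p, rank_biserial)`` where U is the
    Mann-Whitney statistic of ``x`` and the rank-biserial correlation
    2U/(n1 n2) - 1 is positive when ``x`` tends to exceed ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic",
                             use_continuity=use_continuity)
    rb = 2.0 * res.statistic / (x.size * y.size) - 1.0
    return float(res.statistic), float(res.pvalue), float(rb)


def categorical_test(table):
    """Chi-square (or Fisher's exact for sparse 2x2) with Cramer's V.

    Fisher's exact is used when the table is 2x2 and any expected cell
    count is below 5; larger sparse tables fall back to chi-square with
    a warning. V = sqrt(chi2 / (n (min(r, c) - 1))).
    """
    tab = np.asarray(table)
    if tab.ndim != 2 or min(tab.shape) < 2:
        raise ValueError("need a contingency table of at least 2x2")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        raise ValueError("table must hold non-negative integer counts")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("degenerate table: all-zero row or column")
    chi2, chi_p, _, expected = stats.chi2_contingency(tab, correction=False)
    n = tab.sum()
    v = float(np.sqrt(chi2 / (n * (min(tab.shape) - 1)))) if chi2 > 0 else 0.0
    sparse = np.any(expected < 5)
    if sparse and tab.shape == (2, 2):
        _, p = stats.fisher_exact(tab)
        return "fisher", float(p), v
    if sparse:
        warnings.warn("expected counts < 5 in a table larger than 2x2; "
                      "chi-square approximation may be poor")
    return "chi2", float(chi_p), v


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _freedman_lane_p(y: np.ndarray, X: np.ndarray, col: int,
                     n_perm: int, rng) -> float:
    """Two-sided Freedman-Lane permutation p for one coefficient."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    pinvX = np.linalg.pinv(X)
    xtxi = np.linalg.inv(X.T @ X)[col, col]

    def tstat(yv, pv=pinvX, vf=xtxi, Xd=X):
        beta = pv @ yv
        resid = yv - Xd @ beta
        sigma2 = (resid ** 2).sum() / (n - Xd.shape[1])
        se = np.sqrt(sigma2 * vf)
        return 0.0 if se == 0 else beta[col] / se

    t_obs = abs(tstat(y))
    Z = np.delete(X, col, axis=1)
    hat = Z @ np.linalg.pinv(Z)
    fitted = hat @ y
    resid = y - fitted
    exceed = 0
    for _ in range(n_perm):
        yp = fitted + resid[rng.permutation(n)]
        if abs(tstat(yp)) >= t_obs:
            exceed += 1
    return (1.0 + exceed) / (1.0 + n_perm)


def adjusted_perm_test(outcome, group, covariates=None, n_perm: int = 5000,
                       seed: int = 0) -> float:
    """Covariate-adjusted permutation p-value for a group effect.

    The statistic is the OLS t of the group coefficient; the null is
    built by Freedman-Lane permutation of reduced-model residuals.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group, dtype=float)
    if y.shape != g.shape:
        raise ValueError("outcome and group must align")
    cols = [np.ones(y.size), g]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != y.size:
            raise ValueError("covariates must align with the outcome")
        cols.extend(C.T)
    X = np.column_stack(cols)
    rng = np.random.default_rng(seed)
    return _freedman_lane_p(y, X, 1, n_perm, rng)


def interaction_behaviour_test(outcome, factor_a, factor_b, covariates=None,
                               n_perm: int = 5000, seed: int = 0) -> float:
    """Permutation p for the a x b interaction on a behavioural outcome.

    Both factors must be binary; the design is the full factorial
    (a + b + a:b) plus covariates, and the interaction coefficient is
    tested in both tails under Freedman-Lane permutation.
    """
    y = np.asarray(outcome, dtype=float)
    a = np.asarray(factor_a, dtype=float)
    b = np.asarray(factor_b, dtype=float)
    for f, nm in ((a, "factor_a"), (b, "factor_b")):
        if np.unique(f).size != 2:
            raise ValueError(f"{nm} must have exactly two levels")
    a = (a == np.max(a)).astype(float)
    b = (b == np.max(b)).astype(float)
    cols = [np.ones(y.size), a, b, a * b]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.extend(C.T)
    X = np.column_stack(cols)
    rng = np.random.default_rng(seed)
    return _freedman_lane_p(y, X, 3, n_perm, rng)


def compare_groups(features: pd.DataFrame, group: pd.Series,
                   covariates: pd.DataFrame | None = None,
                   n_perm: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Per-feature group comparison table.

    For each feature column: rank-sum p, BH-FDR p over the family,
    covariate-adjusted permutation p (also BH-FDR corrected) and the
    rank-biserial effect size. Group rows are split by the sorted
    order of the two group levels (first level listed first).
    """
    levels = sorted(pd.Series(group).unique())
    if len(levels) != 2:
        raise ValueError("group must have exactly two levels")
    mask = np.asarray(group) == levels[0]
    g01 = mask.astype(float)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in
             ss.spawn(features.shape[1])]
    rows = []
    for j, name in enumerate(features.columns):
        v = features[name].to_numpy(dtype=float)
        u, p, rb = ranksum_test(v[mask], v[~mask])
        adj_p = adjusted_perm_test(v, g01, cov, n_perm=n_perm, seed=seeds[j])
        rows.append({"feature": name, "U": u, "p": p, "adjusted_p": adj_p,
                     "rank_biserial": rb})
    out = pd.DataFrame(rows)
    out["fdr_p"] = bh_fdr(out["p"])
    out["adjusted_fdr_p"] = bh_fdr(out["adjusted_p"])
    return out[["feature", "U", "p", "fdr_p", "adjusted_p",
                "adjusted_fdr_p", "rank_biserial"]]
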