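"""Thresholded Fisher-z connectivity matrices from regional time series.

The processing order is fixed: confound regression -> band-pass ->
Pearson correlation -> threshold at r >= threshold_r -> Fisher z.
Negative correlations are discarded by the threshold rule, not
absolute-valued.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = [
    "regress_confounds",
    "bandpass",
    "correlation_matrix",
    "threshold_fisher",
    "possible_edge_count",
    "edge_index",
    "vectorize_matrix",
    "devectorize_edges",
    "connectivity_from_timeseries",
]

DEFAULT_THRESHOLD_R = 0.2


def _as_timeseries(values: np.ndarray, min_t: int = 8) -> np.ndarray:
    ts = np.asarray(values, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a T x N matrix")
    if ts.shape[0] < min_t:
        raise ValueError(f"need at least {min_t} time points, got {ts.shape[0]}")
    if ts.shape[1] < 2:
        raise ValueError("need at least 2 regions")
    if not np.all(np.isfinite(ts)):
        raise ValueError("time series contain non-finite values")
    return ts


def regress_confounds(ts: np.ndarray, confounds: np.ndarray,
                      add_intercept: bool = True) -> np.ndarray:
    """Remove nuisance signals by ordinary least squares.

    Returns the T x N residual series; each output column is orthogonal
    to every confound column (and mean-centred when an intercept is
    included, the default).
    """
    ts = _as_timeseries(ts)
    conf = np.asarray(confounds, dtype=float)
    if conf.ndim == 1:
        conf = conf[:, None]
    if conf.shape[0] != ts.shape[0]:
        raise ValueError(
            f"confound rows ({conf.shape[0]}) != time points ({ts.shape[0]})")
    if add_intercept:
        conf = np.column_stack([np.ones(conf.shape[0]), conf])
    if np.linalg.matrix_rank(conf) < conf.shape[1]:
        raise ValueError("confound matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(conf, ts, rcond=None)
    return ts - conf @ beta


def bandpass(ts: np.ndarray, tr_seconds: float,
             low_hz: float = 0.01, high_hz: float = 0.1,
             order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass (default 0.01-0.1 Hz).

    Applied forward-backward (``sosfiltfilt``) so phase is preserved.
    """
    ts = _as_timeseries(ts)
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    nyquist = 0.5 / tr_seconds
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie inside (0, {nyquist}) Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=1.0 / tr_seconds, output="sos")
    return signal.sosfiltfilt(sos, ts, axis=0)


def correlation_matrix(ts: np.ndarray) -> np.ndarray:
    """Pearson correlations between every pair of regional time series."""
    ts = _as_timeseries(ts, min_t=2)
    sd = ts.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance time series at node(s) {bad.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def threshold_fisher(r: np.ndarray,
                     threshold_r: float = DEFAULT_THRESHOLD_R) -> np.ndarray:
    """Retain edges with r >= threshold_r and Fisher-z transform them.

    Entries below threshold (including every negative correlation) are
    zeroed; the diagonal is zeroed. Ties at exactly the threshold are
    retained.
    """
    r = np.asarray(r, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        i, j = np.argwhere((np.abs(r) >= 1.0) & off)[0]
        raise ValueError(
            f"|r| >= 1 between nodes {i} and {j}: Fisher z is infinite")
    z = np.where(r >= threshold_r, np.arctanh(np.where(off, r, 0.0)), 0.0)
    z[~off] = 0.0
    return z


def possible_edge_count(n_nodes: int) -> int:
    """Number of unique node pairs, n(n-1)/2 (e.g. 374 regions -> 69751)."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    return n_nodes * (n_nodes - 1) // 2


def edge_index(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Strict upper-triangle pairs (i < j) in lexicographic order, 0-based."""
    return np.triu_indices(n_nodes, k=1)


def vectorize_matrix(mat: np.ndarray) -> np.ndarray:
    """Upper-triangle vector of a symmetric zero-diagonal matrix."""
    mat = np.asarray(mat, dtype=float)
    iu, ju = edge_index(mat.shape[0])
    return mat[iu, ju]


def devectorize_edges(vec: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`vectorize_matrix` (symmetric, zero diagonal)."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != possible_edge_count(n_nodes):
        raise ValueError("edge vector length does not match node count")
    out = np.zeros((n_nodes, n_nodes))
    iu, ju = edge_index(n_nodes)
    out[iu, ju] = vec
    out[ju, iu] = vec
    return out


def connectivity_from_timeseries(ts: np.ndarray, tr_seconds: float,
                                 confounds: np.ndarray | None = None,
                                 low_hz: float = 0.01, high_hz: float = 0.1,
                                 threshold_r: float = DEFAULT_THRESHOLD_R,
                                 ) -> np.ndarray:
    """Full per-subject pipeline from a T x N series to a thresholded
    Fisher-z connectome."""
    if confounds is not None:
        ts = regress_confounds(ts, confounds)
    ts = bandpass(ts, tr_seconds, low_hz=low_hz, high_hz=high_hz)
    return threshold_fisher(correlation_matrix(ts), threshold_r=threshold_r)
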