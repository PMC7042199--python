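"""Connectivity-network construction and sparsity-grid binarization.

Pearson correlation matrices are zeroed on the negatives, binarized at a grid
of sparsity levels (default 0.02..0.50, step 0.01 — 49 networks), and metric
curves over the grid are summarized by their sum ("threshold AUC").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from connectoml.errors import ConfigurationError, DataError

#: default sparsity grid bounds and step
GRID_START = 0.02
GRID_STOP = 0.50
GRID_STEP = 0.01


def sparsity_grid(start: float = GRID_START, stop: float = GRID_STOP, step: float = GRID_STEP) -> np.ndarray:
    """The ordered grid of sparsity levels (inclusive of both endpoints)."""
    if step <= 0 or stop <= start:
        raise ConfigurationError("grid requires step > 0 and stop > start")
    n = (stop - start) / step
    if abs(n - round(n)) > 1e-9:
        raise ConfigurationError(
            f"grid step {step} does not divide the range [{start}, {stop}]"
        )
    return start + step * np.arange(round(n) + 1)


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI Pearson correlation matrix with zero diagonal."""

    values: np.ndarray
    roi_ids: list[int] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError(f"connectivity matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise DataError("connectivity matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-9):
            raise DataError("correlation entries must lie in [-1, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = v
        if self.roi_ids is None:
            self.roi_ids = list(range(v.shape[0]))

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class ThresholdedNetworkStack:
    """Binary undirected adjacency per sparsity-grid value."""

    grid: np.ndarray
    networks: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.networks) != len(self.grid):
            raise DataError("one network per grid value required")

    def __len__(self) -> int:
        return len(self.grid)

    def edge_counts(self) -> np.ndarray:
        return np.array([int(a.sum()) // 2 for a in self.networks])


def pearson_adjacency(timeseries: np.ndarray, roi_ids: list[int] | None = None) -> ConnectivityMatrix:
    """Pearson r between all ROI pairs of an ROI x time matrix; diagonal zeroed."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise DataError(f"expected an ROI x time matrix, got shape {ts.shape}")
    if ts.shape[1] < 3:
        raise DataError(f"need >= 3 time points, got {ts.shape[1]}")
    sd = ts.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise DataError(f"constant time series for ROI(s) {flat.tolist()}")
    r = np.corrcoef(ts)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r, roi_ids=roi_ids)


def zero_negatives(C: ConnectivityMatrix) -> ConnectivityMatrix:
    """Replace negative correlations with zero."""
    return ConnectivityMatrix(np.maximum(C.values, 0.0), roi_ids=list(C.roi_ids))


def _ordered_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    # upper-triangle pairs in lexicographic (i, j) order
    return np.triu_indices(n, k=1)


def sparsity_threshold(C: ConnectivityMatrix, s: float, method: str = "rank") -> np.ndarray:
    """Binarize at sparsity ``s``.

    ``method="rank"`` (default) keeps exactly K = round(s * N(N-1)/2)
    strongest edges, ties at the cutoff broken by lexicographic pair order;
    ``method="quantile"`` keeps every edge whose weight strictly exceeds the
    (1 - s) weight quantile, which may differ from K under ties.  If fewer
    than K strictly positive weights exist, all positive edges are kept.
    """
    if not 0.0 < s <= 1.0:
        raise ConfigurationError(f"sparsity must be in (0, 1], got {s}")
    if method not in ("rank", "quantile"):
        raise ConfigurationError(f"unknown thresholding method {method!r}")
    if np.any(C.values < 0):
        raise DataError("sparsity thresholding requires a non-negative matrix")
    n = C.n_rois
    ii, jj = _ordered_pairs(n)
    w = C.values[ii, jj]
    adj = np.zeros((n, n), dtype=np.int8)
    if method == "quantile":
        cut = np.quantile(w, 1.0 - s)
        keep = (w > cut) & (w > 0)
        adj[ii[keep], jj[keep]] = 1
        adj |= adj.T
        return adj
    k = round(s * n * (n - 1) / 2)
    n_pos = int(np.count_nonzero(w > 0))
    k = min(k, n_pos)
    if k > 0:
        # stable sort on -w keeps lexicographic order within equal weights
        order = np.argsort(-w, kind="stable")[:k]
        adj[ii[order], jj[order]] = 1
        adj |= adj.T
    return adj


def build_stack(
    C: ConnectivityMatrix,
    start: float = GRID_START,
    stop: float = GRID_STOP,
    step: float = GRID_STEP,
) -> ThresholdedNetworkStack:
    """Binarize over the sparsity grid; edge sets are nested across the grid."""
    grid = sparsity_grid(start, stop, step)
    networks = [sparsity_threshold(C, float(s)) for s in grid]
    return ThresholdedNetworkStack(grid=grid, networks=networks)


def metric_auc(values: np.ndarray, n_grid: int = 49, trapezoid: bool = False, step: float = GRID_STEP) -> float:
    """Summarize a metric curve over the grid: the sum of its values.

    A trapezoid alternative is available but off by default.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (n_grid,):
        raise DataError(f"expected exactly {n_grid} values, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise DataError("metric values must be finite")
    if trapezoid:
        return float(np.trapezoid(v, dx=step))
    return float(v.sum())


def fisher_z(values: np.ndarray) -> np.ndarray:
    """Fisher z-transform (atanh), clipping |r| >= 1 to 1 - 1e-7 with a warning."""
    v = np.asarray(values, dtype=float)
    clip = 1.0 - 1e-7
    if np.any(np.abs(v) >= 1.0):
        warnings.warn("correlation magnitude >= 1 clipped before Fisher z", stacklevel=2)
        v = np.clip(v, -clip, clip)
    return np.arctanh(v)


def zscore_columns(X: np.ndarray, mean: np.ndarray | None = None, sd: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise standardization; zero-variance columns map to zero.

    Returns (standardized X, mean, sd) so test folds can reuse train scalers.
    """
    X = np.asarray(X, dtype=float)
    if mean is None:
        mean = X.mean(axis=0)
    if sd is None:
        sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / safe, mean, sd
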