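"""Statistical feature selection.

Covariate residualization, pooled two-sample t-tests (raw or summary form),
Pearson chi-square on 2x2 tables, Benjamini-Hochberg FDR, the network-based
statistic (NBS) permutation test on suprathreshold edge components, and a
group-LASSO logistic selector over node-grouped metric features solved by a
monotone FISTA proximal-gradient scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from connectoml.errors import ConfigurationError, DataError

# ---------------------------------------------------------------------------
# covariate regression


def regress_covariates(features: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Residualize each feature on [1, age, sex, education] via OLS.

    Residuals are returned re-centred at each feature's grand mean.  Sex is
    coded 1 for male, 0 for female.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    for col in ("age", "sex", "education"):
        if col not in covariates.columns:
            raise DataError(f"covariates missing column {col!r}")
    sex = covariates["sex"].map({"M": 1.0, "F": 0.0, 1: 1.0, 0: 0.0}).to_numpy(float)
    design = np.column_stack(
        [
            np.ones(len(covariates)),
            covariates["age"].to_numpy(float),
            sex,
            covariates["education"].to_numpy(float),
        ]
    )
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        names = ["intercept", "age", "sex", "education"]
        collinear = []
        for j in range(1, design.shape[1]):
            reduced = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(names[j])
        raise DataError(f"covariate design is rank deficient; collinear: {collinear}")
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ beta
    return resid + X.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# classic tests


def two_sample_t(
    a: np.ndarray | tuple[float, float, int],
    b: np.ndarray | tuple[float, float, int],
) -> tuple[float, float]:
    """Pooled-variance Student t-test, two-sided.

    Accepts raw vectors or ``(mean, sd, n)`` summaries (SDs are sample SDs).
    Returns ``(t, p)`` with df = n1 + n2 - 2.
    """

    def _moments(x):
        if isinstance(x, tuple) and len(x) == 3:
            m, sd, n = x
            return float(m), float(sd) ** 2, int(n)
        arr = np.asarray(x, dtype=float)
        return float(arr.mean()), float(arr.var(ddof=1)), int(arr.size)

    m1, v1, n1 = _moments(a)
    m2, v2, n2 = _moments(b)
    if n1 < 2 or n2 < 2:
        raise DataError("each group needs n >= 2")
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    if pooled <= 0:
        raise DataError("pooled variance is zero")
    t = (m1 - m2) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise DataError(f"expected a 2x2 table, got shape {tab.shape}")
    if np.any(tab < 0):
        raise DataError("counts must be non-negative")
    row = tab.sum(axis=1)
    col = tab.sum(axis=0)
    n = tab.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise DataError("zero marginal in 2x2 table")
    expected = np.outer(row, col) / n
    chi2 = float(((tab - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def fdr_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def fdr_reject(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Boolean rejection mask at level alpha from the BH step-up rule."""
    return fdr_bh(pvalues) <= alpha


# ---------------------------------------------------------------------------
# network-based statistic


@dataclass
class NBSResult:
    primary_p: float
    components: list[list[tuple[int, int]]]  # suprathreshold edge sets
    component_p: list[float]
    edge_t: np.ndarray  # n_edges vector, triu lexicographic order
    edge_p: np.ndarray
    top_edges: list[tuple[int, int]]  # k lowest-p edges
    nperm: int


def _edge_pairs(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n_rois, k=1)


def _vectorized_t(X: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Pooled two-sample t per column; zero-variance columns give t = 0."""
    n1, n2 = int(g1.sum()), int(g2.sum())
    m1 = X[g1].mean(axis=0)
    m2 = X[g2].mean(axis=0)
    v1 = X[g1].var(axis=0, ddof=1)
    v2 = X[g2].var(axis=0, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    return np.where(np.isfinite(t), t, 0.0)


def _max_component_size(supra: np.ndarray, ii: np.ndarray, jj: np.ndarray, n_rois: int) -> int:
    """Size (edge count) of the largest connected suprathreshold component."""
    if not supra.any():
        return 0
    rows = ii[supra]
    cols = jj[supra]
    adj = sparse.coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n_rois, n_rois)
    )
    n_comp, labels = connected_components(adj, directed=False)
    edge_labels = labels[rows]
    return int(np.bincount(edge_labels, minlength=n_comp).max())


def nbs(
    edge_features: np.ndarray,
    y: np.ndarray,
    n_rois: int,
    primary_p: float = 0.01,
    nperm: int = 10_000,
    seed: int | None = None,
    top_k: int = 100,
) -> NBSResult:
    """Network-based statistic on subjects x edges features.

    ``edge_features`` columns follow upper-triangle lexicographic pair order.
    Edges with two-sided pooled-t p below ``primary_p`` form the
    suprathreshold graph; each connected component's p-value comes from the
    permutation null of the maximal component size (in edges):
    ``p = (1 + #{perm max >= observed}) / (nperm + 1)``.
    """
    if nperm < 100:
        raise ConfigurationError("nperm must be >= 100")
    X = np.asarray(edge_features, dtype=float)
    y = np.asarray(y)
    ii, jj = _edge_pairs(n_rois)
    if X.shape[1] != ii.size:
        raise DataError(
            f"expected {ii.size} edge columns for {n_rois} ROIs, got {X.shape[1]}"
        )
    g1 = y == 1
    g2 = ~g1
    df = int(g1.sum() + g2.sum() - 2)
    t_obs = _vectorized_t(X, g1, g2)
    p_obs = 2.0 * stats.t.sf(np.abs(t_obs), df)
    supra = p_obs < primary_p

    # observed components over the suprathreshold graph
    components: list[list[tuple[int, int]]] = []
    if supra.any():
        rows, cols = ii[supra], jj[supra]
        adj = sparse.coo_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(n_rois, n_rois)
        )
        n_comp, labels = connected_components(adj, directed=False)
        for comp in range(n_comp):
            edges = [
                (int(a), int(b))
                for a, b in zip(rows, cols)
                if labels[a] == comp
            ]
            if edges:
                components.append(edges)

    rng = np.random.default_rng(seed)
    t_crit = stats.t.isf(primary_p / 2.0, df)
    null_max = np.empty(nperm, dtype=int)
    idx = np.arange(X.shape[0])
    for b in range(nperm):
        perm = rng.permutation(idx)
        pg1 = np.zeros(X.shape[0], dtype=bool)
        pg1[perm[: int(g1.sum())]] = True
        t_perm = _vectorized_t(X, pg1, ~pg1)
        null_max[b] = _max_component_size(np.abs(t_perm) > t_crit, ii, jj, n_rois)

    component_p = [
        float((1 + np.count_nonzero(null_max >= len(comp))) / (nperm + 1))
        for comp in components
    ]
    order = np.argsort(p_obs, kind="stable")[: min(top_k, ii.size)]
    top_edges = [(int(ii[e]), int(jj[e])) for e in order]
    return NBSResult(
        primary_p=primary_p,
        components=components,
        component_p=component_p,
        edge_t=t_obs,
        edge_p=p_obs,
        top_edges=top_edges,
        nperm=nperm,
    )


# ---------------------------------------------------------------------------
# group-LASSO logistic selection


@dataclass
class GroupedFeatureMatrix:
    """Subjects x features with a node-group and metric-type per feature."""

    X: np.ndarray
    group_ids: np.ndarray  # feature -> ROI group id (0-based)
    metric_ids: np.ndarray  # feature -> metric-type id (0-based, < 7)
    y: np.ndarray  # in {-1, +1}

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.group_ids = np.asarray(self.group_ids, dtype=int)
        self.metric_ids = np.asarray(self.metric_ids, dtype=int)
        self.y = np.asarray(self.y, dtype=int)
        if not np.all(np.isfinite(self.X)):
            raise DataError("feature matrix contains non-finite entries")
        if self.X.shape != (self.y.size, self.group_ids.size):
            raise DataError("X, y and group map dimensions disagree")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise DataError("labels must be -1/+1")
        counts = np.bincount(self.group_ids)
        if counts.max(initial=0) > 7:
            raise DataError("each ROI group may hold at most 7 metrics")


@dataclass
class GroupLassoModel:
    W: np.ndarray
    c: float
    lam: float
    q: int = 2
    converged: bool = True
    n_iter: int = 0
    objective_path: np.ndarray = field(default_factory=lambda: np.array([]))
    group_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def selected_groups(self, tol: float = 0.0) -> set[int]:
        out = set()
        for g in np.unique(self.group_ids):
            if np.linalg.norm(self.W[self.group_ids == g]) > tol:
                out.add(int(g))
        return out


def _logistic_objective(Xa: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    z = y * (Xa @ w)
    # stable log(1 + exp(-z))
    return float(np.sum(np.logaddexp(0.0, -z)))


def _logistic_grad(Xa: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    z = y * (Xa @ w)
    s = -y / (1.0 + np.exp(z))
    return Xa.T @ s


def _group_penalty(w: np.ndarray, group_ids: np.ndarray, lam: float) -> float:
    total = 0.0
    for g in np.unique(group_ids):
        total += np.linalg.norm(w[1:][group_ids == g])
    return lam * total


def group_lasso_logistic(
    G: GroupedFeatureMatrix,
    lam: float = 1.0,
    q: int = 2,
    max_iter: int = 10_000,
    rel_tol: float = 1e-8,
) -> GroupLassoModel:
    """Minimize logistic loss + lam * sum of group L2 norms (intercept free).

    Monotone FISTA: accelerated proximal gradient with a step of 1/L
    (L = spectral-norm bound of the logistic Hessian) and a fallback to the
    previous iterate whenever the accelerated step would raise the objective,
    so the recorded objective path is non-increasing.
    """
    if q != 2:
        raise ConfigurationError("only the L2 group norm (q=2) is implemented")
    if lam < 0:
        raise ConfigurationError("lam must be >= 0")
    X, y, gids = G.X, G.y.astype(float), G.group_ids
    n, d = X.shape
    Xa = np.column_stack([np.ones(n), X])  # column 0 = intercept
    L = 0.25 * np.linalg.norm(Xa, 2) ** 2
    step = 1.0 / L
    groups = [np.flatnonzero(gids == g) + 1 for g in np.unique(gids)]

    def prox(w: np.ndarray) -> np.ndarray:
        out = w.copy()
        for idx in groups:
            nrm = np.linalg.norm(w[idx])
            if nrm <= lam * step:
                out[idx] = 0.0
            else:
                out[idx] = (1.0 - lam * step / nrm) * w[idx]
        return out

    def F(w: np.ndarray) -> float:
        return _logistic_objective(Xa, y, w) + _group_penalty(w, gids, lam)

    w = np.zeros(d + 1)
    v = w.copy()  # momentum point
    t_k = 1.0
    path = [F(w)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = prox(v - step * _logistic_grad(Xa, y, v))
        fz = F(z)
        if fz <= path[-1]:
            t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_k**2)) / 2.0
            v = z + ((t_k - 1.0) / t_next) * (z - w)
            w, t_k = z, t_next
            path.append(fz)
            denom = max(abs(path[-2]), 1.0)
            if abs(path[-2] - path[-1]) / denom < rel_tol and it > 1:
                converged = True
                break
        else:  # accelerated step overshot: restart momentum, keep iterate
            v = w.copy()
            t_k = 1.0
            path.append(path[-1])
    if not converged:
        warnings.warn(
            f"group-LASSO did not converge in {max_iter} iterations", stacklevel=2
        )
    return GroupLassoModel(
        W=w[1:],
        c=float(w[0]),
        lam=lam,
        q=q,
        converged=converged,
        n_iter=it,
        objective_path=np.asarray(path),
        group_ids=gids.copy(),
    )


def count_selected_per_metric(
    model: GroupLassoModel, metric_ids: np.ndarray, n_metrics: int = 7
) -> np.ndarray:
    """Per metric type, how many features carry nonzero weight."""
    metric_ids = np.asarray(metric_ids, dtype=int)
    nonzero = model.W != 0
    counts = np.zeros(n_metrics, dtype=int)
    for k in range(n_metrics):
        counts[k] = int(np.count_nonzero(nonzero & (metric_ids == k)))
    return counts
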