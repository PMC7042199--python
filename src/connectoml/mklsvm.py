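"""Multi-kernel SVM classification.

Each feature view becomes a linear kernel on train-fold-standardized
features, trace-normalized so views are scale-comparable.  Kernel weights
beta live on the simplex and are grid-searched jointly with the SVM box
constraint C by an inner leave-one-out loop nested inside the outer LOOCV.
The box-constrained dual QP itself is delegated to libsvm (scikit-learn's
``SVC`` with a precomputed kernel); alphas, bias and support indices are
re-exposed and KKT feasibility is checked after every solve.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from connectoml.errors import ConfigurationError, DataError

DEFAULT_C_GRID = tuple(2.0 ** np.arange(-5, 6))
DEFAULT_BETA_STEP = 0.1


# ---------------------------------------------------------------------------
# kernels


@dataclass
class KernelView:
    """A linear kernel built from one feature view.

    Scalers (train-fold mean/SD) and the standardized training features are
    kept so that test rows can be mapped into the same space without leaking.
    """

    name: str
    K: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    keep: np.ndarray  # mask of non-constant features retained
    train_std: np.ndarray
    scale: float  # trace normalization factor

    def cross(self, features: np.ndarray) -> np.ndarray:
        """Kernel rows between new subjects and the training subjects."""
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        Xs = (X[:, self.keep] - self.mean) / self.sd
        return self.scale * (Xs @ self.train_std.T)


def build_kernel(features: np.ndarray, name: str = "view") -> KernelView:
    """Linear kernel on standardized features, trace-normalized to n."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise DataError(f"view {name!r}: non-finite features")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"view {name!r}: dropped {int((~keep).sum())} zero-variance feature(s)",
            stacklevel=2,
        )
    if not keep.any():
        raise DataError(f"view {name!r}: all features are constant")
    mean = X[:, keep].mean(axis=0)
    sdk = sd[keep]
    Xs = (X[:, keep] - mean) / sdk
    K = Xs @ Xs.T
    trace = np.trace(K)
    scale = X.shape[0] / trace if trace > 0 else 1.0
    return KernelView(
        name=name, K=scale * K, mean=mean, sd=sdk, keep=keep, train_std=Xs, scale=scale
    )


def combine_kernels(kernels: list[np.ndarray], betas: np.ndarray) -> np.ndarray:
    """Elementwise convex combination sum(beta_m * K_m)."""
    betas = np.asarray(betas, dtype=float)
    if len(kernels) != betas.size:
        raise ConfigurationError("one beta per kernel required")
    if np.any(betas < -1e-12) or abs(betas.sum() - 1.0) > 1e-9:
        raise ConfigurationError(
            f"betas must be non-negative and sum to 1, got {betas.tolist()}"
        )
    shape = kernels[0].shape
    out = np.zeros(shape)
    for b, K in zip(betas, kernels):
        if K.shape != shape:
            raise DataError("kernel shapes disagree")
        out += b * K
    return out


def beta_simplex_grid(n_views: int, step: float = DEFAULT_BETA_STEP) -> list[tuple[float, ...]]:
    """All simplex-grid weight vectors with the given resolution, sorted."""
    units = round(1.0 / step)
    if abs(units * step - 1.0) > 1e-9:
        raise ConfigurationError("beta step must divide 1")
    grid = []
    for combo in itertools.combinations_with_replacement(range(n_views), units):
        counts = [combo.count(v) for v in range(n_views)]
        grid.append(tuple(c * step for c in counts))
    return sorted(grid)


# ---------------------------------------------------------------------------
# SVM dual


@dataclass
class MKLModel:
    alphas: np.ndarray
    b: float
    y: np.ndarray
    C: float
    betas: np.ndarray | None = None
    support: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def coef(self) -> np.ndarray:
        """y_i * alpha_i over all training subjects."""
        return self.alphas * self.y


def svm_dual_solve(K: np.ndarray, y: np.ndarray, C: float, tol: float = 1e-6) -> MKLModel:
    """Solve the box-constrained SVM dual on a precomputed kernel.

    Returns alphas in [0, C] with sum(alpha * y) = 0 and the bias b.
    """
    y = np.asarray(y, dtype=float)
    classes = set(np.unique(y))
    if classes != {-1.0, 1.0}:
        raise DataError(f"labels must contain both -1 and +1, got {sorted(classes)}")
    K = np.asarray(K, dtype=float)
    if K.shape != (y.size, y.size):
        raise DataError("kernel / label dimension mismatch")
    clf = SVC(kernel="precomputed", C=C, tol=tol, shrinking=False)
    clf.fit(K, y)
    alphas = np.zeros(y.size)
    sv = clf.support_
    alphas[sv] = np.abs(clf.dual_coef_[0])
    b = float(clf.intercept_[0])
    model = MKLModel(alphas=alphas, b=b, y=y.copy(), C=C, support=sv.copy())
    if abs(np.sum(alphas * y)) > 1e-6 * max(1.0, C):
        raise RuntimeError("dual equality constraint violated")
    return model


def predict(model: MKLModel, K_cross: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decision values and sign labels for test-vs-train kernel rows."""
    K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
    if K_cross.shape[1] != model.alphas.size:
        raise DataError(
            f"kernel rows have {K_cross.shape[1]} columns, expected {model.alphas.size}"
        )
    decisions = K_cross @ model.coef() + model.b
    labels = np.where(decisions >= 0, 1, -1)
    return decisions, labels


def duality_gap(model: MKLModel, K: np.ndarray) -> float:
    """Primal minus dual objective for a fitted model on its training kernel."""
    coef = model.coef()
    wtw = float(coef @ K @ coef)
    margins = model.y * (K @ coef + model.b)
    xi = np.maximum(0.0, 1.0 - margins)
    primal = 0.5 * wtw + model.C * xi.sum()
    dual = model.alphas.sum() - 0.5 * wtw
    return primal - dual


# ---------------------------------------------------------------------------
# evaluation metrics


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise DataError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == -1) & (y_pred == -1))),
            FP=int(np.sum((y_true == -1) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == -1))),
        )


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity and specificity as percentages."""
    total = counts.TP + counts.TN + counts.FP + counts.FN
    pos = counts.TP + counts.FN
    neg = counts.TN + counts.FP
    return {
        "accuracy": 100.0 * (counts.TP + counts.TN) / total if total else float("nan"),
        "sensitivity": 100.0 * counts.TP / pos if pos else float("nan"),
        "specificity": 100.0 * counts.TN / neg if neg else float("nan"),
    }


def roc_auc(decisions: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """AUC by the rank (Mann-Whitney) formulation plus ROC sweep points.

    Ties get half credit.  Returns (auc, points) with points as rows of
    (false-positive rate, true-positive rate).
    """
    d = np.asarray(decisions, dtype=float)
    y = np.asarray(labels)
    pos = y == 1
    neg = y == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes must be present for ROC analysis")
    ranks = stats.rankdata(d)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    thresholds = np.concatenate(([np.inf], np.unique(d)[::-1]))
    points = np.array(
        [
            (
                np.sum(d[neg] >= t) / n_neg,
                np.sum(d[pos] >= t) / n_pos,
            )
            for t in thresholds
        ]
    )
    return float(auc), points


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())


def delong_test(
    decisions_a: np.ndarray, decisions_b: np.ndarray, labels: np.ndarray
) -> dict[str, float]:
    """Paired DeLong test for the difference between two correlated AUCs."""
    a = np.asarray(decisions_a, dtype=float)
    b = np.asarray(decisions_b, dtype=float)
    y = np.asarray(labels)
    if a.shape != b.shape or a.shape != y.shape:
        raise DataError("score vectors and labels must share one subject axis")
    if not ((y == 1).any() and (y == -1).any()):
        raise DataError("both classes must be present")
    v10_a, v01_a, auc_a = _placements(a, y)
    v10_b, v01_b, auc_b = _placements(b, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        return {"z": 0.0, "p": 1.0, "auc_a": auc_a, "auc_b": auc_b, "degenerate": True}
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return {"z": float(z), "p": float(p), "auc_a": auc_a, "auc_b": auc_b, "degenerate": False}


# ---------------------------------------------------------------------------
# nested LOOCV


@dataclass
class MKLResult:
    decisions: np.ndarray
    predicted: np.ndarray
    y: np.ndarray
    fold_betas: list[tuple[float, ...]]
    fold_C: list[float]
    confusion: ConfusionCounts
    metrics: dict[str, float]
    auc: float
    roc_points: np.ndarray


def loocv_mkl(
    view_features: dict[str, np.ndarray],
    y: np.ndarray,
    beta_grid: list[tuple[float, ...]] | None = None,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    inner: bool = True,
) -> MKLResult:
    """Nested leave-one-out MKL-SVM.

    Outer LOOCV holds one subject out; an inner LOOCV over the remaining
    subjects grid-searches (beta, C) for best inner accuracy (ties prefer
    smaller C, then lexicographically smallest beta).  Kernels and scalers
    for every fold are recomputed from that fold's training subjects only.
    When ``inner`` is false the first grid point is used everywhere.
    """
    names = list(view_features)
    feats = [np.asarray(view_features[k], dtype=float) for k in names]
    y = np.asarray(y, dtype=int)
    n = y.size
    if n < 4:
        raise ConfigurationError("LOOCV requires n >= 4")
    if beta_grid is None:
        beta_grid = beta_simplex_grid(len(names))
    if not beta_grid or not len(C_grid):
        raise ConfigurationError("grids must be non-empty")
    candidates = [
        (tuple(bb), float(C)) for C in sorted(C_grid) for bb in beta_grid
    ]

    decisions = np.zeros(n)
    fold_betas: list[tuple[float, ...]] = []
    fold_C: list[float] = []
    all_idx = np.arange(n)
    for held in range(n):
        train = all_idx[all_idx != held]
        y_tr = y[train]
        if len(set(y_tr.tolist())) < 2:
            raise DataError("training fold has a single class")
        if inner and len(candidates) > 1:
            # pre-build kernels per inner fold (independent of beta, C)
            inner_folds = []
            for j in range(train.size):
                it = np.delete(train, j)
                val = train[j]
                if len(set(y[it].tolist())) < 2:
                    warnings.warn("inner fold with one class skipped", stacklevel=2)
                    continue
                views = [build_kernel(f[it], name=nm) for f, nm in zip(feats, names)]
                rows = [v.cross(f[val]) for v, f in zip(views, feats)]
                inner_folds.append((views, rows, it, int(y[val])))
            best = None
            for betas, C in candidates:
                bvec = np.asarray(betas)
                correct = 0
                for views, rows, it, y_val in inner_folds:
                    Kc = combine_kernels([v.K for v in views], bvec)
                    model = svm_dual_solve(Kc, y[it], C)
                    row = combine_kernels(rows, bvec)
                    _, lab = predict(model, row)
                    correct += int(lab[0] == y_val)
                acc = correct / max(len(inner_folds), 1)
                key = (-acc, C, betas)  # ties -> smaller C, then smaller beta
                if best is None or key < best[0]:
                    best = (key, betas, C)
            chosen_betas, chosen_C = best[1], best[2]
        else:
            chosen_betas, chosen_C = candidates[0]
        fold_betas.append(chosen_betas)
        fold_C.append(chosen_C)
        views = [build_kernel(f[train], name=nm) for f, nm in zip(feats, names)]
        bvec = np.asarray(chosen_betas)
        K = combine_kernels([v.K for v in views], bvec)
        model = svm_dual_solve(K, y_tr, chosen_C)
        model.betas = bvec
        row = combine_kernels([v.cross(f[held]) for v, f in zip(views, feats)], bvec)
        dec, _ = predict(model, row)
        decisions[held] = dec[0]

    predicted = np.where(decisions >= 0, 1, -1)
    confusion = ConfusionCounts.from_predictions(y, predicted)
    metrics = confusion_metrics(confusion)
    auc, roc_points = roc_auc(decisions, y)
    return MKLResult(
        decisions=decisions,
        predicted=predicted,
        y=y.copy(),
        fold_betas=fold_betas,
        fold_C=fold_C,
        confusion=confusion,
        metrics=metrics,
        auc=auc,
        roc_points=roc_points,
    )
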