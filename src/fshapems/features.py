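"""Residual features, PCA reduction, SVM model selection and evaluation.

The classification feature for each eye is its residual thickness field on
the template mesh, f_m − f̃_i: the signed offset between the template
signal and the subject's registered signal at every template vertex.
Residual matrices are reduced by PCA (retained dimension chosen from the
cumulative scree curve), and an SVM is selected by leave-one-out grid
search over kernels and hyperparameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .grids import Label
from .registration import AtlasResult

log = logging.getLogger(__name__)

__all__ = [
    "ResidualSet",
    "PCAModel",
    "SVMConfig",
    "EvalMetrics",
    "compute_residuals",
    "fit_pca",
    "scree_curve",
    "pca_transform",
    "choose_k",
    "svm_kernel",
    "default_svm_grid",
    "loo_grid_search",
    "fit_svm",
    "evaluate",
    "pointwise_ttest_fraction",
]


@dataclass
class ResidualSet:
    """N×M residual matrix (µm): one row per eye, one column per template vertex."""

    matrix: np.ndarray
    labels: list[Label]
    vertex_map: np.ndarray  # template lattice indices, (M, 2)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("one label per residual row required")


def compute_residuals(atlas: AtlasResult, labels: list[Label]) -> ResidualSet:
    """Residual rows f_m − f̃_i on the template mesh."""
    fm = atlas.template.signal
    rows = []
    for reg in atlas.registered:
        if reg.mesh.n_vertices != atlas.template.mesh.n_vertices or not np.array_equal(
            reg.mesh.faces, atlas.template.mesh.faces
        ):
            raise ValueError("registered F-shape does not share template connectivity")
        rows.append(fm - reg.signal)
    return ResidualSet(np.array(rows), list(labels), atlas.template.mesh.lattice_index.copy())


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    eigenvalues: np.ndarray  # non-increasing, ≥ 0
    components: np.ndarray  # (m, M) right singular directions, rows orthonormal
    k: int
    mean_row: np.ndarray
    center: bool = True

    @property
    def components_k(self) -> np.ndarray:
        return self.components[: self.k]


def fit_pca(
    matrix: np.ndarray,
    k: int | None = None,
    flatten_gain: float = 0.01,
    center: bool = True,
) -> PCAModel:
    """Eigen-decomposition of the row covariance via SVD of the centered matrix.

    ``k`` defaults to the scree rule: the smallest k whose marginal
    cumulative-ratio gain drops below ``flatten_gain`` (the point where the
    cumulative scree curve flattens out).
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA requires at least 2 rows")
    mean_row = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mean_row
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (n - 1)
    model = PCAModel(eigvals, Vt, k=len(eigvals), mean_row=mean_row, center=center)
    model.k = choose_k(model, flatten_gain) if k is None else min(k, len(eigvals))
    return model


def scree_curve(model: PCAModel) -> np.ndarray:
    """Cumulative eigenvalue-ratio curve Σ_{i≤k} λ_i / Σ_i λ_i for k = 1…m."""
    tot = model.eigenvalues.sum()
    if tot == 0:
        return np.ones_like(model.eigenvalues)
    return np.cumsum(model.eigenvalues) / tot


def choose_k(model: PCAModel, flatten_gain: float = 0.01) -> int:
    curve = scree_curve(model)
    gains = np.diff(np.concatenate([[0.0], curve]))
    below = np.nonzero(gains < flatten_gain)[0]
    # keep everything before the first flat component, never fewer than one
    return max(int(below[0]), 1) if below.size else len(curve)


def pca_transform(model: PCAModel, rows: np.ndarray) -> np.ndarray:
    """Project rows onto the first k components: (rows − mean)·V_kᵀ."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return (rows - model.mean_row) @ model.components_k.T


# ---------------------------------------------------------------------------
# SVM


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "linear"  # linear | polynomial | rbf | sigmoid
    gamma: float = 1.0
    r: float = 0.0
    degree: int = 3
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel not in {"linear", "polynomial", "rbf", "sigmoid"}:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.kernel in {"polynomial", "rbf"} and self.gamma <= 0:
            raise ValueError("gamma must be > 0 for polynomial/rbf kernels")
        if self.C <= 0:
            raise ValueError("C must be > 0")


def svm_kernel(xi: np.ndarray, xj: np.ndarray, cfg: SVMConfig) -> float:
    """The four standard SVM kernel functions, evaluated on a vector pair."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError("vectors must have equal length")
    if cfg.kernel == "linear":
        return float(xi @ xj)
    if cfg.kernel == "polynomial":
        return float((cfg.gamma * (xi @ xj) + cfg.r) ** cfg.degree)
    if cfg.kernel == "rbf":
        return float(np.exp(-cfg.gamma * np.sum((xi - xj) ** 2)))
    return float(np.tanh(cfg.gamma * (xi @ xj) + cfg.r))


_SKLEARN_KERNEL = {"linear": "linear", "polynomial": "poly", "rbf": "rbf", "sigmoid": "sigmoid"}


def fit_svm(features: np.ndarray, y: np.ndarray, cfg: SVMConfig) -> SVC:
    clf = SVC(
        kernel=_SKLEARN_KERNEL[cfg.kernel],
        C=cfg.C,
        gamma=cfg.gamma,
        coef0=cfg.r,
        degree=cfg.degree,
    )
    clf.fit(features, y)
    return clf


def _encode(labels) -> np.ndarray:
    """MS is the positive class (+1)."""
    return np.array([1 if Label(l) == Label.MS else 0 for l in labels])


def default_svm_grid() -> list[SVMConfig]:
    """Linear-kernel grid in the neighborhood of the selected hyperparameters."""
    grid = []
    for C in [0.1, 0.4, 1.0, 4.0, 10.0, 40.0, 100.0]:
        grid.append(SVMConfig(kernel="linear", C=C))
    for gamma in [1e-3, 1e-2, 1e-1, 1.0]:
        for C in [0.1, 1.0, 10.0, 100.0]:
            grid.append(SVMConfig(kernel="rbf", gamma=gamma, C=C))
    return grid


def loo_grid_search(
    features: np.ndarray, labels, grid: list[SVMConfig]
) -> tuple[SVMConfig, float, SVC, list[dict]]:
    """Leave-one-out grid search; ties broken by grid order.

    The CV score of a configuration is the fraction of held-out samples it
    classifies correctly across the N single-sample folds.  The winning
    configuration is refit on the full training set.
    """
    X = np.asarray(features, dtype=float)
    y = _encode(labels)
    n = len(y)
    if n < 2 or not grid:
        raise ValueError("need at least 2 samples and a non-empty grid")
    report = []
    best: tuple[float, int] | None = None
    for gi, cfg in enumerate(grid):
        correct = 0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            ytr = y[mask]
            if len(np.unique(ytr)) < 2:
                warnings.warn(
                    "a class is absent from a LOO training fold; fold scored incorrect",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            clf = fit_svm(X[mask], ytr, cfg)
            correct += int(clf.predict(X[i : i + 1])[0] == y[i])
        score = correct / n
        report.append({"config": cfg, "cv_score": score})
        if best is None or score > best[0]:
            best = (score, gi)
    best_score, best_i = best
    best_cfg = grid[best_i]
    final = fit_svm(X, y, best_cfg)
    return best_cfg, best_score, final, report


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class EvalMetrics:
    TP: int
    TN: int
    FP: int
    FN: int
    ACC: float
    SEN: float
    SPE: float
    PREC: float
    F1: float
    FPR: float
    AUC: float
    roc: np.ndarray  # (n, 2) columns FPR, SEN

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("TP", "TN", "FP", "FN")}
        d.update(
            {k: float(getattr(self, k)) for k in ("ACC", "SEN", "SPE", "PREC", "F1", "FPR", "AUC")}
        )
        return d


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator)", RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def metrics_from_counts(TP: int, TN: int, FP: int, FN: int) -> dict:
    """Confusion-count metrics: ACC, SEN, SPE, PREC, F1 and FPR."""
    ACC = _ratio(TP + TN, TP + TN + FP + FN, "ACC")
    SEN = _ratio(TP, TP + FN, "SEN")
    SPE = _ratio(TN, TN + FP, "SPE")
    PREC = _ratio(TP, TP + FP, "PREC")
    if np.isnan(PREC) or np.isnan(SEN) or (PREC + SEN) == 0:
        F1 = float("nan")
    else:
        F1 = 2 * PREC * SEN / (PREC + SEN)
    FPR = _ratio(FP, FP + TN, "FPR")
    return {"ACC": ACC, "SEN": SEN, "SPE": SPE, "PREC": PREC, "F1": F1, "FPR": FPR}


def evaluate(model: SVC, test_features: np.ndarray, test_labels) -> EvalMetrics:
    """Hard-prediction confusion metrics plus threshold-swept ROC/AUC.

    The ROC sweeps the SVM decision score (signed distance to the
    separating hyperplane); AUC is the trapezoidal area under it.
    """
    X = np.atleast_2d(np.asarray(test_features, dtype=float))
    y = _encode(test_labels)
    if len(y) == 0:
        raise ValueError("empty test set")
    pred = model.predict(X)
    TP = int(np.sum((pred == 1) & (y == 1)))
    TN = int(np.sum((pred == 0) & (y == 0)))
    FP = int(np.sum((pred == 1) & (y == 0)))
    FN = int(np.sum((pred == 0) & (y == 1)))
    m = metrics_from_counts(TP, TN, FP, FN)
    if len(np.unique(y)) < 2:
        auc = float("nan")
        roc = np.array([[0.0, 0.0], [1.0, 1.0]])
        warnings.warn("single-class test set: AUC undefined", RuntimeWarning, stacklevel=2)
    else:
        scores = model.decision_function(X)
        fpr, tpr, _ = roc_curve(y, scores)
        roc = np.column_stack([fpr, tpr])
        auc = float(np.trapezoid(tpr, fpr))
    return EvalMetrics(TP=TP, TN=TN, FP=FP, FN=FN, AUC=auc, roc=roc, **m)


# ---------------------------------------------------------------------------
# Pointwise group comparison


def pointwise_ttest_fraction(
    group_a: np.ndarray,
    group_b: np.ndarray,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> float:
    """Fraction of vertices with a significant two-sample t-test (p < alpha).

    Welch's unequal-variance test by default.  Vertices where both groups
    have zero variance are assigned p = 1 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 samples per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    degenerate = np.isnan(p)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} vertex(es) with zero variance in both groups; p set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.where(degenerate, 1.0, p)
    return float(np.mean(p < alpha))
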