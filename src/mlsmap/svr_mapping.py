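"""Support vector regression on lesion designs: LOOCV hyperparameter
training, model fitting and voxelwise beta-map extraction.

Covers both the single-lesion (SVR-LSM) and multi-lesion (SVR-MLSM) cases;
the design's column blocks decide which one you are running. The multi-
lesion model supports the linear kernel only.

Hyperparameter grids default to integer powers of two across the published
search ranges: C in 2^-20 .. 2^20 for the linear kernel, and C in
2^-20 .. 2^6 with kernel scale gamma in 1 .. 16 for the RBF kernel.

The deficit vector is z-scored before training by default (epsilon = 0.1 is
interpreted on that scale); betas are reported on the standardized scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVR

from .design_matrix import MultiLesionDesign

__all__ = [
    "FittedSvr",
    "TrainingReport",
    "BetaMaps",
    "default_c_grid",
    "default_gamma_grid",
    "loocv_train",
    "fit_svr",
    "extract_beta",
    "train_and_fit",
]

DEFAULT_EPSILON = 0.1


def default_c_grid(kernel: str = "linear") -> np.ndarray:
    """Powers of two across the published C range for the kernel."""
    if kernel == "linear":
        return 2.0 ** np.arange(-20, 21)
    if kernel == "rbf":
        return 2.0 ** np.arange(-20, 7)
    raise ValueError(f"unknown kernel {kernel!r}")


def default_gamma_grid() -> np.ndarray:
    """Integer kernel scales 1..16 for the RBF kernel."""
    return np.arange(1, 17, dtype=float)


@dataclass
class FittedSvr:
    """An epsilon-insensitive SVR solution and its provenance."""

    kernel: str
    C: float
    gamma: float | None
    epsilon: float
    estimator: SVR
    n_features: int

    @property
    def dual_coef(self) -> np.ndarray:
        return self.estimator.dual_coef_.ravel()

    @property
    def intercept(self) -> float:
        return float(self.estimator.intercept_[0])

    @property
    def support_vectors(self) -> np.ndarray:
        return self.estimator.support_vectors_

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.estimator.predict(x)


@dataclass
class TrainingReport:
    kernel: str
    c_grid: np.ndarray
    gamma_grid: np.ndarray | None
    accuracy: np.ndarray            # (len(c_grid),) or (len(c_grid), len(gamma_grid))
    p_value: np.ndarray
    best_C: float
    best_gamma: float | None
    best_accuracy: float
    best_p: float
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "kernel": self.kernel,
            "c_grid": self.c_grid.tolist(),
            "gamma_grid": None if self.gamma_grid is None else self.gamma_grid.tolist(),
            "accuracy": self.accuracy.tolist(),
            "p_value": self.p_value.tolist(),
            "best_C": self.best_C,
            "best_gamma": self.best_gamma,
            "best_accuracy": self.best_accuracy,
            "best_p": self.best_p,
        }


@dataclass
class BetaMaps:
    """Per lesion-type voxel weights plus provenance."""

    blocks: dict[str, np.ndarray]
    voxels: dict[str, np.ndarray]
    kernel: str
    volume_mode: str
    C: float
    gamma: float | None = None

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.blocks[t] for t in self.blocks]) if self.blocks \
            else np.empty(0)


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("deficit vector is constant; cannot standardize or correlate")
    return (v - v.mean()) / sd


def _pearson_with_p(pred: np.ndarray, real: np.ndarray) -> tuple[float, float]:
    """Pearson r and one-sided p for r > 0 via the t approximation."""
    if np.std(pred) == 0 or np.std(real) == 0:
        return 0.0, 1.0
    r = float(np.corrcoef(pred, real)[0, 1])
    n = len(real)
    r_c = min(max(r, -0.999999999999), 0.999999999999)
    tval = r_c * np.sqrt((n - 2) / (1.0 - r_c ** 2))
    return r, float(stats.t.sf(tval, df=n - 2))


def _make_svr(kernel: str, C: float, gamma: float | None, epsilon: float,
              tol: float = 1e-3, max_iter: int = -1) -> SVR:
    if kernel == "linear":
        return SVR(kernel="linear", C=C, epsilon=epsilon, tol=tol, max_iter=max_iter)
    if kernel == "rbf":
        if gamma is None:
            raise ValueError("rbf kernel needs gamma")
        return SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon, tol=tol,
                   max_iter=max_iter)
    raise ValueError(f"unknown kernel {kernel!r}")


#: iteration cap for grid-search exploration fits. libsvm's SMO can spin
#: near-indefinitely at very large C on data it cannot fit within epsilon;
#: approximate solutions are fine for hyperparameter comparison (those C
#: never win the grid search), while final fits stay exact.
GRID_SEARCH_MAX_ITER = 100_000


def _loocv_predictions(x: np.ndarray, y: np.ndarray, kernel: str, C: float,
                       gamma: float | None, epsilon: float,
                       max_iter: int = GRID_SEARCH_MAX_ITER) -> np.ndarray:
    m = len(y)
    preds = np.empty(m)
    idx = np.arange(m)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        for i in range(m):
            train = idx != i
            est = _make_svr(kernel, C, gamma, epsilon, max_iter=max_iter)
            est.fit(x[train], y[train])
            preds[i] = est.predict(x[i:i + 1])[0]
    return preds


def loocv_train(
    design: MultiLesionDesign,
    deficit: np.ndarray,
    kernel: str = "linear",
    c_grid: np.ndarray | None = None,
    gamma_grid: np.ndarray | None = None,
    epsilon: float = DEFAULT_EPSILON,
    standardize: bool = True,
) -> TrainingReport:
    """Grid search by leave-one-out cross-validation.

    For each grid point, M leave-one-out fits produce M held-out
    predictions; accuracy is the Pearson correlation between those
    predictions and the real deficit scores. Ties are broken toward
    smaller C, then smaller gamma.
    """
    y = np.asarray(deficit, dtype=float)
    if design.n_subjects != len(y):
        raise ValueError("deficit length does not match design subjects")
    if design.n_subjects < 10:
        warnings.warn(f"M={design.n_subjects} subjects is very small for LOOCV training",
                      stacklevel=2)
    y = _zscore(y) if standardize else y
    if np.std(y) == 0:
        raise ValueError("deficit vector is constant; accuracy is undefined")
    c_grid = default_c_grid(kernel) if c_grid is None else np.asarray(c_grid, float)
    if c_grid.size == 0:
        raise ValueError("empty C grid")
    x = design.matrix

    if kernel == "linear":
        acc = np.empty(c_grid.size)
        pvl = np.empty(c_grid.size)
        for a, C in enumerate(c_grid):
            preds = _loocv_predictions(x, y, kernel, C, None, epsilon)
            acc[a], pvl[a] = _pearson_with_p(preds, y)
        best = int(np.argmax(acc))  # argmax takes the first (smallest C) on ties
        return TrainingReport(kernel, c_grid, None, acc, pvl,
                              best_C=float(c_grid[best]), best_gamma=None,
                              best_accuracy=float(acc[best]), best_p=float(pvl[best]))

    gamma_grid = default_gamma_grid() if gamma_grid is None else np.asarray(gamma_grid, float)
    if gamma_grid.size == 0:
        raise ValueError("empty gamma grid")
    acc = np.empty((c_grid.size, gamma_grid.size))
    pvl = np.empty_like(acc)
    for a, C in enumerate(c_grid):
        for g, gamma in enumerate(gamma_grid):
            preds = _loocv_predictions(x, y, kernel, C, gamma, epsilon)
            acc[a, g], pvl[a, g] = _pearson_with_p(preds, y)
    flat = int(np.argmax(acc))
    a, g = np.unravel_index(flat, acc.shape)
    return TrainingReport(kernel, c_grid, gamma_grid, acc, pvl,
                          best_C=float(c_grid[a]), best_gamma=float(gamma_grid[g]),
                          best_accuracy=float(acc[a, g]), best_p=float(pvl[a, g]))


def fit_svr(
    design: MultiLesionDesign | np.ndarray,
    deficit: np.ndarray,
    kernel: str = "linear",
    C: float = 1.0,
    gamma: float | None = None,
    epsilon: float = DEFAULT_EPSILON,
    tol: float = 1e-3,
) -> FittedSvr:
    """Fit one epsilon-insensitive SVR; deterministic (convex problem).

    Operates on the deficit vector as given (standardize upstream if
    desired).
    """
    if C <= 0 or (gamma is not None and gamma <= 0) or epsilon < 0:
        raise ValueError("C and gamma must be positive, epsilon non-negative")
    x = design.matrix if isinstance(design, MultiLesionDesign) else np.asarray(design, float)
    y = np.asarray(deficit, dtype=float)
    est = _make_svr(kernel, C, gamma, epsilon, tol=tol)
    est.fit(x, y)
    if est.fit_status_ != 0:
        raise RuntimeError("SVR solver did not converge (libsvm iteration cap reached)")
    return FittedSvr(kernel=kernel, C=float(C), gamma=gamma, epsilon=float(epsilon),
                     estimator=est, n_features=x.shape[1])


def extract_beta(model: FittedSvr, design: MultiLesionDesign) -> BetaMaps:
    """Voxelwise beta maps from the dual expansion beta = sum_s lambda_s x_s.

    For the linear kernel this is the exact primal weight vector; for the
    RBF kernel it is the first-order sensitivity approximation on the same
    dual coefficients. The vector is split into the design's per-lesion-type
    blocks.
    """
    if model.n_features != design.n_columns:
        raise ValueError("model was not fitted on this design")
    if model.estimator.support_.size:
        beta = model.dual_coef @ model.support_vectors
    else:
        beta = np.zeros(design.n_columns)
    blocks = {t: beta[design.block_slices[t]].copy() for t in design.block_slices}
    voxels = {t: design.block_voxels(t) for t in design.block_slices}
    return BetaMaps(blocks=blocks, voxels=voxels, kernel=model.kernel,
                    volume_mode=design.volume_mode, C=model.C, gamma=model.gamma)


def train_and_fit(
    design: MultiLesionDesign,
    deficit: np.ndarray,
    kernel: str = "linear",
    c_grid: np.ndarray | None = None,
    gamma_grid: np.ndarray | None = None,
    epsilon: float = DEFAULT_EPSILON,
    standardize: bool = True,
) -> tuple[TrainingReport, FittedSvr, BetaMaps]:
    """LOOCV-train hyperparameters, refit on the full cohort and extract
    beta maps. Multi-block designs (SVR-MLSM) accept the linear kernel only."""
    if kernel == "rbf" and sum(sl.stop > sl.start for sl in design.block_slices.values()) > 1:
        raise ValueError("the multi-lesion model supports the linear kernel only")
    report = loocv_train(design, deficit, kernel, c_grid, gamma_grid, epsilon,
                         standardize=standardize)
    y = _zscore(deficit) if standardize else np.asarray(deficit, float)
    model = fit_svr(design, y, kernel, C=report.best_C, gamma=report.best_gamma,
                    epsilon=epsilon)
    return report, model, extract_beta(model, design)
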