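"""Significant-cluster volumes of interest (SVOI) and the nested
behavior-prediction ladder.

Per subject, the SVOI of a lesion type is the volume (ml) of their FULL
lesion mask that falls inside the union of the significant clusters of
that type. SVOI vectors from different mapping models then enter nested
linear SVR prediction models of the raw behavior score; the added value of
a map is the change in leave-one-out Pearson accuracy when its SVOI is
added to the covariate baseline.

Predictors are z-scored inside each training fold (no information from the
held-out subject leaks into the fit); the raw score is left unstandardized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lesion_io import LesionTensor
from .permutation_inference import ClusterSet
from .svr_mapping import (DEFAULT_EPSILON, GRID_SEARCH_MAX_ITER, _make_svr,
                          _pearson_with_p)

__all__ = [
    "SVOIVector",
    "ModelSpec",
    "PredictionLadder",
    "compute_svoi",
    "loocv_predict",
    "run_ladder",
    "nested_ladder",
]


@dataclass
class SVOIVector:
    source: str                      # which mapping model produced the clusters
    lesion_type: str
    subject_ids: list[str]
    volume_ml: np.ndarray            # per-subject overlap volume, ml


@dataclass
class ModelSpec:
    name: str
    predictors: list[str]
    baseline: str | None = None      # name of the model to report the delta against


@dataclass
class PredictionLadder:
    models: list[ModelSpec]
    accuracy: dict[str, float]
    p_value: dict[str, float]
    best_C: dict[str, float]
    delta: dict[str, float]          # accuracy minus the baseline model's accuracy

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.models:
            rows.append({
                "model": m.name, "predictors": "+".join(m.predictors),
                "accuracy": self.accuracy[m.name], "p": self.p_value[m.name],
                "best_C": self.best_C[m.name],
                "baseline": m.baseline or "",
                "delta_vs_baseline": self.delta.get(m.name, np.nan),
            })
        return pd.DataFrame(rows)


def nested_ladder(svoi_names: list[str] | None = None) -> list[ModelSpec]:
    """The canonical nested model ladder.

    Model 1: demographics (age, sex, education); Model 2: + AIL volume;
    Model 3: + WMH volume. Each entry of ``svoi_names`` is appended to
    Model 3 (with Model 3 as its delta baseline), and when two or more SVOI
    predictors are given a final model adds them jointly.
    """
    models = [
        ModelSpec("model1", ["age", "sex", "education"]),
        ModelSpec("model2", ["age", "sex", "education", "ail_volume_ml"],
                  baseline="model1"),
        ModelSpec("model3", ["age", "sex", "education", "ail_volume_ml",
                             "wmh_volume_ml"], baseline="model2"),
    ]
    base = models[-1].predictors
    for nm in svoi_names or []:
        models.append(ModelSpec(f"model3+{nm}", base + [nm], baseline="model3"))
    if svoi_names and len(svoi_names) > 1:
        models.append(ModelSpec("model3+" + "+".join(svoi_names),
                                base + list(svoi_names), baseline="model3"))
    return models


def compute_svoi(clusters: ClusterSet, tensor: LesionTensor,
                 source: str = "") -> SVOIVector:
    """Overlap volume between each subject's lesion mask and the union of
    the significant clusters of the tensor's lesion type.

    Use the unfiltered tensor: the overlap is anatomical, so the full masks
    count, not just the prevalence-filtered voxels.
    """
    union = clusters.union_voxels(tensor.lesion_type)
    if union.size == 0:
        warnings.warn(f"no significant {tensor.lesion_type} clusters: SVOI is all zero",
                      stacklevel=2)
        vols = np.zeros(tensor.n_subjects)
    else:
        inside = np.isin(tensor.voxel_index, union)
        vols = tensor.data[:, inside].sum(axis=1) * tensor.grid.voxel_volume_ml
    return SVOIVector(source=source, lesion_type=tensor.lesion_type,
                      subject_ids=list(tensor.subject_ids), volume_ml=vols)


def _fold_standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def loocv_predict(x: np.ndarray, y: np.ndarray, c_grid: np.ndarray,
                  epsilon: float = DEFAULT_EPSILON) -> tuple[np.ndarray, float, float, float]:
    """Linear-SVR LOOCV predictions with fold-internal predictor z-scoring.

    Returns (predictions at the best C, accuracy, p, best C); ties in the
    grid go to the smaller C.
    """
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = len(y)
    idx = np.arange(m)
    best = None
    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", category=ConvergenceWarning)
        for C in np.asarray(c_grid, dtype=float):
            preds = np.empty(m)
            for i in range(m):
                tr = idx != i
                xtr, xte = _fold_standardize(x[tr], x[i:i + 1])
                est = _make_svr("linear", C, None, epsilon,
                                max_iter=GRID_SEARCH_MAX_ITER)
                est.fit(xtr, y[tr])
                preds[i] = est.predict(xte)[0]
            r, p = _pearson_with_p(preds, y)
            if best is None or r > best[1]:
                best = (preds, r, p, float(C))
    return best


def run_ladder(
    table: pd.DataFrame,
    svois: dict[str, SVOIVector],
    score_column: str,
    models: list[ModelSpec],
    c_grid: np.ndarray | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> PredictionLadder:
    """Evaluate a nested set of prediction models of the raw score.

    Model predictors name either cohort-table columns or keys of ``svois``.
    Note the caveat: when the SVOIs were derived on this same cohort the
    ladder is an in-sample comparison, not external validation.
    """
    if c_grid is None:
        c_grid = 2.0 ** np.arange(-10, 11)
    if score_column not in table.columns:
        raise ValueError(f"cohort table has no score column {score_column!r}")
    y = table[score_column].to_numpy(dtype=float)

    def predictor_matrix(names: list[str]) -> np.ndarray:
        cols = []
        for nm in names:
            if nm in table.columns:
                cols.append(table[nm].to_numpy(dtype=float))
            elif nm in svois:
                v = svois[nm]
                if len(v.volume_ml) != len(y):
                    raise ValueError(f"SVOI {nm!r} has wrong length")
                cols.append(np.asarray(v.volume_ml, dtype=float))
            else:
                raise ValueError(f"unknown predictor {nm!r}: not a table column or SVOI")
        return np.column_stack(cols)

    accuracy: dict[str, float] = {}
    p_value: dict[str, float] = {}
    best_c: dict[str, float] = {}
    for m in models:
        x = predictor_matrix(m.predictors)
        _, r, p, C = loocv_predict(x, y, c_grid, epsilon)
        accuracy[m.name] = r
        p_value[m.name] = p
        best_c[m.name] = C

    delta: dict[str, float] = {}
    for m in models:
        if m.baseline is not None:
            if m.baseline not in accuracy:
                raise ValueError(f"baseline model {m.baseline!r} not in the ladder")
            delta[m.name] = accuracy[m.name] - accuracy[m.baseline]
    return PredictionLadder(models=models, accuracy=accuracy, p_value=p_value,
                            best_C=best_c, delta=delta)
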