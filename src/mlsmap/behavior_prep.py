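"""Behavior-score preparation: covariate norm-correction, optional
lesion-volume regression, and the deficit-score transform.

Composition order is fixed: norm_correct -> (optional) regress_out_volumes
-> to_deficit. Downstream permutation inference shuffles the final deficit
vector only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PreparedScores",
    "norm_correct",
    "regress_out_volumes",
    "to_deficit",
    "prepare_scores",
]


@dataclass
class PreparedScores:
    subject_ids: list[str]
    raw: np.ndarray
    residual: np.ndarray
    deficit: np.ndarray
    covariates_used: list[str] = field(default_factory=list)
    volumes_regressed: list[str] = field(default_factory=list)
    score_direction: str = "higher_is_better"


def _as_matrix(covariates) -> tuple[np.ndarray, list[str]]:
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), [str(c) for c in covariates.columns]
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"col{j}" for j in range(arr.shape[1])]


def _find_collinear(design: np.ndarray, names: list[str]) -> list[str]:
    # columns whose removal restores full column rank of the rest
    full_rank = np.linalg.matrix_rank(design)
    bad = []
    for j in range(design.shape[1]):
        rest = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(rest) == full_rank:
            bad.append(names[j])
    return bad


def _ols_residuals(y: np.ndarray, covariates, what: str) -> tuple[np.ndarray, list[str]]:
    y = np.asarray(y, dtype=float)
    x, names = _as_matrix(covariates)
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"{what}: {x.shape[0]} rows of covariates for {y.shape[0]} scores")
    # constant columns are redundant with the intercept, not an error
    varying = x.std(axis=0) > 0
    x, names = x[:, varying], [n for n, v in zip(names, varying) if v]
    design = np.c_[np.ones(len(y)), x]
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _find_collinear(design, ["intercept"] + names)
        raise ValueError(f"{what}: covariate matrix is rank deficient; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef, names


def norm_correct(scores, covariates) -> np.ndarray:
    """OLS residuals of the scores on [intercept, covariates]."""
    resid, _ = _ols_residuals(scores, covariates, "norm_correct")
    return resid


def regress_out_volumes(residual, volumes) -> np.ndarray:
    """OLS residuals of the (already norm-corrected) scores on [intercept,
    lesion volumes]; the "regress-out" volume-control strategy."""
    resid, _ = _ols_residuals(residual, volumes, "regress_out_volumes")
    return resid


def to_deficit(residual, score_direction: str = "higher_is_better") -> np.ndarray:
    """Deficit transform: negate when higher raw scores mean better
    performance, so that larger deficit always means worse performance."""
    residual = np.asarray(residual, dtype=float)
    if score_direction == "higher_is_better":
        return -residual
    if score_direction == "higher_is_worse":
        return residual.copy()
    raise ValueError(f"unknown score_direction {score_direction!r}")


def prepare_scores(
    table: pd.DataFrame,
    score_column: str,
    covariates: list[str] = ("age", "sex", "education"),
    volume_columns: list[str] | None = None,
    score_direction: str = "higher_is_better",
) -> PreparedScores:
    """Full preparation pipeline on a cohort table.

    ``volume_columns`` is set only under the "regress_out" volume-control
    strategy (e.g. ["ail_volume_ml"] for single-lesion models, both volume
    columns for multi-lesion models).
    """
    covariates = list(covariates)
    for col in [score_column, *covariates, *(volume_columns or [])]:
        if col not in table.columns:
            raise ValueError(f"cohort table has no column {col!r}")
        if table[col].isna().any():
            raise ValueError(f"column {col!r} has missing values")
    raw = table[score_column].to_numpy(dtype=float)
    if covariates:
        residual = norm_correct(raw, table[covariates])
    else:
        residual = raw - raw.mean()
    volumes_regressed: list[str] = []
    if volume_columns:
        residual = regress_out_volumes(residual, table[list(volume_columns)])
        volumes_regressed = list(volume_columns)
    deficit = to_deficit(residual, score_direction)
    return PreparedScores(
        subject_ids=[str(s) for s in table["id"]] if "id" in table.columns
        else [str(i) for i in range(len(raw))],
        raw=raw,
        residual=residual,
        deficit=deficit,
        covariates_used=covariates,
        volumes_regressed=volumes_regressed,
        score_direction=score_direction,
    )
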