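"""Mass-univariate voxelwise lesion-symptom mapping.

Each retained voxel gets a pooled-variance two-sample t statistic comparing
the scores of lesioned vs intact subjects (negative t means lesioned
subjects score lower). Familywise error is controlled by the maxT
permutation scheme: each shuffle of the score vector records its maximum
|t| over testable voxels, and the adjusted p of a voxel is

    p = (1 + #{shuffles with max |t| >= real |t|}) / (P + 1).

Per-voxel uncorrected permutation p values are computed from the same
shuffles for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .behavior_prep import PreparedScores
from .lesion_io import LesionTensor

__all__ = ["VlsmResult", "voxel_t", "t_statistics", "vlsm_run"]


@dataclass
class VlsmResult:
    voxel_index: np.ndarray          # flat grid indices of retained voxels
    t: np.ndarray                    # NaN where untestable
    df: int
    p_fwe: np.ndarray                # maxT-adjusted; NaN where untestable
    p_unc: np.ndarray                # per-voxel permutation p
    testable: np.ndarray             # bool per voxel
    n_permutations: int
    seed: int | None
    volume_mode: str = "none"
    sided: str = "two-sided"


def voxel_t(scores, lesion_col) -> tuple[float, int]:
    """Pooled two-sample t for one voxel; sign is mean(lesioned) - mean(intact).

    Raises if either group has fewer than 2 subjects or the pooled variance
    is zero (such voxels are excluded from maps by :func:`vlsm_run`).
    """
    scores = np.asarray(scores, dtype=float)
    lesion_col = np.asarray(lesion_col)
    t, testable = t_statistics(scores, lesion_col[:, None].astype(float))
    if not testable[0]:
        raise ValueError("voxel untestable: a group with < 2 subjects or zero pooled variance")
    return float(t[0]), len(scores) - 2


def t_statistics(scores: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled two-sample t over all columns of a binary matrix.

    Returns (t, testable); t is NaN where a group has < 2 members or the
    pooled variance is zero (degenerate voxels are flagged, not infinite).
    """
    scores = np.asarray(scores, dtype=float)
    m = scores.shape[0]
    n1 = x.sum(axis=0)
    n0 = m - n1
    testable = (n1 >= 2) & (n0 >= 2)

    sum1 = x.T @ scores
    total = scores.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mean1 = sum1 / n1
        mean0 = (total - sum1) / n0
        sumsq1 = x.T @ (scores ** 2)
        ss1 = sumsq1 - n1 * mean1 ** 2
        ss0 = ((scores ** 2).sum() - sumsq1) - n0 * mean0 ** 2
        pooled = (ss1 + ss0) / (m - 2)
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n0))
        t = (mean1 - mean0) / se
    # zero pooled variance: equal means -> t = 0; unequal -> flagged untestable
    degenerate = ~np.isfinite(t)
    tied = degenerate & np.isclose(mean1, mean0, atol=1e-12, equal_nan=False)
    t = np.where(tied, 0.0, t)
    testable &= np.isfinite(t)
    t = np.where(testable, t, np.nan)
    return t, testable


def vlsm_run(
    scores: PreparedScores | np.ndarray,
    t: LesionTensor,
    P: int = 1000,
    seed: int | None = 0,
    sided: str = "two-sided",
    volume_mode: str = "none",
    permutations: np.ndarray | None = None,
) -> VlsmResult:
    """Run mass-univariate VLSM with permutation correction.

    ``scores`` is a PreparedScores (its residual is used: VLSM tests the
    norm-corrected score, no deficit flip needed) or a plain vector.
    ``permutations`` optionally supplies explicit row orderings (P x M),
    e.g. for exhaustive enumeration at tiny M; otherwise P random shuffles
    are drawn from ``seed``.
    """
    y = scores.residual if isinstance(scores, PreparedScores) else np.asarray(scores, float)
    if t.n_subjects != y.shape[0]:
        raise ValueError("score vector length does not match tensor subjects")
    if permutations is not None:
        permutations = np.asarray(permutations)
        P = permutations.shape[0]
    if P < 100:
        warnings.warn(f"P={P} permutations is too coarse for p<0.05 thresholds",
                      stacklevel=2)

    x = t.data.astype(float)
    real_t, testable = t_statistics(y, x)
    stat = np.abs(real_t) if sided == "two-sided" else real_t

    rng = np.random.default_rng(seed)
    exceed_max = np.zeros(x.shape[1])
    exceed_vox = np.zeros(x.shape[1])
    for b in range(P):
        order = permutations[b] if permutations is not None else rng.permutation(len(y))
        perm_t, perm_ok = t_statistics(y[order], x)
        pstat = np.abs(perm_t) if sided == "two-sided" else perm_t
        pstat = np.where(perm_ok & testable, pstat, -np.inf)
        if np.any(np.isfinite(pstat)):
            exceed_max += pstat.max() >= stat
        exceed_vox += pstat >= stat

    p_fwe = (1.0 + exceed_max) / (P + 1.0)
    p_unc = (1.0 + exceed_vox) / (P + 1.0)
    p_fwe = np.where(testable, p_fwe, np.nan)
    p_unc = np.where(testable, p_unc, np.nan)
    return VlsmResult(
        voxel_index=t.voxel_index.copy(), t=real_t, df=len(y) - 2,
        p_fwe=p_fwe, p_unc=p_unc, testable=testable,
        n_permutations=P, seed=seed, volume_mode=volume_mode, sided=sided,
    )
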