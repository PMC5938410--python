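"""Synthetic two-lesion-type cohort simulator.

Generates co-registered binary lesion masks for two lesion types (by
convention "AIL" and "WMH") with known strategic voxels, demographic
covariates and a behavior score that is a linear function of the planted
lesion damage plus covariate effects and Gaussian noise. Every downstream
stage can therefore be tested by parameter recovery.

The generative model is test scaffolding: lesions are unions of random
spheres (or independent per-voxel Bernoulli draws when a prevalence rate
must be controlled exactly), not a model of vascular anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .lesion_io import LesionTensor, ReferenceGrid

__all__ = [
    "LesionSpec",
    "SimulationConfig",
    "SimulatedCohort",
    "generate_brain_mask",
    "sample_cohort",
    "generate_scores",
]


@dataclass
class LesionSpec:
    """Sampler parameters for one lesion type.

    kind="spheres": per subject, draw ``n_seeds`` sphere centers uniformly
    from the spatial prior and radii uniformly from ``radius_range``; the
    subject mask is the union of the spheres intersected with the brain mask.

    kind="bernoulli": each prior voxel is lesioned independently with
    probability ``rate`` — prevalence at prior voxels is then exactly
    ``rate`` in expectation, which calibration tests rely on.

    ``prior`` is either "uniform" (whole brain mask) or a boolean volume.
    """

    kind: str = "spheres"
    n_seeds: tuple[int, int] = (1, 3)
    radius_range: tuple[float, float] = (1.0, 3.0)
    rate: float = 0.1
    prior: str | np.ndarray = "uniform"

    def __post_init__(self) -> None:
        if self.kind not in ("spheres", "bernoulli"):
            raise ValueError(f"unknown sampler kind {self.kind!r}")
        if self.kind == "spheres" and min(self.radius_range) < 1:
            raise ValueError("sphere radii must be >= 1 voxel")
        if self.kind == "bernoulli" and not 0 <= self.rate <= 1:
            raise ValueError("rate must be in [0, 1]")


@dataclass
class SimulationConfig:
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_subjects: int = 40
    ail_spec: LesionSpec = field(default_factory=LesionSpec)
    wmh_spec: LesionSpec = field(default_factory=lambda: LesionSpec(n_seeds=(2, 5)))
    strategic_ail: Mapping[int, float] = field(default_factory=dict)
    strategic_wmh: Mapping[int, float] = field(default_factory=dict)
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    age_range: tuple[float, float] = (50.0, 85.0)
    education_range: tuple[float, float] = (0.0, 16.0)
    base_score: float = 30.0
    noise_sd: float = 1.0
    score_range: tuple[float, float] | None = (0.0, 30.0)
    score_name: str = "moca"
    brain_mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)

    @property
    def grid(self) -> ReferenceGrid:
        return ReferenceGrid(shape=self.grid_shape, voxel_size=self.voxel_size,
                             space="synthetic")


@dataclass
class SimulatedCohort:
    """A generated cohort plus its ground truth.

    ``truth_beta_ail`` / ``truth_beta_wmh`` are full-grid (flat) weight maps;
    nonzero exactly at the planted strategic voxels. Per subject and voxel
    the AIL and WMH indicators are never both 1 (AIL wins ties).
    """

    config: SimulationConfig
    brain_mask: np.ndarray
    ail: LesionTensor
    wmh: LesionTensor
    table: pd.DataFrame
    truth_beta_ail: np.ndarray
    truth_beta_wmh: np.ndarray

    def truth_voxels(self, lesion_type: str) -> np.ndarray:
        beta = self.truth_beta_ail if lesion_type.upper() == "AIL" else self.truth_beta_wmh
        return np.flatnonzero(beta)


def _rng(seed: int, stream: int) -> np.random.Generator:
    # named substreams so e.g. changing the noise draw does not move lesions
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


_STREAM_AIL, _STREAM_WMH, _STREAM_COV, _STREAM_NOISE = 0, 1, 2, 3


def generate_brain_mask(config: SimulationConfig) -> np.ndarray:
    """Ellipsoidal brain mask inscribed in the grid (or the user-supplied one)."""
    if config.brain_mask is not None:
        mask = np.asarray(config.brain_mask, dtype=bool)
        if mask.shape != config.grid_shape:
            raise ValueError("supplied brain mask does not match grid_shape")
        if not mask.any():
            raise ValueError("supplied brain mask is empty")
        return mask
    shape = np.asarray(config.grid_shape, dtype=float)
    semi = (shape - 1.0) / 2.0
    if (semi < 1).any():
        raise ValueError(f"grid {config.grid_shape} too small to contain a brain mask")
    center = (shape - 1.0) / 2.0
    coords = np.indices(config.grid_shape, dtype=float)
    d2 = sum(((coords[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return d2 <= 1.0


def _resolve_prior(spec: LesionSpec, mask: np.ndarray) -> np.ndarray:
    if isinstance(spec.prior, str):
        if spec.prior != "uniform":
            raise ValueError(f"unknown prior {spec.prior!r}")
        prior = mask
    else:
        prior = np.asarray(spec.prior, dtype=bool) & mask
    if not prior.any():
        raise ValueError("spatial prior contains no voxels inside the brain mask")
    return prior


def _sample_subject(spec: LesionSpec, prior: np.ndarray, mask: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    shape = mask.shape
    out = np.zeros(shape, dtype=bool)
    prior_flat = np.flatnonzero(prior)
    if spec.kind == "bernoulli":
        hit = rng.random(prior_flat.size) < spec.rate
        out.reshape(-1)[prior_flat[hit]] = True
        return out & mask
    lo, hi = spec.n_seeds
    n = int(rng.integers(lo, hi + 1))
    coords = np.indices(shape, dtype=float)
    for _ in range(n):
        center_flat = prior_flat[rng.integers(prior_flat.size)]
        c = np.unravel_index(center_flat, shape)
        r = rng.uniform(*spec.radius_range)
        d2 = sum((coords[a] - c[a]) ** 2 for a in range(3))
        out |= d2 <= r * r
    return out & mask


def sample_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw lesion masks, covariates and behavior scores for one cohort.

    Deterministic given the config (including its seed). At every
    subject-voxel the two lesion indicators are exclusive: a voxel drawn as
    both is recorded as AIL only (the acute event masks the chronic one).
    """
    grid = config.grid
    mask = generate_brain_mask(config)
    mask_flat = np.flatnonzero(mask)

    for name, strat in (("strategic_ail", config.strategic_ail),
                        ("strategic_wmh", config.strategic_wmh)):
        bad = [v for v in strat if not mask.reshape(-1)[int(v)]]
        if bad:
            raise ValueError(f"{name} voxels outside the brain mask: {bad[:5]}")

    prior_ail = _resolve_prior(config.ail_spec, mask)
    prior_wmh = _resolve_prior(config.wmh_spec, mask)
    rng_a = _rng(config.seed, _STREAM_AIL)
    rng_w = _rng(config.seed, _STREAM_WMH)

    m = config.n_subjects
    ail = np.zeros((m, mask_flat.size), dtype=np.uint8)
    wmh = np.zeros((m, mask_flat.size), dtype=np.uint8)
    for s in range(m):
        a = _sample_subject(config.ail_spec, prior_ail, mask, rng_a)
        w = _sample_subject(config.wmh_spec, prior_wmh, mask, rng_w)
        w &= ~a  # AIL overrides WMH at shared voxels
        ail[s] = a.reshape(-1)[mask_flat]
        wmh[s] = w.reshape(-1)[mask_flat]

    vox_ml = grid.voxel_volume_ml
    subject_ids = [f"sub-{s + 1:03d}" for s in range(m)]
    ail_t = LesionTensor("AIL", grid, subject_ids, mask_flat, ail,
                         volumes_ml=ail.sum(axis=1) * vox_ml)
    wmh_t = LesionTensor("WMH", grid, subject_ids, mask_flat, wmh,
                         volumes_ml=wmh.sum(axis=1) * vox_ml)

    rng_c = _rng(config.seed, _STREAM_COV)
    table = pd.DataFrame({
        "id": subject_ids,
        "age": np.round(rng_c.uniform(*config.age_range, size=m), 1),
        "sex": rng_c.integers(0, 2, size=m),
        "education": np.round(rng_c.uniform(*config.education_range, size=m), 1),
        "ail_volume_ml": ail_t.volumes_ml,
        "wmh_volume_ml": wmh_t.volumes_ml,
    })

    n_vox = grid.n_voxels
    truth_a = np.zeros(n_vox)
    truth_w = np.zeros(n_vox)
    for v, wgt in config.strategic_ail.items():
        truth_a[int(v)] = float(wgt)
    for v, wgt in config.strategic_wmh.items():
        truth_w[int(v)] = float(wgt)

    cohort = SimulatedCohort(config=config, brain_mask=mask, ail=ail_t, wmh=wmh_t,
                             table=table, truth_beta_ail=truth_a, truth_beta_wmh=truth_w)
    cohort.table = generate_scores(cohort)
    return cohort


def generate_scores(cohort: SimulatedCohort) -> pd.DataFrame:
    """Fill the behavior score: base minus planted lesion damage, plus
    covariate effects and Gaussian noise, clipped to the score range.

    Writes ``<score_name>`` and the pre-noise ``<score_name>_noiseless``
    columns. Signs are arranged so lesions lower the score.
    """
    cfg = cohort.config
    table = cohort.table.copy()
    m = cfg.n_subjects

    damage_a = cohort.ail.data @ cohort.truth_beta_ail[cohort.ail.voxel_index]
    damage_w = cohort.wmh.data @ cohort.truth_beta_wmh[cohort.wmh.voxel_index]
    noiseless = cfg.base_score - damage_a - damage_w
    for cov, wgt in cfg.covariate_effects.items():
        noiseless = noiseless + wgt * table[cov].to_numpy(dtype=float)

    rng = _rng(cfg.seed, _STREAM_NOISE)
    score = noiseless + rng.normal(0.0, cfg.noise_sd, size=m)
    if cfg.score_range is not None:
        score = np.clip(score, *cfg.score_range)
    table[cfg.score_name] = score
    table[f"{cfg.score_name}_noiseless"] = noiseless
    return table
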