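import numpy as np
import pytest

from mlsmap.lesion_io import LesionTensor, ReferenceGrid
from mlsmap.simcohort import LesionSpec, SimulationConfig, sample_cohort


def make_tensor(data, lesion_type="AIL", grid_shape=(4, 4, 4), voxel_index=None,
                volumes_ml=None, voxel_size=(1.0, 1.0, 1.0)):
    """Build a LesionTensor from a dense (M, V) array for unit tests."""
    data = np.asarray(data, dtype=np.uint8)
    grid = ReferenceGrid(shape=grid_shape, voxel_size=voxel_size)
    if voxel_index is None:
        voxel_index = np.arange(data.shape[1])
    return LesionTensor(
        lesion_type=lesion_type,
        grid=grid,
        subject_ids=[f"s{i}" for i in range(data.shape[0])],
        voxel_index=np.asarray(voxel_index),
        data=data,
        volumes_ml=volumes_ml,
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """Bernoulli cohort with strategic AIL and WMH voxels driving the score."""
    shape = (12, 12, 12)
    grid = np.prod(shape)
    center = np.ravel_multi_index((6, 6, 6), shape)
    strategic_ail = {center: 4.0, center + 1: 4.0}
    strategic_wmh = {center + 144: 4.0, center + 145: 4.0}  # one slab over in i
    cfg = SimulationConfig(
        grid_shape=shape, n_subjects=40,
        ail_spec=LesionSpec(kind="bernoulli", rate=0.25),
        wmh_spec=LesionSpec(kind="bernoulli", rate=0.25),
        strategic_ail=strategic_ail, strategic_wmh=strategic_wmh,
        noise_sd=1.0, score_range=None, seed=11,
    )
    return sample_cohort(cfg)
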