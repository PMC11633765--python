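import numpy as np
import pytest

from capdyn.synth import SimConfig, generate_cohort
from capdyn.types import VolumeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_series(n_frames=40, grid_shape=(4, 4, 3), tr=1.3, rng=None, data=None):
    """Small random VolumeSeries over a full rectangular grid."""
    rng = rng or np.random.default_rng(0)
    n_vox = int(np.prod(grid_shape))
    coords = np.argwhere(np.ones(grid_shape, dtype=bool))
    if data is None:
        data = rng.normal(size=(n_frames, n_vox))
    return VolumeSeries(data=data, tr=tr, voxel_coords=coords, grid_shape=grid_shape)


@pytest.fixture
def small_series(rng):
    return make_series(rng=rng)


@pytest.fixture(scope="session")
def tiny_cohort():
    """4+4 synthetic subjects on the default grid; shared across tests."""
    cfg = SimConfig(n_per_group=4, rng_seed=11)
    return cfg, generate_cohort(cfg)
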