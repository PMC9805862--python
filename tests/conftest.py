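import numpy as np
import pytest

from crossfc.simdata import BoldSeries, default_config


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_cfg():
    """Reduced cohort configuration used across unit tests."""
    return default_config(n_subjects=4, n_volumes=120, rng_seed=11)


def make_bold(data, tr_s=2.0, voxel_mm=3.0):
    """Wrap an array (adding singleton spatial axes as needed) in a BoldSeries."""
    data = np.asarray(data, dtype=float)
    while data.ndim < 4:
        data = data[None]
    affine = np.diag([voxel_mm] * 3 + [1.0])
    return BoldSeries(data=data, affine=affine, tr_s=tr_s)


@pytest.fixture
def bold_factory():
    return make_bold
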