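import numpy as np
import pytest

from fliopipe.decay import gaussian_irf, make_time_axis
from fliopipe.simulate import AcquisitionConfig, default_population


@pytest.fixture(scope="session")
def time_axis():
    return make_time_axis(64)


@pytest.fixture(scope="session")
def irf(time_axis):
    return gaussian_irf(time_axis, fwhm_ps=100.0)


@pytest.fixture(scope="session")
def small_acq():
    """64x64 raster over a 6.4 mm field; 64 time bins."""
    return AcquisitionConfig(image_shape=(64, 64), mm_per_pixel=0.1, n_time_bins=64)


@pytest.fixture(scope="session")
def population():
    return default_population()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
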