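import numpy as np
import pytest

from circfish.simulate import SceneConfig
from circfish.simulate.scenes import gaussian_integral


@pytest.fixture
def small_config():
    """A compact noise-free imaging field for fast rendering tests."""
    return SceneConfig(shape=(12, 96, 96), noise_sd=0.0, seed=0)


@pytest.fixture
def unit_integral(small_config):
    """Analytic integrated intensity of one unit-amplitude molecule."""
    return gaussian_integral(small_config.unit_amplitude["intron"],
                             small_config.sigma_xy_nm,
                             small_config.sigma_z_nm)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
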