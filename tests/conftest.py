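import numpy as np
import pytest

from lumenseg import PhantomSpec
from lumenseg.model import NetConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """Small, fast phantom geometry used across tests."""
    return PhantomSpec(grid_shape=(24, 24, 12), n_tubes=2,
                       radius_range=(1.5, 2.5))


@pytest.fixture
def tiny_net_config():
    return NetConfig(encoder_channels=(2, 4), bottleneck_channels=4)
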