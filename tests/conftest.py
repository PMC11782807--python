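import numpy as np
import pytest

from cinefuse.network import ModelConfig, MultiViewCineNet
from cinefuse.synthetic import PhantomConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_config():
    """Reduced-size architecture for fast structural/algebraic tests."""
    return ModelConfig(input_size=32, encoder_pool=1, feature_dim=8,
                       encoder_channels=(4, 8))


@pytest.fixture()
def tiny_net(tiny_config):
    return MultiViewCineNet(tiny_config, seed=7)


@pytest.fixture()
def small_phantom():
    """Quarter-resolution phantom (64 px at 3.76 mm) for fast rendering;
    preprocessing restores the canonical 256 px / 0.94 mm layout."""
    return PhantomConfig(image_size=64, pixel_spacing=4 * 0.94)
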