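import numpy as np
import pytest

from notchseg.network import NetworkConfig
from notchseg.phantom import PhantomConfig, generate_notch_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_net_cfg():
    """Compact network config used across architecture tests."""
    return NetworkConfig(
        stage_channels=(8, 16, 24, 32),
        detail_channels=16,
        input_size_px=64,
        attention_resolution_cap=256,
    )


@pytest.fixture(scope="session")
def tiny_phantom_cfg():
    """32 px phantoms (2 mm spacing keeps the femur in frame)."""
    return PhantomConfig(image_size_px=32, pixel_spacing_mm=2.0)


@pytest.fixture(scope="session")
def train_phantom_cfg():
    """64 px phantoms at 1 mm spacing, the training-sized fixture."""
    return PhantomConfig(image_size_px=64, pixel_spacing_mm=1.0)


@pytest.fixture(scope="session")
def train_phantoms(train_phantom_cfg):
    return [generate_notch_phantom(train_phantom_cfg, s) for s in range(1, 9)]
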