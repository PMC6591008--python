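import numpy as np
import pytest

from synaptiq import IntensityImage, SceneSpec, SegmentationParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return SegmentationParams()


@pytest.fixture
def blank_image():
    return IntensityImage(np.full((64, 64), 10.0), pixel_size_um=0.1)


@pytest.fixture
def block_image():
    """Noise-free background 10 with one 5x5 block of 110 (total above bg
    = 100 x 25 = 2500)."""
    px = np.full((64, 64), 10.0)
    px[20:25, 30:35] = 110.0
    return IntensityImage(px, pixel_size_um=0.1)


@pytest.fixture
def noise_scene():
    return SceneSpec(image_shape=(128, 128), spots=(), noise_sd=5.0, seed=99)
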