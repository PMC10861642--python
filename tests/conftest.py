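import numpy as np
import pytest

from tumortex import GLCMConfig, GrayImage
from tumortex.synth import fixture_images


@pytest.fixture(scope="session")
def fixtures() -> dict:
    return fixture_images()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240130)


@pytest.fixture
def random_8level_images(rng) -> list[GrayImage]:
    """Random 16x16 images quantized to 8 gray levels."""
    return [
        GrayImage(rng.integers(0, 8, size=(16, 16)), levels=8) for _ in range(20)
    ]


@pytest.fixture
def glcm8() -> GLCMConfig:
    return GLCMConfig(levels=8)
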