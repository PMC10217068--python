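import numpy as np
import pytest

from fundushybrid.dataset import SyntheticConfig, generate_synthetic_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grey_img(rng):
    return rng.integers(0, 256, size=(16, 16)).astype(np.uint8)


@pytest.fixture
def rgb_img(rng):
    return rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)


@pytest.fixture(scope="session")
def tiny_dataset():
    """10 images per class, 32x32 — enough for split/pipeline plumbing."""
    return generate_synthetic_dataset(SyntheticConfig(n_per_class=10, image_size=(32, 32), seed=7))
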