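import numpy as np
import pytest

from memstdp import (
    EncoderConfig,
    LifConfig,
    StdpParams,
    SyntheticSpec,
    TrainConfig,
    VariationSpec,
    generate_synthetic,
)


@pytest.fixture
def params():
    """Device-fitted soft-bound STDP defaults."""
    return StdpParams()


@pytest.fixture
def no_variation():
    return VariationSpec()


@pytest.fixture
def encoder():
    return EncoderConfig()


@pytest.fixture
def lif():
    return LifConfig()


@pytest.fixture
def train_cfg():
    return TrainConfig()


@pytest.fixture(scope="session")
def tiny_dataset():
    """4 classes of 12×12 noisy sparse patterns, 400 images."""
    spec = SyntheticSpec(image_side=12, n_classes=4, samples_per_class=100,
                         seed=5)
    images, labels = generate_synthetic(spec)
    return images, labels, spec


@pytest.fixture(scope="session")
def single_pattern():
    """One noise-free 10×10 binary pattern repeated 50 times."""
    spec = SyntheticSpec(image_side=10, n_classes=1,
                         pattern_pixel_fraction=0.15,
                         background_intensity=0, pixel_noise_sd=0.0,
                         samples_per_class=50, seed=3, shuffle=False)
    images, labels = generate_synthetic(spec)
    return images, images[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
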