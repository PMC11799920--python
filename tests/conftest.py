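import numpy as np
import pytest

from freqfed import build_unet, generate_dataset, make_profiles


@pytest.fixture
def tiny_unet():
    """Depth-1, width-4 U-Net on 3 classes: cheapest trainable model."""
    return build_unet(in_channels=1, n_classes=3, depth=1, base_width=4, seed=11)


@pytest.fixture
def small_unet():
    """The depth-2, width-8 reference architecture used throughout."""
    return build_unet(in_channels=1, n_classes=4, depth=2, base_width=8, seed=7)


@pytest.fixture
def tiny_dataset():
    """One 16x16 phantom client with 20 images (16 train / 2 val / 2 test)."""
    profile = make_profiles(1, heterogeneity=0.0, seed=5, n_organs=2)[0]
    return generate_dataset(profile, n=20, size=(16, 16), n_classes=3, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
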