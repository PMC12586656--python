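import numpy as np
import pytest

from aquaqnet.backbones import ToyConvBackbone
from aquaqnet.datasets import SyntheticDatasetConfig, generate_dataset


@pytest.fixture(scope="session")
def small_corpus():
    """A small rendered corpus shared across tests (30 images/class, 64px)."""
    cfg = SyntheticDatasetConfig(per_class=30, image_size=(64, 64), seed=11)
    images, labels = generate_dataset(cfg)
    return images, labels, cfg


@pytest.fixture(scope="session")
def toy_backbone():
    return ToyConvBackbone(feature_dim=16, seed=3)


@pytest.fixture(scope="session")
def cluster_features():
    """Well-separated 5-class Gaussian features (d=16) for fast model tests."""
    rng = np.random.default_rng(5)
    centers = rng.normal(0.0, 2.0, size=(5, 16))

    def make(n_per_class):
        x = np.concatenate(
            [c + rng.normal(0.0, 0.5, size=(n_per_class, 16)) for c in centers]
        )
        y = np.repeat(np.arange(5), n_per_class)
        return x, y

    z_train, y_train = make(40)
    z_val, y_val = make(12)
    return z_train, y_train, z_val, y_val
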