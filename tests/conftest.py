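import numpy as np
import pytest
from hypothesis import settings

from mountpat.synthesize import SyntheticConfig, generate_dataset

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny synthetic dataset for fast unit tests (short epochs)."""
    cfg = SyntheticConfig(n_classes=2, nc=6, L=64, n_per_class=10, noise_sigma=0.05, seed=7)
    segments, manifest = generate_dataset(cfg)
    return cfg, segments, manifest
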