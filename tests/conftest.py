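import numpy as np
import pytest
from hypothesis import settings

from mlfssm.datasets import Dataset

# property tests must be reproducible across environments
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """8 samples x 4 features; feature 0 separates the classes perfectly."""
    rng = np.random.default_rng(7)
    y = np.array([-1, -1, -1, -1, 1, 1, 1, 1])
    x = rng.normal(size=(8, 4))
    x[:, 0] = y * 3.0 + rng.normal(0, 0.1, size=8)
    return Dataset(
        values=x,
        labels=y,
        feature_names=[f"f{i}" for i in range(4)],
        sample_ids=[f"s{i}" for i in range(8)],
    )


@pytest.fixture
def separable_dataset():
    """40 samples x 20 features; feature 3 equals the label exactly."""
    rng = np.random.default_rng(11)
    y = np.repeat([-1, 1], 20)
    x = rng.normal(size=(40, 20))
    x[:, 3] = y.astype(float)
    return Dataset(
        values=x,
        labels=y,
        feature_names=[f"g{i}" for i in range(20)],
        sample_ids=[f"s{i}" for i in range(40)],
    )


@pytest.fixture
def noise_dataset():
    """60 samples x 10 pure-noise features, balanced labels."""
    rng = np.random.default_rng(23)
    y = np.repeat([-1, 1], 30)
    x = rng.normal(size=(60, 10))
    return Dataset(
        values=x,
        labels=y,
        feature_names=[f"n{i}" for i in range(10)],
        sample_ids=[f"s{i}" for i in range(60)],
    )
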