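import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blobs():
    """Two well-separated Gaussian blobs: a linearly separable sanity set."""
    gen = np.random.default_rng(7)
    n = 100
    X = np.vstack([gen.normal(-2.0, 1.0, (n, 2)), gen.normal(2.0, 1.0, (n, 2))])
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    return X, y


@pytest.fixture
def small_dataset():
    from batscreen import GeneratorConfig, generate_dataset

    return generate_dataset(GeneratorConfig(n=120, seed=3))
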