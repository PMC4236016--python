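import numpy as np
import pytest

from surprisal import decompose, generate_planted_dataset, log_transform


@pytest.fixture(scope="session")
def planted_default():
    """Planted dataset at the default study scale (2000 genes x 4 stages)."""
    x, truth = generate_planted_dataset(seed=20140101)
    return x, truth


@pytest.fixture(scope="session")
def planted_decomposition(planted_default):
    x, truth = planted_default
    return decompose(log_transform(x)), truth


@pytest.fixture(scope="session")
def small_planted():
    """A quick small planted dataset for structural tests."""
    x, truth = generate_planted_dataset(
        m=300, t=4, n_stable=30, n_deviating=30, seed=7
    )
    return x, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
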