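import numpy as np
import pytest

from netbc.io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr(rng):
    values = rng.standard_normal((10, 5))
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(10)],
        [f"s{j}" for j in range(5)],
    )


def hard_indicator(labels, k):
    """Exact one-hot indicator matrix from integer labels."""
    labels = np.asarray(labels)
    M = np.zeros((labels.shape[0], k))
    M[np.arange(labels.shape[0]), labels] = 1.0
    return M


def random_partition(rng, n, k):
    """Random labels guaranteed to use all k clusters."""
    while True:
        lab = rng.integers(0, k, size=n)
        if len(np.unique(lab)) == k:
            return lab
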