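import numpy as np
import pytest

from providervar import ProviderCounts


def make_counts(y, n, ids=None):
    y = np.asarray(y)
    n = np.asarray(n)
    if ids is None:
        ids = np.array([f"H{i}" for i in range(y.size)], dtype=object)
    return ProviderCounts(np.asarray(ids, dtype=object), y, n)


@pytest.fixture
def toy_counts():
    """Two providers with identical proportions 0.25."""
    return make_counts([10, 5], [40, 20], ids=["A", "B"])


@pytest.fixture
def mixed_counts():
    """Small heterogeneous cohort, no boundary proportions."""
    rng = np.random.default_rng(42)
    n = rng.integers(20, 80, 40)
    p = rng.uniform(0.15, 0.45, 40)
    y = rng.binomial(n, p)
    y = np.clip(y, 1, n - 1)  # keep off the boundary for determinate tests
    return make_counts(y, n)
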