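import numpy as np
import pytest

from sgrcorr import JointPMF, default_marginals, thresholds_from_marginals


@pytest.fixture
def rng():
    return np.random.default_rng(20231108)


@pytest.fixture
def thresholds_v5():
    return thresholds_from_marginals(default_marginals(5))


def random_pmf(rng, v=5, concentration=1.0):
    """Random joint pmf with strictly positive cells."""
    grid = rng.gamma(concentration, size=(v, v)) + 1e-6
    return JointPMF(grid / grid.sum())


def random_sample_array(rng, n, v):
    """Random integer sample, guaranteed non-constant in both columns."""
    while True:
        data = rng.integers(1, v + 1, size=(n, 2))
        if len(np.unique(data[:, 0])) > 1 and len(np.unique(data[:, 1])) > 1:
            return data
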