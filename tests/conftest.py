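import numpy as np
import pytest

from timedhn.ctmc import HazardNetwork, Profile


@pytest.fixture
def rng():
    return np.random.default_rng(20230316)


def random_network(rng, n, density=0.5, diag_low=0.05):
    """Random nonnegative hazard matrix with positive spontaneous rates."""
    R = rng.random((n, n)) * (rng.random((n, n)) < density)
    np.fill_diagonal(R, diag_low + rng.random(n))
    return HazardNetwork(R)


def random_profile(rng, n, k=None):
    bits = np.zeros(n, dtype=int)
    if k is None:
        k = int(rng.integers(0, n + 1))
    if k:
        bits[rng.choice(n, size=k, replace=False)] = 1
    return Profile(bits)
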