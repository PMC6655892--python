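import numpy as np
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_subcritical(rng, n, radius=0.45, density=0.3):
    """Random sparse nonnegative matrix rescaled to the given spectral radius."""
    G = (rng.random((n, n)) < density) * rng.uniform(0.5, 1.5, (n, n))
    np.fill_diagonal(G, 0.0)
    r = np.abs(np.linalg.eigvals(G)).max()
    if r > 0:
        G *= radius / r
    return G


def random_psd(rng, n, rank=None):
    k = rank or n
    A = rng.standard_normal((n, k))
    return A @ A.T
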