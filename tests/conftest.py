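import numpy as np
import pytest

from capla.pla import PLASizeTable
from capla.spectrum import spectrum_from_values


def make_random_spectrum(rng, u_max=128, n_max=60):
    """Small random multiset over a small universe (brute-forceable)."""
    u = int(rng.integers(4, u_max + 1))
    count = int(rng.integers(1, n_max + 1))
    return spectrum_from_values(rng.integers(0, u, size=count), u)


def make_random_table(rng, n=1000, eps_max=1024, size=24):
    """Random valid PLA-size table: 1 in the eps set, b nonincreasing."""
    extra = np.unique(rng.integers(2, eps_max + 1, size=size - 1))
    eps = np.concatenate(([1.0], extra.astype(float)))
    b = np.sort(rng.uniform(1.0, 400.0, size=eps.size))[::-1]
    return PLASizeTable(eps_values=eps, b_values=b, n=n, N=2 * n)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
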