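import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


def random_weighted_graph(rng, n, density=0.4, low=0.05, high=1.0):
    """Random symmetric non-negative weight matrix with zero diagonal."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < density
    vals = rng.uniform(low, high, len(iu[0])) * mask
    w[iu] = vals
    return w + w.T


def random_z_matrix(rng, n, positive=True):
    """Random symmetric Fisher-z-like matrix (all-positive by default)."""
    iu = np.triu_indices(n, k=1)
    vals = rng.uniform(0.01, 1.2, len(iu[0]))
    if not positive:
        vals *= rng.choice([-1, 1], len(iu[0]))
    z = np.zeros((n, n))
    z[iu] = vals
    return z + z.T


def complete_binary_graph(n):
    w = np.ones((n, n))
    np.fill_diagonal(w, 0.0)
    return w


def star_graph(n):
    """Binary star: node 0 is the hub."""
    w = np.zeros((n, n))
    w[0, 1:] = 1.0
    w[1:, 0] = 1.0
    return w
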