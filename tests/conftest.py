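import numpy as np
import pytest

import fse


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric(rng, n, scale=0.5):
    """Random signed symmetric coupling matrix with zero diagonal."""
    J = rng.uniform(-scale, scale, (n, n))
    J = np.triu(J, 1)
    return J + J.T


def complete_graph_coupling(n):
    """Uniform ferromagnet J_ij = 1/N (mean-field critical T = 1)."""
    J = np.full((n, n), 1.0 / n)
    np.fill_diagonal(J, 0.0)
    return J


def square_lattice_coupling(L):
    """Periodic 2D nearest-neighbour lattice with J = 1 (Onsager model)."""
    N = L * L
    J = np.zeros((N, N))
    for x in range(L):
        for y in range(L):
            i = x * L + y
            for dx, dy in ((1, 0), (0, 1)):
                j = ((x + dx) % L) * L + (y + dy) % L
                J[i, j] = J[j, i] = 1.0
    return J


def config_codes(states):
    """Encode +/-1 configurations (columns) as integers for histogramming."""
    N = states.shape[0]
    return ((states.T > 0) @ (1 << np.arange(N))).astype(int)


@pytest.fixture
def two_spin_samples():
    """20,000 iid draws from the exact 2-spin Boltzmann distribution, J=0.4."""
    J = np.array([[0.0, 0.4], [0.4, 0.0]])
    dist, pair, _, _ = fse.exact_moments(J, 1.0)
    idx = np.random.default_rng(5).choice(4, size=20000, p=dist.probabilities)
    S = dist.configurations[idx].T.astype(int)
    return fse.BinarizedActivity(S), J, pair[0, 1]
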