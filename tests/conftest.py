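import numpy as np
import pytest

from interdep import Ecology, compute_stats


@pytest.fixture(scope="session")
def pd_stats():
    """Statistics of the PD-centred heterogeneous ecology used throughout."""
    return compute_stats(Ecology(-0.5, 1.5, 2.0, m=200_000, seed=1))


@pytest.fixture(scope="session")
def harmony_stats():
    """Degenerate single-game harmony (MD) ecology: always-cooperate territory."""
    return compute_stats(Ecology(0.5, 0.5, 0.0))


@pytest.fixture(scope="session")
def pd_point_stats():
    """Degenerate single-game PD ecology."""
    return compute_stats(Ecology(-0.5, 1.5, 0.0))


def dense_absorption_oracle(M: np.ndarray, N: int, beta: float, scale: float = 1.0):
    """Brute-force absorption probabilities of the pairwise-comparison chain.

    Independent of the package's sparse solver: enumerates states as python
    tuples, builds the dense transition matrix entry by entry, and solves the
    absorbing-chain system with numpy.  Only sensible for small N.
    """
    states = [(x, y, N - x - y) for x in range(N + 1) for y in range(N + 1 - x)]
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    T = np.zeros((n, n))
    for s, i in index.items():
        total = 0.0
        pi = np.zeros(3)
        for a in range(3):
            acc = 0.0
            for b in range(3):
                acc += (s[b] - (1 if a == b else 0)) * _pair_payoff(M, a, b)
            pi[a] = acc / (N - 1)
        for a in range(3):
            for b in range(3):
                if a == b or s[a] == 0 or s[b] == 0:
                    continue
                p = s[a] * s[b] / (N * (N - 1))
                p *= 1.0 / (1.0 + np.exp(-beta * (pi[a] - pi[b]) / scale))
                t = list(s)
                t[a] += 1
                t[b] -= 1
                T[i, index[tuple(t)]] += p
                total += p
        T[i, i] += 1.0 - total
    vertices = [index[(N, 0, 0)], index[(0, N, 0)], index[(0, 0, N)]]
    transient = [i for i in range(n) if i not in vertices]
    Q = T[np.ix_(transient, transient)]
    R = T[np.ix_(transient, vertices)]
    B = np.linalg.solve(np.eye(len(transient)) - Q, R)
    out = np.zeros((n, 3))
    out[transient] = B
    for k, v in enumerate(vertices):
        out[v, k] = 1.0
    return out, index


def _pair_payoff(M, a, b):
    return M[a][b]
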