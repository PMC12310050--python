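import numpy as np
import pytest

from selhmm import (
    SelectionParams,
    TemporalObservations,
    chebychev_grid,
    transition_matrix,
)


@pytest.fixture(scope="session")
def grid3():
    return chebychev_grid(3)


@pytest.fixture(scope="session")
def grid_small():
    return chebychev_grid(64)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


def enumerate_paths(init, P, ems, T, grid):
    """Brute-force posterior oracle: sum over all M^T hidden paths.

    Returns (log_likelihood, gamma, xi) by exhaustive enumeration; only
    usable for tiny M and T.
    """
    import itertools

    M = grid.M
    total = 0.0
    gamma = np.zeros((T, M))
    xi = np.zeros((T - 1, M, M))
    for path in itertools.product(range(M), repeat=T):
        pr = init[path[0]]
        if 1 in ems:
            pr *= ems[1][path[0]]
        for t in range(1, T):
            pr *= P[path[t - 1], path[t]]
            if (t + 1) in ems:
                pr *= ems[t + 1][path[t]]
        total += pr
        for t in range(T):
            gamma[t, path[t]] += pr
        for t in range(T - 1):
            xi[t, path[t], path[t + 1]] += pr
    if total <= 0:
        return -np.inf, gamma, xi
    return np.log(total), gamma / total, xi / total


@pytest.fixture(scope="session")
def tiny_hmm(grid3):
    """A small fully-specified HMM instance shared by oracle tests."""
    P = transition_matrix(grid3, SelectionParams(0.08, -0.03), 40.0)
    init = np.array([0.25, 0.5, 0.25])
    obs = TemporalObservations.from_samples(3, [1, 3], [4, 6], [1, 4])
    return P, init, obs
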