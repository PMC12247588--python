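import numpy as np
import pytest

from warpelast.dtw import TimeSeriesPair, dtw


def brute_force_dtw_cost(x, y, band_radius=None):
    """Exhaustive minimum alignment cost over all monotone boundary paths.

    Plain recursion over the three admissible steps -- no dynamic
    programming, no memoization -- so it is an independent oracle for
    the DP implementation.  Only usable for tiny series.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = x.size, y.size

    def inside(i, j):
        return band_radius is None or abs(i - j) <= band_radius

    def rec(i, j):
        cost = abs(x[i] - y[j])
        if i == n - 1 and j == m - 1:
            return cost
        best = np.inf
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m and inside(ni, nj):
                sub = rec(ni, nj)
                if sub < best:
                    best = sub
        return cost + best

    return rec(0, 0)


def assert_valid_path(path, n, m):
    """Boundary, monotonicity/continuity, coverage, cost bookkeeping."""
    pairs = path.pairs
    assert tuple(pairs[0]) == (0, 0)
    assert tuple(pairs[-1]) == (n - 1, m - 1)
    steps = np.diff(pairs, axis=0)
    assert all(tuple(s) in {(1, 0), (0, 1), (1, 1)} for s in steps)
    assert set(pairs[:, 0]) == set(range(n))
    assert set(pairs[:, 1]) == set(range(m))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture(scope="session", autouse=True)
def warm_dtw():
    # trigger numba compilation once so individual test timings are honest
    dtw(TimeSeriesPair([0.0, 1.0], [0.0, 1.0]))
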