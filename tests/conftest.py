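"""Shared helpers and independent oracles for the test suite."""

from math import comb

import numpy as np
import pytest


def fisher_enum_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by brute-force hypergeometric enumeration.

    Enumerates every 2x2 table with the observed margins and sums the
    probabilities of tables no more probable than the observed one.  All
    comparisons are on exact integers, so there is no floating tolerance.
    """
    n1, n2 = a + b, c + d
    k = a + c
    lo, hi = max(0, k - n2), min(k, n1)

    def weight(x: int) -> int:
        return comb(n1, x) * comb(n2, k - x)

    obs = weight(a)
    total = sum(weight(x) for x in range(lo, hi + 1))
    tail = sum(weight(x) for x in range(lo, hi + 1) if weight(x) <= obs)
    return tail / total


def permutation_score_p(g: np.ndarray, y: np.ndarray, n_perm: int, seed: int) -> float:
    """Permutation p-value for the intercept-only score statistic.

    Under label permutation the score variance is invariant, so the
    permutation distribution of the statistic is that of (g'(y_perm - ybar))^2.
    The statistic is discrete, so ties at the observed value are counted
    with weight 1/2 (mid-p), the convention that matches a continuous
    reference distribution.
    """
    rng = np.random.default_rng(seed)
    g = np.asarray(g, float)
    y = np.asarray(y, float)
    u_obs = abs(g @ (y - y.mean()))
    exceed = ties = 0
    for _ in range(n_perm):
        u = abs(g @ (rng.permutation(y) - y.mean()))
        if u > u_obs + 1e-9:
            exceed += 1
        elif u > u_obs - 1e-9:
            ties += 1
    return (exceed + 0.5 * ties) / n_perm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
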