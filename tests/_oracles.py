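"""Independent brute-force oracles used by the test suite.

These are deliberately naive implementations — exact integer arithmetic and
full enumeration — kept separate from the package so they can adjudicate its
results.
"""

from itertools import combinations
from math import comb

import numpy as np


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration of tables with fixed margins.

    Sums hypergeometric probabilities of every table whose probability is at
    most the observed one; ties decided in exact integer arithmetic.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def weight(x: int) -> int:
        return comb(r1, x) * comb(r2, c1 - x)

    w_obs = weight(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum(weight(x) for x in range(lo, hi + 1) if weight(x) <= w_obs)
    return total / denom


def bh_oracle(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up by direct sorted prefix minima."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


def mann_whitney_exact_oracle(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group labelings.

    Only valid for tie-free data; counts labelings whose U statistic is at
    least as extreme (in either tail) as the observed one.
    """
    x, y = list(x), list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi)

    u_obs = u_stat(x, y)
    mean_u = nx * len(y) / 2
    dev = abs(u_obs - mean_u)
    n_extreme = 0
    n_total = 0
    for idx in combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        n_total += 1
        if abs(u_stat(xs, ys) - mean_u) >= dev - 1e-12:
            n_extreme += 1
    return n_extreme / n_total
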