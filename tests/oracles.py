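"""Independent reference implementations used only by the tests.

The branching-process oracle evolves the full population distribution
forward period by period in exact rational arithmetic, which is a different
computational path from the generating-function composition in the package.
"""

from fractions import Fraction
from functools import lru_cache


def _convolve(d1: dict, d2: dict) -> dict:
    out: dict = {}
    for c1, p1 in d1.items():
        for c2, p2 in d2.items():
            out[c1 + c2] = out.get(c1 + c2, Fraction(0)) + p1 * p2
    return out


def _dist_power(dist_items: tuple, power: int) -> dict:
    """``power``-fold convolution of a distribution."""
    result = {0: Fraction(1)}
    base = dict(dist_items)
    while power:
        if power & 1:
            result = _convolve(result, base)
        base = _convolve(base, base)
        power >>= 1
    return result


def branching_pmf_exact(alpha: Fraction, beta: Fraction, gamma: Fraction,
                        n_periods: int, wgd_time: int | None = None) -> dict:
    """Copy-number distribution from one starting copy after ``n_periods``,
    optionally doubling all copies after period ``wgd_time``."""
    offspring = ((0, Fraction(alpha)), (1, Fraction(beta)), (2, Fraction(gamma)))

    @lru_cache(maxsize=None)
    def pop_step(c: int) -> tuple:
        return tuple(sorted(_dist_power(offspring, c).items()))

    dist = {1: Fraction(1)}
    for period in range(1, n_periods + 1):
        new: dict = {}
        for c, p in dist.items():
            for c2, p2 in pop_step(c):
                new[c2] = new.get(c2, Fraction(0)) + p * p2
        dist = new
        if wgd_time is not None and period == wgd_time:
            dist = {2 * c: p for c, p in dist.items()}
    return dist


def barnard_p_bruteforce(a: int, b: int, c: int, d: int,
                         grid_size: int = 999) -> float:
    """Naive double-loop Barnard p-value with fixed column margins and a
    pooled Wald statistic."""
    from math import comb, sqrt

    n1, n2 = a + b, c + d

    def wald(x1: int, x2: int) -> float:
        pooled = (x1 + x2) / (n1 + n2)
        if pooled in (0.0, 1.0):
            return 0.0
        return (x1 / n1 - x2 / n2) / sqrt(
            pooled * (1 - pooled) * (1 / n1 + 1 / n2))

    t_obs = abs(wald(b, d))
    best = 0.0
    for g in range(1, grid_size + 1):
        pi = g / (grid_size + 1)
        total = 0.0
        for x1 in range(n1 + 1):
            p1 = comb(n1, x1) * pi ** x1 * (1 - pi) ** (n1 - x1)
            for x2 in range(n2 + 1):
                if abs(wald(x1, x2)) >= t_obs - 1e-12:
                    total += p1 * comb(n2, x2) * pi ** x2 * (1 - pi) ** (n2 - x2)
        best = max(best, total)
    return min(best, 1.0)
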