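"""Exact and rank tests implemented from first principles.

``fisher_exact_two_tailed`` computes the two-tailed Fisher exact P for a 2x2
table by the probability-mass method: with margins fixed, every admissible
table's hypergeometric point probability is computed in exact rational
arithmetic, and those no more probable than the observed table are summed.
The result is therefore exact (no floating-point tie ambiguity) before the
final conversion to float.

``mann_whitney_two_tailed`` uses the exact null distribution of the U
statistic (standard counting recurrence) for small untied samples, and the
normal approximation with tie and continuity corrections otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Sequence


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("at least one cell must be positive")


def _hypergeom_point(a: int, r1: int, r2: int, c1: int) -> Fraction:
    """P(first cell = a) with row sums r1, r2 and first column sum c1."""
    n = r1 + r2
    return Fraction(math.comb(r1, a) * math.comb(r2, c1 - a), math.comb(n, c1))


def fisher_exact_two_tailed(table: ContingencyTable2x2) -> float:
    """Two-tailed Fisher exact P for a 2x2 table (probability-mass method)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = _hypergeom_point(a, r1, r2, c1)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p = _hypergeom_point(x, r1, r2, c1)
        if p <= p_obs:
            total += p
    return float(min(total, Fraction(1)))


@lru_cache(maxsize=None)
def _u_count(n: int, m: int, u: int) -> int:
    """Number of arrangements of n x-ranks among n+m with U statistic = u."""
    if u < 0 or u > n * m:
        return 0
    if n == 0 or m == 0:
        return 1 if u == 0 else 0
    return _u_count(n - 1, m, u - m) + _u_count(n, m - 1, u)


def _exact_mwu_p(u: float, n: int, m: int) -> float:
    """Two-tailed exact P: twice the smaller tail mass at U (point included)."""
    u_lo = min(u, n * m - u)
    # U is integer-valued without ties
    cdf = sum(_u_count(n, m, k) for k in range(int(u_lo) + 1))
    p = 2.0 * cdf / math.comb(n + m, n)
    return min(p, 1.0)


def _rank_with_ties(values: Sequence[float]) -> tuple[list[float], list[int]]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    tie_sizes: list[int] = []
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        tie_sizes.append(j - i + 1)
        i = j + 1
    return ranks, tie_sizes


def mann_whitney_two_tailed(
    sample_x: Sequence[float], sample_y: Sequence[float], *, exact_max_n: int = 20
) -> float:
    """Two-tailed Mann-Whitney P value.

    Uses the exact U distribution when the combined sample size is at most
    ``exact_max_n`` and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.  Symmetric in (x, y).
    """
    x = list(sample_x)
    y = list(sample_y)
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    ranks, tie_sizes = _rank_with_ties(x + y)
    rank_sum_x = sum(ranks[:n])
    u = rank_sum_x - n * (n + 1) / 2.0
    has_ties = any(t > 1 for t in tie_sizes)
    if not has_ties and n + m <= exact_max_n:
        return _exact_mwu_p(u, n, m)
    nm = n + m
    mean = n * m / 2.0
    tie_term = sum(t**3 - t for t in tie_sizes)
    var = n * m / 12.0 * ((nm + 1) - tie_term / (nm * (nm - 1)))
    if var <= 0.0:
        return 1.0  # all observations identical
    z = (abs(u - mean) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, math.erfc(z / math.sqrt(2.0)))
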