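"""Map-distance and crossover-interference estimators for tetrad data.

For an interval scored in ``n = PD + TT + NPD`` tetrads the Perkins estimator
of genetic distance corrects the single-crossover frequency for double
crossovers detectable as NPDs::

    cM = 100 * (TT/2 + 3*NPD) / n

Its standard error follows from the multinomial sampling variance of
(TT, NPD) by the delta method (the estimator is linear in the class counts,
so the delta-method variance is the exact sampling variance under
multinomial resampling)::

    SE = (100/sqrt(n)) * sqrt(fT/4 + 9*fN - (fT/2 + 3*fN)**2)

with fT = TT/n and fN = NPD/n.

Crossover interference is summarized by the ratio of observed NPDs to the
count expected, from the observed tetratype frequency alone, under no
interference (Papazian)::

    fN_expected = 0.5 * (1 - fT - (1 - 3*fT/2)**(2/3))

A ratio below 1 indicates positive interference.  The ratio is undefined
("n.d.") when no NPDs were observed or when fT >= 2/3 makes the expectation
non-positive.

Random-spore recombination is estimated as ``100*r/t`` with binomial
standard error ``100*sqrt((r/t)*(1-r/t)/t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .tetrad_data import IntervalClassCounts, IntervalDef


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves away from zero, matching spreadsheet display rounding."""
    scale = 10.0 ** ndigits
    y = math.floor(abs(x) * scale + 0.5) / scale
    return math.copysign(y, x)


def _require_n(counts: IntervalClassCounts) -> int:
    if counts.n <= 0:
        raise ValueError("no scorable tetrads (n = 0)")
    return counts.n


def perkins_cM(counts: IntervalClassCounts) -> float:
    """Perkins map distance in centiMorgans (unrounded)."""
    n = _require_n(counts)
    return 100.0 * (counts.TT / 2.0 + 3.0 * counts.NPD) / n


def perkins_se(counts: IntervalClassCounts) -> float:
    """Delta-method standard error of the Perkins estimate, in cM."""
    n = _require_n(counts)
    fT = counts.TT / n
    fN = counts.NPD / n
    var = fT / 4.0 + 9.0 * fN - (fT / 2.0 + 3.0 * fN) ** 2
    return 100.0 / math.sqrt(n) * math.sqrt(max(var, 0.0))


def papazian_expected_npd(counts: IntervalClassCounts) -> tuple[float, float] | None:
    """Expected NPD (frequency, count) under no interference, or None.

    Returns None when the formula's base ``1 - 3*fT/2`` is non-positive
    (fT >= 2/3), where the expectation is undefined.
    """
    n = _require_n(counts)
    fT = counts.TT / n
    base = 1.0 - 1.5 * fT
    if base <= 0.0:
        return None
    freq = 0.5 * (1.0 - fT - base ** (2.0 / 3.0))
    return freq, freq * n


def npd_ratio(counts: IntervalClassCounts) -> tuple[float, float] | None:
    """Observed/expected NPD ratio and its SE, or None ("n.d.").

    Undefined when no NPDs were observed or the Papazian expectation is
    undefined or zero.  The SE treats the observed NPD count as Poisson:
    ``sqrt(NPD) / expected_count``.
    """
    expected = papazian_expected_npd(counts)
    if expected is None or counts.NPD == 0:
        return None
    _, exp_count = expected
    if exp_count <= 0.0:
        return None
    return counts.NPD / exp_count, math.sqrt(counts.NPD) / exp_count


@dataclass(frozen=True)
class RandomSporeEstimate:
    pct_recombinant: float
    se_pct: float


def random_spore_pct(r: int, t: int) -> RandomSporeEstimate:
    """Percent recombinant spores 100*r/t with binomial SE (unrounded)."""
    if t <= 0:
        raise ValueError("total viable spore count t must be positive")
    if not 0 <= r <= t:
        raise ValueError(f"recombinant count r={r} outside [0, t={t}]")
    p = r / t
    return RandomSporeEstimate(100.0 * p, 100.0 * math.sqrt(p * (1.0 - p) / t))


@dataclass(frozen=True)
class ChromosomeSummary:
    chromosome: str
    cM_total: float
    pct_of_control: float | None = None


def chromosome_sum(
    values: Mapping[IntervalDef, float],
    chromosome: str,
    *,
    round_inputs_to: int | None = 1,
) -> ChromosomeSummary:
    """Sum per-interval map values over one chromosome.

    Tetrad-based cM totals are conventionally computed from the
    display-rounded (1-decimal) interval values, which is the behaviour the
    original spreadsheet analyses exhibit; pass ``round_inputs_to=None`` to
    sum unrounded values (the convention for random-spore percent totals).
    """
    member = [v for iv, v in values.items() if iv.chromosome == chromosome]
    if not member:
        raise ValueError(f"no intervals on chromosome {chromosome!r}")
    if round_inputs_to is not None:
        member = [round_half_away(v, round_inputs_to) for v in member]
    return ChromosomeSummary(chromosome, sum(member))


def normalize_to_control(value: float, control_value: float) -> float:
    """Percent of control: 100*value/control (unrounded; report as integer)."""
    if control_value <= 0:
        raise ValueError("control value must be positive")
    return 100.0 * value / control_value
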