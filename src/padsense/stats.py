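"""QC and method-comparison statistics for the assay.

Covers replicate reproducibility (relative standard deviation), shelf-stability
breakpoints, optimum selection over a parameter scan, relative error against a
reference method, and the two-sample Student t test on per-sample summary
statistics (pooled variance by default, df = n1 + n2 - 2; Welch available
behind a flag).

Reported percentages and concentrations are rounded to one decimal with
half-away-from-zero ties, matching common analytical-chemistry reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "round_half_away",
    "relative_error",
    "rsd",
    "TTestResult",
    "two_sample_t",
    "GroupSummary",
    "group_summary",
    "select_optimum",
    "stability_check",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the reporting convention here;
    Python's ``round`` uses banker's rounding)."""
    q = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5), x) / q


def relative_error(measured: float, reference: float, ndigits: int | None = 1) -> float:
    """100 × (measured − reference) / reference, in percent.

    Rounded to ``ndigits`` decimals half-away-from-zero; pass ``ndigits=None``
    for the unrounded value.
    """
    if reference == 0:
        raise ValueError("reference value must be non-zero")
    re = 100.0 * (measured - reference) / reference
    return re if ndigits is None else round_half_away(re, ndigits)


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation, 100 × sample SD / mean, in percent."""
    vals = np.asarray(values, dtype=float).reshape(-1)
    if vals.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return 100.0 * vals.std(ddof=1) / mean


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    t_critical: float
    alpha: float
    significant: bool


def two_sample_t(
    m1: float,
    s1: float,
    n1: int,
    m2: float,
    s2: float,
    n2: int,
    alpha: float = 0.05,
    welch: bool = False,
) -> TTestResult:
    """Two-sample t test from summary statistics (means, sample SDs, sizes).

    Pooled-variance Student form by default, df = n1 + n2 − 2, two-tailed
    critical value at ``alpha``; ``welch=True`` switches to the unequal-variance
    form with Welch–Satterthwaite df.  Antisymmetric under swapping the groups.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 determinations")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be non-negative")
    if s1 == 0 and s2 == 0:
        if m1 != m2:
            raise ValueError("zero variance in both groups with unequal means: "
                             "t statistic is infinite")
        t_stat, df = 0.0, float(n1 + n2 - 2)
    else:
        res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=not welch)
        t_stat = float(res.statistic)
        if welch:  # Welch–Satterthwaite degrees of freedom
            v1, v2 = s1**2 / n1, s2**2 / n2
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        else:
            df = float(n1 + n2 - 2)
    t_crit = float(sps.t.ppf(1.0 - alpha / 2.0, df))
    return TTestResult(t_stat, df, t_crit, alpha, abs(t_stat) > t_crit)


@dataclass(frozen=True)
class GroupSummary:
    mean: float  # one-decimal, half-away-from-zero
    sd: float  # sample SD; nan for a single value
    n: int


def group_summary(sample_means: Sequence[float]) -> GroupSummary:
    """Mean (reported to one decimal) and sample SD of per-sample means."""
    vals = np.asarray(sample_means, dtype=float).reshape(-1)
    if vals.size == 0:
        raise ValueError("empty list of sample means")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else math.nan
    return GroupSummary(round_half_away(float(vals.mean()), 1), sd, int(vals.size))


def select_optimum(
    levels: Sequence[float], replicate_responses_per_level: Sequence[Sequence[float]]
) -> float:
    """Level with the maximal mean response; ties break toward the smaller
    level value (resource-minimising)."""
    if len(levels) < 2 or len(levels) != len(replicate_responses_per_level):
        raise ValueError("need >= 2 levels with one response list each")
    means = []
    for level, reps in zip(levels, replicate_responses_per_level):
        reps = np.asarray(reps, dtype=float).reshape(-1)
        if reps.size < 1:
            raise ValueError(f"level {level} has no responses")
        means.append(reps.mean())
    best = max(means)
    return float(min(lvl for lvl, m in zip(levels, means) if m == best))


def stability_check(
    series: Sequence[tuple[float, float]], rel_threshold: float = 0.05
) -> float:
    """Largest day through which every response stays within ``rel_threshold``
    (fractional) of the day-0 response.

    ``series`` is (day, response) pairs with strictly increasing days; the
    first entry is the day-0 baseline.
    """
    pts = list(series)
    if len(pts) < 2:
        raise ValueError("need at least 2 time points")
    days = [d for d, _ in pts]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("days must be strictly increasing")
    baseline = float(pts[0][1])
    if baseline == 0:
        raise ValueError("day-0 response must be non-zero")
    last_stable = float(pts[0][0])
    for day, resp in pts[1:]:
        if abs(resp - baseline) / abs(baseline) > rel_threshold:
            break
        last_stable = float(day)
    return last_stable
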