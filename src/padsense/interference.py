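"""Selectivity analysis: tolerance limits for foreign species.

The tolerance limit of a foreign species is the largest
[foreign species]/[analyte] concentration ratio whose presence changes the
determination by a relative error of strictly less than 5% (equality fails).
Ratios are scanned in ascending order and the scan stops at the first breach,
so the reported tolerance is the largest passing ratio below the first
failure; if every tested ratio passes, the largest tested ratio is reported
with an ``exceeds_max_tested`` marker.

Comparisons are made at the response-norm level (determination error of the
analyte signal), not after concentration back-prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .stats import relative_error

__all__ = ["ToleranceResult", "tolerance_ratio", "mixture_effect"]

#: Default pass criterion: |relative error| strictly below 5 percent.
TOLERANCE_RE_PERCENT = 5.0


@dataclass(frozen=True)
class ToleranceResult:
    species: str
    ratios_tested: tuple[float, ...]
    re_percent_per_ratio: tuple[float, ...]
    tolerance_ratio: float | None  # None when even the smallest ratio fails
    exceeds_max_tested: bool


def tolerance_ratio(
    pure_response: float,
    responses_by_ratio: Mapping[float, float],
    *,
    threshold: float = TOLERANCE_RE_PERCENT,
    species: str = "",
) -> ToleranceResult:
    """Tolerance limit from responses measured at increasing foreign-species
    ratios.

    ``responses_by_ratio`` maps each tested [foreign]/[analyte] ratio to the
    response norm measured in the species' presence; ``pure_response`` is the
    analyte-only response.
    """
    if not pure_response > 0:
        raise ValueError("pure_response must be positive")
    if not responses_by_ratio:
        raise ValueError("no ratios tested")
    if any(r <= 0 for r in responses_by_ratio):
        raise ValueError("ratios must be positive")

    ratios = tuple(sorted(responses_by_ratio))
    res = tuple(
        relative_error(responses_by_ratio[r], pure_response, ndigits=None)
        for r in ratios
    )
    tolerance: float | None = None
    for ratio, re in zip(ratios, res):
        if abs(re) < threshold:
            tolerance = ratio
        else:
            break
    return ToleranceResult(
        species=species,
        ratios_tested=ratios,
        re_percent_per_ratio=res,
        tolerance_ratio=tolerance,
        exceeds_max_tested=tolerance == ratios[-1],
    )


def mixture_effect(
    pure_response: float,
    mixture_response: float,
    threshold: float = TOLERANCE_RE_PERCENT,
) -> tuple[float, bool]:
    """Relative error (%) of a 1:1 analyte/foreign-species mixture response
    against the pure-analyte response, and whether it passes (|RE| < threshold)."""
    if not pure_response > 0:
        raise ValueError("pure_response must be positive")
    re = relative_error(mixture_response, pure_response, ndigits=None)
    return re, abs(re) < threshold
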