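"""Population-level impact of offering surgery above a risk threshold.

The fraction of national breast-cancer cases arising in women above the
threshold is a prevalence-weighted risk share,

    case_fraction = sum_g prevalence_g * mean_risk_g / population_risk,

and the annual cases prevented by surgery in that group are

    prevented = annual_cases * case_fraction * risk_reduction,

with the reduction's uncertainty interval carried through linearly.
The case fraction is kept unrounded inside the product; reported counts
are rounded half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError
from .params import PrevalenceMix

__all__ = ["PrevalenceMix", "ImpactResult", "case_fraction", "prevented_cases"]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ImpactResult:
    case_fraction: float
    prevented_point: int
    prevented_low: int
    prevented_high: int
    prevented_fraction: float

    def __post_init__(self) -> None:
        if not self.prevented_low <= self.prevented_point <= self.prevented_high:
            raise ValidationError("prevented-case bounds must bracket the point")
        for name in ("case_fraction", "prevented_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")


def case_fraction(mix: PrevalenceMix) -> float:
    """Share of all cases arising in the above-threshold subgroups."""
    share = sum(p * r for p, r in mix.subgroups) / mix.population_lifetime_risk
    if share > 1.0:
        raise ValidationError(
            f"case fraction {share:.4f} exceeds 1: inconsistent prevalence mix"
        )
    return share


def prevented_cases(
    mix: PrevalenceMix,
    reduction_point: float,
    reduction_low: float,
    reduction_high: float,
) -> ImpactResult:
    """Annual cases prevented by surgery in the above-threshold group.

    ``reduction_*`` is the proportional risk reduction from surgery
    (point and interval bounds), e.g. 0.91 with (0.62, 0.98).
    """
    if not 0.0 <= reduction_low <= reduction_point <= reduction_high <= 1.0:
        raise ValidationError("require 0 <= low <= point <= high <= 1")
    frac = case_fraction(mix)
    counts = {
        name: mix.annual_cases * frac * r
        for name, r in (
            ("point", reduction_point),
            ("low", reduction_low),
            ("high", reduction_high),
        )
    }
    point = _round_half_away(counts["point"])
    return ImpactResult(
        case_fraction=frac,
        prevented_point=point,
        prevented_low=_round_half_away(counts["low"]),
        prevented_high=_round_half_away(counts["high"]),
        prevented_fraction=(point / mix.annual_cases if mix.annual_cases else 0.0),
    )
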