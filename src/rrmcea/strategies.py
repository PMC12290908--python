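"""Comparator arms: risk-reducing mastectomy versus tiered screening.

The screening comparator follows the NICE familial breast-cancer tiers,
with lifetime-risk breakpoints at 17%, 32% and 45%:

* < 17%        routine triennial mammography at 50, 53, ..., 68;
* 17% to <32%  annual mammography 40-49, then triennial to 69;
* 32% to <45%  annual mammography 40-59, then triennial 60, 63, 66, 69;
* >= 45%       annual MRI 30-49 plus annual mammography 50-69.

Medical prevention (tamoxifen while premenopausal, anastrozole after) is
offered with 16.3% uptake: a 5-year course starting at 30 for women at
>= 30% lifetime risk, at 40 for 17% to <30%, none below 17%.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import DomainError, ValidationError
from .risk import RiskProfile


class Modality(str, enum.Enum):
    MAMMOGRAPHY = "MAMMOGRAPHY"
    MRI = "MRI"


class Tier(str, enum.Enum):
    SUB_NICE = "SUB_NICE"
    TIER_17_32 = "TIER_17_32"
    TIER_32_45 = "TIER_32_45"
    TIER_45_PLUS = "TIER_45_PLUS"


class StrategyKind(str, enum.Enum):
    RRM = "RRM"
    SCREEN = "SCREEN"


#: Lifetime-risk breakpoints between screening tiers (half-open below,
#: 0.45 inclusive to the top tier).
TIER_BREAKPOINTS = (0.17, 0.32, 0.45)

#: Last age at which any screening event may occur.
SCREENING_MAX_AGE = 69


@dataclass(frozen=True)
class ScreeningEvent:
    age: int
    modality: Modality

    def __post_init__(self) -> None:
        if not 30 <= self.age <= SCREENING_MAX_AGE:
            raise ValidationError(f"screening age {self.age} outside [30, 69]")


@dataclass(frozen=True)
class ScreeningSchedule:
    events: tuple
    tier: Tier

    def __post_init__(self) -> None:
        keys = [(e.age, e.modality) for e in self.events]
        if keys != sorted(keys, key=lambda k: (k[0], k[1].value)):
            raise ValidationError("events must be sorted by age")
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (age, modality) screening event")

    @property
    def active_window(self) -> tuple:
        """Closed age interval in which diagnoses count as screen-era.

        Women diagnosed inside this window get the screened-context stage
        distribution; those outside get the general-population one.  The
        window runs from the first scheduled age to 69.
        """
        if not self.events:
            return (SCREENING_MAX_AGE + 1, SCREENING_MAX_AGE)  # empty
        return (self.events[0].age, SCREENING_MAX_AGE)

    def events_from(self, start_age: int):
        """Events at or after a cohort entry age (earlier ones dropped)."""
        return [e for e in self.events if e.age >= start_age]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": [e.age for e in self.events],
             "modality": [e.modality.value for e in self.events]}
        )


@dataclass(frozen=True)
class PreventionPlan:
    start_age: int
    duration: int = 5
    uptake: float = 0.163
    hr_tamoxifen: float = 0.71
    hr_anastrozole: float = 0.51
    carryover_years: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.uptake <= 1.0:
            raise ValidationError("uptake must lie in [0, 1]")
        for name in ("hr_tamoxifen", "hr_anastrozole"):
            hr = getattr(self, name)
            if not 0.0 < hr <= 1.0:
                raise ValidationError(f"{name} must lie in (0, 1]")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        if self.carryover_years < 0:
            raise ValidationError("carryover_years must be non-negative")


@dataclass(frozen=True)
class Strategy:
    kind: StrategyKind
    rrm_age: Optional[int] = None
    rrm_hazard_ratio: float = 0.09
    schedule: Optional[ScreeningSchedule] = None
    prevention: Optional[PreventionPlan] = None

    def __post_init__(self) -> None:
        if self.kind is StrategyKind.RRM:
            if self.rrm_age is None or self.schedule is not None:
                raise ValidationError("RRM arm needs rrm_age and no schedule")
        else:
            if self.schedule is None:
                raise ValidationError("SCREEN arm needs a schedule")
        if not 0.0 <= self.rrm_hazard_ratio <= 1.0:
            raise ValidationError("rrm_hazard_ratio must lie in [0, 1]")


def _triennial(first: int, last: int = SCREENING_MAX_AGE):
    return list(range(first, last + 1, 3))


def screening_schedule(lifetime_risk: float) -> ScreeningSchedule:
    """NICE-tier screening schedule for a lifetime risk in (0, 1)."""
    if not 0.0 < lifetime_risk < 1.0:
        raise DomainError("lifetime_risk must lie in (0, 1)")
    lo, mid, hi = TIER_BREAKPOINTS
    if lifetime_risk < lo:
        tier = Tier.SUB_NICE
        ages = [(a, Modality.MAMMOGRAPHY) for a in _triennial(50)]
    elif lifetime_risk < mid:
        tier = Tier.TIER_17_32
        ages = [(a, Modality.MAMMOGRAPHY) for a in range(40, 50)]
        ages += [(a, Modality.MAMMOGRAPHY) for a in _triennial(50)]
    elif lifetime_risk < hi:
        tier = Tier.TIER_32_45
        ages = [(a, Modality.MAMMOGRAPHY) for a in range(40, 60)]
        ages += [(a, Modality.MAMMOGRAPHY) for a in _triennial(60)]
    else:
        tier = Tier.TIER_45_PLUS
        ages = [(a, Modality.MRI) for a in range(30, 50)]
        ages += [(a, Modality.MAMMOGRAPHY) for a in range(50, 70)]
    events = tuple(ScreeningEvent(a, m) for a, m in ages)
    return ScreeningSchedule(events=events, tier=tier)


def prevention_plan(lifetime_risk: float, **overrides) -> Optional[PreventionPlan]:
    """Chemoprevention plan for a risk tier; ``None`` below 17% risk."""
    if not 0.0 < lifetime_risk < 1.0:
        raise DomainError("lifetime_risk must lie in (0, 1)")
    if lifetime_risk < TIER_BREAKPOINTS[0]:
        return None
    start = 30 if lifetime_risk >= 0.30 else 40
    return PreventionPlan(start_age=start, **overrides)


def make_strategies(
    profile: RiskProfile,
    start_age: int,
    rrm_hazard_ratio: float = 0.09,
    prevention_overrides: Optional[dict] = None,
) -> tuple:
    """Build the (RRM, SCREEN) pair for one risk profile and entry age.

    Surgery in the RRM arm happens at cohort entry (100% uptake); the
    screening arm gets the tier schedule and prevention plan implied by
    the profile's target lifetime risk.
    """
    if not 30 <= start_age <= 60:
        raise DomainError("start_age must lie in [30, 60]")
    risk = profile.lifetime_risk_target
    rrm = Strategy(
        kind=StrategyKind.RRM, rrm_age=start_age, rrm_hazard_ratio=rrm_hazard_ratio
    )
    screen = Strategy(
        kind=StrategyKind.SCREEN,
        rrm_hazard_ratio=rrm_hazard_ratio,
        schedule=screening_schedule(risk),
        prevention=prevention_plan(risk, **(prevention_overrides or {})),
    )
    return rrm, screen
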