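"""Lifetime breast-cancer risk under competing mortality.

The lifetime risk over an age window is the life-table cumulative
probability of a first breast-cancer diagnosis, with all-cause mortality
as the competing event:

    R = sum_a inc(a) * prod_{b<a} (1 - inc(b)) (1 - mort(b))

A woman whose assumed lifetime risk differs from the general population's
is modelled through a single lifetime-average hazard ratio on the
log-complement scale,

    HR = ln(1 - target risk) / ln(1 - baseline risk),

held constant across ages, and applied by multiplying the age-specific
annual incidence probabilities (clamped at 1).  Against the UK baseline
of 10.79% (ages 20-80) this gives HR = 2.52 for a 25% lifetime risk and
6.07 for 50%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .errors import CalibrationError, DomainError
from .tables import AgeRateTable

#: UK general-population lifetime breast-cancer risk, ages 20-80.
BASELINE_LIFETIME_RISK = 0.1079

#: Age window over which lifetime risk is defined (closed-open).
LIFETIME_WINDOW = (20, 80)


def cumulative_lifetime_risk(
    incidence: AgeRateTable,
    all_cause_mortality: AgeRateTable,
    start_age: int,
    end_age: int,
) -> float:
    """Cumulative probability of diagnosis over [start_age, end_age).

    Within each year, diagnosis is drawn from the start-of-year healthy
    mass; competing death removes only the non-diagnosed, so the first
    year's incidence enters undiscounted (standard life-table form).
    """
    if end_age <= start_age:
        raise DomainError("end_age must exceed start_age")
    inc = incidence.window(start_age, end_age)
    mort = all_cause_mortality.window(start_age, end_age)
    risk = 0.0
    healthy = 1.0
    for p, q in zip(inc, mort):
        risk += healthy * p
        healthy *= (1.0 - p) * (1.0 - q)
    return risk


def hazard_ratio_for_risk(target_risk: float, baseline_risk: float) -> float:
    """Lifetime-average hazard ratio ln(1-target)/ln(1-baseline)."""
    for name, x in (("target_risk", target_risk), ("baseline_risk", baseline_risk)):
        if not 0.0 < x < 1.0:
            raise DomainError(f"{name} must lie strictly in (0, 1), got {x}")
    return math.log1p(-target_risk) / math.log1p(-baseline_risk)


def scale_incidence(incidence: AgeRateTable, hazard_ratio: float) -> AgeRateTable:
    """Multiply age-specific incidence by a hazard ratio, clamped at 1."""
    if hazard_ratio < 0:
        raise DomainError("hazard_ratio must be non-negative")
    return incidence.scaled(hazard_ratio)


def calibrate_baseline(
    shape: AgeRateTable,
    mortality: AgeRateTable,
    target: float,
    tol: float = 1e-10,
) -> AgeRateTable:
    """Scale a positive incidence shape so its lifetime risk hits ``target``.

    Finds the single multiplier m such that the cumulative lifetime risk
    of ``m * shape`` over the 20-80 window equals ``target`` within
    ``tol``.  Raises :class:`CalibrationError` if the target would
    require clamping any annual probability above 1 (the scaled-shape
    risk saturates below the target).
    """
    lo_age, hi_age = LIFETIME_WINDOW
    if not 0.0 < target < 1.0:
        raise DomainError("target must lie in (0, 1)")
    window = shape.window(lo_age, hi_age)
    if not (window > 0).any():
        raise CalibrationError("shape is identically zero on the lifetime window")
    vmax = float(window.max())
    m_cap = 1.0 / vmax  # largest multiplier with no clamping

    def risk_at(m: float) -> float:
        return cumulative_lifetime_risk(
            shape.scaled(m, warn_on_clamp=False), mortality, lo_age, hi_age
        )

    if risk_at(m_cap) < target - tol:
        raise CalibrationError(
            f"target {target} unreachable without clamping annual probabilities"
        )
    m = brentq(lambda m: risk_at(m) - target, 0.0, m_cap, xtol=1e-14, rtol=1e-15)
    return shape.scaled(float(m))


@dataclass(frozen=True)
class RiskProfile:
    """An assumed lifetime risk with its derived incidence scaling.

    ``scaled_incidence`` is the general-population age-specific incidence
    multiplied by the log-complement hazard ratio.
    """

    lifetime_risk_target: float
    baseline_lifetime_risk: float
    hazard_ratio: float
    scaled_incidence: AgeRateTable

    @classmethod
    def from_target(
        cls,
        target: float,
        baseline_incidence: AgeRateTable,
        baseline_risk: float = BASELINE_LIFETIME_RISK,
    ) -> "RiskProfile":
        hr = hazard_ratio_for_risk(target, baseline_risk)
        return cls(
            lifetime_risk_target=target,
            baseline_lifetime_risk=baseline_risk,
            hazard_ratio=hr,
            scaled_incidence=scale_incidence(baseline_incidence, hr),
        )
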