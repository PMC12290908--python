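"""Cost-effectiveness comparison and lifetime-risk threshold search.

The incremental cost-effectiveness ratio (ICER) of surgery against the
screening comparator is the difference in discounted costs divided by
the difference in discounted QALYs, with dominance classified before any
division.  The threshold search walks an ascending lifetime-risk grid
(default 17%-50% in 1% steps, mirroring the published tables) and
returns the smallest risk at which surgery is cost-effective at a given
willingness to pay.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .economics import EconResult, summarize
from .errors import DomainError
from .markov import run_cohort
from .params import ParameterSet
from .risk import RiskProfile
from .strategies import make_strategies

log = logging.getLogger(__name__)


class Dominance(str, enum.Enum):
    NONE = "NONE"
    ALT_DOMINANT = "ALT_DOMINANT"
    ALT_DOMINATED = "ALT_DOMINATED"


class ThresholdCriterion(str, enum.Enum):
    ICER_BELOW_WTP = "ICER_BELOW_WTP"
    PSA_MAJORITY = "PSA_MAJORITY"


@dataclass(frozen=True)
class ICERResult:
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    dominance: Dominance

    def cost_effective_at(self, wtp: float) -> bool:
        """Is the alternative cost-effective at a willingness to pay?

        Dominant alternatives always qualify; dominated ones never do;
        otherwise the alternative qualifies when it buys QALYs at or
        below the stated price.
        """
        if self.dominance is Dominance.ALT_DOMINANT:
            return True
        if self.dominance is Dominance.ALT_DOMINATED:
            return False
        return bool(self.delta_qaly > 0 and self.icer is not None and self.icer <= wtp)


@dataclass(frozen=True)
class ThresholdResult:
    start_age: int
    wtp: float
    threshold_risk: Optional[float]
    criterion: ThresholdCriterion = ThresholdCriterion.ICER_BELOW_WTP


@dataclass(frozen=True)
class ScenarioResult:
    """Both arms of one (age, lifetime risk) scenario plus their ICER."""

    age: int
    lifetime_risk: float
    screen: EconResult
    rrm: EconResult
    comparison: ICERResult


def icer(reference: EconResult, alternative: EconResult) -> ICERResult:
    """ICER of ``alternative`` versus ``reference`` with dominance flags."""
    dc = alternative.discounted_cost - reference.discounted_cost
    dq = alternative.discounted_qaly - reference.discounted_qaly
    if dq > 0 and dc <= 0:
        return ICERResult(dc, dq, None, Dominance.ALT_DOMINANT)
    if dq < 0 and dc >= 0:
        return ICERResult(dc, dq, None, Dominance.ALT_DOMINATED)
    if dq == 0:
        dom = Dominance.ALT_DOMINATED if dc > 0 else (
            Dominance.ALT_DOMINANT if dc < 0 else Dominance.NONE
        )
        return ICERResult(dc, dq, None, dom)
    return ICERResult(dc, dq, dc / dq, Dominance.NONE)


def net_monetary_benefit(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """NMB = dQALY * WTP - dCost; positive iff cost-effective at WTP."""
    if wtp < 0:
        raise DomainError("willingness to pay must be non-negative")
    return delta_qaly * wtp - delta_cost


def evaluate_scenario(
    bundle: ParameterSet, age: int, lifetime_risk: float
) -> ScenarioResult:
    """Run both arms for one surgery age and assumed lifetime risk."""
    from dataclasses import replace

    config = replace(bundle.config, start_age=age)
    profile = RiskProfile.from_target(
        lifetime_risk, bundle.incidence, bundle.baseline_lifetime_risk
    )
    iv = bundle.intervention
    rrm, screen = make_strategies(
        profile,
        age,
        rrm_hazard_ratio=iv.rrm_hazard_ratio,
        prevention_overrides=dict(
            uptake=iv.uptake,
            hr_tamoxifen=iv.hr_tamoxifen,
            hr_anastrozole=iv.hr_anastrozole,
            duration=iv.duration,
            carryover_years=iv.carryover_years,
        ),
    )
    results = {}
    for name, strat in (("screen", screen), ("rrm", rrm)):
        trace = run_cohort(strat, profile, bundle.disease, config, bundle.mortality)
        results[name] = summarize(
            trace, bundle.costs, bundle.utilities,
            bundle.discount_cost, bundle.discount_effect,
        )
    return ScenarioResult(
        age=age,
        lifetime_risk=lifetime_risk,
        screen=results["screen"],
        rrm=results["rrm"],
        comparison=icer(results["screen"], results["rrm"]),
    )


def default_risk_grid(start: float = 0.17, stop: float = 0.50, step: float = 0.01):
    n = int(round((stop - start) / step))
    return [round(start + i * step, 10) for i in range(n + 1)]


def find_threshold(
    bundle: ParameterSet,
    start_age: int,
    wtp: float,
    risk_grid: Optional[Sequence[float]] = None,
) -> ThresholdResult:
    """Smallest grid lifetime risk at which surgery is cost-effective.

    The ICER is expected to fall as risk rises; if it crosses the WTP
    non-monotonically the smallest qualifying risk is still returned and
    the non-monotonicity logged.
    """
    grid = list(risk_grid) if risk_grid is not None else default_risk_grid()
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise DomainError("risk grid must be strictly ascending")
    qualifying = []
    icers = []
    for r in grid:
        cmp = evaluate_scenario(bundle, start_age, r).comparison
        icers.append(cmp.icer)
        if cmp.cost_effective_at(wtp):
            qualifying.append(r)
    finite = [x for x in icers if x is not None]
    if any(b > a for a, b in zip(finite, finite[1:])):
        log.info("ICER not monotone over the risk grid at age %d", start_age)
    threshold = min(qualifying) if qualifying else None
    return ThresholdResult(start_age=start_age, wtp=wtp, threshold_risk=threshold)


def threshold_sweep(
    bundle: ParameterSet,
    ages: Sequence[int],
    wtps: Sequence[float],
    risk_grid: Optional[Sequence[float]] = None,
):
    """ICER per (risk, age) cell plus thresholds per (age, wtp).

    Returns ``(cells, thresholds)`` where ``cells`` is a list of dicts
    shaped like the published risk-by-age table.
    """
    grid = list(risk_grid) if risk_grid is not None else default_risk_grid()
    cells = []
    by_age = {}
    for age in ages:
        col = {}
        for r in grid:
            cmp = evaluate_scenario(bundle, age, r).comparison
            col[r] = cmp
            cells.append(
                {"lifetime_risk": r, "age": age, "icer": cmp.icer,
                 "dominance": cmp.dominance.value}
            )
        by_age[age] = col
    thresholds = []
    for age in ages:
        for wtp in wtps:
            qual = [r for r, cmp in by_age[age].items() if cmp.cost_effective_at(wtp)]
            thresholds.append(
                ThresholdResult(start_age=age, wtp=wtp,
                                threshold_risk=min(qual) if qual else None)
            )
    return cells, thresholds
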