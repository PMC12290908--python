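"""Costs, utilities, discounting, and trace summarisation.

The payer (NHS) perspective is used with all costs in 2021 GBP.  Costs
and health effects are discounted at 3.5% per year by default,
independently configurable because one-way sensitivity analysis varies
them separately.  Utilities are age-adjusted multiplicatively: the
utility lived in a state at age ``a`` is ``norm(a) * state_utility``.
Event disutilities are short absolute decrements — 1/52 year for a
screen attended, 5/52 year for a false positive, a full-year decrement
in the year of surgery, and an annual decrement per treated
chemoprevention year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .disease import N_STAGES, STAGES, PathologyMix
from .errors import DomainError, ValidationError
from .markov import CohortTrace
from .tables import AgeRateTable

log = logging.getLogger(__name__)

DEFAULT_DISCOUNT_RATE = 0.035

SCREEN_DISUTILITY_YEARS = 1.0 / 52.0
FALSE_POSITIVE_DISUTILITY_YEARS = 5.0 / 52.0


def discount_factor(rate: float, years_since_start: float) -> float:
    """Present-value factor (1 + rate)^(-t)."""
    if rate < 0:
        raise DomainError("discount rate must be non-negative")
    if years_since_start < 0:
        raise DomainError("years_since_start must be non-negative")
    return (1.0 + rate) ** (-years_since_start)


def age_adjusted_utility(age: int, state_utility: float, norms: AgeRateTable) -> float:
    """Multiplicative age adjustment: norm(age) * state utility."""
    if not 0.0 <= state_utility <= 1.0:
        raise DomainError("state utility must lie in [0, 1]")
    return norms.value_at(age) * state_utility


def weight_treatment_costs(
    pathology_mix: PathologyMix, subtype_costs: dict
) -> np.ndarray:
    """Pathology-weighted per-stage annual treatment costs.

    ``subtype_costs`` maps each pathology axis name (``er_positive``,
    ``erbb2_positive``, ``node_positive``, ``premenopausal``) to a pair
    of per-stage cost vectors ``(cost_if_positive, cost_if_negative)``,
    plus an optional ``"base"`` per-stage vector.  Each axis contributes
    the convex combination ``p * positive + (1 - p) * negative``.
    """
    total = np.zeros(N_STAGES)
    base = subtype_costs.get("base")
    if base is not None:
        total += np.asarray(base, dtype=float)
    mix = pathology_mix.as_dict()
    for axis, p in mix.items():
        if axis not in subtype_costs:
            continue
        pos, neg = subtype_costs[axis]
        total += p * np.asarray(pos, float) + (1.0 - p) * np.asarray(neg, float)
    if np.any(total < 0):
        raise ValidationError("weighted treatment costs must be non-negative")
    return total


@dataclass(frozen=True)
class CostTable:
    """Unit costs, 2021 GBP.  Stage vectors are ordered as STAGES."""

    rrm: float
    mammography: float
    mri: float
    false_positive_recall: float
    false_positive_biopsy: float
    prevention_annual_tamoxifen: float
    prevention_annual_anastrozole: float
    stage_first_year: np.ndarray
    stage_subsequent: np.ndarray
    stage_terminal: np.ndarray
    recurrence_annual: float
    local_recurrence_event: float

    def __post_init__(self) -> None:
        for name in ("stage_first_year", "stage_subsequent", "stage_terminal"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (N_STAGES,):
                raise ValidationError(f"{name} must have one entry per stage")
        for name in (
            "rrm", "mammography", "mri", "false_positive_recall",
            "false_positive_biopsy", "prevention_annual_tamoxifen",
            "prevention_annual_anastrozole", "recurrence_annual",
            "local_recurrence_event",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for name in ("stage_first_year", "stage_subsequent", "stage_terminal"):
            if np.any(getattr(self, name) < 0):
                raise ValidationError(f"{name} entries must be non-negative")

    def __eq__(self, other):
        if not isinstance(other, CostTable):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f))
            if isinstance(getattr(self, f), np.ndarray)
            else getattr(self, f) == getattr(other, f)
            for f in self.__dataclass_fields__
        )

    def __hash__(self):
        return hash((self.rrm, self.mri, self.stage_first_year.tobytes()))


@dataclass(frozen=True)
class UtilityTable:
    """Health-state utilities, population norms, and event disutilities."""

    norms: AgeRateTable
    healthy: float
    stage_year1: np.ndarray
    stage_subsequent: np.ndarray
    recurrence: float
    survivor: float
    disutility_rrm: float
    disutility_screen: float
    disutility_false_positive: float
    disutility_prevention: float

    def __post_init__(self) -> None:
        for name in ("stage_year1", "stage_subsequent"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (N_STAGES,):
                raise ValidationError(f"{name} must have one entry per stage")
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValidationError(f"{name} utilities must lie in [0, 1]")
        for name in ("healthy", "recurrence", "survivor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} utility must lie in [0, 1]")
        for name in (
            "disutility_rrm", "disutility_screen",
            "disutility_false_positive", "disutility_prevention",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    def __eq__(self, other):
        if not isinstance(other, UtilityTable):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f))
            if isinstance(getattr(self, f), np.ndarray)
            else getattr(self, f) == getattr(other, f)
            for f in self.__dataclass_fields__
        )

    def __hash__(self):
        return hash((self.healthy, self.recurrence, self.stage_year1.tobytes()))


@dataclass(frozen=True)
class EconResult:
    """Discounted and undiscounted summary of one strategy arm."""

    discounted_cost: float
    discounted_qaly: float
    discounted_ly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    undiscounted_ly: float
    cumulative_bc_incidence: float
    cumulative_bc_death: float

    def __post_init__(self) -> None:
        if self.cumulative_bc_death > self.cumulative_bc_incidence + 1e-12:
            raise ValidationError("BC deaths cannot exceed BC incidence")


def summarize(
    trace: CohortTrace,
    costs: CostTable,
    utilities: UtilityTable,
    discount_rate_costs: float = DEFAULT_DISCOUNT_RATE,
    discount_rate_effects: float = DEFAULT_DISCOUNT_RATE,
) -> EconResult:
    """Attach costs and utilities to a cohort trace.

    Per cycle, costs are event flows times unit costs plus diagnosed
    occupancy times annual treatment costs (terminal care charged in the
    cycle of breast-cancer death); the QALY contribution is occupancy
    times age-adjusted state utility minus event disutilities, clamped
    at zero.  Everything is discounted by whole years since model start.
    """
    T = trace.n_cycles
    t_idx = np.arange(T)
    dfc = (1.0 + _check_rate(discount_rate_costs)) ** (-t_idx)
    dfe = (1.0 + _check_rate(discount_rate_effects)) ** (-t_idx)
    ages = trace.ages[:T]
    norms = utilities.norms.window(int(ages[0]), int(ages[-1]) + 1)

    # occupancy pieces, cycle-start rows 0..T-1
    tun = trace.tunnels[:T]                       # (T, C, 5, 20)
    occ_year1 = tun[:, :, :, 0].sum(axis=1)       # (T, 5)
    occ_subseq = tun[:, :, :, 1:].sum(axis=(1, 3))  # (T, 5)

    # ---- costs ---------------------------------------------------------
    cost = np.zeros(T)
    cost += trace.screens[:, 0] * costs.mammography
    cost += trace.screens[:, 1] * costs.mri
    cost += trace.false_positives.sum(axis=1) * costs.false_positive_recall
    cost += trace.biopsies.sum(axis=1) * costs.false_positive_biopsy
    cost += trace.rrm_performed * costs.rrm
    cost += trace.prevention_person_years[:, 0] * costs.prevention_annual_tamoxifen
    cost += trace.prevention_person_years[:, 1] * costs.prevention_annual_anastrozole
    cost += occ_year1 @ costs.stage_first_year
    cost += occ_subseq @ costs.stage_subsequent
    cost += trace.recurrence[:T] * costs.recurrence_annual
    cost += trace.bc_deaths_stage.sum(axis=1) @ costs.stage_terminal
    cost += trace.bc_deaths_recurrence * float(costs.stage_terminal[-1])
    cost += trace.local_recurrences * costs.local_recurrence_event

    # ---- QALYs ---------------------------------------------------------
    state_u = (
        trace.healthy[:T] * utilities.healthy
        + occ_year1 @ utilities.stage_year1
        + occ_subseq @ utilities.stage_subsequent
        + trace.recurrence[:T] * utilities.recurrence
        + trace.survivor[:T] * utilities.survivor
    )
    qaly = norms * state_u
    qaly -= trace.screens.sum(axis=1) * SCREEN_DISUTILITY_YEARS * utilities.disutility_screen
    qaly -= (
        trace.false_positives.sum(axis=1)
        * FALSE_POSITIVE_DISUTILITY_YEARS
        * utilities.disutility_false_positive
    )
    qaly -= trace.rrm_performed * utilities.disutility_rrm
    qaly -= trace.prevention_person_years.sum(axis=1) * utilities.disutility_prevention
    if np.any(qaly < 0):
        log.warning("negative per-cycle utility clamped to 0 in %d cycle(s)",
                    int(np.sum(qaly < 0)))
        qaly = np.maximum(qaly, 0.0)

    ly = trace.alive()[:T]

    return EconResult(
        discounted_cost=float(cost @ dfc),
        discounted_qaly=float(qaly @ dfe),
        discounted_ly=float(ly @ dfe),
        undiscounted_cost=float(cost.sum()),
        undiscounted_qaly=float(qaly.sum()),
        undiscounted_ly=float(ly.sum()),
        cumulative_bc_incidence=trace.cumulative_bc_incidence,
        cumulative_bc_death=trace.cumulative_bc_death,
    )


def _check_rate(rate: float) -> float:
    if rate < 0:
        raise DomainError("discount rate must be non-negative")
    return rate


def result_row(strategy_name: str, res: EconResult, icer=None) -> dict:
    """One reporting row in the published table's column order."""
    return {
        "strategy": strategy_name,
        "bc_incidence_pct": 100.0 * res.cumulative_bc_incidence,
        "bc_death_pct": 100.0 * res.cumulative_bc_death,
        "cost_gbp": res.discounted_cost,
        "lyg": res.discounted_ly,
        "qaly": res.discounted_qaly,
        "icer_gbp_per_qaly": icer,
    }
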