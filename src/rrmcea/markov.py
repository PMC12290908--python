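"""Annual-cycle Markov cohort engine.

The cohort starts healthy at ``start_age`` and is propagated in annual
cycles to age 80 across the states

    HEALTHY -> stage tunnels (context, stage, years-since-diagnosis 1..20)
            -> DISTANT_RECURRENCE | LONG_TERM_SURVIVOR | DEAD_BC | DEAD_OTHER

Occupancy is recorded at the start of every cycle; event flows (new
diagnoses, screens, false positives, deaths, recurrences) are recorded
per cycle.  Within a cycle the conventions are:

* From HEALTHY, diagnosis is drawn from the start-of-cycle mass
  (``H * p``), so the first year's incidence is not discounted by
  same-year competing death; other-cause death then removes
  ``H * (1-p) * q``.  This matches the life-table definition of lifetime
  risk used to calibrate incidence.
* In a diagnosed tunnel, other-cause death acts first, then stage- and
  duration-specific breast-cancer death, then distant recurrence;
  survivors advance one tunnel year.  Local recurrence is a costed flow
  that does not move mass.
* No half-cycle correction is applied.

Probability mass is checked every cycle; a leak beyond 1e-9 aborts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .disease import N_STAGES, STAGES, SURVIVOR_CUTOFF, DiseaseHistoryParams, StageDistribution
from .errors import ConsistencyError, DomainError, ValidationError
from .risk import RiskProfile
from .strategies import Modality, ScreeningSchedule, Strategy, StrategyKind
from .tables import AgeRateTable

MASS_TOL = 1e-9

MODALITIES = (Modality.MAMMOGRAPHY, Modality.MRI)


@dataclass(frozen=True)
class ModelConfig:
    start_age: int = 30
    horizon_age: int = 80
    cycle_length: int = 1
    menopause_age: int = 51

    def __post_init__(self) -> None:
        if not (30 <= self.start_age <= 60 < self.horizon_age <= 80):
            raise ValidationError(
                "require 30 <= start_age <= 60 < horizon_age <= 80"
            )
        if self.cycle_length != 1:
            raise ValidationError("cycle length is fixed at 1 year")

    @property
    def n_cycles(self) -> int:
        return self.horizon_age - self.start_age


@dataclass
class CohortTrace:
    """Per-cycle occupancy and event flows of one cohort run.

    Occupancy arrays have ``n_cycles + 1`` rows (cycle starts, including
    the horizon); flow arrays have ``n_cycles`` rows.  ``tunnels`` is
    (cycle, context, stage, years-since-diagnosis).
    """

    start_age: int
    contexts: tuple
    healthy: np.ndarray
    tunnels: np.ndarray
    recurrence: np.ndarray
    survivor: np.ndarray
    dead_bc: np.ndarray
    dead_other: np.ndarray
    # flows, one row per cycle
    new_dx: np.ndarray            # (T, C, 5)
    bc_deaths_stage: np.ndarray   # (T, C, 5) deaths out of tunnels
    bc_deaths_recurrence: np.ndarray  # (T,)
    other_deaths: np.ndarray      # (T,)
    screens: np.ndarray           # (T, 2) by MODALITIES order
    false_positives: np.ndarray   # (T, 2)
    biopsies: np.ndarray          # (T, 2)
    local_recurrences: np.ndarray  # (T,)
    distant_recurrences: np.ndarray  # (T,)
    prevention_person_years: np.ndarray  # (T, 2) [tamoxifen, anastrozole]
    rrm_performed: np.ndarray     # (T,)

    @property
    def n_cycles(self) -> int:
        return len(self.healthy) - 1

    @property
    def ages(self) -> np.ndarray:
        return self.start_age + np.arange(self.n_cycles + 1)

    def total_occupancy(self) -> np.ndarray:
        return (
            self.healthy
            + self.tunnels.sum(axis=(1, 2, 3))
            + self.recurrence
            + self.survivor
            + self.dead_bc
            + self.dead_other
        )

    def alive(self) -> np.ndarray:
        return self.total_occupancy() - self.dead_bc - self.dead_other

    @property
    def cumulative_bc_incidence(self) -> float:
        return float(self.new_dx.sum())

    @property
    def cumulative_bc_death(self) -> float:
        return float(self.bc_deaths_stage.sum() + self.bc_deaths_recurrence.sum())

    def to_frame(self) -> pd.DataFrame:
        """Wide per-cycle export: occupancy by state, flows per cycle."""
        T = self.n_cycles
        d = {"age": self.ages[:-1], "healthy": self.healthy[:-1]}
        for si, s in enumerate(STAGES):
            d[f"tunnel_{s}"] = self.tunnels[:-1, :, si, :].sum(axis=(1, 2))
        d["distant_recurrence"] = self.recurrence[:-1]
        d["long_term_survivor"] = self.survivor[:-1]
        d["dead_bc"] = self.dead_bc[:-1]
        d["dead_other"] = self.dead_other[:-1]
        for si, s in enumerate(STAGES):
            d[f"new_dx_{s}"] = self.new_dx[:, :, si].sum(axis=1)
        d["screens_mammography"] = self.screens[:, 0]
        d["screens_mri"] = self.screens[:, 1]
        d["false_positives"] = self.false_positives.sum(axis=1)
        d["biopsies"] = self.biopsies.sum(axis=1)
        d["bc_deaths"] = (
            self.bc_deaths_stage.sum(axis=(1, 2)) + self.bc_deaths_recurrence
        )
        d["other_deaths"] = self.other_deaths
        d["local_recurrences"] = self.local_recurrences
        d["distant_recurrences"] = self.distant_recurrences
        return pd.DataFrame(d)


def stage_distribution_at(
    age: int, schedule: Optional[ScreeningSchedule], params: DiseaseHistoryParams
) -> StageDistribution:
    """Stage distribution at diagnosis for a given age and schedule.

    Screened-context distribution inside the schedule's active window,
    general-population distribution outside (or with no schedule).
    """
    if schedule is not None:
        lo, hi = schedule.active_window
        if lo <= age <= hi:
            return params.screened.stage_distribution
    return params.general.stage_distribution


def apply_strategy_modifiers(
    incidence: AgeRateTable, strategy: Strategy, config: ModelConfig
) -> AgeRateTable:
    """Strategy-modified annual incidence.

    RRM multiplies incidence by the residual hazard ratio from the
    surgery age onward.  Chemoprevention multiplies incidence by
    ``(1 - uptake) + uptake * HR(agent)`` during the treated years and a
    carryover window, with tamoxifen before the menopause age and
    anastrozole after.  A plan whose nominal start precedes cohort entry
    is shifted to start at entry.
    """
    values = incidence.values.copy()
    ages = incidence.ages
    if strategy.kind is StrategyKind.RRM:
        mask = ages >= strategy.rrm_age
        values[mask] *= strategy.rrm_hazard_ratio
        return incidence.with_values(values)
    plan = strategy.prevention
    if plan is None or plan.uptake == 0.0:
        return incidence.with_values(values)
    start = max(plan.start_age, config.start_age)
    end = start + plan.duration + plan.carryover_years
    for i, a in enumerate(ages):
        if start <= a < end:
            hr = plan.hr_tamoxifen if a < config.menopause_age else plan.hr_anastrozole
            values[i] *= (1.0 - plan.uptake) + plan.uptake * hr
    return incidence.with_values(values)


def prevention_treated_window(strategy: Strategy, config: ModelConfig) -> tuple:
    """Ages [lo, hi) during which prevention drugs are actually taken."""
    plan = strategy.prevention
    if strategy.kind is not StrategyKind.SCREEN or plan is None:
        return (0, 0)
    lo = max(plan.start_age, config.start_age)
    return (lo, lo + plan.duration)


def run_cohort(
    strategy: Strategy,
    profile: RiskProfile,
    params: DiseaseHistoryParams,
    config: ModelConfig,
    mortality: AgeRateTable,
) -> CohortTrace:
    """Propagate a unit cohort from ``start_age`` to the horizon."""
    start, end = config.start_age, config.horizon_age
    T = config.n_cycles
    profile.scaled_incidence.require(start, end)
    mortality.require(start, end)

    inc_mod = apply_strategy_modifiers(profile.scaled_incidence, strategy, config)
    p = inc_mod.window(start, end)
    q = mortality.window(start, end)

    is_rrm = strategy.kind is StrategyKind.RRM
    contexts = ("post_rrm",) if is_rrm else ("screened", "general")
    C = len(contexts)
    cp = [params.context(c) for c in contexts]
    death = np.stack([c.bc_death for c in cp])            # (C,5,20)
    drec = np.stack([c.distant_recurrence for c in cp])
    lrec = np.stack([c.local_recurrence for c in cp])
    stage_dist = np.stack([c.stage_distribution.probabilities for c in cp])

    schedule = strategy.schedule
    if schedule is not None:
        win_lo, win_hi = schedule.active_window
        events_by_age: dict = {}
        for e in schedule.events_from(start):
            events_by_age.setdefault(e.age, []).append(e.modality)
    else:
        win_lo, win_hi = (1, 0)
        events_by_age = {}
    perf = params.screening_performance
    fp_rate = {
        Modality.MAMMOGRAPHY: perf.fp_recall_mammography,
        Modality.MRI: perf.fp_recall_mri,
    }
    biopsy_frac = {
        Modality.MAMMOGRAPHY: perf.biopsy_fraction_mammography,
        Modality.MRI: perf.biopsy_fraction_mri,
    }
    prev_lo, prev_hi = prevention_treated_window(strategy, config)
    uptake = strategy.prevention.uptake if strategy.prevention else 0.0

    Y = SURVIVOR_CUTOFF
    healthy = np.zeros(T + 1)
    tunnels = np.zeros((T + 1, C, N_STAGES, Y))
    recurrence = np.zeros(T + 1)
    survivor = np.zeros(T + 1)
    dead_bc = np.zeros(T + 1)
    dead_other = np.zeros(T + 1)
    healthy[0] = 1.0

    new_dx = np.zeros((T, C, N_STAGES))
    bc_deaths_stage = np.zeros((T, C, N_STAGES))
    bc_deaths_rec = np.zeros(T)
    other_deaths = np.zeros(T)
    screens = np.zeros((T, 2))
    false_positives = np.zeros((T, 2))
    biopsies = np.zeros((T, 2))
    local_recs = np.zeros(T)
    distant_recs = np.zeros(T)
    prevention_py = np.zeros((T, 2))
    rrm_flow = np.zeros(T)

    for t in range(T):
        a = start + t
        H = healthy[t]
        tun = tunnels[t]
        R = recurrence[t]
        V = survivor[t]
        pa, qa = p[t], q[t]

        # screening flows on start-of-cycle healthy mass
        for m in events_by_age.get(a, ()):  # noqa: B007
            mi = MODALITIES.index(m)
            screens[t, mi] += H
            fp = H * fp_rate[m]
            false_positives[t, mi] += fp
            biopsies[t, mi] += fp * biopsy_frac[m]
        if prev_lo <= a < prev_hi:
            agent = 0 if a < config.menopause_age else 1
            prevention_py[t, agent] = H * uptake
        if is_rrm and a == strategy.rrm_age:
            rrm_flow[t] = H

        # healthy: diagnosis from start-of-cycle mass, then other-cause death
        dx_total = H * pa
        if is_rrm:
            ci = 0
        else:
            ci = 0 if win_lo <= a <= win_hi else 1
        dx_by_stage = dx_total * stage_dist[ci]
        new_dx[t, ci] = dx_by_stage
        h_dead = H * (1.0 - pa) * qa
        healthy[t + 1] = H * (1.0 - pa) * (1.0 - qa)

        # tunnels: other-cause death, BC death, distant recurrence, advance
        t_other = tun * qa
        rem = tun - t_other
        t_bc = rem * death
        rem = rem - t_bc
        t_dr = rem * drec
        adv = rem - t_dr
        t_lr = adv * lrec  # costed flow; mass still advances
        bc_deaths_stage[t] = t_bc.sum(axis=2)
        local_recs[t] = t_lr.sum()
        distant_recs[t] = t_dr.sum()

        nxt = np.zeros_like(tun)
        nxt[:, :, 1:] = adv[:, :, :-1]
        nxt[ci, :, 0] += dx_by_stage
        to_survivor = adv[:, :, -1].sum()
        tunnels[t + 1] = nxt

        # distant recurrence state: other-cause then BC death
        r_other = R * qa
        r_rem = R - r_other
        r_bc = r_rem * params.recurrence_death
        bc_deaths_rec[t] = r_bc
        recurrence[t + 1] = r_rem - r_bc + t_dr.sum()

        # long-term survivors: general-population mortality only
        v_other = V * qa
        survivor[t + 1] = V - v_other + to_survivor

        cycle_other = h_dead + t_other.sum() + r_other + v_other
        other_deaths[t] = cycle_other
        dead_other[t + 1] = dead_other[t] + cycle_other
        dead_bc[t + 1] = dead_bc[t] + t_bc.sum() + r_bc

        total = (
            healthy[t + 1]
            + tunnels[t + 1].sum()
            + recurrence[t + 1]
            + survivor[t + 1]
            + dead_bc[t + 1]
            + dead_other[t + 1]
        )
        if abs(total - 1.0) > MASS_TOL:
            raise ConsistencyError(
                f"probability mass leak at cycle {t} (age {a}): total {total!r}"
            )

    return CohortTrace(
        start_age=start,
        contexts=contexts,
        healthy=healthy,
        tunnels=tunnels,
        recurrence=recurrence,
        survivor=survivor,
        dead_bc=dead_bc,
        dead_other=dead_other,
        new_dx=new_dx,
        bc_deaths_stage=bc_deaths_stage,
        bc_deaths_recurrence=bc_deaths_rec,
        other_deaths=other_deaths,
        screens=screens,
        false_positives=false_positives,
        biopsies=biopsies,
        local_recurrences=local_recs,
        distant_recurrences=distant_recs,
        prevention_person_years=prevention_py,
        rrm_performed=rrm_flow,
    )
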