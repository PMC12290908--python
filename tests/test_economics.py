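"""Discounting, utility adjustment, cost weighting, trace summaries."""

import numpy as np
import pytest

from rrmcea import (
    DomainError,
    ModelConfig,
    PathologyMix,
    RiskProfile,
    Strategy,
    StrategyKind,
    age_adjusted_utility,
    discount_factor,
    make_strategies,
    run_cohort,
    summarize,
    weight_treatment_costs,
)
from rrmcea.strategies import (
    Modality,
    ScreeningEvent,
    ScreeningSchedule,
    Tier,
)

from .conftest import flat_table
from .test_markov import toy_disease, toy_profile


class TestDiscountFactor:
    def test_time_zero_is_one(self):
        assert discount_factor(0.035, 0) == 1.0

    def test_zero_rate_is_one_forever(self):
        assert discount_factor(0.0, 37) == 1.0

    def test_one_year_at_nice_rate(self):
        assert discount_factor(0.035, 1) == pytest.approx(0.96618, abs=5e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            discount_factor(0.035, -1)


class TestAgeAdjustedUtility:
    def test_multiplicative_combination(self, paper_bundle):
        norms = flat_table(20, 80, 0.9)
        assert age_adjusted_utility(40, 0.8, norms) == pytest.approx(0.72)
        assert age_adjusted_utility(40, 1.0, norms) == pytest.approx(0.9)
        assert age_adjusted_utility(40, 0.8, flat_table(20, 80, 1.0)) == (
            pytest.approx(0.8)
        )


class TestWeightTreatmentCosts:
    def test_degenerate_mix_selects_subtype(self):
        mix = PathologyMix(1.0, 0.0, 0.0, 0.0)
        costs = {"er_positive": (np.full(5, 300.0), np.full(5, 100.0))}
        assert np.allclose(weight_treatment_costs(mix, costs), 300.0)

    def test_equal_costs_mix_independent(self):
        costs = {"node_positive": (np.full(5, 200.0), np.full(5, 200.0))}
        for p in (0.0, 0.3, 1.0):
            mix = PathologyMix(0.5, 0.5, p, 0.5)
            assert np.allclose(weight_treatment_costs(mix, costs), 200.0)

    def test_midpoint(self):
        mix = PathologyMix(0.5, 0.5, 0.5, 0.5)
        costs = {"erbb2_positive": (np.full(5, 300.0), np.full(5, 100.0))}
        assert np.allclose(weight_treatment_costs(mix, costs), 200.0)


def _disease_free_trace(start=30, horizon=80):
    config = ModelConfig(start_age=start, horizon_age=horizon)
    profile = toy_profile(start, horizon, 0.0)
    return run_cohort(
        Strategy(kind=StrategyKind.RRM, rrm_age=60, rrm_hazard_ratio=1.0),
        profile,
        toy_disease([1, 0, 0, 0, 0]),
        config,
        flat_table(start, horizon, 0.0),
    )


def _neutral_utilities(bundle):
    from dataclasses import replace

    u = bundle.utilities
    return replace(
        u,
        norms=flat_table(20, 80, 1.0),
        healthy=1.0,
        disutility_rrm=0.0,
        disutility_screen=0.0,
        disutility_false_positive=0.0,
        disutility_prevention=0.0,
    )


class TestSummarize:
    def test_disease_free_undiscounted_qaly_equals_life_years(self, paper_bundle):
        trace = _disease_free_trace()
        res = summarize(
            trace, paper_bundle.costs, _neutral_utilities(paper_bundle), 0.0, 0.0
        )
        assert res.undiscounted_ly == pytest.approx(50.0)
        assert res.undiscounted_qaly == pytest.approx(50.0)
        assert res.discounted_qaly == pytest.approx(50.0)

    def test_discounted_life_years_geometric_series(self, paper_bundle):
        trace = _disease_free_trace()
        res = summarize(
            trace, paper_bundle.costs, _neutral_utilities(paper_bundle), 0.035, 0.035
        )
        expected = sum(1.035 ** (-t) for t in range(50))
        assert res.discounted_ly == pytest.approx(expected, abs=1e-10)
        assert res.discounted_ly == pytest.approx(24.28, abs=0.005)

    def test_single_screen_cost_discounted_at_event_year(self, paper_bundle):
        from dataclasses import replace

        config = ModelConfig(start_age=30)
        profile = toy_profile(30, 80, 0.0)
        schedule = ScreeningSchedule(
            events=(ScreeningEvent(45, Modality.MAMMOGRAPHY),), tier=Tier.SUB_NICE
        )
        strat = Strategy(
            kind=StrategyKind.SCREEN, schedule=schedule, prevention=None
        )
        disease = toy_disease([1, 0, 0, 0, 0])
        trace = run_cohort(strat, profile, disease, config, flat_table(30, 80, 0.0))
        costs = replace(
            paper_bundle.costs,
            mammography=123.0,
            mri=0.0,
            false_positive_recall=0.0,
            false_positive_biopsy=0.0,
        )
        # disease-free cohort: the only cost is the single screen at 45
        res = summarize(trace, costs, _neutral_utilities(paper_bundle), 0.035, 0.035)
        assert res.discounted_cost == pytest.approx(123.0 * 1.035 ** (-15), rel=1e-12)

    def test_discounted_never_exceeds_undiscounted(self, paper_bundle):
        from rrmcea import evaluate_scenario

        sc = evaluate_scenario(paper_bundle, 30, 0.34)
        for res in (sc.screen, sc.rrm):
            assert res.discounted_cost <= res.undiscounted_cost
            assert res.discounted_qaly <= res.undiscounted_qaly
            assert res.discounted_ly <= res.undiscounted_ly
            assert res.cumulative_bc_death <= res.cumulative_bc_incidence

    def test_totals_non_increasing_in_discount_rate(self, paper_bundle):
        profile = RiskProfile.from_target(0.34, paper_bundle.incidence)
        _, screen = make_strategies(profile, 30)
        trace = run_cohort(
            screen, profile, paper_bundle.disease, ModelConfig(start_age=30),
            paper_bundle.mortality,
        )
        rates = (0.0, 0.015, 0.035, 0.06)
        out = [
            summarize(trace, paper_bundle.costs, paper_bundle.utilities, r, r)
            for r in rates
        ]
        for a, b in zip(out, out[1:]):
            assert b.discounted_cost < a.discounted_cost
            assert b.discounted_qaly < a.discounted_qaly

    def test_extra_screen_costs_more_and_hurts_qalys(self, paper_bundle):
        """Adding one screening event (same disease course) weakly raises
        cost and weakly lowers QALYs."""
        config = ModelConfig(start_age=30)
        profile = toy_profile(30, 80, 0.0)
        base_events = tuple(
            ScreeningEvent(a, Modality.MAMMOGRAPHY) for a in (50, 53, 56)
        )
        extra_events = tuple(
            sorted(
                base_events + (ScreeningEvent(55, Modality.MAMMOGRAPHY),),
                key=lambda e: e.age,
            )
        )
        disease = toy_disease([1, 0, 0, 0, 0])
        results = []
        for events in (base_events, extra_events):
            strat = Strategy(
                kind=StrategyKind.SCREEN,
                schedule=ScreeningSchedule(events=events, tier=Tier.SUB_NICE),
                prevention=None,
            )
            trace = run_cohort(
                strat, profile, disease, config, flat_table(30, 80, 0.001)
            )
            results.append(
                summarize(trace, paper_bundle.costs, paper_bundle.utilities)
            )
        assert results[1].discounted_cost > results[0].discounted_cost
        assert results[1].discounted_qaly < results[0].discounted_qaly
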