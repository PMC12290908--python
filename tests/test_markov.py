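"""Cohort engine: conservation, oracle equivalence, dose-response."""

import numpy as np
import pytest

from rrmcea import (
    ContextParams,
    DiseaseHistoryParams,
    ModelConfig,
    PathologyMix,
    RiskProfile,
    ScreeningPerformance,
    StageDistribution,
    Strategy,
    StrategyKind,
    apply_strategy_modifiers,
    cumulative_lifetime_risk,
    make_strategies,
    run_cohort,
    stage_distribution_at,
    screening_schedule,
)
from rrmcea.disease import N_STAGES, SURVIVOR_CUTOFF

from .conftest import flat_table
from .oracle import enumerate_occupancy


def toy_disease(stage_probs, death_map=None, drec_map=None, rec_death=0.0):
    """All three contexts identical, from sparse (stage, year) -> prob maps."""
    death = np.zeros((N_STAGES, SURVIVOR_CUTOFF))
    drec = np.zeros((N_STAGES, SURVIVOR_CUTOFF))
    for (s, y), p in (death_map or {}).items():
        death[s, y - 1] = p
    for (s, y), p in (drec_map or {}).items():
        drec[s, y - 1] = p
    ctx = ContextParams(
        stage_distribution=StageDistribution(np.asarray(stage_probs, float)),
        bc_death=death,
        distant_recurrence=drec,
        local_recurrence=np.zeros((N_STAGES, SURVIVOR_CUTOFF)),
    )
    return DiseaseHistoryParams(
        screened=ctx,
        general=ctx,
        post_rrm=ctx,
        pathology_screened=PathologyMix(0.5, 0.5, 0.5, 0.5),
        pathology_general=PathologyMix(0.5, 0.5, 0.5, 0.5),
        screening_performance=ScreeningPerformance(0.0, 0.0, 0.0, 0.0),
        recurrence_death=rec_death,
    )


def toy_profile(start, horizon, inc_value):
    table = flat_table(start, horizon, inc_value)
    return RiskProfile(
        lifetime_risk_target=0.5,
        baseline_lifetime_risk=0.5,
        hazard_ratio=1.0,
        scaled_incidence=table,
    )


def natural_history_strategy():
    # surgery with no effect: pure natural history via one context
    return Strategy(kind=StrategyKind.RRM, rrm_age=60, rrm_hazard_ratio=1.0)


class TestTrivialCohorts:
    def test_no_disease_no_death_everyone_healthy(self, paper_bundle):
        config = ModelConfig(start_age=30)
        profile = toy_profile(30, 80, 0.0)
        trace = run_cohort(
            Strategy(kind=StrategyKind.RRM, rrm_age=30, rrm_hazard_ratio=1.0),
            profile,
            toy_disease([1, 0, 0, 0, 0]),
            config,
            flat_table(30, 80, 0.0),
        )
        assert np.all(trace.healthy == 1.0)
        assert trace.alive()[:-1].sum() == pytest.approx(50.0)

    def test_perfect_surgery_eliminates_cancer(self, paper_bundle):
        config = ModelConfig(start_age=30)
        profile = RiskProfile.from_target(0.50, paper_bundle.incidence)
        trace = run_cohort(
            Strategy(kind=StrategyKind.RRM, rrm_age=30, rrm_hazard_ratio=0.0),
            profile,
            paper_bundle.disease,
            config,
            paper_bundle.mortality,
        )
        assert trace.cumulative_bc_incidence == 0.0
        assert trace.cumulative_bc_death == 0.0


class TestTwoCycleToy:
    def test_hand_enumerated_occupancy(self):
        """Incidence 0.1, no mortality, all mass to stage 1, first-year
        death probability 0.2: after two cycles HEALTHY is 0.81, the
        year-1 tunnel holds the 0.09 newly diagnosed, and 0.018 of them
        die in the following cycle."""
        config = ModelConfig(start_age=60, horizon_age=63)
        profile = toy_profile(60, 63, 0.1)
        disease = toy_disease([0, 1, 0, 0, 0], death_map={(1, 1): 0.2})
        trace = run_cohort(
            natural_history_strategy(), profile, disease, config,
            flat_table(60, 63, 0.0),
        )
        assert trace.healthy[1] == pytest.approx(0.9, abs=1e-15)
        assert trace.tunnels[1, 0, 1, 0] == pytest.approx(0.1, abs=1e-15)
        assert trace.healthy[2] == pytest.approx(0.81, abs=1e-15)
        assert trace.tunnels[2, 0, 1, 0] == pytest.approx(0.09, abs=1e-15)
        assert trace.tunnels[2, 0, 1, 1] == pytest.approx(0.08, abs=1e-15)
        assert trace.dead_bc[2] == pytest.approx(0.02, abs=1e-15)
        # the 0.09 year-1 cohort loses 20% in the next cycle
        assert trace.bc_deaths_stage[2, 0, 1] == pytest.approx(
            0.09 * 0.2 + 0.08 * 0.0, abs=1e-15
        )


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_three_cycles_match_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        inc = rng.uniform(0.0, 0.3, 3)
        mort = rng.uniform(0.0, 0.3, 3)
        w = rng.uniform(0.1, 1.0, 3)
        stage_probs = [w[0] / w.sum(), w[1] / w.sum(), w[2] / w.sum(), 0.0, 0.0]
        death_map = {(s, y): rng.uniform(0, 0.4) for s in range(3) for y in (1, 2, 3)}
        drec_map = {(s, y): rng.uniform(0, 0.3) for s in range(3) for y in (1, 2, 3)}
        rec_death = rng.uniform(0, 0.5)

        config = ModelConfig(start_age=60, horizon_age=63)
        inc_table = flat_table(60, 63, 0.0).with_values(inc)
        mort_table = flat_table(60, 63, 0.0).with_values(mort)
        profile = RiskProfile(0.5, 0.5, 1.0, inc_table)
        disease = toy_disease(stage_probs, death_map, drec_map, rec_death)
        trace = run_cohort(
            natural_history_strategy(), profile, disease, config, mort_table
        )

        occ = enumerate_occupancy(
            3, list(inc), list(mort), stage_probs, death_map, drec_map, rec_death
        )
        for t in range(4):
            assert trace.healthy[t] == pytest.approx(occ[t][("H",)], abs=1e-12)
            for s in range(3):
                for y in (1, 2, 3):
                    assert trace.tunnels[t, 0, s, y - 1] == pytest.approx(
                        occ[t][("T", s, y)], abs=1e-12
                    )
            assert trace.recurrence[t] == pytest.approx(occ[t][("R",)], abs=1e-12)
            assert trace.dead_bc[t] == pytest.approx(occ[t][("DB",)], abs=1e-12)
            assert trace.dead_other[t] == pytest.approx(occ[t][("DO",)], abs=1e-12)


class TestConservationAndIdentities:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("risk,age", [(0.20, 30), (0.45, 40), (0.34, 55)])
    def test_occupancy_sums_to_one(self, random_bundle_factory, seed, risk, age):
        from rrmcea import evaluate_scenario

        bundle = random_bundle_factory(seed)
        from dataclasses import replace

        config = replace(bundle.config, start_age=age)
        profile = RiskProfile.from_target(
            risk, bundle.incidence, bundle.baseline_lifetime_risk
        )
        rrm, screen = make_strategies(profile, age)
        for strat in (rrm, screen):
            trace = run_cohort(strat, profile, bundle.disease, config, bundle.mortality)
            assert np.max(np.abs(trace.total_occupancy() - 1.0)) < 1e-12

    def test_no_intervention_matches_life_table(self, paper_bundle):
        """With routine screening only and zero prevention uptake the
        cohort's cumulative diagnoses equal the life-table risk of the
        scaled incidence over the same window."""
        profile = RiskProfile.from_target(0.15, paper_bundle.incidence)
        _, screen = make_strategies(
            profile, 30, prevention_overrides=None
        )
        assert screen.prevention is None  # below the 17% tier
        config = ModelConfig(start_age=30)
        trace = run_cohort(
            screen, profile, paper_bundle.disease, config, paper_bundle.mortality
        )
        expected = cumulative_lifetime_risk(
            profile.scaled_incidence, paper_bundle.mortality, 30, 80
        )
        assert trace.cumulative_bc_incidence == pytest.approx(expected, abs=1e-9)


class TestStageDistributionAt:
    def test_inside_window_uses_screened_context(self, paper_bundle):
        sched = screening_schedule(0.25)
        d = stage_distribution_at(45, sched, paper_bundle.disease)
        assert d == paper_bundle.disease.screened.stage_distribution

    def test_outside_window_uses_general_population(self, paper_bundle):
        sched = screening_schedule(0.25)
        d = stage_distribution_at(35, sched, paper_bundle.disease)
        assert d == paper_bundle.disease.general.stage_distribution

    def test_equal_contexts_age_independent(self):
        disease = toy_disease([0.2, 0.2, 0.2, 0.2, 0.2])
        sched = screening_schedule(0.25)
        assert stage_distribution_at(35, sched, disease) == stage_distribution_at(
            45, sched, disease
        )


class TestStrategyModifiers:
    def test_rrm_scales_incidence_from_surgery_age(self, paper_bundle):
        inc = paper_bundle.incidence
        strat = Strategy(kind=StrategyKind.RRM, rrm_age=40, rrm_hazard_ratio=0.09)
        out = apply_strategy_modifiers(inc, strat, ModelConfig(start_age=30))
        before = inc.ages < 40
        assert np.allclose(out.values[before], inc.values[before])
        assert np.allclose(out.values[~before], 0.09 * inc.values[~before])

    def test_null_prevention_effect(self, paper_bundle):
        profile = RiskProfile.from_target(0.25, paper_bundle.incidence)
        _, screen = make_strategies(
            profile, 30, prevention_overrides=dict(hr_tamoxifen=1.0, hr_anastrozole=1.0)
        )
        out = apply_strategy_modifiers(
            paper_bundle.incidence, screen, ModelConfig(start_age=30)
        )
        assert np.allclose(out.values, paper_bundle.incidence.values)

    def test_full_uptake_halves_incidence_only_in_window(self, paper_bundle):
        profile = RiskProfile.from_target(0.25, paper_bundle.incidence)
        _, screen = make_strategies(
            profile,
            30,
            prevention_overrides=dict(
                uptake=1.0, hr_tamoxifen=0.5, hr_anastrozole=0.5, carryover_years=0
            ),
        )
        cfg = ModelConfig(start_age=30)
        out = apply_strategy_modifiers(paper_bundle.incidence, screen, cfg)
        window = (paper_bundle.incidence.ages >= 40) & (
            paper_bundle.incidence.ages < 45
        )
        assert np.allclose(out.values[window], 0.5 * paper_bundle.incidence.values[window])
        assert np.allclose(out.values[~window], paper_bundle.incidence.values[~window])

    def test_zero_uptake_matches_no_prevention_downstream(self, paper_bundle):
        profile = RiskProfile.from_target(0.25, paper_bundle.incidence)
        _, screen0 = make_strategies(
            profile, 30, prevention_overrides=dict(uptake=1e-9)
        )
        cfg = ModelConfig(start_age=30)
        base = run_cohort(
            Strategy(
                kind=StrategyKind.SCREEN,
                schedule=screen0.schedule,
                prevention=None,
                rrm_hazard_ratio=0.09,
            ),
            profile,
            paper_bundle.disease,
            cfg,
            paper_bundle.mortality,
        )
        treated = run_cohort(
            screen0, profile, paper_bundle.disease, cfg, paper_bundle.mortality
        )
        assert treated.cumulative_bc_incidence == pytest.approx(
            base.cumulative_bc_incidence, abs=1e-8
        )


class TestDoseResponse:
    def test_cumulative_incidence_monotone_in_hazard_ratio(self, paper_bundle):
        cfg = ModelConfig(start_age=30)
        incid = []
        for target in (0.20, 0.30, 0.40, 0.50):
            profile = RiskProfile.from_target(target, paper_bundle.incidence)
            _, screen = make_strategies(profile, 30)
            trace = run_cohort(
                screen, profile, paper_bundle.disease, cfg, paper_bundle.mortality
            )
            incid.append(trace.cumulative_bc_incidence)
        assert all(b > a for a, b in zip(incid, incid[1:]))

    def test_monotone_in_rrm_effect(self, paper_bundle):
        cfg = ModelConfig(start_age=30)
        profile = RiskProfile.from_target(0.34, paper_bundle.incidence)
        incid = []
        for hr in (0.0, 0.09, 0.38, 1.0):
            trace = run_cohort(
                Strategy(kind=StrategyKind.RRM, rrm_age=30, rrm_hazard_ratio=hr),
                profile,
                paper_bundle.disease,
                cfg,
                paper_bundle.mortality,
            )
            incid.append(trace.cumulative_bc_incidence)
        assert all(b > a for a, b in zip(incid, incid[1:]))

    def test_prevention_uptake_and_hr_reduce_incidence(self, paper_bundle):
        cfg = ModelConfig(start_age=30)
        profile = RiskProfile.from_target(0.34, paper_bundle.incidence)

        def incidence_for(**ov):
            _, screen = make_strategies(profile, 30, prevention_overrides=ov)
            trace = run_cohort(
                screen, profile, paper_bundle.disease, cfg, paper_bundle.mortality
            )
            return trace.cumulative_bc_incidence

        by_uptake = [incidence_for(uptake=u) for u in (1e-12, 0.163, 0.5, 1.0)]
        assert all(b < a for a, b in zip(by_uptake, by_uptake[1:]))
        by_hr = [
            incidence_for(uptake=0.5, hr_tamoxifen=h, hr_anastrozole=h)
            for h in (1.0, 0.7, 0.4, 0.1)
        ]
        assert all(b < a for a, b in zip(by_hr, by_hr[1:]))
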