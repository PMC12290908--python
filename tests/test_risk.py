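"""Lifetime-risk arithmetic: life table, hazard ratio, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrmcea import (
    BASELINE_LIFETIME_RISK,
    CalibrationError,
    DomainError,
    RiskProfile,
    TableCoverageError,
    calibrate_baseline,
    cumulative_lifetime_risk,
    hazard_ratio_for_risk,
    scale_incidence,
)
from rrmcea.tables import AgeRateTable

from .conftest import flat_table


class TestCumulativeLifetimeRisk:
    def test_closed_form_without_competing_mortality(self):
        # constant incidence p over n years, no deaths: 1 - (1-p)^n
        inc = flat_table(20, 80, 0.01)
        mort = flat_table(20, 80, 0.0)
        got = cumulative_lifetime_risk(inc, mort, 20, 80)
        assert got == pytest.approx(1 - 0.99**60, abs=1e-12)

    def test_zero_incidence_gives_zero(self):
        assert cumulative_lifetime_risk(
            flat_table(20, 80, 0.0), flat_table(20, 80, 0.02), 20, 80
        ) == 0.0

    def test_two_cycle_hand_enumeration(self):
        # year 1: 0.1 diagnosed; survivors 0.9*0.5 face 0.1 -> 0.145 total
        inc = flat_table(60, 62, 0.1)
        mort = flat_table(60, 62, 0.5)
        assert cumulative_lifetime_risk(inc, mort, 60, 62) == pytest.approx(
            0.145, abs=1e-15
        )

    def test_missing_ages_raise_coverage_error(self):
        inc = flat_table(30, 50, 0.01)
        with pytest.raises(TableCoverageError):
            cumulative_lifetime_risk(inc, flat_table(20, 80, 0.0), 20, 80)

    def test_degenerate_window_rejected(self):
        inc = flat_table(20, 80, 0.01)
        with pytest.raises(DomainError):
            cumulative_lifetime_risk(inc, inc, 50, 50)

    @pytest.mark.parametrize("bump_age", [25, 45, 70])
    def test_monotone_in_incidence_and_mortality(self, bump_age):
        rng = np.random.default_rng(7)
        inc_v = rng.uniform(0.0, 0.02, 60)
        mort_v = rng.uniform(0.0, 0.05, 60)
        inc = AgeRateTable(np.arange(20, 80), inc_v)
        mort = AgeRateTable(np.arange(20, 80), mort_v)
        base = cumulative_lifetime_risk(inc, mort, 20, 80)
        i = bump_age - 20
        inc_up = inc.with_values(inc_v + np.eye(60)[i] * 0.01)
        mort_up = mort.with_values(mort_v + np.eye(60)[i] * 0.01)
        assert cumulative_lifetime_risk(inc_up, mort, 20, 80) >= base
        assert cumulative_lifetime_risk(inc, mort_up, 20, 80) <= base


class TestHazardRatio:
    @pytest.mark.parametrize(
        "target,expected",
        [(0.25, 2.52), (0.50, 6.07), (0.35, 3.77)],
    )
    def test_printed_values_against_uk_baseline(self, target, expected):
        assert round(hazard_ratio_for_risk(target, 0.1079), 2) == expected

    @given(st.floats(min_value=0.01, max_value=0.99))
    @settings(derandomize=True, max_examples=30)
    def test_identity_at_equal_risks(self, x):
        assert hazard_ratio_for_risk(x, x) == pytest.approx(1.0, abs=1e-12)

    @given(
        st.floats(min_value=0.02, max_value=0.9),
        st.floats(min_value=0.02, max_value=0.9),
    )
    @settings(derandomize=True, max_examples=50)
    def test_reciprocal_identity(self, a, b):
        assert hazard_ratio_for_risk(a, b) * hazard_ratio_for_risk(b, a) == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_strictly_increasing_in_target(self):
        hrs = [hazard_ratio_for_risk(t, 0.1079) for t in np.linspace(0.05, 0.9, 40)]
        assert all(b > a for a, b in zip(hrs, hrs[1:]))

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            hazard_ratio_for_risk(bad, 0.1079)
        with pytest.raises(DomainError):
            hazard_ratio_for_risk(0.25, bad)


class TestScaleIncidence:
    def test_unit_ratio_is_identity(self):
        t = flat_table(20, 80, 0.01)
        assert scale_incidence(t, 1.0) == t

    def test_direct_multiplication(self):
        t = flat_table(20, 80, 0.01)
        assert scale_incidence(t, 2.52).values[0] == pytest.approx(0.0252)

    def test_clamp_at_one_with_warning(self, caplog):
        t = flat_table(20, 80, 0.6)
        with caplog.at_level("WARNING"):
            out = scale_incidence(t, 2.0)
        assert np.all(out.values == 1.0)
        assert any("clamp" in r.message for r in caplog.records)

    def test_negative_ratio_rejected(self):
        with pytest.raises(DomainError):
            scale_incidence(flat_table(20, 80, 0.01), -1.0)


class TestCalibrateBaseline:
    def test_already_on_target_keeps_multiplier_one(self):
        mort = flat_table(20, 80, 0.0)
        p = 1 - (1 - 0.1079) ** (1 / 60)  # exact constant-p solution
        shape = flat_table(20, 80, p)
        out = calibrate_baseline(shape, mort, 0.1079)
        assert out.values == pytest.approx(shape.values, rel=1e-9)

    def test_closed_form_inversion_constant_shape(self):
        # m solves 1-(1-m p)^n = t with zero mortality
        p, n, t = 0.005, 60, 0.2
        shape = flat_table(20, 80, p)
        out = calibrate_baseline(shape, flat_table(20, 80, 0.0), t)
        m_expected = (1 - (1 - t) ** (1 / n)) / p
        assert out.values[0] / p == pytest.approx(m_expected, rel=1e-10)

    def test_postcondition_recovers_target(self, paper_bundle):
        got = cumulative_lifetime_risk(
            paper_bundle.incidence, paper_bundle.mortality, 20, 80
        )
        assert got == pytest.approx(BASELINE_LIFETIME_RISK, abs=1e-10)

    def test_unreachable_target_raises(self):
        # incidence possible only at 79 behind heavy competing mortality:
        # even with the annual probability clamped at 1 the lifetime risk
        # saturates at (1-q)^59 << target
        values = np.zeros(60)
        values[-1] = 0.5
        shape = AgeRateTable(np.arange(20, 80), values)
        with pytest.raises(CalibrationError):
            calibrate_baseline(shape, flat_table(20, 80, 0.1), 0.5)


class TestRoundTrip:
    @pytest.mark.parametrize("target", [0.17, 0.25, 0.34, 0.45, 0.50])
    def test_probability_scaling_approximates_target_risk(self, paper_bundle, target):
        """Scaling annual probabilities by the HR recovers the target
        lifetime risk within 5% relative error (probability-scaling
        approximates hazard-scaling)."""
        profile = RiskProfile.from_target(target, paper_bundle.incidence)
        got = cumulative_lifetime_risk(
            profile.scaled_incidence, paper_bundle.mortality, 20, 80
        )
        assert got == pytest.approx(target, rel=0.05)

    def test_profile_invariants(self, paper_bundle):
        p = RiskProfile.from_target(0.34, paper_bundle.incidence)
        assert p.hazard_ratio > 1
        assert np.all(p.scaled_incidence.values <= 1.0)
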