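"""Scenario runs, age standardization, and decomposition arithmetic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cvdpm.exceptions import ValidationError
from cvdpm.profiles import SEXES, Sex
from cvdpm.scenarios import (
    OUTCOMES,
    S_HIGH,
    S_IDEAL,
    S_LOW,
    S_M1,
    age_standardize,
    decompose_gap,
    decompose_low_ses,
    run_analysis,
    run_scenario,
    single_factor_reduction,
    standard_weights,
)
from cvdpm.synthetic import SyntheticConfig, generate_calibration


@pytest.fixture(scope="module")
def analysis(bundle):
    return run_analysis(bundle)


class TestAgeStandardize:
    def test_constant_rates_any_weights(self):
        py = np.array([100.0, 200.0, 400.0])
        events = 0.002 * py
        w = np.array([0.2, 0.3, 0.5])
        assert age_standardize(events, py, w) == pytest.approx(20.0, rel=1e-12)

    def test_two_band_hand_arithmetic(self):
        """Band rates 10 and 30 per 10,000 at equal weights average to 20."""
        py = np.array([1e4, 1e4])
        events = np.array([10.0, 30.0])
        assert age_standardize(events, py, np.array([0.5, 0.5])) == pytest.approx(20.0)

    def test_degenerate_weights_pick_one_band(self):
        py = np.array([1e4, 1e4])
        events = np.array([10.0, 30.0])
        assert age_standardize(events, py, np.array([1.0, 0.0])) == pytest.approx(10.0)

    def test_all_zero_person_years_error(self):
        with pytest.raises(ValidationError):
            age_standardize(np.zeros(2), np.zeros(2), np.array([0.5, 0.5]))

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValidationError):
            age_standardize(np.ones(2), np.ones(2), np.array([0.5, 0.6]))


class TestDecomposeGap:
    def test_reported_men_incident_chd_row(self):
        """(80.8, 42.9, 51.8): overall 37.9, RR 1.88, split 8.9 / 29.0 = 23.5% / 76.5%."""
        d = decompose_gap(80.8, 42.9, 51.8)
        assert d.overall_excess == pytest.approx(37.9, abs=1e-9)
        assert round(d.rr_low_vs_high, 2) == 1.88
        assert d.rf_excess == pytest.approx(8.9, abs=1e-9)
        assert d.ses_excess == pytest.approx(29.0, abs=1e-9)
        assert round(d.pct_rf, 1) == 23.5
        assert round(d.pct_ses, 1) == 76.5

    def test_reported_women_incident_chd_row(self):
        d = decompose_gap(39.0, 18.6, 25.0)
        assert d.overall_excess == pytest.approx(20.4, abs=1e-9)
        assert round(d.rr_low_vs_high, 2) == 2.10
        assert d.rf_excess == pytest.approx(6.4, abs=1e-9)
        assert d.ses_excess == pytest.approx(14.0, abs=1e-9)
        assert round(d.pct_rf, 1) == 31.4

    def test_degenerate_equal_rates_flagged(self):
        d = decompose_gap(5.0, 5.0, 5.0)
        assert d.overall_excess == 0.0
        assert np.isnan(d.pct_rf) and np.isnan(d.pct_ses)
        assert "zero_overall_excess" in d.flags

    def test_zero_comparator_flags_rr(self):
        d = decompose_gap(5.0, 0.0, 3.0)
        assert np.isnan(d.rr_low_vs_high)
        assert "rr_undefined" in d.flags

    @given(
        r_low=st.floats(min_value=0, max_value=500),
        r_high=st.floats(min_value=0, max_value=500),
        r_m1=st.floats(min_value=0, max_value=500),
    )
    def test_exact_additivity_property(self, r_low, r_high, r_m1):
        d = decompose_gap(r_low, r_high, r_m1)
        assert d.rf_excess + d.ses_excess == d.overall_excess  # exact
        if abs(d.overall_excess) > 1e-6:
            assert d.pct_rf + d.pct_ses == pytest.approx(100.0, abs=1e-9)


class TestDecomposeLowSes:
    def test_three_component_split(self):
        b = decompose_low_ses(80.8, 51.8, 20.0)
        assert b.ses_component == pytest.approx(29.0, abs=1e-9)
        assert b.management_component == pytest.approx(31.8, abs=1e-9)
        assert b.unmodifiable == 20.0

    def test_degenerate_equal_rates(self):
        b = decompose_low_ses(7.0, 7.0, 7.0)
        assert (b.ses_component, b.management_component, b.unmodifiable) == (0.0, 0.0, 7.0)

    def test_ordering_violation_flagged_not_raised(self):
        b = decompose_low_ses(1.0, 2.0, 0.5)
        assert "ordering_violation" in b.flags

    @given(
        r_low=st.floats(min_value=0, max_value=500),
        f1=st.floats(min_value=0, max_value=1),
        f2=st.floats(min_value=0, max_value=1),
    )
    def test_components_telescope_to_total(self, r_low, f1, f2):
        r_m1 = r_low * f1
        r_ideal = r_m1 * f2
        b = decompose_low_ses(r_low, r_m1, r_ideal)
        total = b.ses_component + b.management_component + b.unmodifiable
        assert total == pytest.approx(r_low, rel=1e-12, abs=1e-12)


class TestScenarioRuns:
    def test_ses_rr_monotonicity(self, analysis):
        for sex in SEXES:
            for outcome in OUTCOMES:
                assert (
                    analysis.rates[("low", sex, outcome)]
                    >= analysis.rates[("m1", sex, outcome)]
                )

    def test_ideal_control_lowers_rates(self, analysis):
        for sex in SEXES:
            assert (
                analysis.rates[("ideal", sex, "incident_chd")]
                < analysis.rates[("m1", sex, "incident_chd")]
            )

    def test_first_cycle_rate_ratio_equals_rr(self, bundle):
        """One-cycle incident-CHD ratio, SES flag on vs off, equals 1.58 exactly."""
        tables = {
            enabled: run_scenario(
                S_LOW if enabled else S_M1, bundle, years=range(2015, 2016)
            )
            for enabled in (True, False)
        }
        for sex in SEXES:
            on = tables[True].events[(sex, "incident_chd")].sum()
            off = tables[False].events[(sex, "incident_chd")].sum()
            assert on / off == pytest.approx(bundle.ses_spec.rr, rel=1e-12)

    def test_scale_invariance_of_standardized_rates(self, bundle, analysis):
        big = generate_calibration(
            SyntheticConfig(seed=bundle.config.seed, population_size=10 * bundle.config.population_size)
        )
        res = run_analysis(big)
        for key, rate in analysis.rates.items():
            assert res.rates[key] == pytest.approx(rate, rel=1e-9)

    def test_gap_decomposition_consistent_with_rates(self, analysis):
        for sex in SEXES:
            d = analysis.gap[(sex, "incident_chd")]
            assert d.rf_excess + d.ses_excess == d.overall_excess
            assert d.overall_excess == pytest.approx(
                analysis.rates[("low", sex, "incident_chd")]
                - analysis.rates[("high", sex, "incident_chd")],
                rel=1e-12,
            )

    def test_fixed_weights_are_required_for_additivity(self, bundle):
        """Per-scenario weights break the decomposition identity; fixed ones keep it."""
        tables = {
            name: run_scenario(spec, bundle)
            for name, spec in (("low", S_LOW), ("high", S_HIGH), ("m1", S_M1))
        }
        w_fixed = standard_weights(tables["high"])
        sex = Sex.MALE
        fixed = {
            n: t.standardized_rate(sex, "incident_chd", w_fixed[sex])
            for n, t in tables.items()
        }
        d = decompose_gap(fixed["low"], fixed["high"], fixed["m1"])
        assert d.rf_excess + d.ses_excess == d.overall_excess
        # own-weights rates differ from fixed-weight ones (so mixing them
        # would not telescope)
        own = tables["low"].standardized_rate(
            sex, "incident_chd", standard_weights(tables["low"])[sex]
        )
        assert own != pytest.approx(fixed["low"], rel=1e-9)


class TestSingleFactor:
    def test_ses_independent_reduction_matches_gap_component(self, bundle, analysis):
        red = single_factor_reduction(S_LOW, "ses_independent", bundle)
        for sex in SEXES:
            assert red[sex] == pytest.approx(
                analysis.gap[(sex, "incident_chd")].ses_excess, rel=1e-9
            )

    def test_already_ideal_factor_reduces_nothing(self, bundle):
        base = S_IDEAL
        red = single_factor_reduction(base, "smoking", bundle)
        for sex in SEXES:
            assert red[sex] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_factor_rejected(self, bundle):
        with pytest.raises(ValidationError):
            single_factor_reduction(S_LOW, "stress", bundle)

    def test_reductions_subadditive_vs_full_idealization(self, bundle):
        """Single-factor gains sum to more than the joint all-factor gain."""
        weights = standard_weights(run_scenario(S_HIGH, bundle))
        sex = Sex.MALE
        singles = sum(
            single_factor_reduction(S_M1, f, bundle, sex=sex, weights=weights)[sex]
            for f in ("sbp", "ldl", "smoking", "diabetes", "bmi", "hdl")
        )
        t_m1 = run_scenario(S_M1, bundle)
        t_ideal = run_scenario(S_IDEAL, bundle)
        joint_gain = t_m1.standardized_rate(sex, "incident_chd", weights[sex]) - \
            t_ideal.standardized_rate(sex, "incident_chd", weights[sex])
        assert singles >= joint_gain
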