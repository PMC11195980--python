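"""Synthetic calibration generator: discretization, joints, hazards, fixtures."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cvdpm.exceptions import ValidationError
from cvdpm.fixtures import bundles_equal, read_fixtures, write_fixtures
from cvdpm.profiles import FACTORS, SEXES, Sex, factor_level_masks
from cvdpm.risk import CAUSES
from cvdpm.synthetic import (
    DEFAULT_MARGINALS,
    HIGH,
    LOW,
    SES_STRATA,
    SyntheticConfig,
    build_joint_distribution,
    discretize_normal,
    factor_level_probabilities,
    generate_calibration,
)


class TestDiscretizeNormal:
    def test_sbp_upper_stratum_closed_form(self):
        """Low-SES men SBP 137.5 (17.0): P(>=140) = 1 - Phi(2.5/17)."""
        p = discretize_normal(137.5, 17.0, (130.0, 140.0))
        assert p[2] == pytest.approx(1 - stats.norm.cdf(2.5 / 17.0), rel=1e-12)
        assert p[2] == pytest.approx(0.44154, abs=5e-5)

    def test_symmetry(self):
        p = discretize_normal(0.0, 1.0, (0.0,))
        assert p == pytest.approx([0.5, 0.5], abs=1e-15)

    def test_non_ascending_cutpoints_rejected(self):
        with pytest.raises(ValidationError):
            discretize_normal(0, 1, (1.0, 1.0))
        with pytest.raises(ValidationError):
            discretize_normal(0, -1, (0.0,))

    @given(
        mean=st.floats(min_value=-100, max_value=300),
        sd=st.floats(min_value=0.1, max_value=80),
        cuts=st.lists(
            st.floats(min_value=-50, max_value=250), min_size=1, max_size=4, unique=True
        ),
    )
    def test_probabilities_sum_to_one(self, mean, sd, cuts):
        p = discretize_normal(mean, sd, sorted(cuts))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)


class TestJointDistribution:
    @pytest.mark.parametrize("sex", SEXES)
    @pytest.mark.parametrize("ses", SES_STRATA)
    def test_marginal_recovery_exact_under_independence(self, sex, ses):
        m = DEFAULT_MARGINALS[(sex, ses)]
        joint = build_joint_distribution(m)
        assert joint.sum() == pytest.approx(1.0, abs=1e-9)
        target = factor_level_probabilities(m)
        for factor in FACTORS:
            masks = factor_level_masks(factor)
            recovered = np.array([joint[mk].sum() for mk in masks])
            np.testing.assert_allclose(recovered, target[factor], atol=1e-9)

    def test_survey_smoking_marginal(self):
        joint = build_joint_distribution(DEFAULT_MARGINALS[(Sex.MALE, LOW)])
        active = factor_level_masks("smoking")[2]
        assert joint[active].sum() == pytest.approx(0.317, abs=1e-12)

    def test_degenerate_marginals_single_profile(self):
        import dataclasses

        m = dataclasses.replace(
            DEFAULT_MARGINALS[(Sex.MALE, LOW)],
            smoking_active=0.0, smoking_secondhand=0.0, diabetes=0.0,
            sbp_mean=100.0, sbp_sd=1e-9 + 0.001, bmi_mean=20.0, bmi_sd=0.001,
            ldl_mean=50.0, ldl_sd=0.001, hdl_mean=20.0, hdl_sd=0.001,
        )
        joint = build_joint_distribution(m)
        assert joint.max() == pytest.approx(1.0, abs=1e-9)
        assert (joint > 1e-12).sum() == 1

    def test_copula_correlation_shifts_joint_mass(self):
        """Positive SBP-BMI latent correlation raises P(both in top stratum)."""
        m = DEFAULT_MARGINALS[(Sex.MALE, LOW)]
        corr = np.eye(6)
        i, j = FACTORS.index("sbp"), FACTORS.index("bmi")
        corr[i, j] = corr[j, i] = 0.6
        rng = np.random.default_rng(0)
        dep = build_joint_distribution(
            m, dependence="gaussian_copula", correlation=corr, rng=rng,
            copula_samples=100_000,
        )
        indep = build_joint_distribution(m)
        both_top = factor_level_masks("sbp")[2] & factor_level_masks("bmi")[2]
        assert dep[both_top].sum() > indep[both_top].sum()


class TestGenerateCalibration:
    def test_deterministic_given_seed(self):
        a = generate_calibration(SyntheticConfig(seed=11, population_size=1000))
        b = generate_calibration(SyntheticConfig(seed=11, population_size=1000))
        assert bundles_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_calibration(SyntheticConfig(seed=11, population_size=1000))
        b = generate_calibration(SyntheticConfig(seed=12, population_size=1000))
        assert not bundles_equal(a, b)

    def test_hazards_increase_with_age(self, bundle):
        for cause in ("incident_chd", "incident_stroke", "noncvd_death"):
            base = np.exp(bundle.risk_function.baseline_log_hazard[cause])
            assert np.all(np.diff(base, axis=0) > 0)
            assert base[-1, 0] > base[0, 0]

    def test_male_chd_hazard_at_least_female(self, bundle):
        base = np.exp(bundle.risk_function.baseline_log_hazard["incident_chd"])
        assert np.all(base[:, 0] >= base[:, 1])

    def test_one_year_probabilities_below_half(self, bundle):
        for cause in CAUSES:
            h = bundle.risk_function.hazard_grid(cause)
            p = -np.expm1(-h)
            if cause in bundle.ses_spec.applies_to:
                p = np.minimum(1.0, p * bundle.ses_spec.rr)
            assert p.max() < 0.5

    def test_lipids_identical_across_ses(self, bundle):
        for sex in SEXES:
            lo, hi = bundle.marginals[(sex, LOW)], bundle.marginals[(sex, HIGH)]
            assert (lo.ldl_mean, lo.ldl_sd, lo.hdl_mean, lo.hdl_sd) == (
                hi.ldl_mean, hi.ldl_sd, hi.hdl_mean, hi.hdl_sd
            )

    def test_population_split_matches_config(self, config, bundle):
        totals = {
            ses: bundle.demographics[ses].initial_counts.sum() for ses in SES_STRATA
        }
        assert totals[LOW] / (totals[LOW] + totals[HIGH]) == pytest.approx(
            config.low_ses_share
        )
        low = bundle.demographics[LOW].initial_counts
        assert low[:, 1].sum() / low.sum() == pytest.approx(config.female_share_low)


class TestFixtures:
    def test_round_trip_lossless(self, bundle, tmp_path):
        write_fixtures(bundle, tmp_path)
        again = read_fixtures(tmp_path)
        assert bundles_equal(bundle, again)

    def test_missing_directory_errors_with_path(self, bundle, tmp_path):
        with pytest.raises(ValidationError, match="no/such/place"):
            write_fixtures(bundle, tmp_path / "no" / "such" / "place")

    def test_files_byte_identical_for_fixed_seed(self, tmp_path):
        cfg = SyntheticConfig(seed=3, population_size=500)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        d1.mkdir(), d2.mkdir()
        f1 = write_fixtures(generate_calibration(cfg), d1)
        f2 = write_fixtures(generate_calibration(cfg), d2)
        for p1, p2 in zip(sorted(f1), sorted(f2)):
            assert p1.read_bytes() == p2.read_bytes()
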