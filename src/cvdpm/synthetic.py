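"""Synthetic calibration inputs for the full pipeline.

The original model is calibrated from national survey microdata, census
projections, and Framingham-derived Cox coefficients, none of which are
distributable.  This module generates a complete stand-in calibration
bundle so the whole analysis runs self-contained:

* joint risk-cell distributions per (sex, SES stratum) built from published
  survey marginals (continuous factors modeled normal with the published
  mean/SD and discretized at the model's stratum cutpoints);
* smooth, age-increasing synthetic baseline hazards with male excess for
  CHD;
* synthetic covariate log-hazard-ratios with the qualitative structure of
  Framingham risk equations (positive for smoking, diabetes, higher
  SBP/LDL/BMI strata; protective for high HDL);
* prior-CVD transition rates, acute CHD case fatality, and a flat synthetic
  age structure with constant annual entrants.

Everything is deterministic given the config seed.  Lipid parameters are
identical in the low- and high-SES strata by design (the source survey
showed no SES difference in total cholesterol and publishes no LDL/HDL by
SES).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .exceptions import ValidationError
from .population import AGES, AGE_MIN, N_AGES, Demographics
from .profiles import (
    CUTPOINTS,
    FACTOR_LEVELS,
    FACTORS,
    LEVEL_CODES,
    N_PROFILES,
    SEXES,
    SEX_INDEX,
    Sex,
)
from .risk import CAUSES, RiskFunction, SesRiskSpec

LOW, HIGH = "low", "high"
SES_STRATA = (LOW, HIGH)


@dataclass(frozen=True)
class StratumMarginals:
    """Risk-factor marginals for one (sex, SES) stratum.

    Continuous factors carry mean/SD (SBP mmHg, BMI kg/m², LDL and HDL
    mg/dL); binary/categorical factors carry prevalences.
    """

    smoking_active: float
    smoking_secondhand: float
    sbp_mean: float
    sbp_sd: float
    diabetes: float
    bmi_mean: float
    bmi_sd: float
    ldl_mean: float
    ldl_sd: float
    hdl_mean: float
    hdl_sd: float

    def validate(self) -> None:
        for name in ("smoking_active", "smoking_secondhand", "diabetes"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.smoking_active + self.smoking_secondhand > 1:
            raise ValidationError("smoking categories exceed probability 1")
        for name in ("sbp_sd", "bmi_sd", "ldl_sd", "hdl_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


# Published survey marginals by sex and SES (active smoking %, SBP mean/SD,
# diabetes %, BMI mean/SD).  Secondhand-smoke prevalence and all lipid
# parameters are synthetic defaults: the survey prints neither; lipids are
# identical across SES strata on purpose.
_SECONDHAND = 0.10
_LIPIDS = {
    Sex.MALE: dict(ldl_mean=125.0, ldl_sd=33.0, hdl_mean=45.0, hdl_sd=12.0),
    Sex.FEMALE: dict(ldl_mean=122.0, ldl_sd=32.0, hdl_mean=54.0, hdl_sd=14.0),
}
DEFAULT_MARGINALS: dict[tuple[Sex, str], StratumMarginals] = {
    (Sex.MALE, LOW): StratumMarginals(
        smoking_active=0.317, smoking_secondhand=_SECONDHAND,
        sbp_mean=137.5, sbp_sd=17.0, diabetes=0.157,
        bmi_mean=29.6, bmi_sd=4.3, **_LIPIDS[Sex.MALE],
    ),
    (Sex.MALE, HIGH): StratumMarginals(
        smoking_active=0.238, smoking_secondhand=_SECONDHAND,
        sbp_mean=133.6, sbp_sd=13.4, diabetes=0.132,
        bmi_mean=28.7, bmi_sd=3.5, **_LIPIDS[Sex.MALE],
    ),
    (Sex.FEMALE, LOW): StratumMarginals(
        smoking_active=0.225, smoking_secondhand=_SECONDHAND,
        sbp_mean=130.2, sbp_sd=19.2, diabetes=0.185,
        bmi_mean=29.8, bmi_sd=5.7, **_LIPIDS[Sex.FEMALE],
    ),
    (Sex.FEMALE, HIGH): StratumMarginals(
        smoking_active=0.197, smoking_secondhand=_SECONDHAND,
        sbp_mean=124.8, sbp_sd=16.6, diabetes=0.116,
        bmi_mean=27.7, bmi_sd=5.6, **_LIPIDS[Sex.FEMALE],
    ),
}


class SyntheticConfig(BaseModel):
    """Configuration of the synthetic calibration bundle."""

    model_config = {"extra": "forbid"}

    seed: int = 0
    population_size: float = Field(default=100_000.0, gt=0)
    low_ses_share: float = Field(default=0.56, ge=0, le=1)
    female_share_low: float = Field(default=0.513, ge=0, le=1)
    female_share_high: float = Field(default=0.528, ge=0, le=1)
    dependence: Literal["independent", "gaussian_copula"] = "independent"
    correlation: Optional[list[list[float]]] = None
    copula_samples: int = Field(default=200_000, ge=1000)

    @model_validator(mode="after")
    def _check_correlation(self):
        if self.dependence == "gaussian_copula":
            if self.correlation is None:
                raise ValueError("gaussian_copula dependence requires a correlation matrix")
            r = np.asarray(self.correlation, dtype=float)
            if r.shape != (len(FACTORS), len(FACTORS)):
                raise ValueError(f"correlation must be {len(FACTORS)}x{len(FACTORS)}")
            if not np.allclose(r, r.T):
                raise ValueError("correlation matrix must be symmetric")
            if np.min(np.linalg.eigvalsh(r)) < -1e-10:
                raise ValueError("correlation matrix must be positive semi-definite")
        return self


def discretize_normal(mean: float, sd: float, cutpoints) -> np.ndarray:
    """Probabilities of the strata a normal(mean, sd) induces at the cutpoints.

    Returns ``len(cutpoints) + 1`` probabilities summing to 1 within 1e-12.
    """
    cut = np.asarray(cutpoints, dtype=float)
    if sd <= 0:
        raise ValidationError(f"sd must be positive, got {sd}")
    if cut.ndim != 1 or len(cut) == 0 or np.any(np.diff(cut) <= 0):
        raise ValidationError(f"cutpoints must be strictly ascending, got {cutpoints}")
    cdf = stats.norm.cdf(cut, loc=mean, scale=sd)
    edges = np.concatenate(([0.0], cdf, [1.0]))
    return np.diff(edges)


def factor_level_probabilities(m: StratumMarginals) -> dict[str, np.ndarray]:
    """Per-factor level probabilities implied by one stratum's marginals."""
    m.validate()
    return {
        "sbp": discretize_normal(m.sbp_mean, m.sbp_sd, CUTPOINTS["sbp"]),
        "ldl": discretize_normal(m.ldl_mean, m.ldl_sd, CUTPOINTS["ldl"]),
        "hdl": discretize_normal(m.hdl_mean, m.hdl_sd, CUTPOINTS["hdl"]),
        "smoking": np.array(
            [1.0 - m.smoking_active - m.smoking_secondhand, m.smoking_secondhand, m.smoking_active]
        ),
        "diabetes": np.array([1.0 - m.diabetes, m.diabetes]),
        "bmi": discretize_normal(m.bmi_mean, m.bmi_sd, CUTPOINTS["bmi"]),
    }


def build_joint_distribution(
    marginals: StratumMarginals,
    dependence: str = "independent",
    correlation=None,
    rng: np.random.Generator | None = None,
    copula_samples: int = 200_000,
) -> np.ndarray:
    """Joint probability over the 486 risk profiles from one stratum's marginals.

    Under independence the joint is the outer product of the per-factor level
    probabilities, so every recovered marginal equals its input exactly.
    Under the Gaussian copula, level thresholds are placed at the marginal
    quantiles of latent standard normals and the joint is estimated by Monte
    Carlo over correlated latents (deterministic given ``rng``).
    """
    probs = factor_level_probabilities(marginals)
    if dependence == "independent":
        joint = np.ones(N_PROFILES)
        for col, factor in enumerate(FACTORS):
            joint *= probs[factor][LEVEL_CODES[:, col]]
        return joint
    if dependence != "gaussian_copula":
        raise ValidationError(f"unknown dependence {dependence!r}")
    if correlation is None:
        raise ValidationError("gaussian_copula requires a correlation matrix")
    if rng is None:
        rng = np.random.default_rng(0)
    corr = np.asarray(correlation, dtype=float)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(FACTORS)))
    z = rng.standard_normal((copula_samples, len(FACTORS))) @ chol.T
    codes = np.zeros((copula_samples,), dtype=np.int64)
    stride = 1
    # accumulate a mixed-radix cell index, bmi fastest (canonical order)
    for col in reversed(range(len(FACTORS))):
        p = probs[FACTORS[col]]
        thresholds = stats.norm.ppf(np.cumsum(p)[:-1])
        lvl = np.searchsorted(thresholds, z[:, col], side="left")
        codes += lvl * stride
        stride *= len(p)
    joint = np.bincount(codes, minlength=N_PROFILES).astype(float)
    return joint / joint.sum()


@dataclass
class TransitionRates:
    """Annual prior-CVD transition rates and acute CHD case fatality.

    ``prior[history][event]`` is a (60, 2) hazard array for history in
    {prior_chd, prior_stroke} and event in {recurrent_chd, stroke,
    cvd_death, noncvd_death}; the combined-history compartment uses the
    elementwise maximum of the two.  ``case_fatality`` is the (60, 2)
    fraction of incident CHD events fatal within the cycle.
    """

    prior: dict[str, dict[str, np.ndarray]]
    case_fatality: np.ndarray

    PRIOR_EVENTS = ("recurrent_chd", "stroke", "cvd_death", "noncvd_death")

    def __post_init__(self) -> None:
        for hist in ("prior_chd", "prior_stroke"):
            if hist not in self.prior:
                raise ValidationError(f"missing prior-CVD rates for {hist!r}")
            for ev in self.PRIOR_EVENTS:
                arr = np.asarray(self.prior[hist][ev], dtype=float)
                if arr.shape != (N_AGES, 2) or np.any(arr < 0):
                    raise ValidationError(f"invalid rate array {hist}/{ev}")
                self.prior[hist][ev] = arr
        cf = np.asarray(self.case_fatality, dtype=float)
        if cf.shape != (N_AGES, 2) or np.any((cf < 0) | (cf > 1)):
            raise ValidationError("case_fatality must be (60, 2) fractions in [0, 1]")
        self.case_fatality = cf

    def rates_for(self, history: str) -> dict[str, np.ndarray]:
        if history == "prior_both":
            return {
                ev: np.maximum(self.prior["prior_chd"][ev], self.prior["prior_stroke"][ev])
                for ev in self.PRIOR_EVENTS
            }
        return self.prior[history]


@dataclass
class CalibrationBundle:
    """Everything one analysis run needs, generated or loaded from files."""

    config: SyntheticConfig
    marginals: dict[tuple[Sex, str], StratumMarginals]
    joints: dict[str, np.ndarray]  # ses -> (2, 486)
    risk_function: RiskFunction
    rates: TransitionRates
    demographics: dict[str, Demographics]  # ses -> Demographics
    ses_spec: SesRiskSpec = field(default_factory=SesRiskSpec)

    def joint_for(self, ses: str) -> dict[Sex, np.ndarray]:
        return {sex: self.joints[ses][SEX_INDEX[sex]] for sex in SEXES}


# Synthetic hazard shape parameters: reference-profile hazard at age 35,
# exponential age slope per year, and female/male hazard ratio.
_HAZARD_SHAPES = {
    "incident_chd": dict(h35=0.0012, slope=0.055, female_ratio=0.50),
    "incident_stroke": dict(h35=0.0006, slope=0.060, female_ratio=0.75),
    "diabetes_incidence": dict(h35=0.0030, slope=0.020, female_ratio=0.95),
    "noncvd_death": dict(h35=0.0020, slope=0.073, female_ratio=0.80),
}

# Synthetic covariate log-hazard-ratios per cause: (factor, level) -> beta.
# Signs follow the qualitative Framingham structure; magnitudes are round
# values in the range of published CVD risk equations.
def _betas(sbp2, sbp3, ldl2, ldl3, hdl2, hdl3, smk2, smk3, dm, bmi2, bmi3):
    return {
        ("sbp", "s130to139_9"): sbp2, ("sbp", "ge140"): sbp3,
        ("ldl", "s100to129_9"): ldl2, ("ldl", "ge130"): ldl3,
        ("hdl", "s40to59_9"): hdl2, ("hdl", "ge60"): hdl3,
        ("smoking", "secondhand"): smk2, ("smoking", "active"): smk3,
        ("diabetes", "yes"): dm,
        ("bmi", "s25to29_9"): bmi2, ("bmi", "ge30"): bmi3,
    }


DEFAULT_BETAS: dict[str, dict[tuple[str, str], float]] = {
    "incident_chd": _betas(0.25, 0.50, 0.20, 0.40, -0.20, -0.40, 0.15, 0.60, 0.60, 0.10, 0.25),
    "incident_stroke": _betas(0.35, 0.70, 0.10, 0.20, -0.10, -0.20, 0.10, 0.40, 0.50, 0.10, 0.20),
    "diabetes_incidence": _betas(0.05, 0.10, 0.0, 0.0, 0.0, 0.0, 0.0, 0.10, 0.0, 0.40, 0.80),
    "noncvd_death": _betas(0.0, 0.10, 0.0, 0.0, 0.0, 0.0, 0.10, 0.30, 0.30, 0.0, 0.15),
}


def _default_beta_sd(betas: dict[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    # standard error: 15% of the effect plus a floor, a plausible precision
    # for cohort-study coefficients
    return {k: 0.15 * abs(b) + 0.02 for k, b in betas.items()}


def make_risk_function(rng: np.random.Generator | None = None) -> RiskFunction:
    """Synthetic risk function: smooth age-increasing baselines, default betas.

    A small seeded lognormal jitter on each cause's hazard scale keeps
    distinct seeds distinguishable without touching the age slope or the
    male/female ordering.
    """
    baseline: dict[str, np.ndarray] = {}
    for cause, shape in _HAZARD_SHAPES.items():
        # clipped so no seed can push worst-case one-year probabilities past
        # the 0.5 plausibility guard
        jitter = (
            float(np.exp(np.clip(rng.normal(0.0, 0.05), -0.1, 0.1)))
            if rng is not None
            else 1.0
        )
        h_male = shape["h35"] * jitter * np.exp(shape["slope"] * (AGES - AGE_MIN))
        grid = np.stack([h_male, h_male * shape["female_ratio"]], axis=1)
        baseline[cause] = np.log(grid)
    return RiskFunction(
        baseline_log_hazard=baseline,
        betas={c: dict(b) for c, b in DEFAULT_BETAS.items()},
        beta_sd={"incident_chd": _default_beta_sd(DEFAULT_BETAS["incident_chd"])},
    )


def make_transition_rates() -> TransitionRates:
    g = np.exp(0.030 * (AGES - AGE_MIN))  # shared age gradient
    sex = lambda m, ratio: np.stack([m, m * ratio], axis=1)
    prior = {
        "prior_chd": {
            "recurrent_chd": sex(0.025 * g, 0.7),
            "stroke": sex(0.008 * g, 0.8),
            "cvd_death": sex(0.020 * g, 0.7),
            "noncvd_death": sex(0.0030 * np.exp(0.070 * (AGES - AGE_MIN)), 0.8),
        },
        "prior_stroke": {
            "recurrent_chd": sex(0.012 * g, 0.7),
            "stroke": sex(0.020 * g, 0.9),
            "cvd_death": sex(0.015 * g, 0.8),
            "noncvd_death": sex(0.0030 * np.exp(0.070 * (AGES - AGE_MIN)), 0.8),
        },
    }
    cf_male = 0.10 + 0.23 * (AGES - AGE_MIN) / (N_AGES - 1)
    case_fatality = np.stack([cf_male + 0.02, cf_male], axis=1)
    return TransitionRates(prior=prior, case_fatality=case_fatality)


def make_demographics(config: SyntheticConfig, ses: str) -> Demographics:
    """Flat synthetic age structure with constant annual entrants at 35."""
    share = config.low_ses_share if ses == LOW else 1.0 - config.low_ses_share
    female = config.female_share_low if ses == LOW else config.female_share_high
    n = config.population_size * share
    per_age = np.array([n * (1 - female), n * female]) / N_AGES
    initial = np.tile(per_age, (N_AGES, 1))
    entrants = {year: per_age.copy() for year in range(2015, 2026)}
    frac = (AGES - AGE_MIN) / (N_AGES - 1)
    prev = np.zeros((N_AGES, 2, 3))
    for s in range(2):
        prev[:, s, 0] = 0.002 + 0.080 * frac  # prior CHD
        prev[:, s, 1] = 0.001 + 0.040 * frac  # prior stroke
        prev[:, s, 2] = 0.0005 + 0.015 * frac  # both
    return Demographics(initial_counts=initial, entrants=entrants, prior_prevalence=prev)


def generate_calibration(
    config: SyntheticConfig,
    marginals: dict[tuple[Sex, str], StratumMarginals] | None = None,
) -> CalibrationBundle:
    """Generate the full synthetic calibration bundle, deterministic per seed."""
    marginals = dict(marginals or DEFAULT_MARGINALS)
    for (sex, ses), m in marginals.items():
        m.validate()
    # lipids must not differ by SES stratum
    for sex in SEXES:
        lo, hi = marginals[(sex, LOW)], marginals[(sex, HIGH)]
        if (lo.ldl_mean, lo.ldl_sd, lo.hdl_mean, lo.hdl_sd) != (
            hi.ldl_mean, hi.ldl_sd, hi.hdl_mean, hi.hdl_sd
        ):
            raise ValidationError(f"lipid parameters differ across SES strata for {sex.value}")
    rng = np.random.default_rng(config.seed)
    rf = make_risk_function(rng)
    joints = {}
    for ses in SES_STRATA:
        rows = []
        for sex in SEXES:
            rows.append(
                build_joint_distribution(
                    marginals[(sex, ses)],
                    dependence=config.dependence,
                    correlation=config.correlation,
                    rng=rng,
                    copula_samples=config.copula_samples,
                )
            )
        joints[ses] = np.stack(rows)
    bundle = CalibrationBundle(
        config=config,
        marginals=marginals,
        joints=joints,
        risk_function=rf,
        rates=make_transition_rates(),
        demographics={ses: make_demographics(config, ses) for ses in SES_STRATA},
        ses_spec=SesRiskSpec(),
    )
    _check_plausibility(bundle)
    return bundle


def _check_plausibility(bundle: CalibrationBundle) -> None:
    """Guard: every cell's one-year per-cause probability stays below 0.5."""
    for cause in CAUSES:
        h = bundle.risk_function.hazard_grid(cause)
        p = -np.expm1(-h)
        if cause in bundle.ses_spec.applies_to:
            p = np.minimum(1.0, p * bundle.ses_spec.rr)
        if p.max() >= 0.5:
            raise ValidationError(
                f"one-year probability for {cause!r} reaches {p.max():.3f} >= 0.5"
            )
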