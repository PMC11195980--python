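"""Proportional-hazards risk function and risk-profile transformations.

Annual cause-specific hazards follow a Cox-style multiplicative form: a
baseline log-hazard per (age, sex) plus a log-hazard-ratio for each
non-reference risk-factor level in the cell's profile,

    h(cell) = exp( b0(age, sex) + Σ_f β[f, level_f(cell)] ).

Four causes are modeled for the CVD-free population: incident CHD, incident
stroke, diabetes incidence (a risk-factor transition, not an exit), and
non-CVD death.  The independent low-SES excess risk is a multiplicative
factor applied on the annual probability scale, so the first-cycle
incidence-rate ratio between two otherwise-identical populations equals the
configured relative risk exactly.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .exceptions import ConfigurationError, ValidationError
from .population import AGE_MAX, AGE_MIN, N_AGES, age_index
from .profiles import (
    CUTPOINTS,
    FACTOR_LEVELS,
    FACTORS,
    LEVEL_CODES,
    SEX_INDEX,
    Diabetes,
    RiskProfile,
    Sex,
    Smoking,
)

#: Causes modeled in the CVD-free compartment.
CAUSES: tuple[str, ...] = (
    "incident_chd",
    "incident_stroke",
    "diabetes_incidence",
    "noncvd_death",
)


@dataclass
class RiskFunction:
    """Baseline log-hazards by (age, sex) plus covariate log-hazard-ratios.

    ``baseline_log_hazard[cause]`` is a (60, 2) array over ages 35..94 and
    sexes (male, female).  ``betas[cause]`` maps ``(factor, level-value)`` to
    a log-hazard-ratio; reference (code-0) levels are implicitly 0 and, if
    present, must be exactly 0.  ``beta_sd`` optionally carries a standard
    error per beta for Monte Carlo uncertainty propagation.
    """

    baseline_log_hazard: dict[str, np.ndarray]
    betas: dict[str, dict[tuple[str, str], float]]
    beta_sd: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cause in CAUSES:
            if cause not in self.baseline_log_hazard:
                raise ConfigurationError(f"missing baseline log-hazard for {cause!r}")
            arr = np.asarray(self.baseline_log_hazard[cause], dtype=float)
            if arr.shape != (N_AGES, 2):
                raise ConfigurationError(
                    f"baseline for {cause!r} has shape {arr.shape}, expected {(N_AGES, 2)}"
                )
            if not np.all(np.isfinite(arr)):
                raise ConfigurationError(f"non-finite baseline log-hazard for {cause!r}")
            self.baseline_log_hazard[cause] = arr
            for (factor, level), b in self.betas.get(cause, {}).items():
                if factor not in FACTORS:
                    raise ConfigurationError(f"unknown factor {factor!r} in betas")
                levels = [lvl.value for lvl in FACTOR_LEVELS[factor]]
                if level not in levels:
                    raise ConfigurationError(
                        f"unknown level {level!r} for factor {factor!r}"
                    )
                if level == levels[0] and b != 0.0:
                    raise ConfigurationError(
                        f"reference level beta must be 0: {cause}/{factor}/{level}"
                    )
        self._lhr_cache: dict[str, np.ndarray] = {}

    def beta(self, cause: str, factor: str, level) -> float:
        """Log-hazard-ratio for one (factor, level); reference levels are 0."""
        value = level.value if hasattr(level, "value") else str(level)
        levels = [lvl.value for lvl in FACTOR_LEVELS[factor]]
        table = self.betas.get(cause, {})
        if (factor, value) in table:
            return float(table[(factor, value)])
        if value == levels[0]:
            return 0.0
        raise ConfigurationError(
            f"missing beta for cause={cause!r}, factor={factor!r}, level={value!r}"
        )

    def profile_log_hr(self, cause: str) -> np.ndarray:
        """Total log-hazard-ratio of every profile, shape (486,). Cached."""
        if cause not in self._lhr_cache:
            lhr = np.zeros(LEVEL_CODES.shape[0])
            for col, factor in enumerate(FACTORS):
                per_level = np.array(
                    [self.beta(cause, factor, lvl) for lvl in FACTOR_LEVELS[factor]]
                )
                lhr += per_level[LEVEL_CODES[:, col]]
            self._lhr_cache[cause] = lhr
        return self._lhr_cache[cause]

    def hazard_grid(self, cause: str) -> np.ndarray:
        """Hazard per (age, sex, profile), shape (60, 2, 486)."""
        base = self.baseline_log_hazard[cause]
        return np.exp(base[:, :, None] + self.profile_log_hr(cause)[None, None, :])


@dataclass(frozen=True)
class SesRiskSpec:
    """Independent low-SES relative risk, beyond traditional risk factors.

    Default 1.58 (95% CI 1.31-1.90), applied multiplicatively to the annual
    probabilities of the causes in ``applies_to``.
    """

    rr: float = 1.58
    ci_low: float = 1.31
    ci_high: float = 1.90
    applies_to: frozenset[str] = frozenset({"incident_chd", "incident_stroke"})

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.rr <= self.ci_high):
            raise ValidationError(
                f"require ci_low <= rr <= ci_high, got {self.ci_low}, {self.rr}, {self.ci_high}"
            )
        if not set(self.applies_to) <= set(CAUSES):
            raise ValidationError(f"unknown causes in applies_to: {self.applies_to}")


@dataclass(frozen=True)
class IdealPolicy:
    """Ideal risk-factor control targets.

    SBP <=110 mmHg; LDL-C <=70 mg/dL for high-risk persons (diabetes or
    prior CVD), <=100 otherwise; HDL-C >=50 mg/dL; BMI <=25; no smoking; no
    diabetes.  Each numeric target maps into the stratum that contains it.
    """

    sbp_target: float = 110.0
    ldl_target: float = 100.0
    ldl_target_high_risk: float = 70.0
    hdl_target: float = 50.0
    bmi_target: float = 25.0

    def ideal_levels(self, high_risk: bool = False) -> dict[str, object]:
        ldl = self.ldl_target_high_risk if high_risk else self.ldl_target
        out: dict[str, object] = {}
        for factor, target in (
            ("sbp", self.sbp_target),
            ("ldl", ldl),
            ("hdl", self.hdl_target),
            ("bmi", self.bmi_target),
        ):
            # "target or lower/higher": a target on a cutpoint belongs to the
            # stratum below it (e.g. LDL 100 -> lt100, BMI 25 -> lt25).
            k = bisect.bisect_left(CUTPOINTS[factor], target)
            out[factor] = FACTOR_LEVELS[factor][k]
        out["smoking"] = Smoking.NONE
        out["diabetes"] = Diabetes.NO
        return out


DEFAULT_IDEAL_POLICY = IdealPolicy()
ALL_FACTORS: frozenset[str] = frozenset(FACTORS)


def annual_hazard(
    profile: RiskProfile, age: int, sex: Sex, cause: str, rf: RiskFunction
) -> float:
    """Annual cause-specific hazard (per person-year) for one cell."""
    if not AGE_MIN <= age <= AGE_MAX:
        raise ValidationError(f"age {age} outside {AGE_MIN}..{AGE_MAX}")
    if cause not in CAUSES:
        raise ConfigurationError(f"unknown cause {cause!r}")
    log_h = float(rf.baseline_log_hazard[cause][age_index(age), SEX_INDEX[sex]])
    for factor in FACTORS:
        log_h += rf.beta(cause, factor, getattr(profile, factor))
    return float(np.exp(log_h))


def hazard_to_probability(h):
    """Convert an annual hazard to an annual probability, p = 1 - exp(-h)."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValidationError("hazard must be non-negative")
    p = -np.expm1(-h)
    return float(p) if p.ndim == 0 else p


def apply_ses_rr(p, spec: SesRiskSpec, enabled: bool):
    """Apply the independent low-SES multiplier on the probability scale.

    Capped at 1.  When disabled the probability passes through unchanged.
    """
    p = np.asarray(p, dtype=float)
    out = np.minimum(1.0, p * spec.rr) if enabled else p
    return float(out) if out.ndim == 0 else out


def allocate_competing(hazards: Mapping[str, object]):
    """Split one-cycle mass among competing causes.

    With total hazard H = Σ h_c, the probability of any event is
    1 - exp(-H); each cause receives the share h_c / H of it.  Returns
    ``(per-cause probabilities, survive-all probability)``;  probabilities
    plus survival sum to 1 exactly by construction.
    """
    names = list(hazards)
    arrs = [np.asarray(hazards[c], dtype=float) for c in names]
    for c, a in zip(names, arrs):
        if np.any(a < 0):
            raise ValidationError(f"negative hazard for cause {c!r}")
    total = sum(arrs)
    p_any = -np.expm1(-total)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = [np.where(total > 0, a / np.where(total > 0, total, 1.0), 0.0) for a in arrs]
    probs = {c: p_any * s for c, s in zip(names, shares)}
    p_survive = 1.0 - sum(probs.values())
    if np.ndim(p_survive) == 0:
        probs = {c: float(v) for c, v in probs.items()}
        p_survive = float(p_survive)
    return probs, p_survive


def idealize_profile(
    profile: RiskProfile,
    high_risk: bool = False,
    policy: IdealPolicy = DEFAULT_IDEAL_POLICY,
    factors: Iterable[str] = ALL_FACTORS,
) -> RiskProfile:
    """Force selected factors of a profile to their ideal-control strata.

    Idempotent; unselected factors pass through unchanged.  ``high_risk``
    selects the stricter LDL target used for persons with diabetes or prior
    CVD (both targets fall in the same LDL stratum, so the flag is kept for
    interface fidelity).
    """
    factors = set(factors)
    unknown = factors - ALL_FACTORS
    if unknown:
        raise ValidationError(f"unknown factors: {sorted(unknown)}")
    ideal = policy.ideal_levels(high_risk=high_risk)
    return profile._replace(**{f: ideal[f] for f in factors})


def idealize_joint(
    joint: np.ndarray,
    factors: Iterable[str],
    policy: IdealPolicy = DEFAULT_IDEAL_POLICY,
) -> np.ndarray:
    """Push a 486-cell probability vector through profile idealization.

    Mass from each profile moves to its idealized profile; the high-risk LDL
    flag follows the source profile's diabetes status.
    """
    factors = set(factors)
    if not factors:
        return np.asarray(joint, dtype=float).copy()
    joint = np.asarray(joint, dtype=float)
    out = np.zeros_like(joint)
    from .profiles import PROFILES  # local to avoid cluttering module top

    for i, prof in enumerate(PROFILES):
        if joint[i] == 0:
            continue
        target = idealize_profile(
            prof, high_risk=(prof.diabetes is Diabetes.YES), policy=policy, factors=factors
        )
        out[target.index] += joint[i]
    return out
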