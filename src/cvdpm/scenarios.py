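"""Counterfactual scenarios, age standardization, and burden decomposition.

Four canonical scenarios span the decomposition:

* ``S_low``   — low-SES risk-factor distribution, SES multiplier ON;
* ``S_high``  — high-SES distribution, multiplier OFF (the comparator);
* ``S_m1``    — low-SES distribution, multiplier OFF: isolates the excess
  due to traditional risk factors alone;
* ``S_ideal`` — low-SES population with every factor at ideal control and
  the multiplier OFF: what remains is unmodifiable age/sex risk.

The low-vs-high gap then splits as

    overall excess   = r_low − r_high
    risk-factor part = r_m1 − r_high
    SES-independent  = r_low − r_m1

and the within-low-SES burden as SES-independent + suboptimal management
(r_m1 − r_ideal) + unmodifiable (r_ideal).

All rates are age-standardized over 5-year bands of ages 35–64, per 10,000
person-years, using one fixed set of standard weights per analysis (pooled
person-years of the comparator run) — the same weights for every scenario,
otherwise the decomposition identities break.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import EventTally, SimulationInputs, simulate
from .exceptions import ValidationError
from .population import AGE_MIN, build_population
from .profiles import SEXES, Sex
from .risk import ALL_FACTORS, DEFAULT_IDEAL_POLICY, IdealPolicy, SesRiskSpec, idealize_joint
from .synthetic import LOW, CalibrationBundle

#: Outcome age range and 5-year standardization bands.
OUTCOME_AGES = (35, 64)
BAND_EDGES = tuple(range(35, 70, 5))  # 35-39 ... 60-64
N_BANDS = len(BAND_EDGES)
BAND_LABELS = tuple(f"{lo}-{lo + 4}" for lo in BAND_EDGES)

#: Outcomes reported per scenario.
OUTCOMES = ("incident_chd", "chd_death")


@dataclass(frozen=True)
class ScenarioSpec:
    """One counterfactual scenario."""

    rf_distribution: str  # "low" or "high" SES risk-factor distribution
    ses_rr_enabled: bool
    idealized_factors: frozenset = frozenset()
    label: str = ""

    def __post_init__(self) -> None:
        if self.rf_distribution not in ("low", "high"):
            raise ValidationError(f"unknown rf_distribution {self.rf_distribution!r}")
        unknown = set(self.idealized_factors) - ALL_FACTORS
        if unknown:
            raise ValidationError(f"unknown factors {sorted(unknown)}")


S_LOW = ScenarioSpec("low", True, frozenset(), "low SES, observed")
S_HIGH = ScenarioSpec("high", False, frozenset(), "high SES, observed")
S_M1 = ScenarioSpec("low", False, frozenset(), "low SES risk factors only")
S_IDEAL = ScenarioSpec("low", False, ALL_FACTORS, "low SES, ideal control")


@dataclass
class RateTable:
    """Events and person-years by 5-year band, per sex and outcome."""

    events: dict[tuple[Sex, str], np.ndarray]  # (sex, outcome) -> (6,)
    person_years: dict[Sex, np.ndarray]  # sex -> (6,)
    label: str = ""

    def band_rates(self, sex: Sex, outcome: str) -> np.ndarray:
        """Rates per 10,000 person-years per band (0 where no exposure)."""
        py = self.person_years[sex]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(py > 0, self.events[(sex, outcome)] / np.where(py > 0, py, 1.0), 0.0) * 1e4

    def crude_rate(self, sex: Sex, outcome: str) -> float:
        return float(self.events[(sex, outcome)].sum() / self.person_years[sex].sum() * 1e4)

    def standardized_rate(self, sex: Sex, outcome: str, weights: np.ndarray) -> float:
        return age_standardize(self.events[(sex, outcome)], self.person_years[sex], weights)


def age_standardize(events: np.ndarray, person_years: np.ndarray, weights: np.ndarray) -> float:
    """Weighted average of band rates, per 10,000 person-years.

    Weights must be non-negative and sum to 1; bands with zero person-years
    contribute zero to the sum.
    """
    events = np.asarray(events, dtype=float)
    py = np.asarray(person_years, dtype=float)
    w = np.asarray(weights, dtype=float)
    if events.shape != py.shape or events.shape != w.shape:
        raise ValidationError("events, person_years and weights must have equal shape")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("weights must be non-negative and sum to 1")
    if np.all(py == 0):
        raise ValidationError("all bands have zero person-years")
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(py > 0, events / np.where(py > 0, py, 1.0), 0.0)
    return float(np.sum(w * rates) * 1e4)


def _band_aggregate(tally: EventTally) -> RateTable:
    """Collapse a tally to 5-year bands over the outcome age range."""
    events: dict[tuple[Sex, str], np.ndarray] = {}
    py = {}
    for si, sex in enumerate(SEXES):
        bp = np.zeros(N_BANDS)
        for b, lo in enumerate(BAND_EDGES):
            sl = slice(lo - AGE_MIN, lo - AGE_MIN + 5)
            bp[b] = tally.person_years[:, sl, si].sum()
        py[sex] = bp
        for outcome in OUTCOMES:
            be = np.zeros(N_BANDS)
            for b, lo in enumerate(BAND_EDGES):
                sl = slice(lo - AGE_MIN, lo - AGE_MIN + 5)
                be[b] = tally.events[outcome][:, sl, si].sum()
            events[(sex, outcome)] = be
    return RateTable(events=events, person_years=py)


def run_scenario(
    spec: ScenarioSpec,
    bundle: CalibrationBundle,
    years: range = range(2015, 2025),
    risk_function=None,
    ses_spec: SesRiskSpec | None = None,
    policy: IdealPolicy = DEFAULT_IDEAL_POLICY,
) -> RateTable:
    """Simulate one scenario and return its banded events/person-years.

    ``risk_function`` and ``ses_spec`` default to the bundle's; overrides
    exist for Monte Carlo parameter draws.
    """
    rf = risk_function if risk_function is not None else bundle.risk_function
    ses = ses_spec if ses_spec is not None else bundle.ses_spec
    joint = bundle.joints[spec.rf_distribution].copy()
    if spec.idealized_factors:
        joint = np.stack(
            [idealize_joint(joint[s], spec.idealized_factors, policy) for s in range(2)]
        )
    demo = bundle.demographics[spec.rf_distribution]
    state = build_population(
        demo, {sex: joint[si] for si, sex in enumerate(SEXES)}, year=min(years)
    )
    inputs = SimulationInputs(
        risk_function=rf,
        rates=bundle.rates,
        ses_spec=ses,
        ses_enabled=spec.ses_rr_enabled,
        entrants=demo.entrants,
        entrant_joint=joint,
    )
    tally = simulate(state, years, inputs)
    table = _band_aggregate(tally)
    table.label = spec.label
    return table


def standard_weights(reference: RateTable) -> dict[Sex, np.ndarray]:
    """Standard age weights: the reference run's person-year distribution."""
    out = {}
    for sex in SEXES:
        py = reference.person_years[sex]
        if py.sum() <= 0:
            raise ValidationError(f"reference run has no person-years for {sex.value}")
        out[sex] = py / py.sum()
    return out


@dataclass
class DecompositionResult:
    """Apportionment of the low-vs-high-SES rate gap."""

    rate_low: float
    rate_high: float
    rate_m1: float
    overall_excess: float
    rr_low_vs_high: float  # nan when rate_high == 0
    rf_excess: float
    ses_excess: float
    pct_rf: float  # nan when overall_excess == 0
    pct_ses: float
    flags: tuple[str, ...] = ()


def decompose_gap(r_low: float, r_high: float, r_m1: float) -> DecompositionResult:
    """Split the low-vs-high-SES rate gap into its two components.

    The risk-factor component is the gap that persists when the low-SES
    population keeps its own risk-factor distribution but loses the
    SES-independent multiplier (r_m1 − r_high); the rest (r_low − r_m1) is
    the SES-independent component.  The two components sum to the overall
    excess exactly, and the two percentages to 100 exactly.
    """
    if min(r_low, r_high, r_m1) < 0:
        raise ValidationError("rates must be non-negative")
    flags = []
    rf_excess = r_m1 - r_high
    ses_excess = r_low - r_m1
    overall = rf_excess + ses_excess  # == r_low - r_high, exact additivity
    if r_high > 0:
        rr = r_low / r_high
    else:
        rr, flags = math.nan, flags + ["rr_undefined"]
    if overall != 0:
        pct_rf = 100.0 * rf_excess / overall
        pct_ses = 100.0 - pct_rf
    else:
        pct_rf = pct_ses = math.nan
        flags.append("zero_overall_excess")
    return DecompositionResult(
        rate_low=r_low, rate_high=r_high, rate_m1=r_m1,
        overall_excess=overall, rr_low_vs_high=rr,
        rf_excess=rf_excess, ses_excess=ses_excess,
        pct_rf=pct_rf, pct_ses=pct_ses, flags=tuple(flags),
    )


@dataclass
class BurdenComponents:
    """Within-population burden split: SES-independent / management / unmodifiable."""

    ses_component: float
    management_component: float
    unmodifiable: float
    total: float
    flags: tuple[str, ...] = ()


def decompose_low_ses(r_low: float, r_m1: float, r_ideal: float) -> BurdenComponents:
    """Split a population's burden into its three drivers.

    Expects r_low >= r_m1 >= r_ideal >= 0; ordering violations are flagged,
    not raised.  Components sum to r_low (floating-point additivity to 1 ulp;
    the unmodifiable part is r_ideal).
    """
    flags = []
    if not (r_low >= r_m1 >= r_ideal >= 0):
        flags.append("ordering_violation")
    ses = r_low - r_m1
    mgmt = r_m1 - r_ideal
    return BurdenComponents(
        ses_component=ses,
        management_component=mgmt,
        unmodifiable=r_ideal,
        total=r_low,
        flags=tuple(flags),
    )


def single_factor_reduction(
    base: ScenarioSpec,
    factor: str,
    bundle: CalibrationBundle,
    outcome: str = "incident_chd",
    sex: Sex | None = None,
    years: range = range(2015, 2025),
    weights: dict[Sex, np.ndarray] | None = None,
) -> dict[Sex, float]:
    """Standardized-rate reduction from idealizing one factor (or the SES RR).

    ``factor`` is one of the six risk factors or ``"ses_independent"``,
    which instead switches the SES multiplier off.  Returns the reduction
    per 10,000 person-years per sex (for the requested sex only, if given).
    """
    if factor == "ses_independent":
        modified = ScenarioSpec(
            base.rf_distribution, False, base.idealized_factors,
            f"{base.label} - SES RR off",
        )
    elif factor in ALL_FACTORS:
        modified = ScenarioSpec(
            base.rf_distribution, base.ses_rr_enabled,
            frozenset(base.idealized_factors) | {factor},
            f"{base.label} - ideal {factor}",
        )
    else:
        raise ValidationError(f"unknown factor {factor!r}")
    if weights is None:
        weights = standard_weights(run_scenario(S_HIGH, bundle, years))
    t_base = run_scenario(base, bundle, years)
    t_mod = run_scenario(modified, bundle, years)
    sexes = [sex] if sex is not None else list(SEXES)
    return {
        s: t_base.standardized_rate(s, outcome, weights[s])
        - t_mod.standardized_rate(s, outcome, weights[s])
        for s in sexes
    }


@dataclass
class AnalysisResult:
    """Full four-scenario analysis: rates, gap decomposition, burden split."""

    rates: dict[tuple[str, Sex, str], float]  # (scenario, sex, outcome) -> std rate
    gap: dict[tuple[Sex, str], DecompositionResult]
    burden: dict[tuple[Sex, str], BurdenComponents]
    weights: dict[Sex, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table mirroring the headline decomposition layout."""
        rows = []
        for (sex, outcome), d in self.gap.items():
            b = self.burden[(sex, outcome)]
            rows.append(
                dict(
                    outcome=outcome, sex=sex.value,
                    rate_low=d.rate_low, rate_high=d.rate_high,
                    overall_excess=d.overall_excess, rr=d.rr_low_vs_high,
                    rf_excess=d.rf_excess, pct_rf=d.pct_rf,
                    ses_excess=d.ses_excess, pct_ses=d.pct_ses,
                    management_component=b.management_component,
                    unmodifiable=b.unmodifiable,
                )
            )
        return pd.DataFrame(rows)


def run_analysis(
    bundle: CalibrationBundle,
    years: range = range(2015, 2025),
    risk_function=None,
    ses_spec: SesRiskSpec | None = None,
) -> AnalysisResult:
    """Run the four canonical scenarios and both decompositions.

    Standard weights are the comparator (high-SES) run's pooled person-year
    distribution, applied identically to every scenario.
    """
    tables = {
        name: run_scenario(spec, bundle, years, risk_function=risk_function, ses_spec=ses_spec)
        for name, spec in (("low", S_LOW), ("high", S_HIGH), ("m1", S_M1), ("ideal", S_IDEAL))
    }
    weights = standard_weights(tables["high"])
    rates = {
        (name, sex, outcome): tables[name].standardized_rate(sex, outcome, weights[sex])
        for name in tables
        for sex in SEXES
        for outcome in OUTCOMES
    }
    gap = {}
    burden = {}
    for sex in SEXES:
        for outcome in OUTCOMES:
            gap[(sex, outcome)] = decompose_gap(
                rates[("low", sex, outcome)],
                rates[("high", sex, outcome)],
                rates[("m1", sex, outcome)],
            )
            burden[(sex, outcome)] = decompose_low_ses(
                rates[("low", sex, outcome)],
                rates[("m1", sex, outcome)],
                rates[("ideal", sex, outcome)],
            )
    return AnalysisResult(rates=rates, gap=gap, burden=burden, weights=weights)


def format_results(df: pd.DataFrame) -> pd.DataFrame:
    """Display rounding: rates 1 decimal, RR 2 decimals, percentages 1 decimal."""
    out = df.copy()
    for col in ("rate_low", "rate_high", "overall_excess", "rf_excess",
                "ses_excess", "pct_rf", "pct_ses", "management_component", "unmodifiable"):
        if col in out:
            out[col] = out[col].round(1)
    if "rr" in out:
        out["rr"] = out["rr"].round(2)
    return out
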