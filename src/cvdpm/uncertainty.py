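"""Monte Carlo propagation of parameter uncertainty.

Each of ``n_draws`` iterations (default 2000) resamples the varied
parameters — the CHD-incidence log-hazard-ratios and the independent
low-SES relative risk — from distributions centred on the point estimates
with spread set by their 95% confidence intervals, reruns the full
analysis, and stores every output.  95% uncertainty intervals are the
empirical 2.5th/97.5th percentiles across draws (linear interpolation
between order statistics).

Betas are drawn normal on the coefficient scale with
sd = (ci_high − ci_low) / (2·1.96).  The relative risk is drawn normal on
the log scale (its printed CI is near-symmetric there) and exponentiated;
a linear-scale option is retained.  Within one iteration all scenarios
share the same parameter draw, so decomposition components stay additive
draw by draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .risk import RiskFunction, SesRiskSpec
from .scenarios import OUTCOMES, run_analysis
from .profiles import SEXES
from .synthetic import CalibrationBundle

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ParameterPrior:
    """Mean and 95% CI of one varied parameter."""

    mean: float
    ci_low: float
    ci_high: float
    scale: Literal["linear", "log"] = "linear"

    def __post_init__(self) -> None:
        if self.ci_high < self.ci_low:
            raise ValidationError(
                f"ci_high {self.ci_high} < ci_low {self.ci_low}"
            )
        if self.scale == "log" and min(self.mean, self.ci_low) <= 0:
            raise ValidationError("log-scale priors require positive mean and CI")

    @property
    def sd(self) -> float:
        if self.scale == "log":
            return (np.log(self.ci_high) - np.log(self.ci_low)) / (2 * Z95)
        return (self.ci_high - self.ci_low) / (2 * Z95)


@dataclass
class ParameterDraws:
    """Reproducible joint draws for every varied parameter."""

    n_draws: int
    seed: int
    values: dict[str, np.ndarray]  # name -> (n_draws,)
    priors: dict[str, ParameterPrior] = field(default_factory=dict)

    def central(self) -> dict[str, float]:
        return {name: prior.mean for name, prior in self.priors.items()}

    def draw(self, i: int) -> dict[str, float]:
        return {name: float(v[i]) for name, v in self.values.items()}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values)
        df.insert(0, "draw", np.arange(self.n_draws))
        return df


def draw_parameters(
    priors: Mapping[str, ParameterPrior], n: int, seed: int
) -> ParameterDraws:
    """Draw ``n`` values per parameter; deterministic given ``seed``."""
    if n < 1:
        raise ValidationError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    values = {}
    for name, prior in priors.items():
        z = rng.standard_normal(n)
        if prior.scale == "log":
            values[name] = np.exp(np.log(prior.mean) + prior.sd * z)
        else:
            values[name] = prior.mean + prior.sd * z
    return ParameterDraws(n_draws=n, seed=seed, values=values, priors=dict(priors))


@dataclass
class UncertaintyResult:
    """Point estimates with 95% uncertainty intervals per output quantity."""

    point: dict[str, float]
    ui_low: dict[str, float]
    ui_high: dict[str, float]
    n_draws: int
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(quantity=q, point=self.point[q], ui_low=self.ui_low[q], ui_high=self.ui_high[q])
            for q in self.point
        ]
        return pd.DataFrame(rows)


def monte_carlo_ui(
    closure: Callable[[dict[str, float]], dict[str, float]],
    draws: ParameterDraws,
) -> UncertaintyResult:
    """Propagate parameter draws through an analysis closure.

    The closure maps one parameter assignment to a dict of named outputs.
    The point estimate uses the central (mean) parameters; the interval per
    output is the empirical 2.5/97.5 percentile across successful draws.
    Draws whose evaluation raises are excluded with a warning.
    """
    point = closure(draws.central())
    samples: dict[str, list[float]] = {k: [] for k in point}
    n_failed = 0
    for i in range(draws.n_draws):
        try:
            out = closure(draws.draw(i))
        except Exception:  # noqa: BLE001 - per-draw failures are survivable
            n_failed += 1
            continue
        for k in samples:
            samples[k].append(out[k])
    if n_failed:
        warnings.warn(f"{n_failed} of {draws.n_draws} Monte Carlo draws failed", stacklevel=2)
    if not any(samples.values()):
        raise ValidationError("every Monte Carlo draw failed")
    ui_low = {}
    ui_high = {}
    for k, vals in samples.items():
        arr = np.asarray(vals, dtype=float)
        lo, hi = np.percentile(arr, [2.5, 97.5])  # linear interpolation
        ui_low[k], ui_high[k] = float(lo), float(hi)
    return UncertaintyResult(
        point=point, ui_low=ui_low, ui_high=ui_high,
        n_draws=draws.n_draws, n_failed=n_failed,
    )


def default_priors(bundle: CalibrationBundle) -> dict[str, ParameterPrior]:
    """Varied parameters: CHD-incidence betas plus the SES relative risk."""
    priors: dict[str, ParameterPrior] = {
        "rr": ParameterPrior(
            mean=bundle.ses_spec.rr,
            ci_low=bundle.ses_spec.ci_low,
            ci_high=bundle.ses_spec.ci_high,
            scale="log",
        )
    }
    betas = bundle.risk_function.betas["incident_chd"]
    sds = bundle.risk_function.beta_sd.get("incident_chd", {})
    for (factor, level), b in betas.items():
        sd = sds.get((factor, level), 0.15 * abs(b) + 0.02)
        priors[f"beta:incident_chd:{factor}:{level}"] = ParameterPrior(
            mean=b, ci_low=b - Z95 * sd, ci_high=b + Z95 * sd
        )
    return priors


def _apply_parameters(
    bundle: CalibrationBundle, params: dict[str, float]
) -> tuple[RiskFunction, SesRiskSpec]:
    rf = bundle.risk_function
    new_betas = {c: dict(b) for c, b in rf.betas.items()}
    for name, value in params.items():
        if name.startswith("beta:"):
            _, cause, factor, level = name.split(":")
            new_betas[cause][(factor, level)] = value
    rf2 = RiskFunction(
        baseline_log_hazard=dict(rf.baseline_log_hazard),
        betas=new_betas,
        beta_sd=rf.beta_sd,
    )
    rr = params.get("rr", bundle.ses_spec.rr)
    spec = bundle.ses_spec
    ses = SesRiskSpec(
        rr=rr, ci_low=min(spec.ci_low, rr), ci_high=max(spec.ci_high, rr),
        applies_to=spec.applies_to,
    )
    return rf2, ses


def analysis_with_uncertainty(
    bundle: CalibrationBundle,
    n_draws: int = 2000,
    seed: int = 0,
    years: range = range(2015, 2025),
) -> UncertaintyResult:
    """Full four-scenario analysis with 95% UIs on all reported quantities.

    Outputs are keyed ``{quantity}:{sex}:{outcome}`` for the standardized
    rates of the four scenarios and every decomposition component.
    """
    priors = default_priors(bundle)
    draws = draw_parameters(priors, n_draws, seed)

    def closure(params: dict[str, float]) -> dict[str, float]:
        rf, ses = _apply_parameters(bundle, params)
        res = run_analysis(bundle, years, risk_function=rf, ses_spec=ses)
        out: dict[str, float] = {}
        for (name, sex, outcome), rate in res.rates.items():
            out[f"rate_{name}:{sex.value}:{outcome}"] = rate
        for sex in SEXES:
            for outcome in OUTCOMES:
                d = res.gap[(sex, outcome)]
                b = res.burden[(sex, outcome)]
                key = f"{sex.value}:{outcome}"
                out[f"overall_excess:{key}"] = d.overall_excess
                out[f"rr_low_vs_high:{key}"] = d.rr_low_vs_high
                out[f"rf_excess:{key}"] = d.rf_excess
                out[f"ses_excess:{key}"] = d.ses_excess
                out[f"pct_rf:{key}"] = d.pct_rf
                out[f"pct_ses:{key}"] = d.pct_ses
                out[f"management_component:{key}"] = b.management_component
                out[f"unmodifiable:{key}"] = b.unmodifiable
        return out

    return monte_carlo_ui(closure, draws)
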