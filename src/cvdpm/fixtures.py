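"""Calibration-bundle serialization: plain CSV/JSON files, lossless round trip.

Layout of a fixture directory::

    config.json               synthetic-generation config
    marginals.csv             sex, ses, <marginal fields>
    joint_<sex>_<ses>.csv     profile_index, <factor levels>, probability
    baseline_hazards.csv      cause, age, sex, log_hazard
    betas.csv                 cause, factor, level, beta, sd
    prior_rates.csv           history, event, age, sex, rate
    case_fatality.csv         age, sex, fraction
    demographics_<ses>.csv    age, sex, count
    entrants_<ses>.csv        year, sex, count
    prevalence_<ses>.csv      age, sex, history, fraction

Floats are written with ``repr`` precision, so reading a written bundle
reproduces it exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .population import AGES, AGE_MIN, N_AGES, Demographics
from .profiles import FACTORS, N_PROFILES, PROFILES, PRIOR_HISTORIES, SEXES, SEX_INDEX, Sex
from .risk import CAUSES, RiskFunction, SesRiskSpec
from .synthetic import (
    SES_STRATA,
    CalibrationBundle,
    StratumMarginals,
    SyntheticConfig,
    TransitionRates,
)

def _write(df: pd.DataFrame, path: Path) -> None:
    # default float formatting is repr (shortest round-trip digits)
    df.to_csv(path, index=False)


def write_fixtures(bundle: CalibrationBundle, directory) -> list[Path]:
    """Write a calibration bundle to ``directory``; returns files written."""
    d = Path(directory)
    if not d.is_dir():
        raise ValidationError(f"not a writable directory: {d}")
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = d / name
        _write(df, path)
        written.append(path)

    cfg = d / "config.json"
    cfg.write_text(json.dumps(bundle.config.model_dump(), indent=1, sort_keys=True) + "\n")
    written.append(cfg)

    rows = []
    for (sex, ses), m in sorted(bundle.marginals.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
        rows.append({"sex": sex.value, "ses": ses, **dataclasses.asdict(m)})
    emit(pd.DataFrame(rows), "marginals.csv")

    for ses in SES_STRATA:
        for sex in SEXES:
            joint = bundle.joints[ses][SEX_INDEX[sex]]
            df = pd.DataFrame(
                {
                    "profile_index": np.arange(N_PROFILES),
                    **{f: [getattr(p, f).value for p in PROFILES] for f in FACTORS},
                    "probability": joint,
                }
            )
            emit(df, f"joint_{sex.value}_{ses}.csv")

    rf = bundle.risk_function
    rows = []
    for cause in CAUSES:
        for si, sex in enumerate(SEXES):
            for ai, age in enumerate(AGES):
                rows.append((cause, int(age), sex.value, rf.baseline_log_hazard[cause][ai, si]))
    emit(pd.DataFrame(rows, columns=["cause", "age", "sex", "log_hazard"]), "baseline_hazards.csv")

    rows = []
    for cause, table in sorted(rf.betas.items()):
        sds = rf.beta_sd.get(cause, {})
        for (factor, level), b in sorted(table.items()):
            rows.append((cause, factor, level, b, sds.get((factor, level), np.nan)))
    emit(pd.DataFrame(rows, columns=["cause", "factor", "level", "beta", "sd"]), "betas.csv")

    rows = []
    for hist in ("prior_chd", "prior_stroke"):
        for ev in TransitionRates.PRIOR_EVENTS:
            arr = bundle.rates.prior[hist][ev]
            for si, sex in enumerate(SEXES):
                for ai, age in enumerate(AGES):
                    rows.append((hist, ev, int(age), sex.value, arr[ai, si]))
    emit(pd.DataFrame(rows, columns=["history", "event", "age", "sex", "rate"]), "prior_rates.csv")

    rows = [
        (int(age), sex.value, bundle.rates.case_fatality[ai, si])
        for si, sex in enumerate(SEXES)
        for ai, age in enumerate(AGES)
    ]
    emit(pd.DataFrame(rows, columns=["age", "sex", "fraction"]), "case_fatality.csv")

    for ses in SES_STRATA:
        demo = bundle.demographics[ses]
        rows = [
            (int(age), sex.value, demo.initial_counts[ai, si])
            for si, sex in enumerate(SEXES)
            for ai, age in enumerate(AGES)
        ]
        emit(pd.DataFrame(rows, columns=["age", "sex", "count"]), f"demographics_{ses}.csv")
        rows = [
            (int(year), sex.value, counts[si])
            for year, counts in sorted(demo.entrants.items())
            for si, sex in enumerate(SEXES)
        ]
        emit(pd.DataFrame(rows, columns=["year", "sex", "count"]), f"entrants_{ses}.csv")
        rows = [
            (int(age), sex.value, hist.value, demo.prior_prevalence[ai, si, hi])
            for si, sex in enumerate(SEXES)
            for ai, age in enumerate(AGES)
            for hi, hist in enumerate(PRIOR_HISTORIES)
        ]
        emit(pd.DataFrame(rows, columns=["age", "sex", "history", "fraction"]), f"prevalence_{ses}.csv")

    return written


def _read_csv(d: Path, name: str) -> pd.DataFrame:
    path = d / name
    if not path.is_file():
        raise ValidationError(f"missing calibration file: {path}")
    return pd.read_csv(path, float_precision="round_trip")


def read_fixtures(directory) -> CalibrationBundle:
    """Read a calibration bundle previously written by :func:`write_fixtures`."""
    d = Path(directory)
    if not d.is_dir():
        raise ValidationError(f"not a directory: {d}")
    cfg_path = d / "config.json"
    if not cfg_path.is_file():
        raise ValidationError(f"missing calibration file: {cfg_path}")
    config = SyntheticConfig.model_validate(json.loads(cfg_path.read_text()))

    mdf = _read_csv(d, "marginals.csv")
    fields = [f.name for f in dataclasses.fields(StratumMarginals)]
    marginals = {
        (Sex(row["sex"]), row["ses"]): StratumMarginals(**{f: float(row[f]) for f in fields})
        for _, row in mdf.iterrows()
    }

    joints = {}
    for ses in SES_STRATA:
        rows = []
        for sex in SEXES:
            df = _read_csv(d, f"joint_{sex.value}_{ses}.csv").sort_values("profile_index")
            rows.append(df["probability"].to_numpy())
        joints[ses] = np.stack(rows)

    hdf = _read_csv(d, "baseline_hazards.csv")
    baseline = {}
    for cause in CAUSES:
        arr = np.zeros((N_AGES, 2))
        sub = hdf[hdf["cause"] == cause]
        for _, row in sub.iterrows():
            arr[int(row["age"]) - AGE_MIN, SEX_INDEX[Sex(row["sex"])]] = row["log_hazard"]
        baseline[cause] = arr

    bdf = _read_csv(d, "betas.csv")
    betas: dict[str, dict[tuple[str, str], float]] = {}
    beta_sd: dict[str, dict[tuple[str, str], float]] = {}
    for _, row in bdf.iterrows():
        betas.setdefault(row["cause"], {})[(row["factor"], row["level"])] = float(row["beta"])
        if not pd.isna(row["sd"]):
            beta_sd.setdefault(row["cause"], {})[(row["factor"], row["level"])] = float(row["sd"])
    rf = RiskFunction(baseline_log_hazard=baseline, betas=betas, beta_sd=beta_sd)

    rdf = _read_csv(d, "prior_rates.csv")
    prior: dict[str, dict[str, np.ndarray]] = {}
    for hist in ("prior_chd", "prior_stroke"):
        prior[hist] = {}
        for ev in TransitionRates.PRIOR_EVENTS:
            arr = np.zeros((N_AGES, 2))
            sub = rdf[(rdf["history"] == hist) & (rdf["event"] == ev)]
            for _, row in sub.iterrows():
                arr[int(row["age"]) - AGE_MIN, SEX_INDEX[Sex(row["sex"])]] = row["rate"]
            prior[hist][ev] = arr
    cdf = _read_csv(d, "case_fatality.csv")
    cf = np.zeros((N_AGES, 2))
    for _, row in cdf.iterrows():
        cf[int(row["age"]) - AGE_MIN, SEX_INDEX[Sex(row["sex"])]] = row["fraction"]
    rates = TransitionRates(prior=prior, case_fatality=cf)

    demographics = {}
    for ses in SES_STRATA:
        ddf = _read_csv(d, f"demographics_{ses}.csv")
        counts = np.zeros((N_AGES, 2))
        for _, row in ddf.iterrows():
            counts[int(row["age"]) - AGE_MIN, SEX_INDEX[Sex(row["sex"])]] = row["count"]
        edf = _read_csv(d, f"entrants_{ses}.csv")
        entrants: dict[int, np.ndarray] = {}
        for _, row in edf.iterrows():
            entrants.setdefault(int(row["year"]), np.zeros(2))[
                SEX_INDEX[Sex(row["sex"])]
            ] = row["count"]
        pdf = _read_csv(d, f"prevalence_{ses}.csv")
        prev = np.zeros((N_AGES, 2, len(PRIOR_HISTORIES)))
        hist_idx = {h.value: i for i, h in enumerate(PRIOR_HISTORIES)}
        for _, row in pdf.iterrows():
            prev[int(row["age"]) - AGE_MIN, SEX_INDEX[Sex(row["sex"])], hist_idx[row["history"]]] = row[
                "fraction"
            ]
        demographics[ses] = Demographics(
            initial_counts=counts, entrants=entrants, prior_prevalence=prev
        )

    return CalibrationBundle(
        config=config,
        marginals=marginals,
        joints=joints,
        risk_function=rf,
        rates=rates,
        demographics=demographics,
        ses_spec=SesRiskSpec(),
    )


def bundles_equal(a: CalibrationBundle, b: CalibrationBundle) -> bool:
    """Exact equality of two bundles (used to verify lossless round trips)."""
    if a.config != b.config or a.marginals != b.marginals:
        return False
    for ses in SES_STRATA:
        if not np.array_equal(a.joints[ses], b.joints[ses]):
            return False
        da, db = a.demographics[ses], b.demographics[ses]
        if not np.array_equal(da.initial_counts, db.initial_counts):
            return False
        if sorted(da.entrants) != sorted(db.entrants):
            return False
        if any(not np.array_equal(da.entrants[y], db.entrants[y]) for y in da.entrants):
            return False
        if not np.array_equal(da.prior_prevalence, db.prior_prevalence):
            return False
    for cause in CAUSES:
        if not np.array_equal(
            a.risk_function.baseline_log_hazard[cause], b.risk_function.baseline_log_hazard[cause]
        ):
            return False
    if a.risk_function.betas != b.risk_function.betas:
        return False
    for hist in ("prior_chd", "prior_stroke"):
        for ev in TransitionRates.PRIOR_EVENTS:
            if not np.array_equal(a.rates.prior[hist][ev], b.rates.prior[hist][ev]):
                return False
    return np.array_equal(a.rates.case_fatality, b.rates.case_fatality)
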