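"""Annual-cycle population simulation.

Each cycle, CVD-free mass faces competing cause-specific probabilities for
incident CHD, incident stroke and non-CVD death; incident CHD splits into
acute deaths (case fatality) and survivors who move to the prior-CHD
compartment; stroke survivors move to prior-stroke.  Diabetes incidence is
then applied among cycle survivors (a within-compartment profile
transition), the whole population ages one year, mass reaching 95 exits,
and new 35-year-olds enter.  Entrants join at cycle end and are first at
risk the following year.

Person-years follow the standard cohort half-cycle convention: everyone
alive at cycle start contributes one person-year except in-cycle deaths,
which contribute half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import SimulationError
from .population import AGE_MIN, N_AGES, PopulationState
from .profiles import FACTORS, LEVEL_CODES, PROFILES, SEXES, Diabetes
from .risk import RiskFunction, SesRiskSpec
from .synthetic import TransitionRates

#: Tallied event types.
EVENTS: tuple[str, ...] = (
    "incident_chd",
    "chd_death",
    "stroke",
    "noncvd_death",
    "other_cvd_death",
)

_DM_COL = FACTORS.index("diabetes")
# map each diabetes=no profile index to its diabetes=yes counterpart
_DM_NO = np.flatnonzero(LEVEL_CODES[:, _DM_COL] == 0)
_DM_YES_TARGET = np.array(
    [PROFILES[i]._replace(diabetes=Diabetes.YES).index for i in _DM_NO]
)


@dataclass
class SimulationInputs:
    """Everything an annual cycle needs besides the state itself."""

    risk_function: RiskFunction
    rates: TransitionRates
    ses_spec: SesRiskSpec = field(default_factory=SesRiskSpec)
    ses_enabled: bool = False
    entrants: dict[int, np.ndarray] = field(default_factory=dict)
    entrant_joint: np.ndarray | None = None  # (2, 486); required if entrants > 0
    #: share of prior-CHD/prior-both cvd_death outflow attributed to CHD death
    chd_death_attribution: float = 1.0


@dataclass
class EventTally:
    """Event counts and person-years by (year, age, sex)."""

    years: tuple[int, ...]
    events: dict[str, np.ndarray]  # each (n_years, 60, 2)
    person_years: np.ndarray  # (n_years, 60, 2)

    def total(self, event: str, age_range: tuple[int, int] | None = None) -> float:
        arr = self.events[event]
        if age_range is not None:
            lo, hi = age_range
            arr = arr[:, lo - AGE_MIN : hi - AGE_MIN + 1]
        return float(arr.sum())

    def to_frame(self):
        """Tidy long-format DataFrame: year, age, sex, event, count."""
        import pandas as pd

        rows = []
        for yi, year in enumerate(self.years):
            for event, arr in self.events.items():
                for si, sex in enumerate(SEXES):
                    for ai in range(N_AGES):
                        rows.append((year, ai + AGE_MIN, sex.value, event, arr[yi, ai, si]))
        return pd.DataFrame(rows, columns=["year", "age", "sex", "event", "count"])

    def person_years_frame(self):
        import pandas as pd

        rows = []
        for yi, year in enumerate(self.years):
            for si, sex in enumerate(SEXES):
                for ai in range(N_AGES):
                    rows.append((year, ai + AGE_MIN, sex.value, self.person_years[yi, ai, si]))
        return pd.DataFrame(rows, columns=["year", "age", "sex", "person_years"])


class _CycleKernel:
    """Precomputed per-cell annual probabilities (time-invariant given inputs)."""

    def __init__(self, inputs: SimulationInputs) -> None:
        rf = inputs.risk_function
        h_chd = rf.hazard_grid("incident_chd")
        h_str = rf.hazard_grid("incident_stroke")
        h_nc = rf.hazard_grid("noncvd_death")
        total = h_chd + h_str + h_nc
        p_any = -np.expm1(-total)
        with np.errstate(invalid="ignore"):
            safe = np.where(total > 0, total, 1.0)
            p_chd = p_any * h_chd / safe
            p_str = p_any * h_str / safe
            p_nc = p_any * h_nc / safe
        if inputs.ses_enabled:
            rr = inputs.ses_spec.rr
            if "incident_chd" in inputs.ses_spec.applies_to:
                p_chd = np.minimum(1.0, p_chd * rr)
            if "incident_stroke" in inputs.ses_spec.applies_to:
                p_str = np.minimum(1.0, p_str * rr)
        p_sum = p_chd + p_str + p_nc
        if np.any(p_sum > 1 + 1e-12):
            ai, si, pi = (int(x) for x in np.unravel_index(np.argmax(p_sum), p_sum.shape))
            raise SimulationError(
                f"cause probabilities sum to {p_sum.max():.4f} > 1 at "
                f"(age={ai + AGE_MIN}, sex={SEXES[si].value}, profile={PROFILES[pi]})"
            )
        self.p_chd, self.p_str, self.p_nc = p_chd, p_str, p_nc
        self.p_dm = -np.expm1(-rf.hazard_grid("diabetes_incidence"))
        self.case_fatality = inputs.rates.case_fatality  # (60, 2)

        self.prior_probs: dict[str, dict[str, np.ndarray]] = {}
        for hist in ("prior_chd", "prior_stroke", "prior_both"):
            rates = inputs.rates.rates_for(hist)
            tot = sum(rates[ev] for ev in TransitionRates.PRIOR_EVENTS)
            pa = -np.expm1(-tot)
            safe = np.where(tot > 0, tot, 1.0)
            self.prior_probs[hist] = {
                ev: pa * rates[ev] / safe for ev in TransitionRates.PRIOR_EVENTS
            }
        self.inputs = inputs


def annual_cycle(
    state: PopulationState,
    inputs: SimulationInputs,
    _kernel: _CycleKernel | None = None,
):
    """Advance one year.

    Returns ``(next_state, slice)`` where ``slice`` holds per-(age, sex)
    event counts and person-years for the cycle year.  Mass is conserved:
    next total = current total - deaths + entrants - age-95 exits.
    """
    k = _kernel if _kernel is not None else _CycleKernel(inputs)
    n = state.no_cvd  # (60, 2, 486)

    chd_events = n * k.p_chd
    stroke_events = n * k.p_str
    noncvd_deaths_free = n * k.p_nc
    acute_chd_deaths = chd_events * k.case_fatality[:, :, None]
    chd_survivors = (chd_events - acute_chd_deaths).sum(axis=2)  # -> prior_chd
    stroke_survivors = stroke_events.sum(axis=2)  # -> prior_stroke

    survivors = n - chd_events - stroke_events - noncvd_deaths_free
    # diabetes incidence among cycle survivors: move mass within the profile
    # space from diabetes=no cells to the matching diabetes=yes cells
    moved = survivors[:, :, _DM_NO] * k.p_dm[:, :, _DM_NO]
    survivors[:, :, _DM_NO] -= moved
    survivors[:, :, _DM_YES_TARGET] += moved  # target indices are unique

    # prior-CVD compartment transitions
    pc, ps, pb = (state.prior[:, :, i] for i in range(3))
    probs_c = k.prior_probs["prior_chd"]
    probs_s = k.prior_probs["prior_stroke"]
    probs_b = k.prior_probs["prior_both"]
    stay_c = 1.0 - probs_c["stroke"] - probs_c["cvd_death"] - probs_c["noncvd_death"]
    stay_s = 1.0 - probs_s["recurrent_chd"] - probs_s["cvd_death"] - probs_s["noncvd_death"]
    stay_b = 1.0 - probs_b["cvd_death"] - probs_b["noncvd_death"]
    next_pc = pc * stay_c + chd_survivors
    next_ps = ps * stay_s + stroke_survivors
    next_pb = pb * stay_b + pc * probs_c["stroke"] + ps * probs_s["recurrent_chd"]

    att = k.inputs.chd_death_attribution
    cvd_deaths_chd_side = pc * probs_c["cvd_death"] + pb * probs_b["cvd_death"]
    chd_deaths = acute_chd_deaths.sum(axis=2) + att * cvd_deaths_chd_side
    other_cvd = (1 - att) * cvd_deaths_chd_side + ps * probs_s["cvd_death"]
    noncvd_deaths = (
        noncvd_deaths_free.sum(axis=2)
        + pc * probs_c["noncvd_death"]
        + ps * probs_s["noncvd_death"]
        + pb * probs_b["noncvd_death"]
    )
    strokes = stroke_events.sum(axis=2) + pc * probs_c["stroke"] + ps * probs_s["stroke"] + pb * probs_b["stroke"]

    deaths = chd_deaths + other_cvd + noncvd_deaths
    start_alive = state.alive_by_age_sex()
    person_years = start_alive - 0.5 * deaths

    tally = {
        "incident_chd": chd_events.sum(axis=2),
        "chd_death": chd_deaths,
        "stroke": strokes,
        "noncvd_death": noncvd_deaths,
        "other_cvd_death": other_cvd,
        "person_years": person_years,
    }

    # aging: shift one year up; index 59 (age 94) exits on reaching 95
    next_no_cvd = np.zeros_like(survivors)
    next_no_cvd[1:] = survivors[:-1]
    next_prior = np.zeros_like(state.prior)
    next_prior[1:, :, 0] = next_pc[:-1]
    next_prior[1:, :, 1] = next_ps[:-1]
    next_prior[1:, :, 2] = next_pb[:-1]
    exits = survivors[-1].sum() + next_pc[-1].sum() + next_ps[-1].sum() + next_pb[-1].sum()

    entrants = k.inputs.entrants.get(state.year)
    n_entrants = 0.0
    if entrants is not None and np.any(np.asarray(entrants) > 0):
        if k.inputs.entrant_joint is None:
            raise SimulationError("entrants specified without an entrant_joint")
        ej = np.asarray(k.inputs.entrant_joint, dtype=float)
        next_no_cvd[0] += np.asarray(entrants, dtype=float)[:, None] * ej
        n_entrants = float(np.sum(entrants))

    next_state = PopulationState(no_cvd=next_no_cvd, prior=next_prior, year=state.year + 1)
    expected = state.total() - float(deaths.sum()) + n_entrants - float(exits)
    if abs(next_state.total() - expected) > 1e-9 * max(1.0, expected):
        raise SimulationError(
            f"mass conservation violated in year {state.year}: "
            f"{next_state.total()!r} vs expected {expected!r}"
        )
    return next_state, tally


def simulate(
    initial: PopulationState,
    years: range,
    inputs: SimulationInputs,
) -> EventTally:
    """Run annual cycles over ``years`` and collect the event tally."""
    kernel = _CycleKernel(inputs)
    years = tuple(years)
    events = {ev: np.zeros((len(years), N_AGES, 2)) for ev in EVENTS}
    person_years = np.zeros((len(years), N_AGES, 2))
    state = initial if initial.year == years[0] else PopulationState(
        initial.no_cvd.copy(), initial.prior.copy(), years[0]
    )
    for yi, year in enumerate(years):
        if state.year != year:
            raise SimulationError(f"state year {state.year} != simulation year {year}")
        state, tally = annual_cycle(state, inputs, _kernel=kernel)
        for ev in EVENTS:
            events[ev][yi] = tally[ev]
        person_years[yi] = tally["person_years"]
    return EventTally(years=years, events=events, person_years=person_years)
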