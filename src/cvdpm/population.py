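"""Stratified population state and initial-population construction.

The simulated population is deterministic cell mass (expected persons, real
valued), not sampled individuals: the model is a cohort-proportion Markov
model and cell arithmetic makes every run exactly reproducible.  Mass lives
in single-year-of-age cells 35..94 for each sex, split between a CVD-free
compartment (stratified over the 486 risk profiles) and three prior-CVD
compartments (prior CHD, prior stroke, prior both) that carry no risk
profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exceptions import ValidationError
from .profiles import (
    FACTOR_LEVELS,
    FACTORS,
    LEVEL_CODES,
    N_PROFILES,
    PRIOR_HISTORIES,
    SEX_INDEX,
    SEXES,
    RiskProfile,
    Sex,
)

AGE_MIN = 35
AGE_MAX = 94  # inclusive; mass exits on reaching 95
N_AGES = AGE_MAX - AGE_MIN + 1
AGES = np.arange(AGE_MIN, AGE_MAX + 1)

N_HISTORIES = len(PRIOR_HISTORIES)


def age_index(age: int) -> int:
    if not AGE_MIN <= age <= AGE_MAX:
        raise ValidationError(f"age {age} outside modeled range {AGE_MIN}..{AGE_MAX}")
    return int(age) - AGE_MIN


@dataclass
class PopulationState:
    """Person counts indexed by (age, sex, compartment[, profile]).

    Attributes
    ----------
    no_cvd : ndarray, shape (60, 2, 486)
        CVD-free mass per (age, sex, risk profile).
    prior : ndarray, shape (60, 2, 3)
        Prior-CVD mass per (age, sex, history), history order
        (prior_chd, prior_stroke, prior_both).
    year : int
        Calendar year the state refers to (start of cycle).
    """

    no_cvd: np.ndarray
    prior: np.ndarray
    year: int

    def __post_init__(self) -> None:
        self.no_cvd = np.asarray(self.no_cvd, dtype=float)
        self.prior = np.asarray(self.prior, dtype=float)
        if self.no_cvd.shape != (N_AGES, 2, N_PROFILES):
            raise ValidationError(
                f"no_cvd shape {self.no_cvd.shape} != {(N_AGES, 2, N_PROFILES)}"
            )
        if self.prior.shape != (N_AGES, 2, N_HISTORIES):
            raise ValidationError(
                f"prior shape {self.prior.shape} != {(N_AGES, 2, N_HISTORIES)}"
            )
        self.validate()

    def validate(self) -> None:
        for name, arr in (("no_cvd", self.no_cvd), ("prior", self.prior)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite counts in {name}")
            if np.any(arr < 0):
                idx = tuple(int(i) for i in np.argwhere(arr < 0)[0])
                raise ValidationError(
                    f"negative count in {name} at (age={idx[0] + AGE_MIN}, "
                    f"sex={SEXES[idx[1]].value}, cell={idx[2]})"
                )

    def total(self) -> float:
        return float(self.no_cvd.sum() + self.prior.sum())

    def alive_by_age_sex(self) -> np.ndarray:
        """Total mass per (age, sex), shape (60, 2)."""
        return self.no_cvd.sum(axis=2) + self.prior.sum(axis=2)

    def copy(self) -> "PopulationState":
        return PopulationState(self.no_cvd.copy(), self.prior.copy(), self.year)


@dataclass
class Demographics:
    """Demographic inputs: initial age structure, annual entrants, prior-CVD prevalence.

    ``initial_counts`` has shape (60, 2); ``entrants`` maps calendar year to
    a length-2 array of new 35-year-olds per sex (added at the end of that
    year's cycle); ``prior_prevalence`` has shape (60, 2, 3) with fractions
    of each age-sex stratum holding each CVD history at baseline.
    """

    initial_counts: np.ndarray
    entrants: dict[int, np.ndarray] = field(default_factory=dict)
    prior_prevalence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.initial_counts = np.asarray(self.initial_counts, dtype=float)
        if self.initial_counts.shape != (N_AGES, 2):
            raise ValidationError(
                f"initial_counts shape {self.initial_counts.shape} != {(N_AGES, 2)}"
            )
        if self.prior_prevalence is None:
            self.prior_prevalence = np.zeros((N_AGES, 2, N_HISTORIES))
        self.prior_prevalence = np.asarray(self.prior_prevalence, dtype=float)
        if self.prior_prevalence.shape != (N_AGES, 2, N_HISTORIES):
            raise ValidationError(
                f"prior_prevalence shape {self.prior_prevalence.shape} != "
                f"{(N_AGES, 2, N_HISTORIES)}"
            )
        self.entrants = {int(y): np.asarray(v, dtype=float) for y, v in self.entrants.items()}
        self.validate()

    def validate(self) -> None:
        if np.any(self.initial_counts < 0):
            idx = tuple(int(i) for i in np.argwhere(self.initial_counts < 0)[0])
            raise ValidationError(
                f"negative initial count at (age={idx[0] + AGE_MIN}, "
                f"sex={SEXES[idx[1]].value})"
            )
        for y, v in self.entrants.items():
            if v.shape != (2,) or np.any(v < 0):
                raise ValidationError(f"invalid entrant counts for year {y}: {v}")
        p = self.prior_prevalence
        if np.any(p < 0) or np.any(p > 1):
            raise ValidationError("prior-CVD prevalence fractions must lie in [0, 1]")
        if np.any(p.sum(axis=2) > 1 + 1e-12):
            idx = tuple(int(i) for i in np.argwhere(p.sum(axis=2) > 1 + 1e-12)[0])
            raise ValidationError(
                f"prior-CVD prevalences sum above 1 at (age={idx[0] + AGE_MIN}, "
                f"sex={SEXES[idx[1]].value})"
            )


def joint_as_array(joint) -> np.ndarray:
    """Coerce a per-sex joint profile distribution to a (2, 486) array.

    Accepts ``{Sex: array-like of length 486}`` or
    ``{Sex: {RiskProfile: probability}}``.  Validates non-negativity and
    per-sex normalization to 1 within 1e-9.
    """
    out = np.zeros((2, N_PROFILES))
    for sex in SEXES:
        if sex not in joint:
            raise ValidationError(f"joint distribution missing sex {sex.value!r}")
        val = joint[sex]
        if isinstance(val, Mapping):
            arr = np.zeros(N_PROFILES)
            for prof, p in val.items():
                if not isinstance(prof, RiskProfile):
                    prof = RiskProfile(*prof)
                arr[prof.index] = p
        else:
            arr = np.asarray(val, dtype=float)
            if arr.shape != (N_PROFILES,):
                raise ValidationError(
                    f"joint for {sex.value} has shape {arr.shape}, expected ({N_PROFILES},)"
                )
        if np.any(arr < 0):
            i = int(np.argmin(arr))
            raise ValidationError(
                f"negative probability for {sex.value} at profile index {i}"
            )
        s = arr.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValidationError(
                f"joint distribution for {sex.value} sums to {s!r}, expected 1"
            )
        out[SEX_INDEX[sex]] = arr
    return out


def build_population(
    demographics: Demographics,
    joint,
    year: int,
) -> PopulationState:
    """Construct an initial :class:`PopulationState`.

    For each (age, sex) stratum, prior-CVD mass is the stratum count times
    the corresponding prevalence fraction; the remaining mass is distributed
    over the 486 risk profiles according to the joint distribution for that
    sex.  Total mass is preserved exactly.
    """
    jarr = joint_as_array(joint)
    counts = demographics.initial_counts
    prev = demographics.prior_prevalence
    prior = counts[:, :, None] * prev
    free = counts - prior.sum(axis=2)
    no_cvd = free[:, :, None] * jarr[None, :, :]
    return PopulationState(no_cvd=no_cvd, prior=prior, year=year)


def marginal_distribution(
    state: PopulationState,
    factor: str,
    sex: Sex | None = None,
    age_range: tuple[int, int] | None = None,
):
    """Marginal level distribution of one risk factor in the CVD-free mass.

    Returns a mapping level -> fraction over the selected (sex, age-range)
    slice of the no-CVD compartment; fractions sum to 1.
    """
    if factor not in FACTORS:
        raise ValidationError(f"unknown factor {factor!r}")
    lo, hi = age_range if age_range is not None else (AGE_MIN, AGE_MAX)
    sl = slice(age_index(lo), age_index(hi) + 1)
    mass = state.no_cvd[sl]
    if sex is not None:
        mass = mass[:, SEX_INDEX[sex] : SEX_INDEX[sex] + 1]
    total = mass.sum()
    if total <= 0:
        raise ValidationError(
            f"no CVD-free mass in selection (factor={factor}, ages {lo}..{hi})"
        )
    col = FACTORS.index(factor)
    by_profile = mass.sum(axis=(0, 1))
    out = {}
    for k, level in enumerate(FACTOR_LEVELS[factor]):
        out[level] = float(by_profile[LEVEL_CODES[:, col] == k].sum() / total)
    return out
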