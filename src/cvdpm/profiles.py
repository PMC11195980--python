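"""Risk-factor strata and the 486-cell risk-profile space.

The model stratifies the CVD-free population into every combination of six
categorical risk-factor levels: systolic blood pressure (SBP), LDL
cholesterol, HDL cholesterol, smoking status, diabetes, and body-mass index
(BMI).  With 3·3·3·3·2·3 levels this yields 486 distinct profiles per
age-sex cell.  Everything downstream (joint distributions, hazard
multipliers, counterfactual idealization) indexes into this space, so the
canonical ordering defined here is load-bearing: it is factor-major in the
order sbp, ldl, hdl, smoking, diabetes, bmi, with levels ordered from the
reference (lowest-exposure or listed-first) level upward.
"""

from __future__ import annotations

import enum
import itertools
from typing import NamedTuple

import numpy as np


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


SEXES: tuple[Sex, Sex] = (Sex.MALE, Sex.FEMALE)
SEX_INDEX = {Sex.MALE: 0, Sex.FEMALE: 1}


class SbpLevel(str, enum.Enum):
    """Systolic blood pressure stratum, mmHg."""

    LT130 = "lt130"
    S130TO139_9 = "s130to139_9"
    GE140 = "ge140"


class LdlLevel(str, enum.Enum):
    """LDL cholesterol stratum, mg/dL."""

    LT100 = "lt100"
    S100TO129_9 = "s100to129_9"
    GE130 = "ge130"


class HdlLevel(str, enum.Enum):
    """HDL cholesterol stratum, mg/dL (higher is protective)."""

    LT40 = "lt40"
    S40TO59_9 = "s40to59_9"
    GE60 = "ge60"


class Smoking(str, enum.Enum):
    NONE = "none"
    SECONDHAND = "secondhand"
    ACTIVE = "active"


class Diabetes(str, enum.Enum):
    NO = "no"
    YES = "yes"


class BmiLevel(str, enum.Enum):
    """Body-mass index stratum, kg/m²."""

    LT25 = "lt25"
    S25TO29_9 = "s25to29_9"
    GE30 = "ge30"


class Compartment(str, enum.Enum):
    """Disease-history compartment.

    ``NO_CVD`` cells carry a full :class:`RiskProfile`; the prior-CVD
    compartments depend only on age, sex, and event history.
    """

    NO_CVD = "no_cvd"
    PRIOR_CHD = "prior_chd"
    PRIOR_STROKE = "prior_stroke"
    PRIOR_BOTH = "prior_both"


#: Prior-CVD histories in array-index order.
PRIOR_HISTORIES: tuple[Compartment, ...] = (
    Compartment.PRIOR_CHD,
    Compartment.PRIOR_STROKE,
    Compartment.PRIOR_BOTH,
)
HISTORY_INDEX = {h: i for i, h in enumerate(PRIOR_HISTORIES)}

FACTORS: tuple[str, ...] = ("sbp", "ldl", "hdl", "smoking", "diabetes", "bmi")
FACTOR_ENUMS: dict[str, type[enum.Enum]] = {
    "sbp": SbpLevel,
    "ldl": LdlLevel,
    "hdl": HdlLevel,
    "smoking": Smoking,
    "diabetes": Diabetes,
    "bmi": BmiLevel,
}
FACTOR_LEVELS: dict[str, tuple[enum.Enum, ...]] = {
    f: tuple(e) for f, e in FACTOR_ENUMS.items()
}
FACTOR_SIZES: tuple[int, ...] = tuple(len(FACTOR_LEVELS[f]) for f in FACTORS)
#: Position of each level within its factor (the reference level has code 0).
LEVEL_CODE: dict[str, dict[enum.Enum, int]] = {
    f: {lvl: i for i, lvl in enumerate(levels)} for f, levels in FACTOR_LEVELS.items()
}

N_PROFILES = int(np.prod(FACTOR_SIZES))  # 486

# Continuous-factor stratum cutpoints; used for discretization and for
# locating ideal-control targets within the strata.
CUTPOINTS: dict[str, tuple[float, ...]] = {
    "sbp": (130.0, 140.0),
    "ldl": (100.0, 130.0),
    "hdl": (40.0, 60.0),
    "bmi": (25.0, 30.0),
}


class RiskProfile(NamedTuple):
    """One cell of the 486-member risk-factor space."""

    sbp: SbpLevel
    ldl: LdlLevel
    hdl: HdlLevel
    smoking: Smoking
    diabetes: Diabetes
    bmi: BmiLevel

    def codes(self) -> tuple[int, ...]:
        """Integer level codes in canonical factor order."""
        return tuple(LEVEL_CODE[f][getattr(self, f)] for f in FACTORS)

    @property
    def index(self) -> int:
        """Position of this profile in :func:`enumerate_profiles`."""
        return PROFILE_INDEX[self]


PROFILES: tuple[RiskProfile, ...] = tuple(
    RiskProfile(*combo)
    for combo in itertools.product(*(FACTOR_LEVELS[f] for f in FACTORS))
)
PROFILE_INDEX: dict[RiskProfile, int] = {p: i for i, p in enumerate(PROFILES)}

#: Integer level code of every profile, shape (486, 6), column order = FACTORS.
LEVEL_CODES: np.ndarray = np.array([p.codes() for p in PROFILES], dtype=np.int8)
LEVEL_CODES.setflags(write=False)


def enumerate_profiles() -> tuple[RiskProfile, ...]:
    """All 486 risk profiles in canonical (factor-major) order.

    The order is stable across calls and across processes: sbp varies
    slowest, bmi fastest, levels within a factor from reference upward.
    """
    return PROFILES


def profile_from_codes(codes) -> RiskProfile:
    """Inverse of :meth:`RiskProfile.codes`."""
    return RiskProfile(
        *(FACTOR_LEVELS[f][int(c)] for f, c in zip(FACTORS, codes))
    )


def factor_level_masks(factor: str) -> np.ndarray:
    """Boolean masks, shape (n_levels, 486): which profiles sit at each level."""
    col = FACTORS.index(factor)
    n = len(FACTOR_LEVELS[factor])
    return np.stack([LEVEL_CODES[:, col] == k for k in range(n)])
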