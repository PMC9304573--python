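"""Age-specific mortality for each living health state.

A general-population life table (age -> annual death probability q) is scaled
to the disease population with standardized mortality ratios (SMRs) banded by
age, and to the transplanted population with a pooled ESKD-vs-KT mortality
ratio.  Scaling is done on the hazard-rate scale, the actuarially standard
route that keeps results inside [0, 1] for any multiplier:

    q_state(age) = 1 - exp(-(-ln(1 - q_gen(age))) * m(age, state))

with m = SMR(age) for the dialysis state and m = SMR(age) / ratio for the
three post-transplant states.

Because the WHO table is an external download, a smooth synthetic stand-in
ships as the default: a Gompertz-Makeham hazard h(x) = c + a*exp(b*x) with
a = 2.40834e-5, b = 0.098983, c = 4e-4, fitted to WHO Thailand 2019 landmarks
(life expectancy ~77.5 y at birth, ~21.3 y at 60).  A real table can be
supplied as a two-column delimited file (age, q).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "MortalityModel",
    "prob_to_rate",
    "rate_to_prob",
    "make_gompertz_life_table",
    "load_life_table",
    "DIALYSIS",
    "KT",
    "POST1",
    "SUBSEQUENT",
    "DEATH",
    "STATES",
    "LIVING_STATES",
    "GOMPERTZ_A",
    "GOMPERTZ_B",
    "MAKEHAM_C",
]

# Canonical health-state labels, in transition-matrix order.
DIALYSIS = "dialysis"
KT = "kt"
POST1 = "post_kt_year1"
SUBSEQUENT = "post_kt_subsequent"
DEATH = "death"
STATES = (DIALYSIS, KT, POST1, SUBSEQUENT, DEATH)
LIVING_STATES = (DIALYSIS, KT, POST1, SUBSEQUENT)

GOMPERTZ_A = 2.40834e-05
GOMPERTZ_B = 0.098983
MAKEHAM_C = 4.0e-04


def prob_to_rate(q: float) -> float:
    """Annual probability -> constant hazard rate, -ln(1-q)."""
    if not 0.0 <= q < 1.0:
        raise ValueError(f"probability must lie in [0, 1), got {q}")
    return -math.log1p(-q)


def rate_to_prob(r: float) -> float:
    """Constant hazard rate -> annual probability, 1-exp(-r)."""
    if r < 0:
        raise ValueError(f"rate must be >= 0, got {r}")
    return -math.expm1(-r)


@dataclass(frozen=True)
class LifeTable:
    """Ordered (age, annual death probability) pairs, contiguous in age."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or ages.shape != qx.shape or len(ages) == 0:
            raise ValueError("life table needs matching 1-d age and q arrays")
        if np.any(np.diff(ages) != 1):
            raise ValueError("life-table ages must be contiguous and strictly increasing")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("life-table q values must lie in [0, 1]")

    def q(self, age: int | float) -> float:
        """Annual death probability at integer ``age``."""
        idx = int(age) - int(self.ages[0])
        if idx < 0 or idx >= len(self.ages):
            raise ValueError(
                f"age {age} outside life table [{self.ages[0]}, {self.ages[-1]}]"
            )
        return float(self.qx[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "q": self.qx})


def make_gompertz_life_table(
    a: float = GOMPERTZ_A,
    b: float = GOMPERTZ_B,
    c: float = MAKEHAM_C,
    min_age: int = 0,
    max_age: int = 110,
) -> LifeTable:
    """Synthetic life table from a Gompertz-Makeham hazard c + a*exp(b*age)."""
    ages = np.arange(min_age, max_age + 1)
    hazard = c + a * np.exp(b * ages)
    qx = np.minimum(1.0, -np.expm1(-hazard))
    return LifeTable(ages=ages, qx=qx)


def load_life_table(path) -> LifeTable:
    """Read a two-column delimited text file with header columns age, q."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    if "age" not in cols or "q" not in cols:
        raise ValueError("life-table file must have columns 'age' and 'q'")
    df = df.sort_values(cols["age"])
    return LifeTable(ages=df[cols["age"]].to_numpy(), qx=df[cols["q"]].to_numpy())


@dataclass(frozen=True)
class MortalityModel:
    """Life table + SMR age bands + pooled ESKD-vs-KT mortality ratio."""

    life_table: LifeTable
    smr_bands: tuple[tuple[float, float, float], ...]  # (age_low, age_high, smr)
    eskd_vs_kt_ratio: float

    def __post_init__(self) -> None:
        bands = tuple(sorted(self.smr_bands))
        object.__setattr__(self, "smr_bands", bands)
        if self.eskd_vs_kt_ratio <= 0:
            raise ValueError("eskd_vs_kt_ratio must be > 0")
        for lo, hi, smr in bands:
            if smr <= 0:
                raise ValueError("all SMRs must be > 0")
            if hi < lo:
                raise ValueError(f"band ({lo}, {hi}) inverted")
        for (l0, h0, _), (l1, _, _) in zip(bands, bands[1:]):
            if l1 != h0 + 1:
                raise ValueError("SMR bands must tile the age range without gaps/overlaps")

    @classmethod
    def from_parameters(cls, params, life_table: LifeTable | None = None) -> "MortalityModel":
        """Build from a :class:`~ktcea.parameters.ParameterSet`."""
        lt = life_table if life_table is not None else make_gompertz_life_table()
        bands = (
            (0.0, 59.0, params.value("smr_50_59")),
            (60.0, 69.0, params.value("smr_60_69")),
            (70.0, 79.0, params.value("smr_70_79")),
            (80.0, math.inf, params.value("smr_80_plus")),
        )
        return cls(
            life_table=lt,
            smr_bands=bands,
            eskd_vs_kt_ratio=params.value("eskd_vs_kt_mortality_ratio"),
        )

    def smr(self, age: float) -> float:
        for lo, hi, smr in self.smr_bands:
            if lo <= age <= hi:
                return smr
        raise ValueError(f"age {age} outside SMR bands")

    def death_prob(self, age: float, state: str) -> float:
        """Annual death probability at ``age`` for a living health state."""
        if state not in LIVING_STATES:
            raise ValueError(f"{state!r} is not a living health state")
        rate = prob_to_rate(self.life_table.q(age))
        mult = self.smr(age)
        if state != DIALYSIS:
            mult /= self.eskd_vs_kt_ratio
        return min(1.0, rate_to_prob(rate * mult))
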