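"""Age- and sex-specific annual mortality.

A :class:`LifeTable` holds annual death probabilities (qx) indexed by
integer age, one array per sex, in the layout of a period life table.
Tables can be read from CSV (columns ``age,qx_male,qx_female``) or built
synthetically from a Gompertz hazard so the package never requires a
download.  The packaged default is a Gompertz surrogate calibrated so
that ten-year survival from age 67 matches the cohort the model was
built around (~0.65); it is NOT actuarial data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain import ValidationError

__all__ = [
    "LifeTable",
    "load_life_table",
    "gompertz_table",
    "death_probability",
    "default_life_table",
    "LifeTableError",
]

log = logging.getLogger(__name__)


class LifeTableError(ValueError):
    """Malformed life-table input."""


@dataclass
class LifeTable:
    """qx arrays indexed by integer age 0..max_age; beyond-table lookups
    return 1 (certain death)."""

    qx_male: np.ndarray
    qx_female: np.ndarray

    def __post_init__(self) -> None:
        self.qx_male = np.asarray(self.qx_male, dtype=float)
        self.qx_female = np.asarray(self.qx_female, dtype=float)
        if self.qx_male.shape != self.qx_female.shape or self.qx_male.ndim != 1:
            raise LifeTableError("qx arrays must be 1-D and of equal length")
        if self.qx_male.size == 0:
            raise LifeTableError("life table is empty")
        for name, qx in (("qx_male", self.qx_male), ("qx_female", self.qx_female)):
            bad = np.flatnonzero((qx < 0) | (qx > 1) | ~np.isfinite(qx))
            if bad.size:
                raise LifeTableError(
                    f"{name} outside [0, 1] at age {int(bad[0])}: {qx[bad[0]]}"
                )
        if self.qx_male[-1] != 1.0 or self.qx_female[-1] != 1.0:
            log.warning("life table final row forced to qx = 1 at age %d", self.max_age)
            self.qx_male = self.qx_male.copy()
            self.qx_female = self.qx_female.copy()
            self.qx_male[-1] = 1.0
            self.qx_female[-1] = 1.0

    @property
    def max_age(self) -> int:
        return self.qx_male.size - 1

    def qx(self, age: float, male: bool) -> float:
        if age < 0 or not math.isfinite(age):
            raise ValidationError(f"age must be finite and >= 0: {age}")
        i = int(math.floor(age))
        if i > self.max_age:
            return 1.0
        return float(self.qx_male[i] if male else self.qx_female[i])

    def survival_curve(self, from_age: int, years: int, male: bool) -> np.ndarray:
        """Cumulative survival probability after 1..years annual cycles,
        where each cycle ages first and then draws death at the new age."""
        probs = [self.qx(from_age + k, male) for k in range(1, years + 1)]
        return np.cumprod(1.0 - np.array(probs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": np.arange(self.qx_male.size),
                "qx_male": self.qx_male,
                "qx_female": self.qx_female,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_life_table(path) -> LifeTable:
    """Read a life table from CSV with header ``age,qx_male,qx_female``.

    Ages must be contiguous integers starting at 0.  A final row with
    qx < 1 is forced to 1 with a logged warning.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise LifeTableError(f"could not parse life table {path}: {exc}") from exc
    required = {"age", "qx_male", "qx_female"}
    if not required.issubset(df.columns):
        raise LifeTableError(
            f"life table missing columns: {sorted(required - set(df.columns))}"
        )
    ages = df["age"].to_numpy()
    expected = np.arange(len(df))
    if not np.array_equal(ages, expected):
        first_bad = int(np.flatnonzero(ages != expected)[0])
        raise LifeTableError(
            f"ages must be contiguous from 0; row {first_bad} has age {ages[first_bad]}"
        )
    return LifeTable(df["qx_male"].to_numpy(float), df["qx_female"].to_numpy(float))


def gompertz_table(
    a: float,
    b: float,
    max_age: int = 120,
    a_female: float | None = None,
    b_female: float | None = None,
) -> LifeTable:
    """Synthetic table with qx(age) = 1 - exp(-a * exp(b * age)).

    ``a`` is the baseline annual hazard and ``b`` the log-hazard slope per
    year of age; optional female-specific parameters default to the male
    ones.  The final row is qx = 1 by construction of :class:`LifeTable`.
    """
    if a <= 0 or b < 0:
        raise ValidationError(f"require a > 0 and b >= 0, got a={a}, b={b}")
    ages = np.arange(max_age + 1)

    def qx(aa: float, bb: float) -> np.ndarray:
        return np.clip(1.0 - np.exp(-aa * np.exp(bb * ages)), 0.0, 1.0)

    qm = qx(a, b)
    qf = qx(a_female if a_female is not None else a, b_female if b_female is not None else b)
    qm[-1] = qf[-1] = 1.0
    return LifeTable(qm, qf)


#: Calibration anchors of the packaged default table: ten-year survival of
#: a 67-year-old male of roughly 0.65 (matching the source cohort's
#: realized survival 327/501) at a conventional Gompertz slope.
DEFAULT_GOMPERTZ_B = 0.085
DEFAULT_SURVIVAL_TARGET = 327.0 / 501.0
DEFAULT_ANCHOR_AGE = 67
DEFAULT_ANCHOR_YEARS = 10


def default_life_table(
    target_survival: float = DEFAULT_SURVIVAL_TARGET,
    anchor_age: int = DEFAULT_ANCHOR_AGE,
    anchor_years: int = DEFAULT_ANCHOR_YEARS,
    b: float = DEFAULT_GOMPERTZ_B,
    max_age: int = 120,
) -> LifeTable:
    """Gompertz surrogate whose survival from ``anchor_age`` over
    ``anchor_years`` cycles equals ``target_survival`` in closed form:
    prod exp(-a e^{b age}) = exp(-a sum e^{b age})."""
    ages = np.arange(anchor_age + 1, anchor_age + anchor_years + 1)
    a = -math.log(target_survival) / float(np.sum(np.exp(b * ages)))
    return gompertz_table(a, b, max_age=max_age)


def death_probability(table: LifeTable, age: float, male: bool) -> float:
    """Annual death probability at floor(age) for the given sex; ages past
    the table return 1."""
    return table.qx(age, male)
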