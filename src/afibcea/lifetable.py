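"""Sex-specific annual life tables.

The cohort model draws its background mortality from an annual all-cause
life table, ideally cause-deleted for stroke and heart failure so that
event-attributable mortality added on the hazard scale is not double
counted. The CSV schema is strict: columns ``age``, ``sex``
(``male``/``female``) and ``annual_mortality``, one row per age/sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("age", "sex", "annual_mortality")
SEXES = ("male", "female")


class LifeTableError(ValueError):
    pass


@dataclass
class LifeTable:
    """Annual all-cause mortality probability per integer age and sex."""

    ages: np.ndarray
    q_male: np.ndarray
    q_female: np.ndarray
    cause_deleted: bool = True

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.q_male = np.asarray(self.q_male, dtype=float)
        self.q_female = np.asarray(self.q_female, dtype=float)
        if not (len(self.ages) == len(self.q_male) == len(self.q_female)):
            raise LifeTableError("age and mortality columns have unequal length")
        if len(self.ages) == 0:
            raise LifeTableError("life table is empty")
        if np.any(np.diff(self.ages) != 1):
            raise LifeTableError("ages must be consecutive integers")
        for name, q in (("male", self.q_male), ("female", self.q_female)):
            if np.any((q < 0) | (q > 1)):
                raise LifeTableError(f"{name} annual mortality outside [0, 1]")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual_mortality(self, age: float, sex: str) -> float:
        """Annual death probability at (floored) age for one sex."""
        idx = int(np.floor(age)) - self.min_age
        if idx < 0 or idx >= len(self.ages):
            raise LifeTableError(
                f"age {age} outside life-table support [{self.min_age}, {self.max_age}]"
            )
        if sex == "male":
            return float(self.q_male[idx])
        if sex == "female":
            return float(self.q_female[idx])
        raise LifeTableError(f"unknown sex {sex!r}")

    def sex_weighted(self, age: float, male_fraction: float) -> float:
        """Cohort annual mortality, weighting the sex-specific columns."""
        return male_fraction * self.annual_mortality(age, "male") + (
            1.0 - male_fraction
        ) * self.annual_mortality(age, "female")

    # -- CSV round trip ----------------------------------------------------

    @classmethod
    def from_csv(cls, path, cause_deleted: bool = True) -> "LifeTable":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise LifeTableError(f"life table {path} missing columns {missing}")
        bad_sex = set(df["sex"].unique()) - set(SEXES)
        if bad_sex:
            raise LifeTableError(f"unknown sex labels {sorted(bad_sex)}")
        if df.duplicated(subset=["age", "sex"]).any():
            raise LifeTableError("life table has duplicate age/sex rows")
        wide = df.pivot(index="age", columns="sex", values="annual_mortality").sort_index()
        if wide.isna().any().any():
            raise LifeTableError("life table must cover every age for both sexes")
        return cls(
            ages=wide.index.to_numpy(),
            q_male=wide["male"].to_numpy(),
            q_female=wide["female"].to_numpy(),
            cause_deleted=cause_deleted,
        )

    def to_csv(self, path) -> None:
        rows = []
        for sex, q in (("male", self.q_male), ("female", self.q_female)):
            for age, qi in zip(self.ages, q):
                rows.append({"age": int(age), "sex": sex, "annual_mortality": float(qi)})
        pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "male": self.q_male, "female": self.q_female}
        )
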