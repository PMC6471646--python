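"""BMI-for-age growth assessment against LMS reference tables.

A child's BMI is located on a sex- and age-specific reference distribution
described by the LMS parameters (L: Box-Cox power, M: median, S: coefficient
of variation).  The resulting z-score is converted to a percentile with the
standard normal CDF and classified with the 5th/85th/95th percentile cutoffs
(underweight / normal weight / overweight / obese).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DomainError, TableRangeError

#: Mean Gregorian month length in days, used to convert day counts to months.
DAYS_PER_MONTH = 30.4375

#: Below this |L| the Box-Cox transform is replaced by its log limit.
LOG_BRANCH_L = 1e-8

#: |z| beyond this triggers a plausibility warning (no capping is applied).
Z_PLAUSIBILITY_LIMIT = 5.0


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class MeasurementMode(str, enum.Enum):
    recumbent_length = "recumbent_length"
    standing_height = "standing_height"


class WeightCategory(str, enum.Enum):
    underweight = "underweight"
    normal = "normal"
    overweight = "overweight"
    obese = "obese"


@dataclass(frozen=True)
class Anthropometry:
    """One weight/height measurement pair.

    Recumbent length is only valid for children younger than 24 months;
    that age-dependent rule is enforced where the age is known (record
    validation and :func:`assess_weight_status`).
    """

    weight_kg: float
    height_cm: float
    measurement_mode: MeasurementMode = MeasurementMode.standing_height

    def __post_init__(self) -> None:
        if not self.weight_kg > 0:
            raise DomainError(f"weight_kg must be positive, got {self.weight_kg}")
        if not self.height_cm > 0:
            raise DomainError(f"height_cm must be positive, got {self.height_cm}")


@dataclass(frozen=True)
class WeightStatus:
    """Outcome of a BMI-for-age assessment."""

    category: WeightCategory
    bmi: float
    zscore: float
    percentile: float


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Quetelet's index: weight (kg) divided by squared height (m)."""
    if not weight_kg > 0:
        raise DomainError(f"weight_kg must be positive, got {weight_kg}")
    if not height_cm > 0:
        raise DomainError(f"height_cm must be positive, got {height_cm}")
    height_m = height_cm / 100.0
    return weight_kg / (height_m * height_m)


def age_in_months(birth_date: date, exam_date: date) -> float:
    """Real-valued age in months (days elapsed / 30.4375)."""
    if exam_date < birth_date:
        raise DomainError(
            f"exam_date {exam_date} precedes birth_date {birth_date}"
        )
    return (exam_date - birth_date).days / DAYS_PER_MONTH


def age_in_years(birth_date: date, exam_date: date) -> int:
    """Completed (integer-truncated) years of age."""
    return int(age_in_months(birth_date, exam_date) / 12.0)


def lms_zscore(bmi: float, L: float, M: float, S: float) -> float:
    """Box-Cox (LMS) z-score of ``bmi`` against reference parameters.

    z = ((bmi/M)^L - 1) / (L*S) for |L| above the log-branch threshold,
    and z = ln(bmi/M)/S in the L -> 0 limit; the two branches agree to
    numerical precision at the threshold.
    """
    if not bmi > 0:
        raise DomainError(f"bmi must be positive, got {bmi}")
    if not M > 0:
        raise DomainError(f"M must be positive, got {M}")
    if not S > 0:
        raise DomainError(f"S must be positive, got {S}")
    ratio = bmi / M
    if abs(L) > LOG_BRANCH_L:
        # expm1 form of ((bmi/M)^L - 1)/(L*S): avoids cancellation as L -> 0
        return math.expm1(L * math.log(ratio)) / (L * S)
    return math.log(ratio) / S


def bmi_from_zscore(z: float, L: float, M: float, S: float) -> float:
    """Inverse LMS transform: the BMI whose z-score is ``z``."""
    if not M > 0:
        raise DomainError(f"M must be positive, got {M}")
    if not S > 0:
        raise DomainError(f"S must be positive, got {S}")
    if abs(L) > LOG_BRANCH_L:
        if 1.0 + L * S * z <= 0:
            raise DomainError(f"z={z} is outside the Box-Cox support for L={L}, S={S}")
        # log1p form of M*(1 + L*S*z)^(1/L), stable as L -> 0
        return M * math.exp(math.log1p(L * S * z) / L)
    return M * math.exp(S * z)


def percentile_from_zscore(z: float) -> float:
    """Percentile (0-100) via the exact standard normal CDF."""
    return float(norm.cdf(z) * 100.0)


def classify_weight_status(percentile: float) -> WeightCategory:
    """Percentile cutoffs: <5 underweight, [5,85) normal, [85,95) overweight,
    >=95 obese (left-closed, right-open)."""
    if not 0.0 < percentile < 100.0:
        raise DomainError(f"percentile must lie in (0, 100), got {percentile}")
    if percentile < 5.0:
        return WeightCategory.underweight
    if percentile < 85.0:
        return WeightCategory.normal
    if percentile < 95.0:
        return WeightCategory.overweight
    return WeightCategory.obese


@dataclass
class LMSReferenceTable:
    """Sex- and age-indexed L/M/S parameters with linear age interpolation.

    The TSV interchange format has the header
    ``sex\tage_months\tL\tM\tS``; one file may hold both sexes.
    """

    frames: dict[Sex, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sex, frame in self.frames.items():
            ages = frame["age_months"].to_numpy(dtype=float)
            if len(ages) == 0:
                raise DomainError(f"empty LMS table for sex={sex.value}")
            if not np.all(np.diff(ages) > 0):
                raise DomainError(f"ages must be strictly increasing for sex={sex.value}")
            if not (frame["M"] > 0).all():
                raise DomainError("M values must be positive")
            if not (frame["S"] > 0).all():
                raise DomainError("S values must be positive")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LMSReferenceTable":
        required = {"sex", "age_months", "L", "M", "S"}
        missing = required - set(df.columns)
        if missing:
            raise DomainError(f"LMS table missing columns: {sorted(missing)}")
        frames: dict[Sex, pd.DataFrame] = {}
        for sex_value, sub in df.groupby("sex"):
            sex = Sex(str(sex_value))
            frames[sex] = (
                sub[["age_months", "L", "M", "S"]]
                .astype(float)
                .sort_values("age_months")
                .reset_index(drop=True)
            )
        return cls(frames)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LMSReferenceTable":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"))

    def age_range(self, sex: Sex) -> tuple[float, float]:
        frame = self._frame(sex)
        ages = frame["age_months"]
        return float(ages.iloc[0]), float(ages.iloc[-1])

    def _frame(self, sex: Sex) -> pd.DataFrame:
        try:
            return self.frames[Sex(sex)]
        except KeyError:
            raise TableRangeError(f"no LMS rows for sex={sex}") from None

    def lookup(self, sex: Sex, age_months: float) -> tuple[float, float, float]:
        """Linearly interpolated (L, M, S) at ``age_months``."""
        frame = self._frame(sex)
        ages = frame["age_months"].to_numpy(dtype=float)
        if age_months < ages[0] or age_months > ages[-1]:
            raise TableRangeError(
                f"age {age_months:.2f} months outside LMS table range "
                f"[{ages[0]:.1f}, {ages[-1]:.1f}] for sex={Sex(sex).value}"
            )
        L = float(np.interp(age_months, ages, frame["L"].to_numpy(dtype=float)))
        M = float(np.interp(age_months, ages, frame["M"].to_numpy(dtype=float)))
        S = float(np.interp(age_months, ages, frame["S"].to_numpy(dtype=float)))
        return L, M, S


def load_synthetic_reference() -> LMSReferenceTable:
    """Packaged synthetic LMS fixture table.

    Smooth and monotone but NOT the WHO reference values; real growth
    references are a drop-in TSV supplied by the user.
    """
    path = Path(__file__).parent / "data" / "lms_synthetic.tsv"
    return LMSReferenceTable.from_tsv(path)


def assess_weight_status(
    anthropometry: Anthropometry,
    sex: Sex,
    age_months: float,
    table: LMSReferenceTable,
) -> WeightStatus:
    """Full level-1 assessment: BMI -> z-score -> percentile -> category."""
    if (
        anthropometry.measurement_mode is MeasurementMode.recumbent_length
        and age_months >= 24.0
    ):
        raise DomainError(
            "recumbent length is only valid before 24 months of age "
            f"(age is {age_months:.1f} months)"
        )
    bmi = compute_bmi(anthropometry.weight_kg, anthropometry.height_cm)
    L, M, S = table.lookup(sex, age_months)
    z = lms_zscore(bmi, L, M, S)
    if abs(z) > Z_PLAUSIBILITY_LIMIT:
        warnings.warn(
            f"BMI-for-age z-score {z:.2f} exceeds the plausibility limit of "
            f"|z| <= {Z_PLAUSIBILITY_LIMIT:g}; value reported uncapped",
            stacklevel=2,
        )
    percentile = percentile_from_zscore(z)
    return WeightStatus(
        category=classify_weight_status(percentile),
        bmi=bmi,
        zscore=z,
        percentile=percentile,
    )
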