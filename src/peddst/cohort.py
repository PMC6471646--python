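"""Synthetic family cohorts and trial-arithmetic helpers.

The generator emulates the baseline population of the evaluation trial:
6-12-year-old overweight or obese children (about 39%/61% mix) with the
published means for age, BMI, parental BMI, birth weight, daily activity
time and maternal pre-pregnancy BMI.  Only means, standard errors and
percentages are published, so continuous variables are drawn from truncated
normals whose location is solved so that the *post-truncation* mean equals
the target (the module's contract is moment matching, not distributional
fidelity); SDs are recovered from the printed SEMs via SD = SEM * sqrt(n).

Weight status is generated consistently with the reference table used for
classification: a status category is drawn first, then a BMI-for-age
percentile inside that category's band, and BMI follows from the inverse
LMS transform — so every generated child classifies back into the drawn
category.

The deterministic change-score arithmetic used on trial summary tables
(within-group change, between-group difference, attrition and enrolment
planning) also lives here; the trial's inferential statistics are
deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterator, Optional

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from .energy import ActivityCategory
from .errors import DomainError
from .growth import LMSReferenceTable, Sex, bmi_from_zscore, load_synthetic_reference
from .records import (
    AnthropometrySource,
    ChildRecord,
    Family,
    ParentRecord,
    ParentRole,
    PerinatalRecord,
)

#: Reference sample size behind the printed SEMs.
REFERENCE_N = 65


@dataclass(frozen=True)
class TruncatedNormalSpec:
    """Mean-matched truncated normal: the location is solved so the mean of
    the truncated distribution equals ``mean`` despite the bounds."""

    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise DomainError(f"sd must be positive, got {self.sd}")
        if not self.low < self.high:
            raise DomainError("low must be below high")
        if not self.low <= self.mean <= self.high:
            raise DomainError(
                f"target mean {self.mean} outside bounds [{self.low}, {self.high}]"
            )

    def _solved_loc(self) -> float:
        def gap(loc: float) -> float:
            a = (self.low - loc) / self.sd
            b = (self.high - loc) / self.sd
            return truncnorm.mean(a, b, loc=loc, scale=self.sd) - self.mean

        span = 10.0 * self.sd
        return brentq(gap, self.low - span, self.high + span)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        loc = self._solved_loc()
        a = (self.low - loc) / self.sd
        b = (self.high - loc) / self.sd
        return truncnorm.rvs(a, b, loc=loc, scale=self.sd, size=n, random_state=rng)


def _sem_sd(sem: float, n: int = REFERENCE_N) -> float:
    return sem * math.sqrt(n)


@dataclass
class CohortSpec:
    """Distribution parameters of the synthetic baseline population.

    Defaults reproduce the trial's total-sample baseline: means with SDs
    recovered from printed SEMs (n = 65), the 39.3/60.7% overweight/obese
    mix, and the trial's 6-12-year age window.  Quantities the trial does
    not print (smoking prevalence, disorder prevalences, parental heights,
    the infant weight-gain distribution) use documented field-plausible
    defaults.
    """

    n_children: int = 65
    female_fraction: float = 0.5
    exam_date: date = date(2018, 5, 15)

    age_years: TruncatedNormalSpec = field(
        default_factory=lambda: TruncatedNormalSpec(9.7, _sem_sd(0.2), 6.0, 12.0)
    )
    #: Weight-status mix; fractions must sum to 1.
    underweight_fraction: float = 0.0
    normal_fraction: float = 0.0
    overweight_fraction: float = 0.393
    obese_fraction: float = 0.607
    #: Upper percentile bound for obese draws (plausibility cap).
    max_percentile: float = 99.9

    height_slope_cm_per_year: float = 6.0
    height_at_mean_age_cm: float = 142.4
    height_residual_sd_cm: float = 5.9

    waist_at_mean_bmi_cm: float = 79.9
    waist_slope_cm_per_bmi: float = 2.2
    waist_residual_sd_cm: float = 4.0

    activity_min_day: TruncatedNormalSpec = field(
        default_factory=lambda: TruncatedNormalSpec(21.6, _sem_sd(2.3), 0.0, 120.0)
    )
    #: Daily activity minutes at or above these thresholds map to
    #: moderate / vigorous categories.
    moderate_minutes: float = 30.0
    vigorous_minutes: float = 60.0

    hyperglycaemia_p: float = 0.05
    insulin_resistance_p: float = 0.15
    dyslipidaemia_p: float = 0.10
    hypertension_p: float = 0.10

    father_bmi: TruncatedNormalSpec = field(
        default_factory=lambda: TruncatedNormalSpec(28.6, _sem_sd(0.4), 17.0, 45.0)
    )
    mother_bmi: TruncatedNormalSpec = field(
        default_factory=lambda: TruncatedNormalSpec(27.3, _sem_sd(0.4), 16.0, 45.0)
    )
    father_height: TruncatedNormalSpec = field(
        default_factory=lambda: TruncatedNormalSpec(178.0, 7.0, 155.0, 200.0)
    )
    mother_height: TruncatedNormalSpec = field(
        default_factory=lambda: TruncatedNormalSpec(165.0, 6.5, 145.0, 190.0)
    )
    #: Maternal education mix: P(<9 y), P(9-12 y), P(>12 y).
    education_mix: tuple[float, float, float] = (0.246, 0.328, 0.426)

    maternal_prepregnancy_bmi: TruncatedNormalSpec = field(
        default_factory=lambda: TruncatedNormalSpec(24.9, _sem_sd(0.4), 15.0, 45.0)
    )
    maternal_smoking_p: float = 0.30
    birth_weight_kg: TruncatedNormalSpec = field(
        default_factory=lambda: TruncatedNormalSpec(3.2, _sem_sd(0.1), 1.5, 5.5)
    )
    weight_gain_0_6mo_kg: TruncatedNormalSpec = field(
        default_factory=lambda: TruncatedNormalSpec(4.0, 0.8, 1.8, 7.0)
    )

    def __post_init__(self) -> None:
        if self.n_children <= 0:
            raise DomainError("n_children must be positive")
        fractions = (
            self.underweight_fraction,
            self.normal_fraction,
            self.overweight_fraction,
            self.obese_fraction,
        )
        if any(not 0.0 <= f <= 1.0 for f in fractions):
            raise DomainError("status fractions must lie in [0, 1]")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise DomainError(f"status fractions sum to {sum(fractions)}, expected 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise DomainError("female_fraction must lie in [0, 1]")
        if abs(sum(self.education_mix) - 1.0) > 1e-9:
            raise DomainError("education_mix must sum to 1")


#: Percentile bands per status category (left-closed, right-open; the obese
#: band's upper bound comes from CohortSpec.max_percentile).
_STATUS_BANDS = {
    "underweight": (0.5, 5.0),
    "normal": (5.0, 85.0),
    "overweight": (85.0, 95.0),
    "obese": (95.0, None),
}


def generate_cohort(
    spec: CohortSpec,
    seed: int,
    table: Optional[LMSReferenceTable] = None,
) -> list[Family]:
    """Generate ``spec.n_children`` families, reproducibly under ``seed``."""
    rng = np.random.default_rng(seed)
    table = table or load_synthetic_reference()
    n = spec.n_children

    sexes = np.where(
        rng.random(n) < spec.female_fraction, Sex.female.value, Sex.male.value
    )
    ages = spec.age_years.sample(n, rng)
    statuses = rng.choice(
        ["underweight", "normal", "overweight", "obese"],
        size=n,
        p=[
            spec.underweight_fraction,
            spec.normal_fraction,
            spec.overweight_fraction,
            spec.obese_fraction,
        ],
    )
    heights = spec.height_at_mean_age_cm + spec.height_slope_cm_per_year * (
        ages - spec.age_years.mean
    ) + rng.normal(0.0, spec.height_residual_sd_cm, size=n)
    heights = np.clip(heights, 95.0, 190.0)

    activity_minutes = spec.activity_min_day.sample(n, rng)
    disorder_draws = rng.random((n, 4))
    smoking = rng.random(n) < spec.maternal_smoking_p
    birth_weights = spec.birth_weight_kg.sample(n, rng)
    gains = spec.weight_gain_0_6mo_kg.sample(n, rng)
    prepreg = spec.maternal_prepregnancy_bmi.sample(n, rng)
    father_bmis = spec.father_bmi.sample(n, rng)
    mother_bmis = spec.mother_bmi.sample(n, rng)
    father_heights = spec.father_height.sample(n, rng)
    mother_heights = spec.mother_height.sample(n, rng)
    education_cat = rng.choice(3, size=n, p=list(spec.education_mix))

    families: list[Family] = []
    for i in range(n):
        sex = Sex(sexes[i])
        age_months = float(ages[i]) * 12.0
        birth_date = spec.exam_date - timedelta(days=round(age_months * 30.4375))

        lo, hi = _STATUS_BANDS[statuses[i]]
        hi = spec.max_percentile if hi is None else hi
        pct = rng.uniform(lo, hi)
        L, M, S = table.lookup(sex, age_months)
        bmi = bmi_from_zscore(float(norm.ppf(pct / 100.0)), L, M, S)
        height_cm = float(heights[i])
        weight_kg = bmi * (height_cm / 100.0) ** 2
        waist = (
            spec.waist_at_mean_bmi_cm
            + spec.waist_slope_cm_per_bmi * (bmi - 25.1)
            + rng.normal(0.0, spec.waist_residual_sd_cm)
        )
        minutes = float(activity_minutes[i])
        if minutes >= spec.vigorous_minutes:
            activity = ActivityCategory.vigorous
        elif minutes >= spec.moderate_minutes:
            activity = ActivityCategory.moderate
        else:
            activity = ActivityCategory.light

        if education_cat[i] == 0:
            education = float(rng.integers(6, 9))
        elif education_cat[i] == 1:
            education = float(rng.integers(9, 13))
        else:
            education = float(rng.integers(13, 19))

        child = ChildRecord(
            id=f"syn-{i:04d}",
            sex=sex,
            birth_date=birth_date,
            exam_date=spec.exam_date,
            # full precision keeps classification exactly consistent with the
            # drawn percentile band (rounding can flip boundary draws)
            weight_kg=weight_kg,
            height_cm=height_cm,
            waist_cm=round(max(waist, 40.0), 1),
            activity=activity,
            hyperglycaemia=bool(disorder_draws[i, 0] < spec.hyperglycaemia_p),
            insulin_resistance=bool(disorder_draws[i, 1] < spec.insulin_resistance_p),
            dyslipidaemia=bool(disorder_draws[i, 2] < spec.dyslipidaemia_p),
            hypertension=bool(disorder_draws[i, 3] < spec.hypertension_p),
            perinatal=PerinatalRecord(
                maternal_prepregnancy_bmi=float(prepreg[i]),
                maternal_smoking_pregnancy=bool(smoking[i]),
                birth_weight_kg=float(birth_weights[i]),
                weight_6mo_kg=float(birth_weights[i] + gains[i]),
            ),
        )
        mother = ParentRecord(
            role=ParentRole.mother,
            weight_kg=float(mother_bmis[i]) * (float(mother_heights[i]) / 100.0) ** 2,
            height_cm=float(mother_heights[i]),
            education_years=education,
            source=AnthropometrySource.measured,
        )
        father = ParentRecord(
            role=ParentRole.father,
            weight_kg=float(father_bmis[i]) * (float(father_heights[i]) / 100.0) ** 2,
            height_cm=float(father_heights[i]),
            source=AnthropometrySource.measured,
        )
        families.append(Family(child=child, mother=mother, father=father))
    return families


# ---------------------------------------------------------------------------
# Stratified generator covering the full decision table


def stratified_families(
    table: Optional[LMSReferenceTable] = None,
    exam_date: date = date(2018, 5, 15),
) -> Iterator[tuple[Family, dict]]:
    """Yield one family per non-referral decision-table cell.

    Cells span weight status (normal at both risk levels, overweight, obese)
    x disorder presence x parental obesity, with obese children generated in
    both the 2-5 and 6-15-year bands.  Yields ``(family, cell)`` where
    ``cell`` names the targeted configuration.
    """
    table = table or load_synthetic_reference()
    counter = 0

    def build(
        age_years: float,
        status: str,
        core_high: Optional[bool],
        disorder: bool,
        obese_parent: bool,
    ) -> Family:
        nonlocal counter
        sex = Sex.male if counter % 2 == 0 else Sex.female
        age_months = age_years * 12.0
        representative_pct = {
            "normal": 50.0,
            "overweight": 90.0,
            "obese": 97.0,
        }[status]
        L, M, S = table.lookup(sex, age_months)
        bmi = bmi_from_zscore(float(norm.ppf(representative_pct / 100.0)), L, M, S)
        height_cm = 75.0 + 6.5 * age_years
        weight_kg = bmi * (height_cm / 100.0) ** 2
        if core_high:
            perinatal = PerinatalRecord(
                maternal_prepregnancy_bmi=31.0,
                maternal_smoking_pregnancy=True,
                birth_weight_kg=3.2,
                weight_6mo_kg=8.2,
            )
            education = 8.0
        else:
            perinatal = PerinatalRecord(
                maternal_prepregnancy_bmi=22.0,
                maternal_smoking_pregnancy=False,
                birth_weight_kg=3.2,
                weight_6mo_kg=6.7,
            )
            education = 14.0
        mother = ParentRecord(
            role=ParentRole.mother,
            weight_kg=24.0 * 1.65**2,
            height_cm=165.0,
            education_years=education,
        )
        father_bmi = 33.0 if obese_parent else 24.0
        father = ParentRecord(
            role=ParentRole.father,
            weight_kg=father_bmi * 1.78**2,
            height_cm=178.0,
        )
        child = ChildRecord(
            id=f"strat-{counter:03d}",
            sex=sex,
            birth_date=exam_date - timedelta(days=round(age_months * 30.4375)),
            exam_date=exam_date,
            weight_kg=round(weight_kg, 2),
            height_cm=round(height_cm, 1),
            activity=ActivityCategory.moderate,
            dyslipidaemia=disorder,
            perinatal=perinatal,
        )
        counter += 1
        return Family(child=child, mother=mother, father=father)

    for disorder in (False, True):
        for obese_parent in (False, True):
            for risk in (False, True):
                yield (
                    build(10.0, "normal", risk, disorder, obese_parent),
                    {
                        "status": "normal",
                        "core_high": risk,
                        "disorder": disorder,
                        "obese_parent": obese_parent,
                        "age_band": "y6_15",
                    },
                )
            yield (
                build(10.0, "overweight", None, disorder, obese_parent),
                {
                    "status": "overweight",
                    "core_high": None,
                    "disorder": disorder,
                    "obese_parent": obese_parent,
                    "age_band": "y6_15",
                },
            )
            for age_years, band in ((4.0, "y2_5"), (10.0, "y6_15")):
                yield (
                    build(age_years, "obese", None, disorder, obese_parent),
                    {
                        "status": "obese",
                        "core_high": None,
                        "disorder": disorder,
                        "obese_parent": obese_parent,
                        "age_band": band,
                    },
                )


# ---------------------------------------------------------------------------
# Change-score and trial arithmetic


def change_score(baseline_mean: float, followup_mean: float) -> float:
    """Within-group change: follow-up minus baseline."""
    return followup_mean - baseline_mean


def between_group_difference(ig_change: float, cg_change: float) -> float:
    """Intervention-minus-control difference in changes."""
    return ig_change - cg_change


def attrition(n_enrolled: int, n_analysed: int) -> tuple[int, float]:
    """Drop-out count and rate (%) between enrolment and analysis."""
    if n_analysed > n_enrolled:
        raise DomainError(
            f"n_analysed ({n_analysed}) exceeds n_enrolled ({n_enrolled})"
        )
    if n_enrolled <= 0:
        raise DomainError("n_enrolled must be positive")
    dropped = n_enrolled - n_analysed
    return dropped, 100.0 * dropped / n_enrolled


def plan_enrolment(n_required: int, expected_attrition: float) -> int:
    """Enrolment needed so that ``n_required`` remain after the expected
    attrition fraction: ceil(n_required / (1 - rate))."""
    if not 0.0 <= expected_attrition < 1.0:
        raise DomainError(
            f"expected_attrition must lie in [0, 1), got {expected_attrition}"
        )
    if n_required <= 0:
        raise DomainError("n_required must be positive")
    return math.ceil(n_required / (1.0 - expected_attrition))
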