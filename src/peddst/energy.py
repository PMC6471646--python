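"""Energy requirement estimation and macronutrient planning.

Estimated energy requirements (EER, kcal/day) come from the IOM/DRI
prediction equations for infants, children and adolescents, which combine
sex, age, weight, height and a physical-activity (PA) coefficient.  The
weight-management goal is then applied (maintenance keeps the EER; mild
weight loss subtracts a configurable deficit), and the energy target is
distributed over carbohydrate, fat and protein inside the Acceptable
Macronutrient Distribution Ranges (AMDRs), with grams derived through the
4/9/4 kcal/g Atwater factors.  Weekly meal plans are exchange-based
templates rescaled to the energy target.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError, DomainError, UnsupportedAgeBandError
from .growth import Sex

#: Atwater general factors, kcal per gram.
ATWATER = {"carbohydrate": 4.0, "fat": 9.0, "protein": 4.0}

#: Default AMDR bounds (% of energy) for children/adolescents 4-18 y.
DEFAULT_AMDR = {
    "carbohydrate": (45.0, 65.0),
    "fat": (25.0, 35.0),
    "protein": (10.0, 30.0),
}

#: Default energy deficit fraction for the mild-weight-loss goal.
DEFAULT_DEFICIT = 0.15

#: Default lower bound on a hypocaloric target, kcal/day (6-15 y).
DEFAULT_ENERGY_FLOOR = 1200.0

_DATA_DIR = Path(__file__).parent / "data"


class ActivityCategory(str, enum.Enum):
    """Activity level from METs: light (<4), moderate (4-7), vigorous (>7)."""

    light = "light"
    moderate = "moderate"
    vigorous = "vigorous"


class WeightGoal(str, enum.Enum):
    maintenance = "maintenance"
    mild_loss = "mild_loss"


def _load_constants() -> dict:
    with open(_DATA_DIR / "eer_constants.json") as fh:
        return json.load(fh)


_CONSTANTS = _load_constants()


def activity_category_from_mets(mets: float) -> ActivityCategory:
    """Light < 4 METs, moderate 4-7, vigorous > 7."""
    if mets < 0:
        raise DomainError(f"METs must be non-negative, got {mets}")
    if mets < 4.0:
        return ActivityCategory.light
    if mets <= 7.0:
        return ActivityCategory.moderate
    return ActivityCategory.vigorous


def pa_coefficient(sex: Sex, category: ActivityCategory) -> float:
    """PA coefficient for the activity category, from the configured map.

    The default bridges the MET categories to the IOM PA levels:
    light -> sedentary, moderate -> low active, vigorous -> active.
    """
    table = _CONSTANTS["pa_coefficients"][Sex(sex).value]
    return float(table[ActivityCategory(category).value])


@dataclass(frozen=True)
class ActivityProfile:
    category: ActivityCategory
    pa_coefficient: float

    def __post_init__(self) -> None:
        if not 1.0 <= self.pa_coefficient <= 1.6:
            raise DomainError(
                f"pa_coefficient must lie in [1.0, 1.6], got {self.pa_coefficient}"
            )

    @classmethod
    def from_category(cls, sex: Sex, category: ActivityCategory) -> "ActivityProfile":
        return cls(ActivityCategory(category), pa_coefficient(sex, category))


def estimate_eer(
    sex: Sex,
    age_years: float,
    weight_kg: float,
    height_m: float,
    activity: ActivityProfile | float,
) -> float:
    """IOM EER (kcal/day) for the age band containing ``age_years``.

    Bands: 0-35 months (weight-based infant equation, PA not used),
    3-8 years and 9-18 years (sex-specific equations with PA coefficient
    and a band-specific growth-energy constant).  Ages outside every band
    raise :class:`UnsupportedAgeBandError` rather than extrapolating.
    """
    if not weight_kg > 0:
        raise DomainError(f"weight_kg must be positive, got {weight_kg}")
    if not height_m > 0:
        raise DomainError(f"height_m must be positive, got {height_m}")
    if age_years < 0:
        raise DomainError(f"age_years must be non-negative, got {age_years}")
    pa = activity.pa_coefficient if isinstance(activity, ActivityProfile) else float(activity)
    if not 1.0 <= pa <= 1.6:
        raise DomainError(f"PA coefficient must lie in [1.0, 1.6], got {pa}")

    age_months = age_years * 12.0
    if age_months < 36.0:
        spec = _CONSTANTS["infant_0_35mo"]
        for lo, hi, ge in spec["growth_energy_by_month"]:
            if lo <= age_months <= hi:
                return spec["weight_coeff"] * weight_kg + spec["offset"] + ge
        raise UnsupportedAgeBandError(
            f"no infant growth-energy bin covers age {age_months:.1f} months"
        )
    if 3.0 <= age_years <= 8.0:
        band = _CONSTANTS["child_3_8y"]
    elif 9.0 <= age_years <= 18.0:
        band = _CONSTANTS["adolescent_9_18y"]
    elif 8.0 < age_years < 9.0:
        # Ages between the printed bands use the younger band's equation.
        band = _CONSTANTS["child_3_8y"]
    else:
        raise UnsupportedAgeBandError(
            f"age {age_years:.2f} y outside the supported bands "
            "(0-35 months, 3-8 y, 9-18 y)"
        )
    eq = band[Sex(sex).value]
    return (
        eq["intercept"]
        + eq["age_coeff"] * age_years
        + pa * (eq["weight_coeff"] * weight_kg + eq["height_coeff"] * height_m)
        + band["growth_energy"]
    )


def apply_goal(
    eer: float,
    goal: WeightGoal,
    deficit: float = DEFAULT_DEFICIT,
    floor: float = DEFAULT_ENERGY_FLOOR,
) -> float:
    """Energy target for the goal: maintenance is isocaloric (EER unchanged);
    mild loss subtracts ``deficit``·EER, bounded below by ``floor`` but never
    above the EER itself."""
    if not eer > 0:
        raise DomainError(f"eer must be positive, got {eer}")
    if goal is WeightGoal.maintenance:
        return eer
    if not 0.0 < deficit < 1.0:
        raise ConfigError(f"deficit must lie in (0, 1), got {deficit}")
    raw = eer * (1.0 - deficit)
    if raw <= 0:
        raise ConfigError(
            f"deficit {deficit} yields non-positive target from EER {eer:.0f}"
        )
    return min(eer, max(raw, floor))


@dataclass(frozen=True)
class MacronutrientSplit:
    """Percent-of-energy split over carbohydrate/fat/protein."""

    carbohydrate_pct: float
    fat_pct: float
    protein_pct: float

    def as_dict(self) -> dict[str, float]:
        return {
            "carbohydrate": self.carbohydrate_pct,
            "fat": self.fat_pct,
            "protein": self.protein_pct,
        }


#: Default prescription split, inside every default AMDR.
DEFAULT_SPLIT = MacronutrientSplit(55.0, 30.0, 15.0)


@dataclass(frozen=True)
class EnergyPrescription:
    """EER, goal-adjusted energy target, and macronutrient targets."""

    eer: float
    goal: WeightGoal
    target_energy: float
    carbohydrate_pct: float
    carbohydrate_g: float
    fat_pct: float
    fat_g: float
    protein_pct: float
    protein_g: float


def validate_split(
    split: MacronutrientSplit,
    amdr: dict[str, tuple[float, float]] | None = None,
) -> None:
    amdr = amdr or DEFAULT_AMDR
    total = split.carbohydrate_pct + split.fat_pct + split.protein_pct
    if abs(total - 100.0) > 0.01:
        raise DomainError(f"macronutrient split sums to {total}, expected 100")
    for name, pct in split.as_dict().items():
        lo, hi = amdr[name]
        if not lo <= pct <= hi:
            raise DomainError(
                f"{name} at {pct}% of energy is outside its AMDR [{lo}, {hi}]%"
            )


def macronutrient_targets(
    target_energy: float,
    split: MacronutrientSplit = DEFAULT_SPLIT,
    amdr: dict[str, tuple[float, float]] | None = None,
) -> dict[str, tuple[float, float]]:
    """(percent of energy, grams/day) per macronutrient via Atwater factors."""
    if not target_energy > 0:
        raise DomainError(f"target_energy must be positive, got {target_energy}")
    validate_split(split, amdr)
    return {
        name: (pct, target_energy * pct / 100.0 / ATWATER[name])
        for name, pct in split.as_dict().items()
    }


def prescribe(
    sex: Sex,
    age_years: float,
    weight_kg: float,
    height_m: float,
    activity: ActivityProfile | float,
    goal: WeightGoal,
    split: MacronutrientSplit = DEFAULT_SPLIT,
    deficit: float = DEFAULT_DEFICIT,
    floor: float = DEFAULT_ENERGY_FLOOR,
    amdr: dict[str, tuple[float, float]] | None = None,
) -> EnergyPrescription:
    """Full level 3-4 pipeline: EER -> goal-adjusted target -> macro targets."""
    eer = estimate_eer(sex, age_years, weight_kg, height_m, activity)
    target = apply_goal(eer, goal, deficit=deficit, floor=floor)
    macros = macronutrient_targets(target, split, amdr)
    return EnergyPrescription(
        eer=eer,
        goal=goal,
        target_energy=target,
        carbohydrate_pct=macros["carbohydrate"][0],
        carbohydrate_g=macros["carbohydrate"][1],
        fat_pct=macros["fat"][0],
        fat_g=macros["fat"][1],
        protein_pct=macros["protein"][0],
        protein_g=macros["protein"][1],
    )


# ---------------------------------------------------------------------------
# Exchange-based meal plan templates


#: Macronutrient grams per exchange of each food group (ADA exchange system).
EXCHANGE_COMPOSITION = {
    "starch": {"carbohydrate": 15.0, "protein": 3.0, "fat": 1.0},
    "fruit": {"carbohydrate": 15.0, "protein": 0.0, "fat": 0.0},
    "vegetable": {"carbohydrate": 5.0, "protein": 2.0, "fat": 0.0},
    "milk_lowfat": {"carbohydrate": 12.0, "protein": 8.0, "fat": 5.0},
    "meat_lean": {"carbohydrate": 0.0, "protein": 7.0, "fat": 3.0},
    "fat": {"carbohydrate": 0.0, "protein": 0.0, "fat": 5.0},
}


def _exchange_macros(counts: dict[str, float]) -> dict[str, float]:
    macros = {"carbohydrate": 0.0, "fat": 0.0, "protein": 0.0}
    for group, count in counts.items():
        if group not in EXCHANGE_COMPOSITION:
            raise ConfigError(f"unknown food group {group!r}")
        if count < 0:
            raise ConfigError(f"negative exchange count for {group!r}")
        for macro, grams in EXCHANGE_COMPOSITION[group].items():
            macros[macro] += grams * count
    return macros


def _exchange_energy(counts: dict[str, float]) -> float:
    macros = _exchange_macros(counts)
    return sum(ATWATER[m] * g for m, g in macros.items())


@dataclass(frozen=True)
class MealPlanTemplate:
    """Daily exchange counts at a reference energy, with optional
    machine-checkable composition constraints (plans 2 and 4 carry the
    fibre-rich / low-sugar-fat-sodium metadata)."""

    plan_id: str
    reference_energy: float
    exchanges: dict[str, float]
    constraints: dict[str, float] = field(default_factory=dict)
    description: str = ""

    def __post_init__(self) -> None:
        if not self.reference_energy > 0:
            raise ConfigError("reference_energy must be positive")
        computed = _exchange_energy(self.exchanges)
        if abs(computed - self.reference_energy) > 0.05 * self.reference_energy:
            raise ConfigError(
                f"plan {self.plan_id}: exchange energy {computed:.0f} kcal differs "
                f"from stated reference {self.reference_energy:.0f} kcal by >5%"
            )

    def macro_percentages(self) -> dict[str, float]:
        macros = _exchange_macros(self.exchanges)
        energy = sum(ATWATER[m] * g for m, g in macros.items())
        return {m: 100.0 * ATWATER[m] * g / energy for m, g in macros.items()}


@dataclass(frozen=True)
class ScaledMealPlan:
    plan_id: str
    exchanges: dict[str, float]
    energy: float
    macro_percentages: dict[str, float]
    warnings: tuple[str, ...] = ()


def scale_meal_plan(
    template: MealPlanTemplate,
    target_energy: float,
    granularity: float = 0.5,
    amdr: dict[str, tuple[float, float]] | None = None,
    amdr_tolerance: float = 2.0,
) -> ScaledMealPlan:
    """Rescale exchange counts to ``target_energy``.

    Counts scale by target/reference and round to ``granularity`` (default
    half exchanges).  The post-rounding macronutrient split is re-checked
    against the AMDR; violations beyond ``amdr_tolerance`` percentage points
    are recorded as warnings on the returned plan, never raised.
    """
    if not target_energy > 0:
        raise DomainError(f"target_energy must be positive, got {target_energy}")
    if not granularity > 0:
        raise ConfigError(f"granularity must be positive, got {granularity}")
    factor = target_energy / template.reference_energy
    counts = {
        group: round(count * factor / granularity) * granularity
        for group, count in template.exchanges.items()
    }
    macros = _exchange_macros(counts)
    energy = sum(ATWATER[m] * g for m, g in macros.items())
    pcts = (
        {m: 100.0 * ATWATER[m] * g / energy for m, g in macros.items()}
        if energy > 0
        else {m: 0.0 for m in macros}
    )
    amdr = amdr or DEFAULT_AMDR
    notes = []
    for macro, pct in pcts.items():
        lo, hi = amdr[macro]
        if pct < lo - amdr_tolerance or pct > hi + amdr_tolerance:
            notes.append(
                f"post-rounding {macro} at {pct:.1f}% of energy is outside "
                f"AMDR [{lo:.0f}, {hi:.0f}]% by more than {amdr_tolerance:g} points"
            )
    return ScaledMealPlan(
        plan_id=template.plan_id,
        exchanges=counts,
        energy=energy,
        macro_percentages=pcts,
        warnings=tuple(notes),
    )


def load_meal_plans(path: str | Path | None = None) -> dict[str, MealPlanTemplate]:
    """Load meal-plan templates keyed by plan id (MP1-MP4 packaged defaults)."""
    path = Path(path) if path is not None else _DATA_DIR / "meal_plans.yaml"
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    plans = {}
    for plan_id, spec in raw["plans"].items():
        plans[plan_id] = MealPlanTemplate(
            plan_id=plan_id,
            reference_energy=float(spec["reference_energy"]),
            exchanges={k: float(v) for k, v in spec["exchanges"].items()},
            constraints={k: float(v) for k, v in spec.get("constraints", {}).items()},
            description=spec.get("description", ""),
        )
    return plans
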