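"""End-to-end evaluation of a family: assess -> risk -> decide -> plan -> report."""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional

from . import energy as energy_mod
from .core_index import CoreScoreTable, classify_core
from .energy import (
    DEFAULT_AMDR,
    DEFAULT_DEFICIT,
    DEFAULT_ENERGY_FLOOR,
    DEFAULT_SPLIT,
    ActivityProfile,
    MacronutrientSplit,
    MealPlanTemplate,
    WeightGoal,
    load_meal_plans,
    prescribe,
)
from .engine import (
    AgeBand,
    ChildState,
    CoreRisk,
    Goal,
    MealPlan,
    decide,
)
from .growth import (
    LMSReferenceTable,
    WeightCategory,
    assess_weight_status,
    load_synthetic_reference,
)
from .records import Family
from .report import ReportDocument, build_report


@dataclass
class DSTConfig:
    """Bundle of all runtime configuration for the decision-support pipeline."""

    lms_table: LMSReferenceTable
    core_table: CoreScoreTable
    meal_plans: dict[str, MealPlanTemplate]
    split: MacronutrientSplit = DEFAULT_SPLIT
    deficit: float = DEFAULT_DEFICIT
    energy_floor: float = DEFAULT_ENERGY_FLOOR
    amdr: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AMDR)
    )
    exchange_granularity: float = 0.5
    meta: dict[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "DSTConfig":
        """Packaged defaults: synthetic LMS fixture, placeholder CORE table,
        packaged meal plans.  Suitable for demonstration and testing; real
        deployments supply WHO reference data and a validated CORE table."""
        return cls(
            lms_table=load_synthetic_reference(),
            core_table=CoreScoreTable.default(),
            meal_plans=load_meal_plans(),
            meta={
                "lms_table": "packaged synthetic fixture (not WHO reference)",
                "core_table": "packaged placeholder (not the published points)",
                "eer_constants": "packaged IOM/DRI equation set v1.0",
            },
        )


def _assess(family: Family, config: DSTConfig):
    """Shared first half of the pipeline: weight status, CORE, child state."""
    child = family.child
    captured: list[str] = []
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        status = assess_weight_status(
            child.anthropometry, child.sex, child.age_months, config.lms_table
        )
        captured.extend(str(w.message) for w in caught)

    core_score = core_risk = None
    if status.category is WeightCategory.normal:
        core_score = config.core_table.score(family.core_inputs())
        core_risk = classify_core(core_score.score, config.core_table.threshold)
        risk = CoreRisk.from_risk_level(core_risk)
    else:
        risk = CoreRisk.not_applicable

    state = ChildState(
        age_band=AgeBand.from_age_months(child.age_months),
        weight_status=status.category,
        core_risk=risk,
        any_clinical_disorder=child.any_clinical_disorder,
        any_obese_parent=family.any_obese_parent,
    )
    return status, core_score, core_risk, state, captured


def child_state(family: Family, config: Optional[DSTConfig] = None) -> ChildState:
    """Derive the decision-engine state for a family."""
    config = config or DSTConfig.default()
    return _assess(family, config)[3]


def evaluate_family(family: Family, config: Optional[DSTConfig] = None) -> ReportDocument:
    """Run the full pipeline for one family and return the report."""
    config = config or DSTConfig.default()
    child = family.child
    status, core_score, core_risk, state, captured = _assess(family, config)
    outcome = decide(state)

    prescription = scaled_plan = None
    if outcome.meal_plan is not MealPlan.none:
        activity = ActivityProfile.from_category(child.sex, child.activity)
        goal = (
            WeightGoal.mild_loss
            if outcome.goal is Goal.mild_loss
            else WeightGoal.maintenance
        )
        prescription = prescribe(
            sex=child.sex,
            age_years=child.age_months / 12.0,
            weight_kg=child.weight_kg,
            height_m=child.height_cm / 100.0,
            activity=activity,
            goal=goal,
            split=config.split,
            deficit=config.deficit,
            floor=config.energy_floor,
            amdr=config.amdr,
        )
        template = config.meal_plans[outcome.meal_plan.value]
        scaled_plan = energy_mod.scale_meal_plan(
            template,
            prescription.target_energy,
            granularity=config.exchange_granularity,
            amdr=config.amdr,
        )

    return build_report(
        family=family,
        status=status,
        outcome=outcome,
        core_score=core_score,
        core_risk=core_risk,
        prescription=prescription,
        scaled_plan=scaled_plan,
        warnings=tuple(captured),
        config_meta=config.meta,
    )
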