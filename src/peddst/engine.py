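"""The five-step decision tree mapping child state to personalised advice.

The pathway routes on four facts: the child's age band, BMI-for-age weight
status, CORE risk level (normal-weight children only), the presence of at
least one obesity-related clinical disorder (hyperglycaemia, insulin
resistance, dyslipidaemia, hypertension), and at least one obese parent
(BMI > 30 kg/m2).  The output is a recommendation level (1-4), a meal-plan
assignment, the target population (child vs whole family), the
weight-management goal, and the re-evaluation interval in months.

Recommendation placement is shared across all steps: no disorder and
non-obese parents -> R1; no disorder but an obese parent -> R2 (family);
a disorder with non-obese parents -> R3; both -> R4 (family).  Meal plans
are added for overweight (MP1/MP2, isocaloric) and for obese 6-15-year-olds
(MP3/MP4, hypocaloric with mild weight loss); obese 2-5-year-olds follow the
overweight table.  Underweight children, children over 15, and obese infants
under 2 fall outside every printed pathway and are referred.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .core_index import RiskLevel
from .errors import DomainError
from .growth import WeightCategory


class AgeBand(str, enum.Enum):
    under2 = "under2"
    y2_5 = "y2_5"
    y6_15 = "y6_15"
    over15 = "over15"

    @classmethod
    def from_age_months(cls, age_months: float) -> "AgeBand":
        if age_months < 0:
            raise DomainError(f"age_months must be non-negative, got {age_months}")
        if age_months < 24.0:
            return cls.under2
        if age_months < 72.0:
            return cls.y2_5
        if age_months < 192.0:
            return cls.y6_15
        return cls.over15


class CoreRisk(str, enum.Enum):
    higher = "higher"
    lower = "lower"
    not_applicable = "not_applicable"

    @classmethod
    def from_risk_level(cls, level: RiskLevel) -> "CoreRisk":
        return cls.higher if level is RiskLevel.higher_likelihood else cls.lower


class Recommendation(str, enum.Enum):
    R1 = "R1"
    R2 = "R2"
    R3 = "R3"
    R4 = "R4"
    refer = "refer"


class MealPlan(str, enum.Enum):
    none = "none"
    MP1 = "MP1"
    MP2 = "MP2"
    MP3 = "MP3"
    MP4 = "MP4"


class TargetPopulation(str, enum.Enum):
    child = "child"
    family = "family"


class Goal(str, enum.Enum):
    maintenance = "maintenance"
    mild_loss = "mild_loss"
    none = "none"


class BehaviourGoal(str, enum.Enum):
    balanced_diet = "balanced_diet"
    physical_activity = "physical_activity"
    sleep = "sleep"
    increase_fibre_complex_carb = "increase_fibre_complex_carb"
    reduce_sugar_satfat_chol_sodium = "reduce_sugar_satfat_chol_sodium"


@dataclass(frozen=True)
class ChildState:
    age_band: AgeBand
    weight_status: WeightCategory
    core_risk: CoreRisk
    any_clinical_disorder: bool
    any_obese_parent: bool

    def __post_init__(self) -> None:
        if self.weight_status is WeightCategory.normal:
            if self.core_risk is CoreRisk.not_applicable:
                raise DomainError(
                    "normal-weight children require a CORE risk level "
                    "(higher or lower)"
                )
        elif self.core_risk is not CoreRisk.not_applicable:
            raise DomainError(
                "core_risk must be not_applicable unless weight status is normal"
            )


@dataclass(frozen=True)
class DecisionOutcome:
    recommendation: Recommendation
    meal_plan: MealPlan
    target_population: TargetPopulation
    goal: Goal
    review_months: int
    inferred_cell: bool = False


_REFER = DecisionOutcome(
    recommendation=Recommendation.refer,
    meal_plan=MealPlan.none,
    target_population=TargetPopulation.child,
    goal=Goal.none,
    review_months=3,
)


def _recommendation(disorder: bool, obese_parent: bool) -> Recommendation:
    if disorder:
        return Recommendation.R4 if obese_parent else Recommendation.R3
    return Recommendation.R2 if obese_parent else Recommendation.R1


def _target_population(rec: Recommendation) -> TargetPopulation:
    return (
        TargetPopulation.family
        if rec in (Recommendation.R2, Recommendation.R4)
        else TargetPopulation.child
    )


def decide(state: ChildState) -> DecisionOutcome:
    """Route a child state through the five-step decision tree."""
    dis, obp = state.any_clinical_disorder, state.any_obese_parent

    if state.age_band is AgeBand.over15:
        return _REFER
    if state.weight_status is WeightCategory.underweight:
        return _REFER

    if state.weight_status is WeightCategory.normal:
        # Steps 2-3: no meal plan; advice only.
        if state.core_risk is CoreRisk.lower:
            rec = Recommendation.R1
        else:
            rec = _recommendation(dis, obp)
        return DecisionOutcome(
            recommendation=rec,
            meal_plan=MealPlan.none,
            target_population=_target_population(rec),
            goal=Goal.none,
            review_months=6 if (dis or obp) else 12,
        )

    review = 3 if (dis or obp) else 6
    rec = _recommendation(dis, obp)

    if state.weight_status is WeightCategory.overweight or (
        state.weight_status is WeightCategory.obese
        and state.age_band is AgeBand.y2_5
    ):
        # Step 4 (and Step 5's 2-5-year-old branch): isocaloric plans.
        plan = MealPlan.MP2 if dis else MealPlan.MP1
        return DecisionOutcome(
            recommendation=rec,
            meal_plan=plan,
            target_population=_target_population(rec),
            goal=Goal.maintenance,
            review_months=review,
        )

    if state.weight_status is WeightCategory.obese and state.age_band is AgeBand.y6_15:
        # Step 5: hypocaloric plans with mild weight loss. The
        # no-disorder/non-obese-parents cell is not printed; it is filled by
        # symmetry with the overweight table (R1) and flagged as inferred.
        plan = MealPlan.MP4 if dis else MealPlan.MP3
        return DecisionOutcome(
            recommendation=rec,
            meal_plan=plan,
            target_population=_target_population(rec),
            goal=Goal.mild_loss,
            review_months=review,
            inferred_cell=not dis and not obp,
        )

    # Obese under-2: no printed pathway.
    return _REFER


def reevaluate(previous: DecisionOutcome, new_state: ChildState) -> DecisionOutcome:
    """Re-evaluation routes purely on the new state (memoryless): the child
    is re-classified and the matching step's table applies.  ``previous`` is
    retained only for report trajectories."""
    del previous
    return decide(new_state)


_BASE_GOALS = frozenset(
    {
        BehaviourGoal.balanced_diet,
        BehaviourGoal.physical_activity,
        BehaviourGoal.sleep,
    }
)
_COMPOSITION_GOALS = frozenset(
    {
        BehaviourGoal.increase_fibre_complex_carb,
        BehaviourGoal.reduce_sugar_satfat_chol_sodium,
    }
)


def behaviour_goals(recommendation: Recommendation) -> frozenset[BehaviourGoal]:
    """Behavioural change goals per recommendation level.

    All four levels target a balanced diet, physical activity and sleep;
    levels 3 and 4 add the dietary-composition goals (more fibre and complex
    carbohydrate; less simple sugar, total/saturated fat, cholesterol and
    sodium).  Referral carries no goals.
    """
    if recommendation is Recommendation.refer:
        return frozenset()
    if recommendation in (Recommendation.R3, Recommendation.R4):
        return _BASE_GOALS | _COMPOSITION_GOALS
    return _BASE_GOALS
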