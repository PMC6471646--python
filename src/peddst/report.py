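"""Assembly and serialisation of the clinician-facing report.

The report carries the six assessment items: (a) current weight status and
weight-management goal, (b) future-obesity likelihood (normal-weight
children only), (c) total energy requirement, (d) macronutrient needs,
(e) the meal-plan assignment, and (f) the recommendations with behavioural
change goals — plus a provenance block (inputs digest, configuration
versions, inferred-cell flags, warnings).  Items (b) and (c)-(e) are
conditional: (b) appears only for normal-weight children, (c)-(e) only when
a meal plan and energy target were produced.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Any, Optional

from .core_index import CoreScore, RiskLevel
from .energy import EnergyPrescription, ScaledMealPlan
from .engine import DecisionOutcome, MealPlan, behaviour_goals
from .errors import DSTError, IntegrityError
from .growth import WeightCategory, WeightStatus
from .records import Family

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class ReportDocument:
    schema_version: str
    child_id: str
    weight_assessment: dict[str, Any]              # item (a)
    obesity_risk: Optional[dict[str, Any]]         # item (b)
    energy: Optional[dict[str, Any]]               # item (c)
    macronutrients: Optional[dict[str, Any]]       # item (d)
    meal_plan: Optional[dict[str, Any]]            # item (e)
    recommendations: dict[str, Any]                # item (f)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "ReportDocument":
        return cls(**raw)


def build_report(
    family: Family,
    status: WeightStatus,
    outcome: DecisionOutcome,
    core_score: Optional[CoreScore] = None,
    core_risk: Optional[RiskLevel] = None,
    prescription: Optional[EnergyPrescription] = None,
    scaled_plan: Optional[ScaledMealPlan] = None,
    warnings: tuple[str, ...] = (),
    config_meta: Optional[dict[str, str]] = None,
) -> ReportDocument:
    """Assemble the report, enforcing the item-presence invariants."""
    child = family.child

    is_normal = status.category is WeightCategory.normal
    if is_normal and core_score is None:
        raise IntegrityError("normal-weight children require a CORE assessment")
    if not is_normal and core_score is not None:
        raise IntegrityError("CORE assessment only applies to normal-weight children")

    has_plan = outcome.meal_plan is not MealPlan.none
    if has_plan and (prescription is None or scaled_plan is None):
        raise IntegrityError(
            "a meal-plan outcome requires an energy prescription and scaled plan"
        )
    if not has_plan and (prescription is not None or scaled_plan is not None):
        raise IntegrityError(
            "energy prescription supplied without a meal-plan outcome"
        )
    if scaled_plan is not None and scaled_plan.plan_id != outcome.meal_plan.value:
        raise IntegrityError(
            f"scaled plan {scaled_plan.plan_id} does not match decision "
            f"outcome {outcome.meal_plan.value}"
        )

    weight_assessment = {
        "category": status.category.value,
        "bmi": round(status.bmi, 2),
        "zscore": round(status.zscore, 3),
        "percentile": round(status.percentile, 2),
        "goal": outcome.goal.value,
    }
    obesity_risk = None
    if core_score is not None:
        obesity_risk = {
            "score": core_score.score,
            "components": dict(sorted(core_score.components.items())),
            "n_missing": core_score.n_missing,
            "likelihood": core_risk.value if core_risk is not None else None,
        }
    energy = None
    macronutrients = None
    meal_plan = None
    if has_plan:
        energy = {
            "eer_kcal_day": round(prescription.eer, 1),
            "target_kcal_day": round(prescription.target_energy, 1),
            "goal": prescription.goal.value,
        }
        macronutrients = {
            "carbohydrate": {
                "pct_kcal": prescription.carbohydrate_pct,
                "g_day": round(prescription.carbohydrate_g, 1),
            },
            "fat": {
                "pct_kcal": prescription.fat_pct,
                "g_day": round(prescription.fat_g, 1),
            },
            "protein": {
                "pct_kcal": prescription.protein_pct,
                "g_day": round(prescription.protein_g, 1),
            },
        }
        meal_plan = {
            "plan_id": scaled_plan.plan_id,
            "exchanges": dict(sorted(scaled_plan.exchanges.items())),
            "energy_kcal_day": round(scaled_plan.energy, 1),
            "macro_percentages": {
                k: round(v, 1) for k, v in sorted(scaled_plan.macro_percentages.items())
            },
        }
        warnings = warnings + scaled_plan.warnings

    recommendations = {
        "recommendation": outcome.recommendation.value,
        "target_population": outcome.target_population.value,
        "behaviour_goals": sorted(g.value for g in behaviour_goals(outcome.recommendation)),
        "review_months": outcome.review_months,
    }
    provenance = {
        "inputs": {
            "child_id": child.id,
            "sex": child.sex.value,
            "exam_date": child.exam_date.isoformat(),
            "age_months": round(child.age_months, 2),
            "disorder_flags": child.disorder_flags,
            "any_obese_parent": family.any_obese_parent,
            "parent_anthropometry_sources": {
                p.role.value: p.source.value for p in family.parents
            },
        },
        "config": dict(config_meta or {}),
        "inferred_cell": outcome.inferred_cell,
        "warnings": list(warnings),
    }
    return ReportDocument(
        schema_version=SCHEMA_VERSION,
        child_id=child.id,
        weight_assessment=weight_assessment,
        obesity_risk=obesity_risk,
        energy=energy,
        macronutrients=macronutrients,
        meal_plan=meal_plan,
        recommendations=recommendations,
        provenance=provenance,
    )


def render(report: ReportDocument, fmt: str = "json") -> str:
    """Serialise the report: canonical JSON (lossless round-trip) or Markdown."""
    if fmt == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    if fmt == "markdown":
        return _render_markdown(report)
    raise DSTError(f"unknown report format {fmt!r} (expected 'json' or 'markdown')")


def parse_report(text: str) -> ReportDocument:
    """Inverse of ``render(report, 'json')``."""
    return ReportDocument.from_dict(json.loads(text))


def _render_markdown(report: ReportDocument) -> str:
    lines = [f"# Assessment report — child {report.child_id}", ""]

    wa = report.weight_assessment
    lines += [
        "## Weight status",
        f"- Category: **{wa['category']}** "
        f"(BMI {wa['bmi']} kg/m², z = {wa['zscore']}, "
        f"percentile {wa['percentile']})",
        f"- Weight-management goal: {wa['goal']}",
        "",
    ]
    if report.obesity_risk is not None:
        risk = report.obesity_risk
        lines += [
            "## Future-obesity likelihood",
            f"- CORE score: {risk['score']} ({risk['likelihood']}, "
            f"{risk['n_missing']} missing component(s))",
            "",
        ]
    if report.energy is not None:
        lines += [
            "## Energy requirement",
            f"- EER: {report.energy['eer_kcal_day']} kcal/day",
            f"- Target ({report.energy['goal']}): "
            f"{report.energy['target_kcal_day']} kcal/day",
            "",
        ]
    if report.macronutrients is not None:
        lines.append("## Macronutrient targets")
        for name, m in report.macronutrients.items():
            lines.append(f"- {name}: {m['pct_kcal']}% of energy, {m['g_day']} g/day")
        lines.append("")
    if report.meal_plan is not None:
        mp = report.meal_plan
        lines += [
            "## Meal plan",
            f"- Plan: {mp['plan_id']} at {mp['energy_kcal_day']} kcal/day",
            "- Daily exchanges: "
            + ", ".join(f"{k} {v:g}" for k, v in mp["exchanges"].items()),
            "",
        ]
    rec = report.recommendations
    lines += [
        "## Recommendations",
        f"- Level: {rec['recommendation']} (target: {rec['target_population']})",
        f"- Behaviour goals: {', '.join(rec['behaviour_goals']) or 'none'}",
        f"- Re-evaluation in {rec['review_months']} months",
        "",
    ]
    if report.provenance.get("warnings"):
        lines.append("## Warnings")
        lines += [f"- {w}" for w in report.provenance["warnings"]]
        lines.append("")
    return "\n".join(lines)
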