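"""Energy requirements, goal adjustment, macronutrient and meal-plan math."""

import json
from pathlib import Path

import pytest
from hypothesis import given
from hypothesis import strategies as st

import peddst
from peddst import (
    ActivityProfile,
    ConfigError,
    DomainError,
    MacronutrientSplit,
    MealPlanTemplate,
    Sex,
    UnsupportedAgeBandError,
    WeightGoal,
    apply_goal,
    estimate_eer,
    load_meal_plans,
    macronutrient_targets,
    prescribe,
    scale_meal_plan,
)

CONSTANTS_PATH = Path(peddst.__file__).parent / "data" / "eer_constants.json"


def oracle_eer(sex, age_years, weight_kg, height_m, pa):
    """Independent brute-force evaluation of the packaged constants file."""
    constants = json.loads(CONSTANTS_PATH.read_text())
    months = age_years * 12.0
    if months < 36.0:
        spec = constants["infant_0_35mo"]
        for lo, hi, ge in spec["growth_energy_by_month"]:
            if lo <= months <= hi:
                return spec["weight_coeff"] * weight_kg + spec["offset"] + ge
        raise AssertionError("no bin")
    band = constants["child_3_8y"] if age_years < 9.0 else constants["adolescent_9_18y"]
    eq = band[sex]
    return (
        eq["intercept"]
        + eq["age_coeff"] * age_years
        + pa * (eq["weight_coeff"] * weight_kg + eq["height_coeff"] * height_m)
        + band["growth_energy"]
    )


class TestEER:
    def test_boy_9_18_equation(self):
        assert estimate_eer(Sex.male, 10, 40, 1.40, 1.0) == pytest.approx(
            1826.7, abs=0.05
        )

    def test_girl_9_18_equation(self):
        # 135.3 - 30.8*10 + 1.0*(10*40 + 934*1.40) + 25
        assert estimate_eer(Sex.female, 10, 40, 1.40, 1.0) == pytest.approx(
            1559.9, abs=0.05
        )

    def test_pa_coefficient_increases_eer(self):
        low = estimate_eer(Sex.male, 10, 40, 1.40, 1.0)
        high = estimate_eer(Sex.male, 10, 40, 1.40, 1.13)
        assert high > low

    def test_infant_band_is_weight_based(self):
        # 89*8 - 100 + 22 (7-12-month deposition energy)
        assert estimate_eer(Sex.male, 10 / 12, 8.0, 0.70, 1.0) == pytest.approx(634.0)

    @pytest.mark.parametrize("age", [19.0, 25.0])
    def test_unsupported_band_raises(self, age):
        with pytest.raises(UnsupportedAgeBandError):
            estimate_eer(Sex.male, age, 60, 1.70, 1.0)

    @given(
        sex=st.sampled_from([Sex.male, Sex.female]),
        age=st.floats(3, 18),
        w1=st.floats(12, 80),
        dw=st.floats(0.5, 10),
        h=st.floats(0.9, 1.9),
        pa=st.floats(1.0, 1.6),
    )
    def test_strictly_increasing_in_weight(self, sex, age, w1, dw, h, pa):
        assert estimate_eer(sex, age, w1 + dw, h, pa) > estimate_eer(sex, age, w1, h, pa)

    @given(
        sex=st.sampled_from([Sex.male, Sex.female]),
        age=st.floats(3, 18),
        w=st.floats(12, 80),
        h=st.floats(0.9, 1.8),
        dh=st.floats(0.01, 0.2),
        pa=st.floats(1.0, 1.6),
    )
    def test_strictly_increasing_in_height(self, sex, age, w, h, dh, pa):
        assert estimate_eer(sex, age, w, h + dh, pa) > estimate_eer(sex, age, w, h, pa)

    def test_matches_independent_oracle_on_grid(self):
        for sex in (Sex.male, Sex.female):
            for age in (0.5, 2.0, 4.0, 7.5, 10.0, 16.0):
                for pa in (1.0, 1.16):
                    got = estimate_eer(sex, age, 30.0, 1.3, pa)
                    want = oracle_eer(sex.value, age, 30.0, 1.3, pa)
                    assert got == pytest.approx(want, abs=1e-9)


class TestActivityProfile:
    def test_met_category_mapping(self):
        from peddst.energy import activity_category_from_mets

        assert activity_category_from_mets(3.9).value == "light"
        assert activity_category_from_mets(4.0).value == "moderate"
        assert activity_category_from_mets(7.0).value == "moderate"
        assert activity_category_from_mets(7.1).value == "vigorous"

    def test_coefficient_bounds_enforced(self):
        with pytest.raises(DomainError):
            ActivityProfile(peddst.ActivityCategory.light, 1.8)


class TestGoal:
    def test_maintenance_is_identity(self):
        assert apply_goal(1800.0, WeightGoal.maintenance) == 1800.0

    def test_mild_loss_default_deficit(self):
        assert apply_goal(1800.0, WeightGoal.mild_loss, deficit=0.15) == pytest.approx(
            1530.0
        )

    def test_total_deficit_rejected(self):
        with pytest.raises(ConfigError):
            apply_goal(1800.0, WeightGoal.mild_loss, deficit=1.0)

    def test_floor_bounds_the_target(self):
        # 1300*(1-0.15)=1105 < floor -> clamped to the floor
        assert apply_goal(1300.0, WeightGoal.mild_loss, floor=1200.0) == 1200.0

    @given(eer=st.floats(1300, 4000), deficit=st.floats(0.05, 0.5))
    def test_mild_loss_below_identity(self, eer, deficit):
        assert apply_goal(eer, WeightGoal.mild_loss, deficit=deficit) < eer


class TestMacronutrients:
    def test_reference_split(self):
        macros = macronutrient_targets(1800.0, MacronutrientSplit(50, 30, 20))
        assert macros["carbohydrate"][1] == pytest.approx(225.0)
        assert macros["fat"][1] == pytest.approx(60.0)
        assert macros["protein"][1] == pytest.approx(90.0)

    def test_split_must_sum_to_100(self):
        with pytest.raises(DomainError):
            macronutrient_targets(1800.0, MacronutrientSplit(50, 30, 19))

    def test_amdr_bounds_enforced(self):
        with pytest.raises(DomainError, match="carbohydrate"):
            macronutrient_targets(2000.0, MacronutrientSplit(70, 20, 10))

    @given(
        energy=st.floats(800, 3500),
        carb=st.floats(45, 65),
        fat=st.floats(25, 35),
    )
    def test_energy_conservation(self, energy, carb, fat):
        protein = 100.0 - carb - fat
        if not 10.0 <= protein <= 30.0:
            return
        macros = macronutrient_targets(
            energy, MacronutrientSplit(carb, fat, protein)
        )
        total = (
            macros["carbohydrate"][1] * 4
            + macros["fat"][1] * 9
            + macros["protein"][1] * 4
        )
        assert total == pytest.approx(energy, abs=0.5)

    def test_prescribe_combines_all_stages(self):
        rx = prescribe(
            Sex.male, 10.0, 40.0, 1.40, 1.0, WeightGoal.mild_loss, deficit=0.15
        )
        assert rx.eer == pytest.approx(1826.7, abs=0.05)
        assert rx.target_energy == pytest.approx(1826.7 * 0.85, abs=0.1)
        assert rx.target_energy < rx.eer


class TestMealPlans:
    @pytest.fixture()
    def template(self):
        return MealPlanTemplate(
            plan_id="test",
            reference_energy=1600.0,
            exchanges={
                "starch": 8,
                "fruit": 3,
                "vegetable": 5,
                "milk_lowfat": 1,
                "meat_lean": 5,
                "fat": 5,
            },
        )

    def test_identity_at_reference_energy(self, template):
        scaled = scale_meal_plan(template, 1600.0)
        assert scaled.exchanges == {k: float(v) for k, v in template.exchanges.items()}

    def test_doubling(self, template):
        scaled = scale_meal_plan(template, 3200.0)
        assert scaled.exchanges == {
            k: 2.0 * v for k, v in template.exchanges.items()
        }

    def test_half_exchange_rounding(self, template):
        # factor 1.125: 8->9.0, 3->3.375->3.5, 5->5.625->5.5, 1->1.125->1.0
        scaled = scale_meal_plan(template, 1800.0)
        assert scaled.exchanges == {
            "starch": 9.0,
            "fruit": 3.5,
            "vegetable": 5.5,
            "milk_lowfat": 1.0,
            "meat_lean": 5.5,
            "fat": 5.5,
        }

    def test_amdr_recheck_records_warnings_not_errors(self):
        skewed = MealPlanTemplate(
            plan_id="skewed",
            reference_energy=855.0,
            exchanges={"fruit": 12, "fat": 3},
        )
        scaled = scale_meal_plan(skewed, 855.0)
        assert scaled.warnings  # carbohydrate far above its AMDR

    def test_packaged_plans_valid_and_inside_amdr(self):
        plans = load_meal_plans()
        assert set(plans) == {"MP1", "MP2", "MP3", "MP4"}
        for plan in plans.values():
            pcts = plan.macro_percentages()
            assert 45 <= pcts["carbohydrate"] <= 65
            assert 25 <= pcts["fat"] <= 35
            assert 10 <= pcts["protein"] <= 30
        # the fibre-rich / low-sugar plans carry composition constraints
        for pid in ("MP2", "MP4"):
            assert plans[pid].constraints
        for pid in ("MP1", "MP3"):
            assert not plans[pid].constraints
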