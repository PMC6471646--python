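"""CORE index: component scoring, classification, table configuration."""

from itertools import product

import pytest
from hypothesis import given
from hypothesis import strategies as st

from peddst import (
    ConfigError,
    CoreInputs,
    CoreScoreTable,
    DomainError,
    RiskLevel,
    Sex,
    classify_core,
    score_core,
    weight_gain_0_6mo,
)


class TestWeightGain:
    def test_subtraction(self):
        assert weight_gain_0_6mo(3.2, 7.2) == pytest.approx(4.0)
        assert weight_gain_0_6mo(3.2, 3.2) == 0.0

    def test_missing_propagates(self):
        assert weight_gain_0_6mo(None, 7.2) is None
        assert weight_gain_0_6mo(3.2, None) is None

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            weight_gain_0_6mo(-1.0, 7.2)


def toy_table(points=(2, 1, 1), threshold=4, missing_policy="zero_points"):
    """Three-component table: smoking, sex and education carry the points."""
    return CoreScoreTable.from_dict(
        {
            "threshold": threshold,
            "missing_policy": missing_policy,
            "components": {
                "maternal_smoking_pregnancy": [
                    {"equals": True, "points": points[0]},
                    {"equals": False, "points": 0},
                ],
                "child_sex": [
                    {"equals": "male", "points": points[1]},
                    {"equals": "female", "points": 0},
                ],
                "maternal_education_years": [
                    {"max": 9, "points": points[2]},
                    {"min": 9, "points": 0},
                ],
            },
        }
    )


def toy_inputs(smoking, male, low_edu):
    return CoreInputs(
        child_sex=Sex.male if male else Sex.female,
        maternal_smoking_pregnancy=smoking,
        maternal_education_years=6.0 if low_edu else 14.0,
    )


class TestScoring:
    def test_all_zero_bins(self):
        result = score_core(toy_inputs(False, False, False), toy_table())
        assert result.score == 0
        assert result.n_missing == 0

    def test_all_maximum_bins_reach_reported_max(self):
        table = toy_table()
        result = score_core(toy_inputs(True, True, True), table)
        assert result.score == table.max_score == 4

    def test_brute_force_enumeration_of_trigger_patterns(self):
        # independently enumerate all 8 patterns and the implied sums
        table = toy_table(points=(2, 1, 1))
        for smoking, male, low_edu in product((False, True), repeat=3):
            expected = 2 * smoking + 1 * male + 1 * low_edu
            result = score_core(toy_inputs(smoking, male, low_edu), table)
            assert result.score == expected
            assert sum(result.components.values()) == result.score

    def test_missing_component_policies(self):
        inputs = CoreInputs(child_sex=Sex.male, maternal_smoking_pregnancy=True)
        lenient = score_core(inputs, toy_table())
        assert lenient.score == 3 and lenient.n_missing == 1
        with pytest.raises(DomainError):
            score_core(inputs, toy_table(missing_policy="refuse"))

    def test_derived_weight_gain_component(self):
        table = CoreScoreTable.from_dict(
            {
                "components": {
                    "weight_gain_0_6mo": [
                        {"max": 4.5, "points": 0},
                        {"min": 4.5, "points": 2},
                    ]
                }
            }
        )
        rapid = CoreInputs(infant_weight_birth_kg=3.0, infant_weight_6mo_kg=8.0)
        slow = CoreInputs(infant_weight_birth_kg=3.0, infant_weight_6mo_kg=7.0)
        assert score_core(rapid, table).score == 2
        assert score_core(slow, table).score == 0

    @given(
        smoking=st.booleans(),
        male=st.booleans(),
        edu=st.floats(0, 25),
        p0=st.integers(0, 5),
        p1=st.integers(0, 5),
        p2=st.integers(0, 5),
    )
    def test_component_sum_conservation(self, smoking, male, edu, p0, p1, p2):
        table = toy_table(points=(p0, p1, p2))
        inputs = CoreInputs(
            child_sex=Sex.male if male else Sex.female,
            maternal_smoking_pregnancy=smoking,
            maternal_education_years=edu,
        )
        result = score_core(inputs, table)
        assert sum(result.components.values()) == result.score

    @given(smoking=st.booleans(), male=st.booleans(), low_edu=st.booleans())
    def test_monotone_in_any_single_component(self, smoking, male, low_edu):
        """Moving one component to its maximum-point bin never lowers the
        score or flips a higher classification to lower."""
        table = toy_table()
        base = score_core(toy_inputs(smoking, male, low_edu), table)
        bumped_inputs = [
            toy_inputs(True, male, low_edu),
            toy_inputs(smoking, True, low_edu),
            toy_inputs(smoking, male, True),
        ]
        for inputs in bumped_inputs:
            bumped = score_core(inputs, table)
            assert bumped.score >= base.score
            if classify_core(base.score) is RiskLevel.higher_likelihood:
                assert classify_core(bumped.score) is RiskLevel.higher_likelihood


class TestClassification:
    @pytest.mark.parametrize(
        "score, expected",
        [(4, "higher_likelihood"), (3, "lower_likelihood"), (0, "lower_likelihood")],
    )
    def test_threshold_at_four(self, score, expected):
        assert classify_core(score).value == expected

    def test_negative_score_rejected(self):
        with pytest.raises(DomainError):
            classify_core(-1)

    def test_unreachable_threshold_degenerates_to_lower(self):
        table = toy_table(threshold=99)
        for smoking, male, low_edu in product((False, True), repeat=3):
            result = score_core(toy_inputs(smoking, male, low_edu), table)
            assert (
                classify_core(result.score, table.threshold)
                is RiskLevel.lower_likelihood
            )


class TestTableValidation:
    def test_default_table_loads_and_reports_max(self):
        table = CoreScoreTable.default()
        assert table.threshold == 4
        assert table.max_score >= table.threshold

    def test_non_contiguous_intervals_rejected(self):
        with pytest.raises(ConfigError):
            CoreScoreTable.from_dict(
                {
                    "components": {
                        "maternal_education_years": [
                            {"max": 9, "points": 1},
                            {"min": 10, "points": 0},
                        ]
                    }
                }
            )

    def test_non_exhaustive_categorical_rejected(self):
        with pytest.raises(ConfigError):
            CoreScoreTable.from_dict(
                {
                    "components": {
                        "child_sex": [{"equals": "male", "points": 1}]
                    }
                }
            )

    def test_negative_points_rejected(self):
        with pytest.raises(ConfigError):
            CoreScoreTable.from_dict(
                {
                    "components": {
                        "maternal_smoking_pregnancy": [
                            {"equals": True, "points": -1},
                            {"equals": False, "points": 0},
                        ]
                    }
                }
            )

    def test_sanity_bound_on_six_month_weight(self):
        with pytest.raises(DomainError):
            CoreInputs(infant_weight_birth_kg=4.0, infant_weight_6mo_kg=1.5)
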