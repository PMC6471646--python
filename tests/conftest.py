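from datetime import date

import pytest
from hypothesis import HealthCheck, settings

from peddst import CohortSpec, DSTConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> DSTConfig:
    return DSTConfig.default()


@pytest.fixture(scope="session")
def small_cohort(config):
    """A deterministic 100-family synthetic cohort."""
    return generate_cohort(CohortSpec(n_children=100), seed=20180515)


@pytest.fixture()
def family_payload() -> dict:
    """One valid family as a plain JSON-style document."""
    return {
        "child": {
            "id": "demo-001",
            "sex": "male",
            "birth_date": "2008-03-10",
            "exam_date": "2018-05-15",
            "weight_kg": 52.0,
            "height_cm": 142.0,
            "waist_cm": 80.0,
            "activity": "moderate",
            "dyslipidaemia": True,
            "perinatal": {
                "maternal_prepregnancy_bmi": 24.0,
                "maternal_smoking_pregnancy": False,
                "birth_weight_kg": 3.3,
                "weight_6mo_kg": 7.4,
            },
        },
        "mother": {
            "role": "mother",
            "weight_kg": 65.0,
            "height_cm": 164.0,
            "education_years": 14,
        },
        "father": {
            "role": "father",
            "weight_kg": 98.0,
            "height_cm": 176.0,
        },
    }


@pytest.fixture()
def exam_date() -> date:
    return date(2018, 5, 15)
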