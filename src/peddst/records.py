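"""Clinical record models and file I/O.

A :class:`Family` bundles one child's visit record with optional parent
records.  Two interchange encodings are supported and round-trip to identical
records: a JSON document per family (or a list of them) and a flat CSV with
one row per family (``child_*`` / ``mother_*`` / ``father_*`` column
prefixes).  Dates are ISO-8601.  Loading is forgiving at the collection
level: invalid rows are reported with their identifiers while valid rows are
still returned.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .core_index import CoreInputs
from .energy import ActivityCategory
from .errors import DSTError
from .growth import (
    Anthropometry,
    MeasurementMode,
    Sex,
    age_in_months,
)

OBESITY_BMI_CUTOFF = 30.0  # parents are obese iff BMI strictly above this


class ParentRole(str, enum.Enum):
    mother = "mother"
    father = "father"


class AnthropometrySource(str, enum.Enum):
    measured = "measured"
    reported = "reported"


class PerinatalRecord(BaseModel):
    """Perinatal and maternal factors feeding the CORE index."""

    model_config = ConfigDict(extra="forbid")

    maternal_prepregnancy_bmi: Optional[float] = Field(default=None, gt=0)
    maternal_smoking_pregnancy: Optional[bool] = None
    birth_weight_kg: Optional[float] = Field(default=None, gt=0)
    weight_6mo_kg: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _sane_weight_gain(self) -> "PerinatalRecord":
        if (
            self.birth_weight_kg is not None
            and self.weight_6mo_kg is not None
            and self.weight_6mo_kg < 0.5 * self.birth_weight_kg
        ):
            raise ValueError(
                "weight_6mo_kg below half the birth weight "
                f"({self.weight_6mo_kg} vs {self.birth_weight_kg})"
            )
        return self


class ChildRecord(BaseModel):
    """One child's demographic, anthropometric, activity, clinical-flag and
    perinatal data at a single visit."""

    model_config = ConfigDict(extra="forbid")

    id: str
    sex: Sex
    birth_date: date
    exam_date: date
    weight_kg: float = Field(gt=0)
    height_cm: float = Field(gt=0)
    measurement_mode: MeasurementMode = MeasurementMode.standing_height
    waist_cm: Optional[float] = Field(default=None, gt=0)
    activity: ActivityCategory = ActivityCategory.light
    hyperglycaemia: bool = False
    insulin_resistance: bool = False
    dyslipidaemia: bool = False
    hypertension: bool = False
    perinatal: Optional[PerinatalRecord] = None

    @model_validator(mode="after")
    def _validate_dates_and_mode(self) -> "ChildRecord":
        if self.exam_date < self.birth_date:
            raise ValueError(
                f"exam_date {self.exam_date} precedes birth_date {self.birth_date}"
            )
        if (
            self.measurement_mode is MeasurementMode.recumbent_length
            and self.age_months >= 24.0
        ):
            raise ValueError(
                "recumbent length is only valid before 24 months of age"
            )
        return self

    @property
    def age_months(self) -> float:
        return age_in_months(self.birth_date, self.exam_date)

    @property
    def anthropometry(self) -> Anthropometry:
        return Anthropometry(
            weight_kg=self.weight_kg,
            height_cm=self.height_cm,
            measurement_mode=self.measurement_mode,
        )

    @property
    def any_clinical_disorder(self) -> bool:
        return (
            self.hyperglycaemia
            or self.insulin_resistance
            or self.dyslipidaemia
            or self.hypertension
        )

    @property
    def disorder_flags(self) -> dict[str, bool]:
        return {
            "hyperglycaemia": self.hyperglycaemia,
            "insulin_resistance": self.insulin_resistance,
            "dyslipidaemia": self.dyslipidaemia,
            "hypertension": self.hypertension,
        }


class ParentRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    role: ParentRole
    weight_kg: float = Field(gt=0)
    height_cm: float = Field(gt=0)
    education_years: Optional[float] = Field(default=None, ge=0)
    source: AnthropometrySource = AnthropometrySource.measured

    @property
    def bmi(self) -> float:
        height_m = self.height_cm / 100.0
        return self.weight_kg / (height_m * height_m)

    @property
    def obese(self) -> bool:
        return self.bmi > OBESITY_BMI_CUTOFF


class Family(BaseModel):
    model_config = ConfigDict(extra="forbid")

    child: ChildRecord
    mother: Optional[ParentRecord] = None
    father: Optional[ParentRecord] = None

    @field_validator("mother")
    @classmethod
    def _mother_role(cls, v: Optional[ParentRecord]) -> Optional[ParentRecord]:
        if v is not None and v.role is not ParentRole.mother:
            raise ValueError("mother record must have role=mother")
        return v

    @field_validator("father")
    @classmethod
    def _father_role(cls, v: Optional[ParentRecord]) -> Optional[ParentRecord]:
        if v is not None and v.role is not ParentRole.father:
            raise ValueError("father record must have role=father")
        return v

    @property
    def parents(self) -> list[ParentRecord]:
        return [p for p in (self.mother, self.father) if p is not None]

    @property
    def any_obese_parent(self) -> bool:
        return any(p.obese for p in self.parents)

    def core_inputs(self) -> CoreInputs:
        """Assemble CORE index inputs from the child, perinatal and mother data."""
        peri = self.child.perinatal
        return CoreInputs(
            child_sex=self.child.sex,
            maternal_prepregnancy_bmi=(
                peri.maternal_prepregnancy_bmi if peri else None
            ),
            maternal_smoking_pregnancy=(
                peri.maternal_smoking_pregnancy if peri else None
            ),
            infant_weight_birth_kg=peri.birth_weight_kg if peri else None,
            infant_weight_6mo_kg=peri.weight_6mo_kg if peri else None,
            maternal_education_years=(
                self.mother.education_years if self.mother else None
            ),
        )


@dataclass(frozen=True)
class RecordError:
    """A per-record validation failure collected during bulk loading."""

    record_id: str
    message: str


# ---------------------------------------------------------------------------
# CSV dialect

_CHILD_COLUMNS = [
    "child_id", "child_sex", "birth_date", "exam_date", "weight_kg",
    "height_cm", "measurement_mode", "waist_cm", "activity",
    "hyperglycaemia", "insulin_resistance", "dyslipidaemia", "hypertension",
    "maternal_prepregnancy_bmi", "maternal_smoking_pregnancy",
    "birth_weight_kg", "weight_6mo_kg",
]
_PARENT_COLUMNS = [
    "mother_weight_kg", "mother_height_cm", "mother_education_years",
    "mother_source", "father_weight_kg", "father_height_cm", "father_source",
]
CSV_COLUMNS = _CHILD_COLUMNS + _PARENT_COLUMNS


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def _as_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return bool(int(value))
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def _family_from_row(row: dict) -> Family:
    get = lambda key: None if _is_missing(row.get(key)) else row[key]

    perinatal_fields = {
        "maternal_prepregnancy_bmi": get("maternal_prepregnancy_bmi"),
        "maternal_smoking_pregnancy": (
            None
            if _is_missing(row.get("maternal_smoking_pregnancy"))
            else _as_bool(row["maternal_smoking_pregnancy"])
        ),
        "birth_weight_kg": get("birth_weight_kg"),
        "weight_6mo_kg": get("weight_6mo_kg"),
    }
    perinatal = (
        PerinatalRecord(**perinatal_fields)
        if any(v is not None for v in perinatal_fields.values())
        else None
    )
    child = ChildRecord(
        id=str(get("child_id")),
        sex=get("child_sex"),
        birth_date=get("birth_date"),
        exam_date=get("exam_date"),
        weight_kg=get("weight_kg"),
        height_cm=get("height_cm"),
        measurement_mode=get("measurement_mode")
        or MeasurementMode.standing_height,
        waist_cm=get("waist_cm"),
        activity=get("activity") or ActivityCategory.light,
        hyperglycaemia=_as_bool(row.get("hyperglycaemia", False) or False),
        insulin_resistance=_as_bool(row.get("insulin_resistance", False) or False),
        dyslipidaemia=_as_bool(row.get("dyslipidaemia", False) or False),
        hypertension=_as_bool(row.get("hypertension", False) or False),
        perinatal=perinatal,
    )
    mother = None
    if get("mother_weight_kg") is not None:
        mother = ParentRecord(
            role=ParentRole.mother,
            weight_kg=get("mother_weight_kg"),
            height_cm=get("mother_height_cm"),
            education_years=get("mother_education_years"),
            source=get("mother_source") or AnthropometrySource.measured,
        )
    father = None
    if get("father_weight_kg") is not None:
        father = ParentRecord(
            role=ParentRole.father,
            weight_kg=get("father_weight_kg"),
            height_cm=get("father_height_cm"),
            source=get("father_source") or AnthropometrySource.measured,
        )
    return Family(child=child, mother=mother, father=father)


def _family_to_row(family: Family) -> dict:
    child = family.child
    peri = child.perinatal
    row: dict = {
        "child_id": child.id,
        "child_sex": child.sex.value,
        "birth_date": child.birth_date.isoformat(),
        "exam_date": child.exam_date.isoformat(),
        "weight_kg": child.weight_kg,
        "height_cm": child.height_cm,
        "measurement_mode": child.measurement_mode.value,
        "waist_cm": child.waist_cm,
        "activity": child.activity.value,
        "hyperglycaemia": child.hyperglycaemia,
        "insulin_resistance": child.insulin_resistance,
        "dyslipidaemia": child.dyslipidaemia,
        "hypertension": child.hypertension,
        "maternal_prepregnancy_bmi": peri.maternal_prepregnancy_bmi if peri else None,
        "maternal_smoking_pregnancy": peri.maternal_smoking_pregnancy if peri else None,
        "birth_weight_kg": peri.birth_weight_kg if peri else None,
        "weight_6mo_kg": peri.weight_6mo_kg if peri else None,
    }
    for prefix, parent in (("mother", family.mother), ("father", family.father)):
        row[f"{prefix}_weight_kg"] = parent.weight_kg if parent else None
        row[f"{prefix}_height_cm"] = parent.height_cm if parent else None
        row[f"{prefix}_source"] = parent.source.value if parent else None
        if prefix == "mother":
            row["mother_education_years"] = (
                parent.education_years if parent else None
            )
    return row


# ---------------------------------------------------------------------------
# Bulk loading and writing


def load_records(
    path: str | Path, fmt: Optional[str] = None
) -> tuple[list[Family], list[RecordError]]:
    """Load families from a JSON or CSV file.

    Returns the validated families together with per-record errors; an
    unparseable file raises :class:`DSTError` instead.
    """
    path = Path(path)
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        try:
            payload = json.loads(path.read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise DSTError(f"cannot read {path}: {exc}") from exc
        documents = payload if isinstance(payload, list) else [payload]
        families, errors = [], []
        for i, doc in enumerate(documents):
            ident = str(doc.get("child", {}).get("id", f"record-{i}")) if isinstance(doc, dict) else f"record-{i}"
            try:
                families.append(Family.model_validate(doc))
            except Exception as exc:
                errors.append(RecordError(record_id=ident, message=str(exc)))
        return families, errors
    if fmt == "csv":
        try:
            frame = pd.read_csv(
                path, dtype={"child_id": str}, float_precision="round_trip"
            )
        except Exception as exc:
            raise DSTError(f"cannot read {path}: {exc}") from exc
        families, errors = [], []
        for i, row in enumerate(frame.to_dict(orient="records")):
            ident = str(row.get("child_id", f"row-{i}"))
            try:
                families.append(_family_from_row(row))
            except Exception as exc:
                errors.append(RecordError(record_id=ident, message=str(exc)))
        return families, errors
    raise DSTError(f"unknown record format {fmt!r} (expected 'json' or 'csv')")


def write_records_csv(families: list[Family], path: str | Path) -> None:
    """Write families as one-row-per-family CSV in the documented dialect."""
    frame = pd.DataFrame([_family_to_row(f) for f in families], columns=CSV_COLUMNS)
    frame.to_csv(path, index=False)


def write_records_json(families: list[Family], path: str | Path) -> None:
    payload = [json.loads(f.model_dump_json(exclude_none=True)) for f in families]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
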