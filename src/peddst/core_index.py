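"""CORE (Childhood Obesity Risk Evaluation) index scoring.

The CORE index estimates a normal-weight child's likelihood of manifesting
obesity later in childhood from perinatal and socio-demographic factors:
maternal pre-pregnancy weight status, smoking during pregnancy, infant weight
gain in the first six months, the child's sex and the mother's education.
A total score at or above the threshold (default 4) flags a higher likelihood.

The published point assignments are not hard-coded: the component -> points
mapping is runtime configuration (:class:`CoreScoreTable`).  The packaged
default is a PLACEHOLDER with plausible bins, clearly not the published
coefficients; users supply their own table to reproduce the validated score.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import yaml

from .errors import ConfigError, DomainError
from .growth import Sex

_MISSING_POLICIES = ("zero_points", "refuse")

#: Components whose bins are numeric intervals [min, max).
_NUMERIC_COMPONENTS = {
    "maternal_prepregnancy_bmi",
    "weight_gain_0_6mo",
    "maternal_education_years",
}
#: Components whose bins are exact-value matches, with the exhaustive value set.
_CATEGORICAL_COMPONENTS: dict[str, set[Any]] = {
    "child_sex": {"male", "female"},
    "maternal_smoking_pregnancy": {True, False},
}
KNOWN_COMPONENTS = _NUMERIC_COMPONENTS | set(_CATEGORICAL_COMPONENTS)


class RiskLevel(str, enum.Enum):
    higher_likelihood = "higher_likelihood"
    lower_likelihood = "lower_likelihood"


@dataclass(frozen=True)
class CoreInputs:
    """Raw inputs for the CORE index; any field may be missing (None)."""

    child_sex: Optional[Sex] = None
    maternal_prepregnancy_bmi: Optional[float] = None
    maternal_smoking_pregnancy: Optional[bool] = None
    infant_weight_birth_kg: Optional[float] = None
    infant_weight_6mo_kg: Optional[float] = None
    maternal_education_years: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("maternal_prepregnancy_bmi", "infant_weight_birth_kg",
                     "infant_weight_6mo_kg"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise DomainError(f"{name} must be positive when present, got {value}")
        if (
            self.infant_weight_birth_kg is not None
            and self.infant_weight_6mo_kg is not None
            and self.infant_weight_6mo_kg < 0.5 * self.infant_weight_birth_kg
        ):
            raise DomainError(
                "infant_weight_6mo_kg below half the birth weight "
                f"({self.infant_weight_6mo_kg} vs {self.infant_weight_birth_kg})"
            )


def weight_gain_0_6mo(
    birth_kg: Optional[float], six_mo_kg: Optional[float]
) -> Optional[float]:
    """Weight gained between birth and six months; None if either is missing."""
    if birth_kg is None or six_mo_kg is None:
        return None
    if not birth_kg > 0 or not six_mo_kg > 0:
        raise DomainError("infant weights must be positive")
    return six_mo_kg - birth_kg


@dataclass(frozen=True)
class ScoreBin:
    """One scoring bin: either an exact-value match (``equals``) or a
    half-open numeric interval [``min``, ``max``)."""

    points: int
    equals: Any = None
    min: Optional[float] = None
    max: Optional[float] = None

    def matches(self, value: Any) -> bool:
        if self.equals is not None:
            probe = value.value if isinstance(value, enum.Enum) else value
            return probe == self.equals
        lo = -float("inf") if self.min is None else self.min
        hi = float("inf") if self.max is None else self.max
        return lo <= float(value) < hi


@dataclass(frozen=True)
class CoreScore:
    score: int
    components: dict[str, int]
    n_missing: int


class CoreScoreTable:
    """Configurable component -> points mapping with a classification threshold."""

    def __init__(
        self,
        components: dict[str, list[ScoreBin]],
        threshold: int = 4,
        missing_policy: str = "zero_points",
    ) -> None:
        if missing_policy not in _MISSING_POLICIES:
            raise ConfigError(
                f"missing_policy must be one of {_MISSING_POLICIES}, got {missing_policy!r}"
            )
        if threshold < 0:
            raise ConfigError(f"threshold must be non-negative, got {threshold}")
        self.components = components
        self.threshold = int(threshold)
        self.missing_policy = missing_policy
        self._validate()

    def _validate(self) -> None:
        if not self.components:
            raise ConfigError("score table defines no components")
        for name, bins in self.components.items():
            if name not in KNOWN_COMPONENTS:
                raise ConfigError(
                    f"unknown component {name!r}; known: {sorted(KNOWN_COMPONENTS)}"
                )
            if not bins:
                raise ConfigError(f"component {name!r} has no bins")
            if any(b.points < 0 for b in bins):
                raise ConfigError(f"component {name!r} has negative points")
            if name in _CATEGORICAL_COMPONENTS:
                values = [b.equals for b in bins]
                if any(v is None for v in values):
                    raise ConfigError(
                        f"component {name!r} requires 'equals' bins"
                    )
                if len(set(values)) != len(values):
                    raise ConfigError(f"component {name!r} has overlapping bins")
                if set(values) != _CATEGORICAL_COMPONENTS[name]:
                    raise ConfigError(
                        f"component {name!r} bins not exhaustive over "
                        f"{sorted(map(str, _CATEGORICAL_COMPONENTS[name]))}"
                    )
            else:
                ordered = sorted(
                    bins, key=lambda b: -float("inf") if b.min is None else b.min
                )
                if ordered[0].min is not None or ordered[-1].max is not None:
                    raise ConfigError(
                        f"component {name!r} intervals must cover the whole axis "
                        "(first bin open below, last bin open above)"
                    )
                for left, right in zip(ordered, ordered[1:]):
                    if left.max is None or right.min is None or left.max != right.min:
                        raise ConfigError(
                            f"component {name!r} intervals must be contiguous "
                            "and non-overlapping"
                        )

    @property
    def max_score(self) -> int:
        """The largest achievable total score."""
        return sum(max(b.points for b in bins) for bins in self.components.values())

    # -- construction from config ------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "CoreScoreTable":
        components: dict[str, list[ScoreBin]] = {}
        for name, bins in raw.get("components", {}).items():
            parsed = []
            for spec in bins:
                unknown = set(spec) - {"equals", "min", "max", "points"}
                if unknown:
                    raise ConfigError(f"bin for {name!r} has unknown keys {unknown}")
                if "points" not in spec:
                    raise ConfigError(f"bin for {name!r} lacks 'points'")
                parsed.append(
                    ScoreBin(
                        points=int(spec["points"]),
                        equals=spec.get("equals"),
                        min=spec.get("min"),
                        max=spec.get("max"),
                    )
                )
            components[name] = parsed
        return cls(
            components,
            threshold=int(raw.get("threshold", 4)),
            missing_policy=raw.get("missing_policy", "zero_points"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CoreScoreTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "CoreScoreTable":
        """Packaged placeholder table (NOT the published point assignments)."""
        return cls.from_yaml(Path(__file__).parent / "data" / "core_table_default.yaml")

    # -- scoring ------------------------------------------------------------

    def _component_value(self, name: str, inputs: CoreInputs) -> Any:
        if name == "weight_gain_0_6mo":
            return weight_gain_0_6mo(
                inputs.infant_weight_birth_kg, inputs.infant_weight_6mo_kg
            )
        return getattr(inputs, name if name != "child_sex" else "child_sex")

    def score(self, inputs: CoreInputs) -> CoreScore:
        """Total score, per-component points, and the missing-component count.

        Missing components score under the configured policy: ``zero_points``
        contributes 0 and increments ``n_missing``; ``refuse`` raises.
        """
        points: dict[str, int] = {}
        n_missing = 0
        for name, bins in self.components.items():
            value = self._component_value(name, inputs)
            if value is None:
                if self.missing_policy == "refuse":
                    raise DomainError(f"CORE component {name!r} is missing")
                n_missing += 1
                points[name] = 0
                continue
            matched = [b for b in bins if b.matches(value)]
            if len(matched) != 1:
                raise ConfigError(
                    f"value {value!r} for component {name!r} matched "
                    f"{len(matched)} bins (expected exactly 1)"
                )
            points[name] = matched[0].points
        return CoreScore(score=sum(points.values()), components=points,
                         n_missing=n_missing)


def score_core(inputs: CoreInputs, table: CoreScoreTable) -> CoreScore:
    """Functional wrapper around :meth:`CoreScoreTable.score`."""
    return table.score(inputs)


def classify_core(score: int, threshold: int = 4) -> RiskLevel:
    """Higher likelihood of future obesity iff ``score >= threshold``."""
    if score < 0:
        raise DomainError(f"score must be non-negative, got {score}")
    if threshold < 0:
        raise DomainError(f"threshold must be non-negative, got {threshold}")
    return (
        RiskLevel.higher_likelihood
        if score >= threshold
        else RiskLevel.lower_likelihood
    )
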