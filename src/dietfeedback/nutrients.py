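"""Nutrient definitions and the default 17-nutrient reference registry.

The engine grades habitual intakes of 17 nutrients against dietary reference
intakes (DRI-style values: the Estimated Average Requirement EAR, its standard
deviation, and the Tolerable Upper Intake Level UL for adequacy nutrients; a
population target maximum for moderation nutrients such as saturated fat and
salt).  Reference values ship as an editable CSV table with per-entry
provenance notes; the shipped numbers are implementer-supplied DRI-style
placeholders, configurable per deployment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .errors import ConfigurationError

# Canonical identifiers of the 17 nutrients handled by the engine.
NUTRIENTS: tuple[str, ...] = (
    "protein",
    "carbohydrate",
    "total_fat",
    "mufa",
    "pufa",
    "sfa",
    "salt",
    "omega3",
    "fiber",
    "calcium",
    "iron",
    "vitamin_a",
    "folate",
    "thiamin",
    "riboflavin",
    "vitamin_b12",
    "vitamin_c",
)

#: Nutrients whose intake from supplements is NOT counted towards the total
#: (their decision trees consider food sources only).
SUPPLEMENT_EXEMPT: frozenset[str] = frozenset(
    {"carbohydrate", "mufa", "pufa", "fiber", "salt"}
)

#: Energy density used to express macronutrient intakes as % of energy.
KCAL_PER_G: Mapping[str, float] = {
    "protein": 4.0,
    "carbohydrate": 4.0,
    "total_fat": 9.0,
    "mufa": 9.0,
    "pufa": 9.0,
    "sfa": 9.0,
}

ADEQUACY = "adequacy"
MODERATION = "moderation"

DEFAULT_CV = 0.10  # default coefficient of variation when an SD is not given


@dataclass(frozen=True)
class ReferenceStratum:
    """Reference values for one age/sex stratum of a nutrient."""

    ear: Optional[float] = None
    sd: Optional[float] = None
    ul: Optional[float] = None
    target_max: Optional[float] = None
    sex: Optional[str] = None  # None = both sexes
    age_min: float = 0.0
    age_max: float = math.inf

    def applies(self, age: Optional[float], sex: Optional[str]) -> bool:
        if self.sex is not None and sex is not None and self.sex != sex:
            return False
        if self.sex is not None and sex is None:
            return False
        if age is not None and not (self.age_min <= age <= self.age_max):
            return False
        return True


@dataclass(frozen=True)
class NutrientDefinition:
    """Definition and reference values for one nutrient.

    ``schema`` is ``"adequacy"`` (risk is insufficiency; graded around
    EAR/UL) or ``"moderation"`` (risk is excess; graded against a target
    maximum).  ``unit`` is the grading unit: ``%E`` macronutrients are
    converted from g/day using energy intake before grading.
    """

    nutrient_id: str
    unit: str
    schema: str
    strata: tuple[ReferenceStratum, ...]
    supplement_counted: bool = True
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.schema not in (ADEQUACY, MODERATION):
            raise ConfigurationError(
                f"{self.nutrient_id}: unknown schema {self.schema!r}"
            )
        if not self.strata:
            raise ConfigurationError(f"{self.nutrient_id}: no reference strata")
        for s in self.strata:
            if self.schema == ADEQUACY:
                if s.ear is None or s.ear <= 0:
                    raise ConfigurationError(
                        f"{self.nutrient_id}: adequacy nutrient requires EAR > 0"
                    )
                if s.sd is not None and s.sd < 0:
                    raise ConfigurationError(f"{self.nutrient_id}: SD must be >= 0")
            else:
                if s.target_max is None or s.target_max <= 0:
                    raise ConfigurationError(
                        f"{self.nutrient_id}: moderation nutrient requires "
                        "target_max > 0"
                    )

    def stratum_for(
        self, age: Optional[float] = None, sex: Optional[str] = None
    ) -> ReferenceStratum:
        """Select the reference stratum matching an age/sex pair.

        Falls back to the first stratum when no qualifier matches (the
        default registry always has a matching stratum for adult profiles).
        """
        for s in self.strata:
            if s.applies(age, sex):
                return s
        raise ConfigurationError(
            f"{self.nutrient_id}: no reference stratum for age={age}, sex={sex}"
        )


_DATA_PACKAGE = "dietfeedback.data"


def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files(_DATA_PACKAGE).joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_registry(path: Optional[str | Path] = None) -> dict[str, NutrientDefinition]:
    """Load a nutrient reference registry from a CSV configuration table.

    One row per nutrient x stratum with columns: nutrient_id, unit, schema,
    sex, age_min, age_max, ear, sd, ul, target_max, supplement_counted,
    provenance.  ``path=None`` loads the packaged default registry.
    """
    if path is None:
        df = _read_packaged_csv("references.csv")
    else:
        df = pd.read_csv(path)

    def _num(v) -> Optional[float]:
        return None if pd.isna(v) else float(v)

    registry: dict[str, NutrientDefinition] = {}
    for nid, rows in df.groupby("nutrient_id", sort=False):
        strata = tuple(
            ReferenceStratum(
                ear=_num(r.get("ear")),
                sd=_num(r.get("sd")),
                ul=_num(r.get("ul")),
                target_max=_num(r.get("target_max")),
                sex=None if pd.isna(r.get("sex")) else str(r["sex"]),
                age_min=_num(r.get("age_min")) or 0.0,
                age_max=_num(r.get("age_max")) if _num(r.get("age_max")) else math.inf,
            )
            for _, r in rows.iterrows()
        )
        first = rows.iloc[0]
        registry[str(nid)] = NutrientDefinition(
            nutrient_id=str(nid),
            unit=str(first["unit"]),
            schema=str(first["schema"]),
            strata=strata,
            supplement_counted=bool(first["supplement_counted"]),
            provenance=str(first.get("provenance", "")),
        )
    return registry


def default_registry() -> dict[str, NutrientDefinition]:
    """The shipped 17-nutrient registry."""
    reg = load_registry(None)
    missing = set(NUTRIENTS) - set(reg)
    extra = set(reg) - set(NUTRIENTS)
    if missing or extra:
        raise ConfigurationError(
            f"default registry mismatch: missing={sorted(missing)}, "
            f"extra={sorted(extra)}"
        )
    return reg


def write_registry(
    registry: Mapping[str, NutrientDefinition], path: str | Path
) -> None:
    """Write a registry back to the CSV configuration format (round-trips)."""
    rows = []
    for defn in registry.values():
        for s in defn.strata:
            rows.append(
                {
                    "nutrient_id": defn.nutrient_id,
                    "unit": defn.unit,
                    "schema": defn.schema,
                    "sex": s.sex,
                    "age_min": s.age_min,
                    "age_max": None if math.isinf(s.age_max) else s.age_max,
                    "ear": s.ear,
                    "sd": s.sd,
                    "ul": s.ul,
                    "target_max": s.target_max,
                    "supplement_counted": defn.supplement_counted,
                    "provenance": defn.provenance,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
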