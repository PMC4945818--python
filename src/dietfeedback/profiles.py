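"""Participant intake profiles and their file formats.

An :class:`IntakeProfile` is the contract with the upstream dietary
assessment instrument: habitual nutrient intakes from food and from
supplements, daily energy, food-group contribution shares for the saturated
fat and salt trees, portion counts for the five report food groups, and
basic anthropometry.  Profiles round-trip through a wide delimited table
(one row per participant) and through JSON records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .errors import InputError

_CONTRIB_TOL = 1e-9


@dataclass(frozen=True)
class IntakeProfile:
    participant_id: str
    country: str
    age: float
    sex: str  # 'F' | 'M'
    height: float  # m
    weight: float  # kg
    energy: Optional[float]  # kcal/day
    food_intakes: Mapping[str, float]
    supplement_intakes: Mapping[str, float] = field(default_factory=dict)
    #: per target nutrient (sfa, salt): food group -> share of intake
    food_group_contributions: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )
    #: report food group -> portions/day
    portions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise InputError(f"{self.participant_id}: height must be positive")
        for name, mapping in (
            ("food intake", self.food_intakes),
            ("supplement intake", self.supplement_intakes),
            ("portions", self.portions),
        ):
            for k, v in mapping.items():
                if v < 0:
                    raise InputError(
                        f"{self.participant_id}: negative {name} for {k}"
                    )
        for nutrient, shares in self.food_group_contributions.items():
            if any(v < 0 for v in shares.values()):
                raise InputError(
                    f"{self.participant_id}: negative contribution share "
                    f"for {nutrient}"
                )
            total = sum(shares.values())
            if total > 1.0 + _CONTRIB_TOL:
                raise InputError(
                    f"{self.participant_id}: {nutrient} contribution shares "
                    f"sum to {total} > 1"
                )


# ---------------------------------------------------------------------------
# Wide-table format: one row per participant.  Nutrient columns are prefixed
# food_ / supp_; contribution columns contrib_<nutrient>__<food group>;
# portion columns portion_<food group>.  Spaces in food-group names are kept
# as-is inside the column name after the prefix.
# ---------------------------------------------------------------------------

_SCALARS = ["participant_id", "country", "age", "sex", "height", "weight", "energy"]


def profiles_to_frame(profiles: list[IntakeProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row: dict[str, object] = {k: getattr(p, k) for k in _SCALARS}
        for n, v in p.food_intakes.items():
            row[f"food_{n}"] = v
        for n, v in p.supplement_intakes.items():
            row[f"supp_{n}"] = v
        for nutrient, shares in p.food_group_contributions.items():
            for g, v in shares.items():
                row[f"contrib_{nutrient}__{g}"] = v
        for g, v in p.portions.items():
            row[f"portion_{g}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame) -> list[IntakeProfile]:
    profiles = []
    for _, row in df.iterrows():
        food: dict[str, float] = {}
        supp: dict[str, float] = {}
        contrib: dict[str, dict[str, float]] = {}
        portions: dict[str, float] = {}
        for col, val in row.items():
            if pd.isna(val):
                continue
            col = str(col)
            if col.startswith("food_"):
                food[col[5:]] = float(val)
            elif col.startswith("supp_"):
                supp[col[5:]] = float(val)
            elif col.startswith("contrib_"):
                nutrient, group = col[8:].split("__", 1)
                contrib.setdefault(nutrient, {})[group] = float(val)
            elif col.startswith("portion_"):
                portions[col[8:]] = float(val)
        profiles.append(
            IntakeProfile(
                participant_id=str(row["participant_id"]),
                country=str(row["country"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                height=float(row["height"]),
                weight=float(row["weight"]),
                energy=None if pd.isna(row["energy"]) else float(row["energy"]),
                food_intakes=food,
                supplement_intakes=supp,
                food_group_contributions=contrib,
                portions=portions,
            )
        )
    return profiles


def write_profiles_csv(profiles: list[IntakeProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles_csv(path: str | Path) -> list[IntakeProfile]:
    return frame_to_profiles(pd.read_csv(path))


def _profile_record(p: IntakeProfile) -> dict:
    return {
        "participant_id": p.participant_id,
        "country": p.country,
        "age": p.age,
        "sex": p.sex,
        "height": p.height,
        "weight": p.weight,
        "energy": p.energy,
        "food_intakes": dict(p.food_intakes),
        "supplement_intakes": dict(p.supplement_intakes),
        "food_group_contributions": {
            k: dict(v) for k, v in p.food_group_contributions.items()
        },
        "portions": dict(p.portions),
    }


def write_profiles_json(profiles: list[IntakeProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([_profile_record(p) for p in profiles], fh, indent=1)


def read_profiles_json(path: str | Path) -> list[IntakeProfile]:
    with open(path) as fh:
        records = json.load(fh)
    return [IntakeProfile(**r) for r in records]
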