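"""Selection of the 3 nutrient-related goals from a graded profile.

The 17 nutrients are split into 3 priority groups — fat-related nutrients
first, then the remaining macronutrient/B-vitamin/salt group, then the
micronutrient group — each internally ranked by public-health priority.
Within each group, red-flagged nutrients outrank amber ones regardless of
rank.  One goal is drawn from the top of each group; groups without any
flagged nutrient give their slot up to the next-best flagged candidate from
the other groups, and any slot still open becomes a positive "maintain"
goal on the highest-priority green nutrient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, InputError
from .grading import GradedNutrient

#: Default priority groups, highest priority first within each group.
DEFAULT_GROUPS: tuple[tuple[str, ...], ...] = (
    ("sfa", "omega3", "total_fat", "mufa", "pufa"),
    (
        "folate",
        "fiber",
        "salt",
        "vitamin_b12",
        "riboflavin",
        "thiamin",
        "protein",
        "carbohydrate",
    ),
    ("calcium", "iron", "vitamin_c", "vitamin_a"),
)

N_GOALS = 3


@dataclass(frozen=True)
class PriorityGroupConfig:
    """Ordered priority groups; the union must cover the registry exactly."""

    groups: tuple[tuple[str, ...], ...] = DEFAULT_GROUPS

    def __post_init__(self) -> None:
        flat = [n for g in self.groups for n in g]
        if len(flat) != len(set(flat)):
            raise ConfigurationError("priority groups contain duplicate nutrients")

    def all_nutrients(self) -> frozenset[str]:
        return frozenset(n for g in self.groups for n in g)

    def validate_against(self, nutrient_ids: set[str]) -> None:
        if self.all_nutrients() != nutrient_ids:
            raise ConfigurationError(
                "priority groups do not match the graded registry: "
                f"groups-only={sorted(self.all_nutrients() - nutrient_ids)}, "
                f"registry-only={sorted(nutrient_ids - self.all_nutrients())}"
            )


@dataclass(frozen=True)
class Goal:
    nutrient_id: str
    slot: int  # 1..3
    goal_type: str  # 'improve' | 'maintain'
    flag_color: str  # red | amber | green

    def __post_init__(self) -> None:
        if (self.goal_type == "maintain") != (self.flag_color == "green"):
            raise InputError(
                f"goal {self.nutrient_id}: maintain goals are exactly the "
                "green-flagged ones"
            )


@dataclass(frozen=True)
class GoalSet:
    participant_id: str
    goals: tuple[Goal, ...]

    def __post_init__(self) -> None:
        ids = [g.nutrient_id for g in self.goals]
        if len(ids) != len(set(ids)):
            raise InputError(f"{self.participant_id}: duplicate goal nutrients")
        if [g.slot for g in self.goals] != list(range(1, len(self.goals) + 1)):
            raise InputError(f"{self.participant_id}: goal slots must be 1..n")

    def nutrients(self) -> tuple[str, ...]:
        return tuple(g.nutrient_id for g in self.goals)


def flag_nutrients(
    graded: Mapping[str, GradedNutrient],
    config: PriorityGroupConfig = PriorityGroupConfig(),
) -> list[list[tuple[str, str]]]:
    """Per-group ordered candidate lists of (nutrient, color), reds first.

    Greens are excluded; within a group, candidates are ordered red before
    amber and by group priority rank within a color.
    """
    config.validate_against(set(graded))
    out: list[list[tuple[str, str]]] = []
    for group in config.groups:
        reds = [(n, "red") for n in group if graded[n].color == "red"]
        ambers = [(n, "amber") for n in group if graded[n].color == "amber"]
        out.append(reds + ambers)
    return out


def select_goals(
    graded: Mapping[str, GradedNutrient],
    config: PriorityGroupConfig = PriorityGroupConfig(),
    participant_id: str = "",
) -> GoalSet:
    """Select exactly 3 nutrient-related goals from a graded profile.

    Pass 1 takes the top flagged candidate of each group in group order,
    each into the lowest open slot.  Open slots are then backfilled with the
    remaining flagged candidates scanning groups in order (red before amber,
    then rank).  Slots still open become maintain goals on the
    highest-priority green nutrients, again scanning groups in order.
    """
    candidates = flag_nutrients(graded, config)
    chosen: list[tuple[str, str, str]] = []  # (nutrient, goal_type, color)
    taken: set[str] = set()

    # Pass 1: top candidate of each group, group order.
    for group_cands in candidates:
        if len(chosen) >= N_GOALS:
            break
        if group_cands:
            n, color = group_cands[0]
            chosen.append((n, "improve", color))
            taken.add(n)

    # Pass 2: backfill from remaining flagged candidates across groups.
    for group_cands in candidates:
        for n, color in group_cands:
            if len(chosen) >= N_GOALS:
                break
            if n not in taken:
                chosen.append((n, "improve", color))
                taken.add(n)

    # Pass 3: maintain goals on highest-priority greens.
    for group in config.groups:
        for n in group:
            if len(chosen) >= N_GOALS:
                break
            if n not in taken and graded[n].color == "green":
                chosen.append((n, "maintain", "green"))
                taken.add(n)

    goals = tuple(
        Goal(nutrient_id=n, slot=i + 1, goal_type=t, flag_color=c)
        for i, (n, t, c) in enumerate(chosen)
    )
    return GoalSet(participant_id=participant_id, goals=goals)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def goal_sets_to_frame(goal_sets: Sequence[GoalSet]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": gs.participant_id,
            "slot": g.slot,
            "nutrient_id": g.nutrient_id,
            "goal_type": g.goal_type,
            "flag_color": g.flag_color,
        }
        for gs in goal_sets
        for g in gs.goals
    ]
    return pd.DataFrame(rows)


def frame_to_goal_sets(df: pd.DataFrame) -> list[GoalSet]:
    out = []
    for pid, rows in df.groupby("participant_id", sort=False):
        rows = rows.sort_values("slot")
        goals = tuple(
            Goal(
                nutrient_id=str(r.nutrient_id),
                slot=int(r.slot),
                goal_type=str(r.goal_type),
                flag_color=str(r.flag_color),
            )
            for r in rows.itertuples()
        )
        out.append(GoalSet(participant_id=str(pid), goals=goals))
    return out


def write_goal_sets_csv(goal_sets: Sequence[GoalSet], path: str | Path) -> None:
    goal_sets_to_frame(goal_sets).to_csv(path, index=False)


def read_goal_sets_csv(path: str | Path) -> list[GoalSet]:
    return frame_to_goal_sets(pd.read_csv(path))
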