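"""Percent agreement between two advice-generating systems.

Compares goal selection per slot (1, 2, 3), goal selection in random order
(same three nutrients, any slots), and — for participants whose goal sets
match exactly — the advice messages per slot, categorized as complete
agreement (identical message sets), complete disagreement (no message in
common), or partial agreement (some overlap; only possible for the
multi-message saturated-fat and salt advice).  Summaries are raw percent
agreement per stratum (e.g., country) with an unweighted average row,
percentages printed as integers with the exact fractions retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import InputError
from .goals import GoalSet

N_SLOTS = 3

COMPLETE = "complete"
DISAGREEMENT = "disagreement"
PARTIAL = "partial"


@dataclass(frozen=True)
class AdviceAssignment:
    participant_id: str
    source: str  # 'manual' | 'automated'
    goal_set: GoalSet
    #: slot -> ordered message ids for that goal
    messages: Mapping[int, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        slots = {g.slot for g in self.goal_set.goals}
        bad = set(self.messages) - slots
        if bad:
            raise InputError(
                f"{self.participant_id}: messages keyed by non-existent slots {sorted(bad)}"
            )


def _check_same_participant(a: GoalSet, b: GoalSet) -> None:
    if a.participant_id != b.participant_id:
        raise InputError(
            f"cannot compare goal sets of different participants "
            f"({a.participant_id!r} vs {b.participant_id!r})"
        )


def compare_goal_slots(a: GoalSet, b: GoalSet) -> tuple[bool, bool, bool]:
    """Per-slot nutrient match; a slot missing from either set is a mismatch."""
    _check_same_participant(a, b)
    a_by_slot = {g.slot: g.nutrient_id for g in a.goals}
    b_by_slot = {g.slot: g.nutrient_id for g in b.goals}
    return tuple(
        s in a_by_slot and s in b_by_slot and a_by_slot[s] == b_by_slot[s]
        for s in range(1, N_SLOTS + 1)
    )


def compare_random_order(a: GoalSet, b: GoalSet) -> bool:
    """True iff both systems selected the same three nutrients, in any order."""
    _check_same_participant(a, b)
    sa, sb = set(a.nutrients()), set(b.nutrients())
    return len(sa) == N_SLOTS and sa == sb


def compare_messages(
    a: AdviceAssignment, b: AdviceAssignment
) -> dict[int, str]:
    """Per-slot message-agreement category for a goal-matched pair.

    Only defined for participants given the same goals in the same slots by
    both systems; within-slot message order is ignored.
    """
    _check_same_participant(a.goal_set, b.goal_set)
    a_by_slot = {g.slot: g.nutrient_id for g in a.goal_set.goals}
    b_by_slot = {g.slot: g.nutrient_id for g in b.goal_set.goals}
    if a_by_slot != b_by_slot:
        raise InputError(
            f"{a.participant_id}: message agreement is only computed for "
            "participants with identical goal selections"
        )
    categories: dict[int, str] = {}
    for slot in sorted(a_by_slot):
        ma = set(a.messages.get(slot, ()))
        mb = set(b.messages.get(slot, ()))
        if ma == mb:
            categories[slot] = COMPLETE
        elif not (ma & mb):
            categories[slot] = DISAGREEMENT
        else:
            categories[slot] = PARTIAL
    return categories


@dataclass(frozen=True)
class AgreementSummary:
    """Raw agreement fractions for one stratum (or the average row)."""

    stratum: str
    n: int
    slot_agreement: tuple[float, float, float]  # fractions in [0,1]
    random_order_agreement: float
    n_message_comparisons: int
    message_counts: Mapping[str, int]  # category -> count

    def message_fractions(self) -> dict[str, float]:
        total = self.n_message_comparisons
        return {
            k: (v / total if total else 0.0) for k, v in self.message_counts.items()
        }


def summarize_agreement(
    pairs: Sequence[tuple[AdviceAssignment, AdviceAssignment]],
    strata: Optional[Mapping[str, str]] = None,
) -> list[AgreementSummary]:
    """Summarize agreement per stratum plus an unweighted average row.

    ``pairs`` are (manual, automated) assignments for the same participants;
    ``strata`` maps participant_id -> stratum label (one stratum "all" when
    omitted).  Message categories are tallied over the per-slot comparisons
    of goal-matched participants only.
    """
    if not pairs:
        raise InputError("summarize_agreement: empty input")
    by_stratum: dict[str, list[tuple[AdviceAssignment, AdviceAssignment]]] = {}
    for manual, automated in pairs:
        if manual.participant_id != automated.participant_id:
            raise InputError("pair mixes different participants")
        label = strata.get(manual.participant_id, "all") if strata else "all"
        by_stratum.setdefault(label, []).append((manual, automated))

    summaries = []
    for label in sorted(by_stratum):
        stratum_pairs = by_stratum[label]
        n = len(stratum_pairs)
        slot_hits = [0, 0, 0]
        random_hits = 0
        msg_counts = {COMPLETE: 0, DISAGREEMENT: 0, PARTIAL: 0}
        n_msg = 0
        for manual, automated in stratum_pairs:
            slots = compare_goal_slots(manual.goal_set, automated.goal_set)
            for i, hit in enumerate(slots):
                slot_hits[i] += hit
            random_hits += compare_random_order(manual.goal_set, automated.goal_set)
            if all(slots):
                for category in compare_messages(manual, automated).values():
                    msg_counts[category] += 1
                    n_msg += 1
        summaries.append(
            AgreementSummary(
                stratum=label,
                n=n,
                slot_agreement=tuple(h / n for h in slot_hits),
                random_order_agreement=random_hits / n,
                n_message_comparisons=n_msg,
                message_counts=msg_counts,
            )
        )

    if len(summaries) > 1:
        k = len(summaries)
        summaries.append(
            AgreementSummary(
                stratum="average",
                n=sum(s.n for s in summaries),
                slot_agreement=tuple(
                    sum(s.slot_agreement[i] for s in summaries) / k for i in range(3)
                ),
                random_order_agreement=sum(s.random_order_agreement for s in summaries)
                / k,
                n_message_comparisons=sum(s.n_message_comparisons for s in summaries),
                message_counts={
                    c: sum(s.message_counts[c] for s in summaries)
                    for c in (COMPLETE, DISAGREEMENT, PARTIAL)
                },
            )
        )
    return summaries


def goal_agreement_table(summaries: Sequence[AgreementSummary]) -> pd.DataFrame:
    """Stratum x (slot 1-3, random order) integer-percent table."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "stratum": s.stratum,
                "n": s.n,
                "goal_1_pct": round(100 * s.slot_agreement[0]),
                "goal_2_pct": round(100 * s.slot_agreement[1]),
                "goal_3_pct": round(100 * s.slot_agreement[2]),
                "random_order_pct": round(100 * s.random_order_agreement),
            }
        )
    return pd.DataFrame(rows)


def message_agreement_table(summaries: Sequence[AgreementSummary]) -> pd.DataFrame:
    """Stratum x message-category n (%) table."""
    rows = []
    for s in summaries:
        fr = s.message_fractions()
        rows.append(
            {
                "stratum": s.stratum,
                "n": s.n_message_comparisons,
                "complete_n": s.message_counts[COMPLETE],
                "complete_pct": round(100 * fr[COMPLETE]),
                "disagreement_n": s.message_counts[DISAGREEMENT],
                "disagreement_pct": round(100 * fr[DISAGREEMENT]),
                "partial_n": s.message_counts[PARTIAL],
                "partial_pct": round(100 * fr[PARTIAL]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Assignment files (as written by the advise pipeline or external annotation)
# ---------------------------------------------------------------------------

def assignments_to_frame(assignments: Sequence[AdviceAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        for g in a.goal_set.goals:
            rows.append(
                {
                    "participant_id": a.participant_id,
                    "source": a.source,
                    "slot": g.slot,
                    "nutrient_id": g.nutrient_id,
                    "goal_type": g.goal_type,
                    "flag_color": g.flag_color,
                    "message_ids": ";".join(a.messages.get(g.slot, ())),
                }
            )
    return pd.DataFrame(rows)


def frame_to_assignments(df: pd.DataFrame) -> list[AdviceAssignment]:
    from .goals import Goal

    out = []
    for (pid, source), rows in df.groupby(["participant_id", "source"], sort=False):
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
        messages = {
            int(r.slot): tuple(str(r.message_ids).split(";")) if str(r.message_ids) not in ("", "nan") else ()
            for r in rows.itertuples()
        }
        out.append(
            AdviceAssignment(
                participant_id=str(pid),
                source=str(source),
                goal_set=GoalSet(participant_id=str(pid), goals=goals),
                messages=messages,
            )
        )
    return out


def write_assignments_csv(
    assignments: Sequence[AdviceAssignment], path: str | Path
) -> None:
    assignments_to_frame(assignments).to_csv(path, index=False)


def read_assignments_csv(path: str | Path) -> list[AdviceAssignment]:
    return frame_to_assignments(pd.read_csv(path, keep_default_na=False))
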