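"""Composition and rendering of the four-section personalized feedback report.

Each report opens with a short encouragement naming the participant's main
improvement areas, followed by: (1) portions of five key food groups
compared with guideline amounts, (2) physical characteristics (height,
weight, BMI and activity vs recommendation), (3) the full nutrient profile
on the three-level gradation scale, and (4) the personalized advice table —
the three nutrient-related goals with dietary sources and their
decision-tree messages.  Renders to a structured record (round-trips), plain
text, and HTML.
"""

from __future__ import annotations

import html as _html
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .errors import InputError
from .goals import Goal, GoalSet
from .grading import GradedNutrient
from .profiles import IntakeProfile
from .trees import FeedbackMessage

#: The five report food groups and default guideline amounts (portions).
#: The shipped guideline table is a configurable placeholder amalgamating
#: typical national dietary advice.
REPORT_FOOD_GROUPS: tuple[str, ...] = (
    "fruit and vegetables",
    "whole grains",
    "dairy products",
    "oily fish",
    "red meat",
)


@dataclass(frozen=True)
class FoodGroupGuideline:
    food_group: str
    guideline_portions: float
    period: str  # 'day' | 'week'
    direction: str  # 'at-least' | 'at-most'

    def __post_init__(self) -> None:
        if self.guideline_portions <= 0:
            raise InputError(f"{self.food_group}: guideline must be positive")
        if self.direction not in ("at-least", "at-most"):
            raise InputError(f"{self.food_group}: bad direction {self.direction!r}")


DEFAULT_GUIDELINES: tuple[FoodGroupGuideline, ...] = (
    FoodGroupGuideline("fruit and vegetables", 5, "day", "at-least"),
    FoodGroupGuideline("whole grains", 3, "day", "at-least"),
    FoodGroupGuideline("dairy products", 2, "day", "at-least"),
    FoodGroupGuideline("oily fish", 1, "week", "at-least"),
    FoodGroupGuideline("red meat", 3, "week", "at-most"),
)

#: WHO adult BMI cutoffs.
BMI_CUTOFFS = (18.5, 25.0, 30.0)
BMI_CLASSES = ("underweight", "healthy weight", "overweight", "obese")

#: Default moderate-activity recommendation (min/week).
ACTIVITY_THRESHOLD_MIN_PER_WEEK = 150.0


def compute_bmi(height: float, weight: float) -> float:
    """Body mass index, kg/m^2."""
    if height <= 0 or weight <= 0:
        raise InputError("height and weight must be positive")
    return weight / height**2


def classify_bmi(bmi: float) -> str:
    for cutoff, label in zip(BMI_CUTOFFS, BMI_CLASSES):
        if bmi < cutoff:
            return label
    return BMI_CLASSES[-1]


@dataclass(frozen=True)
class PortionRow:
    food_group: str
    observed: float
    guideline: float
    period: str
    direction: str
    status: str  # 'meets' | 'exceeds' | 'short'


def compare_portions(
    portions: Mapping[str, float],
    guidelines: Sequence[FoodGroupGuideline] = DEFAULT_GUIDELINES,
    permissive: bool = False,
) -> list[PortionRow]:
    """Compare observed portions with guideline amounts, one row per group."""
    import logging

    rows = []
    for g in guidelines:
        if g.food_group not in portions:
            if permissive:
                logging.getLogger(__name__).warning(
                    "portions missing for %s; omitting row", g.food_group
                )
                continue
            raise InputError(f"portions missing for food group {g.food_group!r}")
        observed = portions[g.food_group]
        if g.direction == "at-least":
            status = "meets" if observed >= g.guideline_portions else "short"
        else:
            status = "meets" if observed <= g.guideline_portions else "exceeds"
        rows.append(
            PortionRow(
                food_group=g.food_group,
                observed=observed,
                guideline=g.guideline_portions,
                period=g.period,
                direction=g.direction,
                status=status,
            )
        )
    return rows


@dataclass(frozen=True)
class GoalRow:
    slot: int
    nutrient_id: str
    goal_type: str
    report_label: str
    dietary_sources: str
    message_ids: tuple[str, ...]
    message_texts: tuple[str, ...]


@dataclass(frozen=True)
class FeedbackReport:
    participant_id: str
    opener: str
    section1: tuple[PortionRow, ...]
    section2: dict
    section3: tuple[tuple[str, str], ...]  # (nutrient, report label)
    section4: tuple[GoalRow, ...]


_OPENER_TEMPLATE = (
    "Well done for completing your dietary assessment, {participant_id}! "
    "{focus_clause} Small, consistent changes make the biggest difference."
)


def _opener(participant_id: str, goal_set: GoalSet) -> str:
    improve = [g.nutrient_id.replace("_", " ") for g in goal_set.goals if g.goal_type == "improve"]
    if improve:
        focus = "Your main areas for improvement are: " + ", ".join(improve) + "."
    else:
        focus = "Your nutrient intakes are on track - keep it up."
    return _OPENER_TEMPLATE.format(participant_id=participant_id, focus_clause=focus)


#: Short dietary-source notes shown next to each goal in section 4.
DIETARY_SOURCES: Mapping[str, str] = {
    "protein": "meat, fish, eggs, dairy, beans",
    "carbohydrate": "bread, rice, pasta, potatoes, cereals",
    "total_fat": "oils, spreads, fatty meats, dairy",
    "mufa": "olive and rapeseed oil, nuts, avocado",
    "pufa": "vegetable oils, oily fish, nuts, seeds",
    "sfa": "fatty meats, full-fat dairy, butter, pastries",
    "salt": "bread, processed meats, cheese, ready meals",
    "omega3": "oily fish, walnuts, rapeseed oil",
    "fiber": "wholegrains, fruit, vegetables, pulses",
    "calcium": "milk, yogurt, cheese, fortified drinks",
    "iron": "red meat, pulses, dark-green vegetables",
    "vitamin_a": "carrots, leafy greens, dairy",
    "folate": "leafy greens, beans, fortified cereals",
    "thiamin": "wholegrains, pork, beans",
    "riboflavin": "milk, eggs, fortified cereals",
    "vitamin_b12": "meat, fish, eggs, dairy",
    "vitamin_c": "citrus, berries, peppers, broccoli",
}


def compose_report(
    profile: IntakeProfile,
    graded: Mapping[str, GradedNutrient],
    goal_set: GoalSet,
    messages: Mapping[int, Sequence[FeedbackMessage]],
    guidelines: Sequence[FoodGroupGuideline] = DEFAULT_GUIDELINES,
    activity_min_per_week: Optional[float] = None,
) -> FeedbackReport:
    """Compose the standardized feedback report for one participant.

    ``messages`` maps goal slot -> resolved messages for that goal.
    """
    if goal_set.participant_id != profile.participant_id:
        raise InputError(
            f"goal set participant {goal_set.participant_id!r} does not match "
            f"profile {profile.participant_id!r}"
        )
    bmi = compute_bmi(profile.height, profile.weight)
    section2 = {
        "height_m": profile.height,
        "weight_kg": profile.weight,
        "bmi": round(bmi, 2),
        "bmi_class": classify_bmi(bmi),
        "activity_min_per_week": activity_min_per_week,
        "activity_meets_recommendation": (
            None
            if activity_min_per_week is None
            else activity_min_per_week >= ACTIVITY_THRESHOLD_MIN_PER_WEEK
        ),
    }
    section3 = tuple((nid, gn.report_label) for nid, gn in graded.items())
    section4 = tuple(
        GoalRow(
            slot=g.slot,
            nutrient_id=g.nutrient_id,
            goal_type=g.goal_type,
            report_label=graded[g.nutrient_id].report_label,
            dietary_sources=DIETARY_SOURCES.get(g.nutrient_id, ""),
            message_ids=tuple(m.message_id for m in messages.get(g.slot, ())),
            message_texts=tuple(m.text for m in messages.get(g.slot, ())),
        )
        for g in goal_set.goals
    )
    return FeedbackReport(
        participant_id=profile.participant_id,
        opener=_opener(profile.participant_id, goal_set),
        section1=tuple(compare_portions(profile.portions, guidelines)),
        section2=section2,
        section3=section3,
        section4=section4,
    )


# ---------------------------------------------------------------------------
# Renderers
# ---------------------------------------------------------------------------

def report_to_record(report: FeedbackReport) -> dict:
    """Structured-record (JSON-safe) rendering; parses back losslessly."""
    return asdict(report)


def record_to_report(record: dict) -> FeedbackReport:
    return FeedbackReport(
        participant_id=record["participant_id"],
        opener=record["opener"],
        section1=tuple(PortionRow(**r) for r in record["section1"]),
        section2=dict(record["section2"]),
        section3=tuple((n, lbl) for n, lbl in record["section3"]),
        section4=tuple(
            GoalRow(
                slot=r["slot"],
                nutrient_id=r["nutrient_id"],
                goal_type=r["goal_type"],
                report_label=r["report_label"],
                dietary_sources=r["dietary_sources"],
                message_ids=tuple(r["message_ids"]),
                message_texts=tuple(r["message_texts"]),
            )
            for r in record["section4"]
        ),
    )


def render_text(report: FeedbackReport) -> str:
    lines = [f"Personal nutrition report for {report.participant_id}", ""]
    lines.append(report.opener)
    lines.append("")
    lines.append("1. How your diet compares to recommendations")
    for r in report.section1:
        lines.append(
            f"   - {r.food_group}: {r.observed:g}/{r.period} vs "
            f"{r.direction} {r.guideline:g}/{r.period} -> {r.status}"
        )
    s2 = report.section2
    lines.append("")
    lines.append("2. Your physical characteristics")
    lines.append(f"   - height: {s2['height_m']:.2f} m, weight: {s2['weight_kg']:.1f} kg")
    lines.append(f"   - BMI: {s2['bmi']:.2f} kg/m2 ({s2['bmi_class']})")
    if s2["activity_min_per_week"] is not None:
        verdict = "meets" if s2["activity_meets_recommendation"] else "below"
        lines.append(
            f"   - activity: {s2['activity_min_per_week']:g} min/week ({verdict} recommendation)"
        )
    lines.append("")
    lines.append("3. Your nutrient profile")
    for nid, label in report.section3:
        lines.append(f"   - {nid.replace('_', ' ')}: {label}")
    lines.append("")
    lines.append("4. Your personalized nutrition advice")
    for row in report.section4:
        lines.append(
            f"   Goal {row.slot}: {row.nutrient_id.replace('_', ' ')} "
            f"({row.goal_type}; sources: {row.dietary_sources})"
        )
        for text in row.message_texts:
            lines.append(f"      * {text}")
    return "\n".join(lines) + "\n"


def render_html(report: FeedbackReport) -> str:
    e = _html.escape
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        f"<title>Report {e(report.participant_id)}</title></head><body>",
        f"<h1>Personal nutrition report for {e(report.participant_id)}</h1>",
        f"<p>{e(report.opener)}</p>",
        "<h2>1. How your diet compares to recommendations</h2><table>",
        "<tr><th>Food group</th><th>Your portions</th><th>Guideline</th><th>Status</th></tr>",
    ]
    for r in report.section1:
        parts.append(
            f"<tr><td>{e(r.food_group)}</td><td>{r.observed:g}/{e(r.period)}</td>"
            f"<td>{e(r.direction)} {r.guideline:g}/{e(r.period)}</td>"
            f"<td>{e(r.status)}</td></tr>"
        )
    s2 = report.section2
    parts.append("</table><h2>2. Your physical characteristics</h2><ul>")
    parts.append(f"<li>Height: {s2['height_m']:.2f} m</li>")
    parts.append(f"<li>Weight: {s2['weight_kg']:.1f} kg</li>")
    parts.append(f"<li>BMI: {s2['bmi']:.2f} kg/m&sup2; ({e(s2['bmi_class'])})</li>")
    parts.append("</ul><h2>3. Your nutrient profile</h2><ul>")
    for nid, label in report.section3:
        parts.append(f"<li>{e(nid.replace('_', ' '))}: {e(label)}</li>")
    parts.append("</ul><h2>4. Your personalized nutrition advice</h2>")
    for row in report.section4:
        parts.append(
            f"<h3>Goal {row.slot}: {e(row.nutrient_id.replace('_', ' '))} "
            f"({e(row.goal_type)})</h3>"
        )
        parts.append(f"<p>Dietary sources: {e(row.dietary_sources)}</p><ul>")
        for text in row.message_texts:
            parts.append(f"<li>{e(text)}</li>")
        parts.append("</ul>")
    parts.append("</body></html>")
    return "\n".join(parts)


def write_report(report: FeedbackReport, path: str | Path, fmt: str = "json") -> None:
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report_to_record(report), indent=1))
    elif fmt == "text":
        path.write_text(render_text(report))
    elif fmt == "html":
        path.write_text(render_html(report))
    else:
        raise InputError(f"unknown report format {fmt!r}")
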