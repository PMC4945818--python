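"""End-to-end advice pipeline: grade → select goals → resolve messages → report."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .agreement import AdviceAssignment
from .goals import GoalSet, PriorityGroupConfig, select_goals
from .grading import GradedNutrient, grade_profile
from .nutrients import NutrientDefinition, default_registry
from .profiles import IntakeProfile
from .report import FeedbackReport, FoodGroupGuideline, DEFAULT_GUIDELINES, compose_report
from .trees import (
    DecisionTree,
    FeedbackMessage,
    MessageCatalog,
    default_catalog,
    default_trees,
    resolve_feedback,
    tree_key,
)


def resolve_goal_messages(
    goal_set: GoalSet,
    graded: Mapping[str, GradedNutrient],
    profile: IntakeProfile,
    trees: Mapping[str, DecisionTree],
    catalog: MessageCatalog,
    registry: Mapping[str, NutrientDefinition],
    locale: str = "en",
) -> dict[int, list[FeedbackMessage]]:
    """Resolve the decision-tree messages for every goal in a set."""
    out: dict[int, list[FeedbackMessage]] = {}
    for goal in goal_set.goals:
        tree = trees[tree_key(goal.nutrient_id)]
        out[goal.slot] = resolve_feedback(
            goal,
            graded[goal.nutrient_id],
            profile,
            tree,
            catalog,
            locale=locale,
            supplement_counted=registry[goal.nutrient_id].supplement_counted,
        )
    return out


def advise_profile(
    profile: IntakeProfile,
    registry: Optional[Mapping[str, NutrientDefinition]] = None,
    trees: Optional[Mapping[str, DecisionTree]] = None,
    catalog: Optional[MessageCatalog] = None,
    priority_config: Optional[PriorityGroupConfig] = None,
    locale: str = "en",
) -> tuple[dict[str, GradedNutrient], AdviceAssignment]:
    """Run grading, goal selection and message resolution for one profile."""
    registry = registry or default_registry()
    trees = trees or default_trees()
    catalog = catalog or default_catalog()
    priority_config = priority_config or PriorityGroupConfig()

    graded = grade_profile(profile, registry)
    goal_set = select_goals(graded, priority_config, participant_id=profile.participant_id)
    messages = resolve_goal_messages(
        goal_set, graded, profile, trees, catalog, registry, locale
    )
    assignment = AdviceAssignment(
        participant_id=profile.participant_id,
        source="automated",
        goal_set=goal_set,
        messages={s: tuple(m.message_id for m in msgs) for s, msgs in messages.items()},
    )
    return graded, assignment


def report_for_profile(
    profile: IntakeProfile,
    registry: Optional[Mapping[str, NutrientDefinition]] = None,
    trees: Optional[Mapping[str, DecisionTree]] = None,
    catalog: Optional[MessageCatalog] = None,
    priority_config: Optional[PriorityGroupConfig] = None,
    guidelines: Sequence[FoodGroupGuideline] = DEFAULT_GUIDELINES,
    locale: str = "en",
    activity_min_per_week: Optional[float] = None,
) -> FeedbackReport:
    """Full pipeline for one participant, ending in a composed report."""
    registry = registry or default_registry()
    trees = trees or default_trees()
    catalog = catalog or default_catalog()
    priority_config = priority_config or PriorityGroupConfig()

    graded = grade_profile(profile, registry)
    goal_set = select_goals(graded, priority_config, participant_id=profile.participant_id)
    messages = resolve_goal_messages(
        goal_set, graded, profile, trees, catalog, registry, locale
    )
    return compose_report(
        profile,
        graded,
        goal_set,
        messages,
        guidelines=guidelines,
        activity_min_per_week=activity_min_per_week,
    )
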