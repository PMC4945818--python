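"""Decision trees linking graded intakes to feedback messages.

Sixteen trees cover the 17 nutrients (MUFA and PUFA share a single
unsaturated-fat tree).  Each tree is a flat table of condition rows —
gradation band, optional supplement-use predicate, optional food-group
predicate — mapping to message identifiers in a localized catalog of 92
messages.  The saturated-fat and salt trees additionally identify the two
main contributing food groups out of seven candidates, so their advice on a
flagged band consists of one general message plus one message per identified
contributor (2-4 messages in total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import CatalogIntegrityError, ConfigurationError, InputError
from .goals import Goal
from .grading import BANDS, GradedNutrient
from .profiles import IntakeProfile

logger = logging.getLogger(__name__)

REFERENCE_LOCALE = "en"

#: Nutrient -> tree key.  MUFA and PUFA share the unsaturated-fat tree.
TREE_FOR_NUTRIENT: Mapping[str, str] = {
    "mufa": "unsaturated_fat",
    "pufa": "unsaturated_fat",
}

#: Default candidate food groups for contributor identification
#: (configurable placeholders; seven candidates each).
SFA_CANDIDATE_GROUPS: tuple[str, ...] = (
    "dairy",
    "red and processed meat",
    "butter and spreads",
    "cakes and biscuits",
    "savory snacks",
    "fried foods",
    "sauces and dressings",
)
SALT_CANDIDATE_GROUPS: tuple[str, ...] = (
    "bread and cereals",
    "processed meat",
    "cheese",
    "ready meals",
    "savory snacks",
    "sauces and condiments",
    "canned foods",
)

#: Number of contributing food groups identified for SFA/salt advice.
N_CONTRIBUTORS = 2

FLAGGED_BANDS = frozenset({"very low", "low", "high", "very high"})


def tree_key(nutrient_id: str) -> str:
    """The decision-tree key serving a nutrient."""
    return TREE_FOR_NUTRIENT.get(nutrient_id, nutrient_id)


@dataclass(frozen=True)
class FeedbackMessage:
    message_id: str
    nutrient_id: str  # tree key the message belongs to
    band_condition: str
    supplement_condition: str  # 'any' | 'yes' | 'no'
    food_group_condition: Optional[str]
    locale: str
    positive: bool
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ConfigurationError(f"{self.message_id}: empty message text")


class MessageCatalog:
    """Localized feedback-message archive with reference-locale fallback."""

    def __init__(
        self,
        messages: Iterable[FeedbackMessage],
        reference_locale: str = REFERENCE_LOCALE,
    ):
        self.reference_locale = reference_locale
        self._by_key: dict[tuple[str, str], FeedbackMessage] = {}
        for m in messages:
            key = (m.message_id, m.locale)
            if key in self._by_key:
                raise ConfigurationError(
                    f"duplicate message {m.message_id} for locale {m.locale}"
                )
            self._by_key[key] = m

    def message_ids(self, locale: Optional[str] = None) -> set[str]:
        locale = locale or self.reference_locale
        return {mid for mid, loc in self._by_key if loc == locale}

    def __len__(self) -> int:
        return len(self.message_ids())

    def __contains__(self, message_id: str) -> bool:
        return (message_id, self.reference_locale) in self._by_key

    def lookup(self, message_id: str, locale: Optional[str] = None) -> FeedbackMessage:
        """Fetch a message, falling back to the reference locale."""
        locale = locale or self.reference_locale
        msg = self._by_key.get((message_id, locale))
        if msg is not None:
            return msg
        fallback = self._by_key.get((message_id, self.reference_locale))
        if fallback is not None:
            if locale != self.reference_locale:
                logger.warning(
                    "message %s missing for locale %s; using %s",
                    message_id,
                    locale,
                    self.reference_locale,
                )
            return fallback
        raise CatalogIntegrityError(
            f"message {message_id} absent from catalog (locale {locale})"
        )


@dataclass(frozen=True)
class TreeBranch:
    band: str
    supplement_pred: str  # 'any' | 'yes' | 'no'
    food_group: Optional[str]
    message_ids: tuple[str, ...]

    def matches(
        self, band: str, supplement_use: bool, top_groups: Sequence[str]
    ) -> bool:
        if self.band != band:
            return False
        if self.supplement_pred == "yes" and not supplement_use:
            return False
        if self.supplement_pred == "no" and supplement_use:
            return False
        if self.food_group is not None and self.food_group not in top_groups:
            return False
        return True


@dataclass(frozen=True)
class DecisionTree:
    tree_id: str
    nutrient_id: str  # tree key
    branches: tuple[TreeBranch, ...]
    uses_contributors: bool = False
    candidate_food_groups: tuple[str, ...] = ()

    def reachable_bands(self) -> tuple[str, ...]:
        """Bands this tree declares branches for (ordered)."""
        declared = {b.band for b in self.branches}
        return tuple(b for b in BANDS if b in declared)


@dataclass
class ValidationFinding:
    kind: str  # 'dangling message' | 'uncovered band' | 'duplicate condition' | 'unknown band'
    tree_id: str
    detail: str


def validate_catalog(
    trees: Mapping[str, DecisionTree],
    catalog: MessageCatalog,
    expected_bands: Optional[Mapping[str, Sequence[str]]] = None,
    strict: bool = False,
) -> list[ValidationFinding]:
    """Cross-check the tree library against the message catalog.

    Reports dangling message ids, bands with no covering branch for either
    supplement state, duplicate condition rows, and branch bands outside the
    gradation vocabulary.  ``expected_bands`` maps tree_id to the bands
    grading can produce (defaults to the bands the tree itself declares plus
    nothing — i.e. coverage is checked against the declared set).
    """
    findings: list[ValidationFinding] = []
    for tid, tree in trees.items():
        for br in tree.branches:
            if br.band not in BANDS:
                findings.append(
                    ValidationFinding("unknown band", tid, f"branch band {br.band!r}")
                )
            for mid in br.message_ids:
                if mid not in catalog:
                    findings.append(
                        ValidationFinding("dangling message", tid, mid)
                    )
        seen: set[tuple] = set()
        for br in tree.branches:
            key = (br.band, br.supplement_pred, br.food_group)
            if key in seen:
                findings.append(
                    ValidationFinding("duplicate condition", tid, str(key))
                )
            seen.add(key)
        bands = (
            expected_bands[tid]
            if expected_bands is not None and tid in expected_bands
            else tree.reachable_bands()
        )
        for band in bands:
            for supp in (False, True):
                general = [
                    br
                    for br in tree.branches
                    if br.food_group is None
                    and br.matches(band, supp, ())
                ]
                if not general:
                    findings.append(
                        ValidationFinding(
                            "uncovered band",
                            tid,
                            f"band {band!r}, supplement_use={supp}",
                        )
                    )
    if strict and findings:
        raise CatalogIntegrityError(
            "; ".join(f"{f.tree_id}: {f.kind} ({f.detail})" for f in findings)
        )
    return findings


@dataclass(frozen=True)
class ContributorResult:
    nutrient_id: str
    top_groups: tuple[tuple[str, float], ...]  # (food group, share), share desc

    def group_names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.top_groups)


def top_contributors(
    contributions: Mapping[str, float],
    k: int,
    candidates: Sequence[str],
    nutrient_id: str = "",
) -> ContributorResult:
    """Top-k contributing food groups among the candidate list.

    Groups outside the candidate list are ignored; zero-share groups are
    never selected; ties are broken by candidate-list order.
    """
    if k < 1:
        raise InputError(f"top_contributors: k must be >= 1, got {k}")
    if not candidates:
        raise InputError("top_contributors: empty candidate list")
    ranked = sorted(
        (
            (g, float(contributions.get(g, 0.0)))
            for g in candidates
            if contributions.get(g, 0.0) > 0
        ),
        key=lambda item: (-item[1], candidates.index(item[0])),
    )
    return ContributorResult(nutrient_id=nutrient_id, top_groups=tuple(ranked[:k]))


def resolve_feedback(
    goal: Goal,
    graded: GradedNutrient,
    profile: IntakeProfile,
    tree: DecisionTree,
    catalog: MessageCatalog,
    locale: str = REFERENCE_LOCALE,
    supplement_counted: bool = True,
) -> list[FeedbackMessage]:
    """Traverse a decision tree from a graded intake to its feedback messages.

    Simple trees return exactly one message matching the band and supplement
    state; contributor trees (SFA, salt) on flagged bands return one general
    band message plus one message per identified top contributing food group.
    Maintain goals resolve to a single positive message.
    """
    if tree_key(goal.nutrient_id) != tree.nutrient_id:
        raise InputError(
            f"tree {tree.tree_id} does not serve nutrient {goal.nutrient_id}"
        )
    band = graded.band
    supplement_use = (
        supplement_counted
        and profile.supplement_intakes.get(goal.nutrient_id, 0.0) > 0
    )

    top_groups: tuple[str, ...] = ()
    contributor_order: dict[str, int] = {}
    if tree.uses_contributors and band in FLAGGED_BANDS:
        contrib = profile.food_group_contributions.get(goal.nutrient_id, {})
        result = top_contributors(
            contrib, N_CONTRIBUTORS, tree.candidate_food_groups, goal.nutrient_id
        )
        top_groups = result.group_names()
        contributor_order = {g: i for i, g in enumerate(top_groups)}

    general = [
        br
        for br in tree.branches
        if br.food_group is None and br.matches(band, supplement_use, top_groups)
    ]
    if not general:
        raise CatalogIntegrityError(
            f"no branch for nutrient {goal.nutrient_id}, band {band!r}, "
            f"supplement_use={supplement_use}"
        )
    grouped = [
        br
        for br in tree.branches
        if br.food_group is not None and br.matches(band, supplement_use, top_groups)
    ]
    grouped.sort(key=lambda br: contributor_order.get(br.food_group, len(contributor_order)))

    messages: list[FeedbackMessage] = []
    for br in general + grouped:
        for mid in br.message_ids:
            messages.append(catalog.lookup(mid, locale))
    return messages


# ---------------------------------------------------------------------------
# Table encodings (round-trip losslessly)
# ---------------------------------------------------------------------------

_DATA_PACKAGE = "dietfeedback.data"


def _read_csv(name_or_path: str | Path, packaged: bool) -> pd.DataFrame:
    if packaged:
        with resources.files(_DATA_PACKAGE).joinpath(str(name_or_path)).open("r") as fh:
            return pd.read_csv(fh)
    return pd.read_csv(name_or_path)


def frame_to_trees(df: pd.DataFrame) -> dict[str, DecisionTree]:
    trees: dict[str, DecisionTree] = {}
    for tid, rows in df.groupby("tree_id", sort=False):
        branches = tuple(
            TreeBranch(
                band=str(r.band),
                supplement_pred=str(r.supplement_pred),
                food_group=None if pd.isna(r.food_group) else str(r.food_group),
                message_ids=tuple(str(r.message_ids).split(";")),
            )
            for r in rows.itertuples()
        )
        first = rows.iloc[0]
        candidates = (
            ()
            if pd.isna(first["candidate_food_groups"])
            else tuple(str(first["candidate_food_groups"]).split(";"))
        )
        trees[str(tid)] = DecisionTree(
            tree_id=str(tid),
            nutrient_id=str(first["nutrient_id"]),
            branches=branches,
            uses_contributors=bool(first["uses_contributors"]),
            candidate_food_groups=candidates,
        )
    return trees


def trees_to_frame(trees: Mapping[str, DecisionTree]) -> pd.DataFrame:
    rows = []
    for tree in trees.values():
        for br in tree.branches:
            rows.append(
                {
                    "tree_id": tree.tree_id,
                    "nutrient_id": tree.nutrient_id,
                    "band": br.band,
                    "supplement_pred": br.supplement_pred,
                    "food_group": br.food_group,
                    "message_ids": ";".join(br.message_ids),
                    "uses_contributors": tree.uses_contributors,
                    "candidate_food_groups": ";".join(tree.candidate_food_groups)
                    if tree.candidate_food_groups
                    else None,
                }
            )
    return pd.DataFrame(rows)


def load_trees(path: Optional[str | Path] = None) -> dict[str, DecisionTree]:
    """Load a tree library from its table encoding (default: packaged)."""
    df = _read_csv("trees.csv" if path is None else path, packaged=path is None)
    return frame_to_trees(df)


def write_trees(trees: Mapping[str, DecisionTree], path: str | Path) -> None:
    trees_to_frame(trees).to_csv(path, index=False)


def frame_to_catalog(df: pd.DataFrame) -> MessageCatalog:
    messages = [
        FeedbackMessage(
            message_id=str(r.message_id),
            nutrient_id=str(r.nutrient_id),
            band_condition=str(r.band_condition),
            supplement_condition=str(r.supplement_condition),
            food_group_condition=None
            if pd.isna(r.food_group_condition)
            else str(r.food_group_condition),
            locale=str(r.locale),
            positive=bool(r.positive),
            text=str(r.text),
        )
        for r in df.itertuples()
    ]
    return MessageCatalog(messages)


def catalog_to_frame(catalog: MessageCatalog) -> pd.DataFrame:
    rows = [
        {
            "message_id": m.message_id,
            "nutrient_id": m.nutrient_id,
            "band_condition": m.band_condition,
            "supplement_condition": m.supplement_condition,
            "food_group_condition": m.food_group_condition,
            "locale": m.locale,
            "positive": m.positive,
            "text": m.text,
        }
        for m in sorted(catalog._by_key.values(), key=lambda m: (m.locale, m.message_id))
    ]
    return pd.DataFrame(rows)


def load_catalog(path: Optional[str | Path] = None) -> MessageCatalog:
    """Load a message catalog (default: the packaged 92-message archive)."""
    df = _read_csv("messages.csv" if path is None else path, packaged=path is None)
    return frame_to_catalog(df)


def write_catalog(catalog: MessageCatalog, path: str | Path) -> None:
    catalog_to_frame(catalog).to_csv(path, index=False)


def default_trees() -> dict[str, DecisionTree]:
    return load_trees(None)


def default_catalog() -> MessageCatalog:
    return load_catalog(None)
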