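"""Synthetic multi-country cohorts and a simulated human annotator.

The generator emulates an adult European seven-country cohort: demographics
(age, height, weight, sex ratio) are drawn per country from configurable
normal distributions, and habitual nutrient intakes from log-normal
distributions whose parameters are chosen so that configured gradation-band
prevalences are hit in expectation — by default a diet pattern in which
saturated fat and salt are the most frequently flagged nutrients, followed
by dietary fiber and folate.  A two-quantile constraint determines the
log-normal exactly: sigma = (ln q2 − ln q1)/(z2 − z1), mu = ln q1 − sigma·z1.

The annotator model simulates a researcher using the feedback system
manually: occasionally overruling the priority system on goal 3,
misreporting a goal, erroneously selecting an adequate nutrient, recording
only two goals, or swapping a contributor message — each an independent
Bernoulli event per participant, applied in that fixed order.  All
randomness flows from explicit seeds; no global random state is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import ndtri

from .agreement import AdviceAssignment
from .errors import ConfigurationError
from .goals import Goal, GoalSet
from .grading import GradedNutrient, build_gradation_scheme
from .nutrients import ADEQUACY, KCAL_PER_G, NutrientDefinition, default_registry
from .profiles import IntakeProfile
from .trees import (
    DecisionTree,
    MessageCatalog,
    SALT_CANDIDATE_GROUPS,
    SFA_CANDIDATE_GROUPS,
    resolve_feedback,
    tree_key,
)

# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

#: Default per-country demographics of the emulated cohort (n, mean/SD of
#: age in years, height in m, weight in kg, share of women).
DEFAULT_COUNTRIES: Mapping[str, dict] = {
    "Germany": dict(n=52, age=(42.6, 14.9), height=(1.75, 0.09), weight=(73.48, 13.55), female=0.519),
    "Greece": dict(n=51, age=(38.1, 10.5), height=(1.69, 0.10), weight=(76.02, 19.37), female=0.588),
    "Ireland": dict(n=55, age=(38.9, 12.0), height=(1.70, 0.10), weight=(72.90, 16.13), female=0.564),
    "Netherlands": dict(n=56, age=(43.0, 15.4), height=(1.76, 0.10), weight=(77.70, 16.29), female=0.500),
    "Poland": dict(n=49, age=(36.2, 11.1), height=(1.69, 0.07), weight=(71.46, 16.61), female=0.714),
    "Spain": dict(n=54, age=(41.8, 11.0), height=(1.69, 0.10), weight=(74.83, 16.94), female=0.519),
    "United Kingdom": dict(n=52, age=(37.1, 13.4), height=(1.70, 0.08), weight=(72.60, 17.05), female=0.635),
}

#: Target band prevalences for the default diet pattern.  For adequacy
#: nutrients: (P(intake < EAR), P(intake > UL)) — together the flag rate;
#: for moderation nutrients: (P(intake > target max), P(intake > cushion)).
#: Saturated fat and salt dominate the flagged nutrients, echoing typical
#: European diets.
DEFAULT_BAND_TARGETS: Mapping[str, tuple[float, float]] = {
    "sfa": (0.75, 0.50),
    "salt": (0.72, 0.45),
    "total_fat": (0.15, 0.03),
    "fiber": (0.45, 0.01),
    "folate": (0.35, 0.02),
    "pufa": (0.25, 0.02),
    "calcium": (0.25, 0.05),
    "omega3": (0.20, 0.02),
    "mufa": (0.15, 0.02),
    "carbohydrate": (0.10, 0.05),
    "iron": (0.08, 0.02),
    "vitamin_c": (0.08, 0.05),
    "vitamin_a": (0.06, 0.02),
    "protein": (0.05, 0.02),
    "thiamin": (0.03, 0.01),
    "riboflavin": (0.03, 0.01),
    "vitamin_b12": (0.03, 0.01),
}

#: Probability that a participant takes a supplement of each nutrient
#: (supplement-exempt nutrients and fats default to zero).
DEFAULT_SUPPLEMENT_PROBS: Mapping[str, float] = {
    "omega3": 0.25,
    "calcium": 0.20,
    "iron": 0.20,
    "vitamin_a": 0.10,
    "folate": 0.20,
    "thiamin": 0.10,
    "riboflavin": 0.10,
    "vitamin_b12": 0.15,
    "vitamin_c": 0.30,
    "protein": 0.05,
}

#: Dirichlet concentration parameters for food-group contribution shares
#: (ordered as the candidate lists; earlier groups dominate on average).
DEFAULT_CONTRIB_ALPHA: Mapping[str, tuple[float, ...]] = {
    "sfa": (3.0, 2.5, 1.6, 1.3, 1.0, 1.0, 0.8),
    "salt": (3.0, 2.5, 1.6, 1.3, 1.0, 1.0, 0.8),
}

#: Mean portions for the five report food groups (in the guideline period).
DEFAULT_PORTION_MEANS: Mapping[str, float] = {
    "fruit and vegetables": 3.8,
    "whole grains": 2.2,
    "dairy products": 2.1,
    "oily fish": 1.0,
    "red meat": 3.2,
}


@dataclass(frozen=True)
class CohortConfig:
    seed: int
    countries: Mapping[str, dict] = field(default_factory=lambda: dict(DEFAULT_COUNTRIES))
    band_targets: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_TARGETS)
    )
    supplement_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUPPLEMENT_PROBS)
    )
    contrib_alpha: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CONTRIB_ALPHA)
    )
    portion_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PORTION_MEANS)
    )
    energy_mean: float = 2100.0
    energy_sd: float = 450.0

    def __post_init__(self) -> None:
        for c, d in self.countries.items():
            if d["n"] < 1:
                raise ConfigurationError(f"{c}: n must be >= 1")
            if not 0 <= d["female"] <= 1:
                raise ConfigurationError(f"{c}: female share must be in [0,1]")
        # schema-dependent consistency is enforced in lognormal_from_quantiles
        for nid, (p1, p2) in self.band_targets.items():
            if not (0 < p1 < 1 and 0 < p2 < 1):
                raise ConfigurationError(
                    f"{nid}: band targets must lie in (0,1), got {(p1, p2)}"
                )
        for p in self.supplement_probs.values():
            if not 0 <= p <= 1:
                raise ConfigurationError("supplement probabilities must be in [0,1]")


def load_cohort_config(path, seed: int) -> CohortConfig:
    """Build a CohortConfig from a YAML file of field overrides.

    Any subset of the CohortConfig fields may appear; tuple-valued entries
    (demographic mean/SD pairs, band targets, Dirichlet alphas) may be
    written as YAML lists.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.pop("seed", None)

    def _tuplify(v):
        return tuple(v) if isinstance(v, list) else v

    kwargs: dict = {}
    for key in (
        "countries",
        "band_targets",
        "supplement_probs",
        "contrib_alpha",
        "portion_means",
        "energy_mean",
        "energy_sd",
    ):
        if key in raw:
            v = raw[key]
            if isinstance(v, dict):
                v = {
                    k: ({kk: _tuplify(vv) for kk, vv in val.items()}
                        if isinstance(val, dict) else _tuplify(val))
                    for k, val in v.items()
                }
            kwargs[key] = v
    return CohortConfig(seed=seed, **kwargs)


def load_annotator_model(path, seed: int) -> "AnnotatorModel":
    """Build an AnnotatorModel from a YAML file of probability overrides."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.pop("seed", None)
    return AnnotatorModel(seed=seed, **raw)


def lognormal_from_quantiles(
    q1: float, p1: float, q2: float, p2: float
) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with P(X<q1)=p1 and P(X<q2)=p2."""
    if not (0 < p1 < 1 and 0 < p2 < 1 and p1 != p2):
        raise ConfigurationError(f"invalid quantile probabilities {(p1, p2)}")
    if q1 <= 0 or q2 <= 0 or (q2 > q1) != (p2 > p1):
        raise ConfigurationError(
            f"quantiles {(q1, q2)} inconsistent with probabilities {(p1, p2)}"
        )
    z1, z2 = ndtri(p1), ndtri(p2)
    sigma = (math.log(q2) - math.log(q1)) / (z2 - z1)
    mu = math.log(q1) - sigma * z1
    return mu, sigma


def _intake_params(
    defn: NutrientDefinition,
    targets: Mapping[str, tuple[float, float]],
    sex: str,
) -> tuple[float, float]:
    """Log-normal (mu, sigma) for one nutrient's intake in its grading unit."""
    scheme = build_gradation_scheme(defn, age=40.0, sex=sex)
    p_outer, p_inner = targets[defn.nutrient_id]
    if defn.schema == ADEQUACY:
        ear, ul = scheme.boundaries[1], scheme.boundaries[2]
        # P(X < ear) = p_outer, P(X > ul) = p_inner; their sum is the flag rate
        return lognormal_from_quantiles(ear, p_outer, ul, 1.0 - p_inner)
    tm, cushion = scheme.boundaries
    # P(X > tm) = p_outer, P(X > cushion) = p_inner
    return lognormal_from_quantiles(tm, 1.0 - p_outer, cushion, 1.0 - p_inner)


def generate_cohort(
    config: CohortConfig,
    registry: Optional[Mapping[str, NutrientDefinition]] = None,
) -> list[IntakeProfile]:
    """Generate a deterministic synthetic cohort from a seeded config."""
    registry = registry or default_registry()
    rng = np.random.default_rng(config.seed)
    params: dict[tuple[str, str], tuple[float, float]] = {}
    for nid, defn in registry.items():
        for sex in ("F", "M"):
            params[(nid, sex)] = _intake_params(defn, config.band_targets, sex)

    profiles: list[IntakeProfile] = []
    for country, demo in config.countries.items():
        for i in range(demo["n"]):
            pid = f"{country[:3].upper()}-{i + 1:03d}"
            sex = "F" if rng.random() < demo["female"] else "M"
            age = float(np.clip(rng.normal(*demo["age"]), 18.0, 79.0))
            height = float(np.clip(rng.normal(*demo["height"]), 1.40, 2.10))
            weight = float(np.clip(rng.normal(*demo["weight"]), 40.0, 160.0))
            energy = float(np.clip(rng.normal(config.energy_mean, config.energy_sd), 1200.0, 4500.0))

            food: dict[str, float] = {}
            supp: dict[str, float] = {}
            for nid, defn in registry.items():
                mu, sigma = params[(nid, sex)]
                amount = float(rng.lognormal(mu, sigma))
                if defn.unit == "%E":
                    # calibration is in %E; store grams consistent with energy
                    amount = amount / 100.0 * energy / KCAL_PER_G[nid]
                food[nid] = amount
                p_supp = config.supplement_probs.get(nid, 0.0)
                if p_supp and rng.random() < p_supp:
                    ref = defn.stratum_for(40.0, sex)
                    base = ref.ear if ref.ear is not None else ref.target_max
                    supp[nid] = float(rng.lognormal(math.log(0.5 * base), 0.4))

            contrib = {
                "sfa": dict(
                    zip(SFA_CANDIDATE_GROUPS, rng.dirichlet(config.contrib_alpha["sfa"]))
                ),
                "salt": dict(
                    zip(SALT_CANDIDATE_GROUPS, rng.dirichlet(config.contrib_alpha["salt"]))
                ),
            }
            portions = {
                g: float(rng.gamma(shape=4.0, scale=m / 4.0))
                for g, m in config.portion_means.items()
            }
            profiles.append(
                IntakeProfile(
                    participant_id=pid,
                    country=country,
                    age=age,
                    sex=sex,
                    height=height,
                    weight=weight,
                    energy=energy,
                    food_intakes=food,
                    supplement_intakes=supp,
                    food_group_contributions=contrib,
                    portions=portions,
                )
            )
    return profiles


# ---------------------------------------------------------------------------
# Simulated human annotator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatorModel:
    """Bernoulli perturbation probabilities of the simulated researcher.

    ``p_overrule_goal3``: replace goal 3 with another flagged nutrient;
    ``p_misreport``: record a different nutrient than was advised;
    ``p_error``: substitute an adequate (green) nutrient by mistake;
    ``p_two_goals_only``: record only the first two goals;
    ``p_message_swap``: swap one contributor message on a multi-message
    (saturated fat / salt) slot without changing the goal.
    Perturbations are applied in that fixed order, independently per
    participant.
    """

    p_overrule_goal3: float = 0.0
    p_misreport: float = 0.0
    p_error: float = 0.0
    p_two_goals_only: float = 0.0
    p_message_swap: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_overrule_goal3",
            "p_misreport",
            "p_error",
            "p_two_goals_only",
            "p_message_swap",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {p}")


#: Defaults spanning the imperfect-agreement regime of a human annotator.
DEFAULT_ANNOTATOR = AnnotatorModel(
    p_overrule_goal3=0.30,
    p_misreport=0.04,
    p_error=0.02,
    p_two_goals_only=0.04,
    p_message_swap=0.10,
)


def _goal_for(nutrient_id: str, slot: int, graded: Mapping[str, GradedNutrient]) -> Goal:
    color = graded[nutrient_id].color
    return Goal(
        nutrient_id=nutrient_id,
        slot=slot,
        goal_type="maintain" if color == "green" else "improve",
        flag_color=color,
    )


def simulate_manual_annotator(
    auto: AdviceAssignment,
    model: AnnotatorModel,
    graded: Mapping[str, GradedNutrient],
    profile: IntakeProfile,
    trees: Mapping[str, DecisionTree],
    catalog: MessageCatalog,
    rng: Optional[np.random.Generator] = None,
    locale: str = "en",
) -> AdviceAssignment:
    """Perturb an automated assignment into a simulated manual one.

    Deterministic given the model seed (or a supplied generator when
    simulating a whole cohort from one stream).  Messages are re-resolved
    through the decision trees for every changed goal.
    """
    rng = rng if rng is not None else np.random.default_rng(model.seed)
    goals = list(auto.goal_set.goals)
    changed: set[int] = set()
    registry_ids = list(graded)

    # Bernoulli uniforms are drawn upfront in a fixed order so that, for a
    # fixed seed, raising any single probability can only add perturbations
    # (agreement is then monotone in each probability).
    u_overrule, u_misreport, u_error, u_drop = rng.random(4)

    # overrule: goal 3 replaced by another flagged nutrient
    if len(goals) >= 3 and u_overrule < model.p_overrule_goal3:
        current = {g.nutrient_id for g in goals}
        flagged = [
            n for n in registry_ids if graded[n].color in ("red", "amber") and n not in current
        ]
        if flagged:
            pick = flagged[int(rng.integers(len(flagged)))]
            goals[2] = _goal_for(pick, 3, graded)
            changed.add(3)

    # misreport: one goal's recorded nutrient swapped for a random nutrient
    if goals and u_misreport < model.p_misreport:
        idx = int(rng.integers(len(goals)))
        current = {g.nutrient_id for g in goals}
        options = [n for n in registry_ids if n not in current]
        if options:
            pick = options[int(rng.integers(len(options)))]
            goals[idx] = _goal_for(pick, idx + 1, graded)
            changed.add(idx + 1)

    # error: an adequate (green) nutrient substituted by mistake
    if goals and u_error < model.p_error:
        idx = int(rng.integers(len(goals)))
        current = {g.nutrient_id for g in goals}
        greens = [
            n for n in registry_ids if graded[n].color == "green" and n not in current
        ]
        if greens:
            pick = greens[int(rng.integers(len(greens)))]
            goals[idx] = _goal_for(pick, idx + 1, graded)
            changed.add(idx + 1)

    # drop: only two goals recorded
    dropped = False
    if len(goals) >= 3 and u_drop < model.p_two_goals_only:
        goals = goals[:2]
        dropped = True

    messages: dict[int, tuple[str, ...]] = {}
    for g in goals:
        if g.slot in changed or g.slot not in auto.messages:
            tree = trees[tree_key(g.nutrient_id)]
            resolved = resolve_feedback(
                g, graded[g.nutrient_id], profile, tree, catalog, locale=locale
            )
            messages[g.slot] = tuple(m.message_id for m in resolved)
        else:
            messages[g.slot] = tuple(auto.messages[g.slot])

    # message swap on multi-message (contributor) slots
    if model.p_message_swap:
        for g in goals:
            mids = list(messages[g.slot])
            if len(mids) < 2:
                continue
            if rng.random() < model.p_message_swap:
                tree = trees[tree_key(g.nutrient_id)]
                pool = sorted(
                    mid
                    for br in tree.branches
                    if br.food_group is not None
                    for mid in br.message_ids
                    if mid not in mids
                )
                if pool:
                    mids[-1] = pool[int(rng.integers(len(pool)))]
                    messages[g.slot] = tuple(mids)

    goal_set = GoalSet(participant_id=auto.participant_id, goals=tuple(goals))
    if dropped:
        messages = {s: m for s, m in messages.items() if s <= 2}
    return AdviceAssignment(
        participant_id=auto.participant_id,
        source="manual",
        goal_set=goal_set,
        messages=messages,
    )


def simulate_manual_cohort(
    autos: Sequence[AdviceAssignment],
    model: AnnotatorModel,
    graded_by_pid: Mapping[str, Mapping[str, GradedNutrient]],
    profiles_by_pid: Mapping[str, IntakeProfile],
    trees: Mapping[str, DecisionTree],
    catalog: MessageCatalog,
    locale: str = "en",
) -> list[AdviceAssignment]:
    """Simulate the manual annotator over a whole cohort.

    Each participant gets an independent substream seeded from the model
    seed and their position, so results are reproducible per participant
    and agreement rates respond monotonically to each perturbation
    probability.
    """
    out = []
    for i, auto in enumerate(autos):
        rng = np.random.default_rng([model.seed, i])
        out.append(
            simulate_manual_annotator(
                auto,
                model,
                graded_by_pid[auto.participant_id],
                profiles_by_pid[auto.participant_id],
                trees,
                catalog,
                rng=rng,
                locale=locale,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Trial-registry exclusions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistryRecord:
    participant_id: str
    dropout_immediately_after_randomization: bool = False
    goals_recorded_at_baseline: bool = True


def apply_exclusions(registry: Sequence[RegistryRecord]) -> list[str]:
    """Retain participants with neither exclusion flag, preserving order."""
    return [
        r.participant_id
        for r in registry
        if not r.dropout_immediately_after_randomization
        and r.goals_recorded_at_baseline
    ]
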