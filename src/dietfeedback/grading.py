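"""Gradation of nutrient intakes into five color-coded bands.

Adequacy nutrients are graded on four ordered cut points — the lower cutoff
(EAR minus two standard deviations), the EAR itself, the UL, and an upper
cushion — producing five bands: very low, low, recommended, high, very high,
color-coded red, amber, green, amber, red.  Moderation nutrients (saturated
fat, total fat, salt), for which only excess is a risk, carry the upper three
bands graded against a target maximum and its cushion.

Interval conventions: intake exactly at the EAR counts as adequate
(recommended), intake exactly at the UL still counts as tolerable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .errors import ConfigurationError, InputError
from .nutrients import (
    ADEQUACY,
    DEFAULT_CV,
    KCAL_PER_G,
    MODERATION,
    NutrientDefinition,
)
from .profiles import IntakeProfile

#: The five ordered gradation bands, lowest intake first.
BANDS: tuple[str, ...] = ("very low", "low", "recommended", "high", "very high")

#: Symmetric traffic-light palette: bands equidistant from "recommended"
#: share a color.
BAND_COLOR: Mapping[str, str] = {
    "very low": "red",
    "low": "amber",
    "recommended": "green",
    "high": "amber",
    "very high": "red",
}

#: The three report labels shown on the gradation scale of a feedback report.
COLOR_REPORT_LABEL: Mapping[str, str] = {
    "green": "good, no change recommended",
    "amber": "improvement recommended",
    "red": "improvement strongly recommended",
}

#: Default cushion multipliers producing the topmost boundary.
ADEQUACY_CUSHION_FACTOR = 1.5
MODERATION_CUSHION_FACTOR = 1.3


@dataclass(frozen=True)
class GradationScheme:
    """Ordered band boundaries for one nutrient (one age/sex stratum)."""

    nutrient_id: str
    schema: str
    boundaries: tuple[float, ...]  # adequacy: (lc, ear, ul, cushion); moderation: (tm, cushion)
    bands: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(b >= a for b, a in zip(self.boundaries, self.boundaries[1:])):
            raise ConfigurationError(
                f"{self.nutrient_id}: band boundaries must be strictly "
                f"increasing, got {self.boundaries}"
            )


def build_gradation_scheme(
    defn: NutrientDefinition,
    age: Optional[float] = None,
    sex: Optional[str] = None,
    adequacy_cushion: float = ADEQUACY_CUSHION_FACTOR,
    moderation_cushion: float = MODERATION_CUSHION_FACTOR,
) -> GradationScheme:
    """Build the gradation scheme for a nutrient definition.

    Adequacy: boundaries (EAR − 2·SD, EAR, UL, cushion·UL), five bands; a
    missing SD defaults to ``DEFAULT_CV``·EAR.  Moderation: boundaries
    (target_max, cushion·target_max), three bands.  Raises
    :class:`ConfigurationError` naming the nutrient if the boundaries are
    not strictly increasing (e.g. an SD so large that EAR − 2·SD <= 0).
    """
    s = defn.stratum_for(age, sex)
    if defn.schema == ADEQUACY:
        sd = s.sd if s.sd is not None else DEFAULT_CV * s.ear
        lower_cutoff = s.ear - 2.0 * sd
        if lower_cutoff <= 0:
            raise ConfigurationError(
                f"{defn.nutrient_id}: EAR - 2*SD = {lower_cutoff} is not "
                "positive; check the configured SD"
            )
        if s.ul is None:
            raise ConfigurationError(
                f"{defn.nutrient_id}: adequacy grading requires an upper "
                "boundary (UL or configured cushion base)"
            )
        boundaries = (lower_cutoff, s.ear, s.ul, adequacy_cushion * s.ul)
        bands = BANDS
    elif defn.schema == MODERATION:
        boundaries = (s.target_max, moderation_cushion * s.target_max)
        bands = BANDS[2:]
    else:  # pragma: no cover - guarded in NutrientDefinition
        raise ConfigurationError(f"{defn.nutrient_id}: unknown schema")
    return GradationScheme(defn.nutrient_id, defn.schema, boundaries, bands)


def grade_intake(total_intake: float, scheme: GradationScheme) -> str:
    """Classify an intake (in the scheme's unit) into a gradation band."""
    if total_intake < 0:
        raise InputError(
            f"{scheme.nutrient_id}: negative intake {total_intake}"
        )
    if scheme.schema == ADEQUACY:
        lc, ear, ul, cushion = scheme.boundaries
        if total_intake < lc:
            return "very low"
        if total_intake < ear:
            return "low"
        if total_intake <= ul:
            return "recommended"
        if total_intake <= cushion:
            return "high"
        return "very high"
    tm, cushion = scheme.boundaries
    if total_intake <= tm:
        return "recommended"
    if total_intake <= cushion:
        return "high"
    return "very high"


def band_to_color(band: str) -> str:
    """Map a gradation band to its traffic-light color."""
    try:
        return BAND_COLOR[band]
    except KeyError:
        raise InputError(f"unknown gradation band {band!r}") from None


def band_to_report_label(band: str) -> str:
    """Map a gradation band to the three-level feedback-report label."""
    return COLOR_REPORT_LABEL[band_to_color(band)]


def band_index(band: str) -> int:
    """Position of a band on the very-low → very-high ordering."""
    try:
        return BANDS.index(band)
    except ValueError:
        raise InputError(f"unknown gradation band {band!r}") from None


@dataclass(frozen=True)
class GradedNutrient:
    """One nutrient's graded intake: total, band, color, report label."""

    nutrient_id: str
    total_intake: float  # in the grading unit (%E for macronutrients)
    band: str
    color: str
    report_label: str


def total_intake_for(
    profile: IntakeProfile, defn: NutrientDefinition
) -> float:
    """Total countable intake in the nutrient's grading unit.

    Supplement intake is added only for supplement-counted nutrients;
    %E macronutrients are converted from g/day via the profile's energy.
    """
    nid = defn.nutrient_id
    if nid not in profile.food_intakes:
        raise InputError(
            f"profile {profile.participant_id}: missing food intake for {nid}"
        )
    amount = profile.food_intakes[nid]
    if defn.supplement_counted:
        amount += profile.supplement_intakes.get(nid, 0.0)
    if defn.unit == "%E":
        if profile.energy is None or profile.energy <= 0:
            raise InputError(
                f"profile {profile.participant_id}: energy intake required "
                f"to grade {nid} as % of energy"
            )
        amount = amount * KCAL_PER_G[nid] / profile.energy * 100.0
    return amount


def grade_profile(
    profile: IntakeProfile,
    registry: Mapping[str, NutrientDefinition],
    permissive: bool = False,
) -> dict[str, GradedNutrient]:
    """Grade every registered nutrient for one participant.

    Reference strata are selected from the profile's age and sex.  A missing
    intake raises :class:`InputError` naming the nutrient; in permissive
    mode the nutrient is excluded from the output with a logged warning.
    """
    import logging

    graded: dict[str, GradedNutrient] = {}
    for nid, defn in registry.items():
        try:
            total = total_intake_for(profile, defn)
        except InputError:
            if permissive:
                logging.getLogger(__name__).warning(
                    "profile %s: skipping %s (missing intake)",
                    profile.participant_id,
                    nid,
                )
                continue
            raise
        scheme = build_gradation_scheme(defn, age=profile.age, sex=profile.sex)
        band = grade_intake(total, scheme)
        color = band_to_color(band)
        graded[nid] = GradedNutrient(
            nutrient_id=nid,
            total_intake=total,
            band=band,
            color=color,
            report_label=COLOR_REPORT_LABEL[color],
        )
    return graded
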