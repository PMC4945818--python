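import pytest

from dietfeedback import (
    GradedNutrient,
    IntakeProfile,
    default_catalog,
    default_registry,
    default_trees,
)
from dietfeedback.grading import band_to_color, band_to_report_label
from dietfeedback.nutrients import NUTRIENTS
from dietfeedback.trees import SALT_CANDIDATE_GROUPS, SFA_CANDIDATE_GROUPS


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def trees():
    return default_trees()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_graded(nutrient_id: str, band: str, intake: float = 1.0) -> GradedNutrient:
    """Construct a GradedNutrient with consistent color/label for a band."""
    return GradedNutrient(
        nutrient_id=nutrient_id,
        total_intake=intake,
        band=band,
        color=band_to_color(band),
        report_label=band_to_report_label(band),
    )


def graded_map(bands: dict) -> dict:
    """A full 17-nutrient graded map; unspecified nutrients are recommended."""
    out = {}
    for n in NUTRIENTS:
        out[n] = make_graded(n, bands.get(n, "recommended"))
    return out


@pytest.fixture
def sample_profile():
    """One hand-built participant with a typical risk pattern."""
    return IntakeProfile(
        participant_id="P001",
        country="Ireland",
        age=40.0,
        sex="F",
        height=1.65,
        weight=68.0,
        energy=2000.0,
        food_intakes={
            # grams/day for %E macronutrients
            "protein": 80.0,       # 16 %E
            "carbohydrate": 250.0, # 50 %E
            "total_fat": 70.0,     # 31.5 %E
            "mufa": 25.0,          # 11.25 %E
            "pufa": 14.0,          # 6.3 %E
            "sfa": 32.0,           # 14.4 %E -> very high (>13)
            "salt": 7.5,           # g/day -> high (6 < x <= 7.8)
            "omega3": 0.9,         # below EAR -> low
            "fiber": 22.0,         # between lower cutoff 20 and EAR 25 -> low
            "calcium": 900.0,
            "iron": 10.0,
            "vitamin_a": 700.0,
            "folate": 280.0,       # between lower cutoff 256 and EAR 320 -> low
            "thiamin": 1.4,
            "riboflavin": 1.6,
            "vitamin_b12": 4.0,
            "vitamin_c": 90.0,
        },
        supplement_intakes={"vitamin_c": 60.0, "salt": 1.0},
        food_group_contributions={
            "sfa": {
                "dairy": 0.40,
                "red and processed meat": 0.25,
                "butter and spreads": 0.20,
                "cakes and biscuits": 0.05,
                "savory snacks": 0.05,
                "fried foods": 0.03,
                "sauces and dressings": 0.02,
            },
            "salt": {
                "bread and cereals": 0.35,
                "processed meat": 0.30,
                "cheese": 0.15,
                "ready meals": 0.10,
                "savory snacks": 0.05,
                "sauces and condiments": 0.03,
                "canned foods": 0.02,
            },
        },
        portions={
            "fruit and vegetables": 5.2,
            "whole grains": 2.0,
            "dairy products": 2.5,
            "oily fish": 1.0,
            "red meat": 4.0,
        },
    )
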