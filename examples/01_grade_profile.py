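"""Grade one participant's nutrient intakes into traffic-light bands.

Builds a single intake profile by hand, grades it against the shipped
17-nutrient reference registry, and prints each nutrient's total countable
intake, gradation band, and color.  Red/amber bands are the intakes the
advice engine will consider flagging as goals.
"""

from dietfeedback import IntakeProfile, default_registry, grade_profile

profile = IntakeProfile(
    participant_id="demo-001",
    country="Ireland",
    age=38.0,
    sex="F",
    height=1.68,
    weight=66.0,
    energy=2050.0,
    food_intakes={
        "protein": 78.0, "carbohydrate": 240.0, "total_fat": 72.0,
        "mufa": 26.0, "pufa": 13.0, "sfa": 33.0, "salt": 8.2,
        "omega3": 0.8, "fiber": 19.0, "calcium": 820.0, "iron": 9.5,
        "vitamin_a": 650.0, "folate": 270.0, "thiamin": 1.3,
        "riboflavin": 1.5, "vitamin_b12": 3.8, "vitamin_c": 85.0,
    },
    supplement_intakes={"vitamin_c": 80.0},
)

graded = grade_profile(profile, default_registry())
print(f"{'nutrient':<14}{'intake':>10}  {'band':<12}{'color'}")
for nid, g in graded.items():
    print(f"{nid:<14}{g.total_intake:>10.2f}  {g.band:<12}{g.color}")

flagged = [n for n, g in graded.items() if g.color in ("red", "amber")]
print(f"\n{len(flagged)} of 17 nutrients flagged for improvement: {', '.join(flagged)}")
print("Macronutrient intakes are shown as % of energy; the flagged set feeds goal selection.")
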