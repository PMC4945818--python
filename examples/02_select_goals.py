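"""Prioritize three nutrient-related goals from a graded profile.

The 17 nutrients sit in 3 priority groups (fat-related nutrients first).
Red-flagged nutrients outrank amber within a group; if fewer than three
nutrients are flagged, the remaining slots become positive "maintain"
goals on green nutrients.
"""

from dietfeedback import GradedNutrient, select_goals
from dietfeedback.grading import band_to_color, band_to_report_label
from dietfeedback.nutrients import NUTRIENTS


def graded_with(bands):
    out = {}
    for n in NUTRIENTS:
        band = bands.get(n, "recommended")
        out[n] = GradedNutrient(
            n, 1.0, band, band_to_color(band), band_to_report_label(band)
        )
    return out


scenarios = {
    "one red per group": {"sfa": "very high", "salt": "very high", "calcium": "very low"},
    "two flagged in group 2 only": {"salt": "very high", "fiber": "very low"},
    "single amber flag": {"sfa": "high"},
}

for name, bands in scenarios.items():
    goals = select_goals(graded_with(bands), participant_id="demo")
    print(f"{name}:")
    for g in goals.goals:
        print(f"  goal {g.slot}: {g.nutrient_id} ({g.goal_type}, {g.flag_color})")
print("Exactly 3 goals are always selected; maintain goals fill slots when fewer than 3 nutrients are at risk.")
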