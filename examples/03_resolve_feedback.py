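"""Traverse decision trees from graded intakes to feedback messages.

Simple trees return one message matching the band and supplement state.
The saturated-fat and salt trees add one tip per identified top
contributing food group (2 of 7 candidates), so their advice runs to
2-4 messages.
"""

from dietfeedback import IntakeProfile, default_catalog, default_trees, resolve_feedback
from dietfeedback.goals import Goal
from dietfeedback.grading import GradedNutrient

trees = default_trees()
catalog = default_catalog()

profile = IntakeProfile(
    participant_id="demo-003", country="Poland", age=45.0, sex="M",
    height=1.8, weight=85.0, energy=2400.0,
    food_intakes={}, supplement_intakes={},
    food_group_contributions={
        "sfa": {"dairy": 0.38, "fried foods": 0.27, "butter and spreads": 0.20,
                "cakes and biscuits": 0.15},
    },
)

# Saturated fat graded "very high": general message + 2 contributor tips
goal = Goal("sfa", 1, "improve", "red")
graded = GradedNutrient("sfa", 14.8, "very high", "red",
                        "improvement strongly recommended")
for m in resolve_feedback(goal, graded, profile, trees["sfa"], catalog):
    print(f"[{m.message_id}] {m.text}")

print()

# Vitamin C graded "low" without a supplement: exactly one food-based tip
goal = Goal("vitamin_c", 2, "improve", "amber")
graded = GradedNutrient("vitamin_c", 55.0, "low", "amber", "improvement recommended")
for m in resolve_feedback(goal, graded, profile, trees["vitamin_c"], catalog):
    print(f"[{m.message_id}] {m.text}")

print("\nThe SFA advice has 3 messages (1 general + 2 food-group tips); the vitamin C advice has exactly 1.")
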