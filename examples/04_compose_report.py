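"""Compose and print a complete four-section feedback report.

Generates one synthetic participant, runs the full pipeline (grade ->
goals -> messages -> report), and prints the plain-text rendering: food
group portions vs guidelines, anthropometry, the 17-nutrient profile on
the 3-level scale, and the personalized advice for the 3 goals.
"""

from dietfeedback import CohortConfig, generate_cohort, render_text, report_for_profile

config = CohortConfig(
    seed=42,
    countries={"Spain": dict(n=1, age=(41.8, 11.0), height=(1.69, 0.10),
                             weight=(74.83, 16.94), female=0.519)},
)
(profile,) = generate_cohort(config)
report = report_for_profile(profile, activity_min_per_week=120.0)
print(render_text(report))
print("Each nutrient carries one of 3 report labels; section 4 lists the goals with their decision-tree messages.")
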