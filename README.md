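# dietfeedback

A rule-based engine for generating consistent, personalized dietary advice
from habitual nutrient-intake data, together with an evaluation layer that
quantifies agreement between two advice-generating systems (for example an
automated engine versus human annotators).

It is aimed at nutrition-informatics researchers and developers of
personalized-nutrition services who need a transparent, testable pipeline
from dietary-assessment output (e.g. from a food-frequency questionnaire)
to tailored, food-based feedback reports.

## The method

The engine processes one participant at a time through four stages:

1. **Gradation.** Each of 17 nutrients is graded against dietary reference
   intakes. *Adequacy* nutrients (risk is insufficiency) use four ordered
   cut points — the lower cutoff (EAR − 2·SD), the EAR, the UL and an upper
   cushion — giving five bands: *very low, low, recommended, high, very
   high*, color-coded **red / amber / green / amber / red**. *Moderation*
   nutrients (saturated fat, total fat, salt; risk is excess) carry the
   upper three bands graded against a target maximum. Macronutrients are
   graded as % of energy (4 kcal/g for protein and carbohydrate, 9 kcal/g
   for fats). Supplement intake counts towards the total except for
   carbohydrate, MUFA, PUFA, dietary fiber and salt.

2. **Goal prioritization.** The 17 nutrients sit in 3 ranked priority
   groups (fat-related nutrients first). From each group the highest-
   priority red-flagged nutrient is chosen — amber only when no red exists —
   to fill 3 nutrient-related goals; empty slots are backfilled from other
   groups, and any slot still open becomes a positive *maintain* goal on a
   green nutrient.

3. **Decision trees.** 16 trees (MUFA and PUFA share one unsaturated-fat
   tree) map each goal's band, supplement state and — for saturated fat and
   salt — the 2 top contributing food groups of 7 candidates to messages in
   a 92-message catalog. SFA/salt advice on a flagged band is 2–4 messages;
   every other tree yields exactly one.

4. **Reports.** A standardized four-section report: food-group portions vs
   guideline amounts (5 groups), physical characteristics (BMI against WHO
   cutoffs), the full nutrient profile on a three-level scale, and the
   personalized advice table.

The evaluation layer compares two systems' outputs per participant: goal
agreement per slot (1, 2, 3), agreement of the goal *set* in random order,
and — for goal-matched participants — message agreement categorized as
complete / complete disagreement / partial (partial is only possible for
the multi-message SFA and salt trees). Summaries are raw percent agreement
per country with an unweighted average row.

A seeded synthetic-cohort generator emulates a seven-country adult cohort
(369 participants by default) whose intake distributions make saturated
fat and salt the most frequently flagged nutrients, plus a configurable
"manual annotator" model whose overrules, misreports, errors and two-goal
records produce realistic imperfect agreement.

## Worked example

```bash
python examples/05_simulate_and_compare.py
```

generates the default cohort, runs the automated pipeline, simulates the
annotator and prints:

```
Goal-selection agreement (% of participants):
       stratum   n  goal_1_pct  goal_2_pct  goal_3_pct  random_order_pct
       Germany  52         100          98          77                75
        Greece  51         100          96          80                76
       ...
       average 369          99          98          79                77

Message-selection agreement among goal-matched participants:
       stratum   n  complete_n  complete_pct  disagreement_n  disagreement_pct  partial_n  partial_pct
       ...
       average 849         822            97               0                 0         27            3
```

Goals 1 and 2 agree almost always (the annotator rarely touches them),
goal 3 is lower because the annotator's overrule perturbation targets it,
and the small partial-agreement share is confined to SFA/salt slots where
advice consists of several messages. The other examples
(`examples/01_…`–`04_…`) walk through grading, goal selection, decision-tree
traversal and report composition individually.

A thin CLI wraps the same library:

```bash
dietfeedback simulate --seed 7 --out sim/
dietfeedback grade --input sim/profiles.csv --out graded.csv
dietfeedback advise --input sim/profiles.csv --out advice.csv
dietfeedback report --input sim/profiles.csv --format html --out reports/
dietfeedback compare --manual sim/manual.csv --automated sim/automated.csv \
    --strata sim/strata.csv --out agreement/
```

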