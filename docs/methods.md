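# Methods

This note documents the models and design choices behind `dietfeedback`:
what the engine computes, the defaults it ships, and what the synthetic
cohort does and does not emulate.

## Gradation model

Each nutrient is graded on one of two schemas.

**Adequacy** (risk is insufficiency): four ordered cut points — lower
cutoff = EAR − 2·SD, EAR, UL, and an upper cushion — delimit five bands.
Interval conventions: intake below the lower cutoff is *very low*; at or
above the lower cutoff but below the EAR is *low*; from the EAR up to and
including the UL is *recommended* (meeting the EAR exactly counts as
adequate, and the UL is a tolerable maximum); above the UL up to the
cushion is *high*; above the cushion, *very high*. When a nutrient's SD is
not configured it defaults to a 10% coefficient of variation (the standard
DRI convention), configurable per nutrient.

**Moderation** (risk is excess: saturated fat, total fat, salt): only the
upper three bands exist, graded against a target maximum and its cushion.
Low intakes of these nutrients are never flagged for improvement.

The cushion boundaries exist because five labeled bands require four cut
points while reference frameworks publish only three; defaults are 1.5×UL
(adequacy) and 1.3×target-maximum (moderation), both configurable. Bands
map to colors symmetrically (red/amber/green/amber/red) and colors map to
the three report labels (*good, no change recommended* / *improvement
recommended* / *improvement strongly recommended*).

Macronutrients (protein, carbohydrate, total fat, MUFA, PUFA, SFA) are
graded as % of energy using 4 kcal/g for protein and carbohydrate and
9 kcal/g for fats; salt in g/day; omega-3 in g/day (an open convention —
g/day was chosen because omega-3 recommendations are usually absolute
adequate-intake amounts rather than energy fractions); micronutrients in
their natural units.

The shipped reference table (`src/dietfeedback/data/references.csv`) holds
implementer-supplied DRI-style placeholder values with per-entry provenance
notes; deployments should substitute their authoritative reference set.
Iron and vitamin A carry sex-specific strata selected from the profile;
thiamin, riboflavin and vitamin B12 have no established UL, so their upper
boundary is an explicit generous cushion. Supplement intake is added to
food intake for all nutrients except carbohydrate, MUFA, PUFA, dietary
fiber and salt, whose advice considers food sources only.

## Goal prioritization

The 17 nutrients form 3 ordered priority groups; within a group, nutrients
are ranked by public-health priority (the shipped ranking follows the
conventional listing order and is overridable). Selection runs in three
passes, all deterministic:

1. each group's best flagged candidate — red before amber, then rank —
   takes the lowest open slot, groups scanned in order;
2. open slots are backfilled from the remaining flagged candidates across
   groups in (group order, red-first, rank) order;
3. slots still open become *maintain* goals on the highest-priority green
   nutrients, scanning groups in order.

Pass 3 extends the documented two-flagged-nutrient rule (a green nutrient
with a positive message) to the zero- and one-flagged cases, since the
engine must always emit exactly three goals. An equivalent formulation —
sort all nutrients by the key (pass, group index, red-before-amber, rank)
and take the first three — is used as an independent oracle in the test
suite; the two formulations are verified to agree exhaustively on small
registries and on 10,000 randomized 17-nutrient colorings.

## Decision trees and message catalog

Trees are flat condition tables (band, optional supplement predicate,
optional food-group predicate → message ids), the same "table-like"
encoding a relational implementation would use, and they round-trip
losslessly through CSV. Sixteen trees serve the 17 nutrients: MUFA and
PUFA share one unsaturated-fat tree.

The saturated-fat and salt trees additionally identify the top 2
contributing food groups among 7 configurable candidates. Ties on share
are broken by candidate-list order — a deterministic rule chosen because
no tie rule is conventionally established and reproducibility requires
one. Zero-share groups are never selected, so a profile with a single
contributing group yields one contributor tip; flagged SFA/salt advice is
therefore 2–4 messages, all other trees exactly one.

The shipped 92-message catalog was authored for this package: per
supplement-aware adequacy tree six messages (very-low, low with/without
supplement, maintain, high, very-high), per supplement-exempt adequacy
tree three, per moderation tree three, plus seven food-group tips each for
saturated fat and salt. Message texts are generic food-based tips; the
verifiable surface is their count, their condition coverage and their
roles, not their wording. Catalogs are localized per message id; a missing
translation falls back to the reference locale (`en`) with a logged
warning. `validate_catalog` cross-checks trees against the catalog
(dangling ids, uncovered bands, duplicate conditions) and the shipped
assets validate cleanly.

## Reports

Reports have four fixed sections. Section 1 compares portions of five food
groups with a configurable guideline table (shipped defaults: fruit &
vegetables ≥ 5/day, whole grains ≥ 3/day, dairy ≥ 2/day, oily fish
≥ 1/week, red meat ≤ 3/week — a placeholder amalgam of typical national
advice). Section 2 reports BMI classified by WHO adult cutoffs (18.5, 25,
30) and, when supplied, activity minutes against a single configurable
threshold (default 150 min/week of moderate activity; no further activity
algorithm is in scope). Section 3 shows all 17 nutrients on the
three-level label scale; Section 4 lists the goals with dietary sources
and resolved messages. The opener is template-driven with named slots.
Renders: structured record (JSON; parses back to an equal report), plain
text, and HTML.

## Agreement evaluation

Goal agreement is evaluated per slot and for the goal set in any order; a
slot missing from either system (two-goal manual records) counts as
disagreement for that slot and for random order. Message agreement is
computed only for participants whose goal selections match exactly, per
slot, ignoring within-slot order: *complete* (equal message sets),
*complete disagreement* (empty intersection), *partial* (otherwise — only
reachable for multi-message SFA/salt slots). Percentages are printed as
integers while exact fractions are retained in the data model; the
average row is the unweighted mean of stratum percentages.

## Synthetic cohort

The generator emulates a seven-country adult cohort with per-country n,
age, height, weight and sex ratio (defaults total 369 participants with
means/SDs typical of European adult volunteers). Habitual intakes are
log-normal per nutrient. Calibration is by two quantile constraints, which
determine a log-normal exactly in closed form
(σ = (ln q₂ − ln q₁)/(z₂ − z₁), μ = ln q₁ − σ·z₁): for adequacy nutrients
the constraints are P(intake < EAR) and P(intake > UL) — their sum is the
flag rate — and for moderation nutrients P(intake > target max) and
P(intake > cushion). The default targets make saturated fat (75% flagged,
50% red) and salt (72% flagged) the two most frequently flagged nutrients,
followed by dietary fiber and folate, mirroring the dominant
SFA-and-salt pattern of European diets. Macronutrient intakes are drawn in
%-of-energy space and converted to grams through the participant's drawn
energy, so the calibrated prevalences hold exactly in distribution.
Food-group contribution shares are Dirichlet draws over the candidate
lists (concentration favoring dairy/meat sources); portions are gamma
draws around configurable means; supplement use is Bernoulli per nutrient
with log-normal amounts around half the reference value.

What the generator does **not** emulate: item-level food-frequency
structure, food-composition coupling between nutrients (intakes are drawn
independently given energy), reporting error, or country-specific diet
composition beyond demographics. Passing tests therefore demonstrate the
engine's logic and calibration machinery, not field performance on real
dietary data.

## Annotator model

The simulated human annotator applies independent Bernoulli perturbations
per participant in a fixed order: overrule (goal 3 replaced by another
flagged nutrient), misreport (a recorded nutrient swapped for a random
registry nutrient), error (an adequate nutrient substituted), two-goals-only
(goal 3 dropped), then message swap (one contributor message on a
multi-message slot replaced by another candidate-group message). The first
four perturbations change goals, and messages are re-resolved through the
decision trees for changed goals; the message swap exists because message
agreement is evaluated only on goal-matched participants, so without a
message-level perturbation the partial and disagreement categories could
never occur. Defaults (0.30 / 0.04 / 0.02 / 0.04 / 0.10) put goal-3
agreement well below goals 1–2 and confine partial agreement to SFA/salt
slots; the real-world relative frequencies of these behaviors are not
quantified anywhere, so the defaults are illustrative.

All randomness flows from explicit seeds through `numpy` generators; no
global random state is used. The cohort-level annotator gives each
participant an independent substream seeded by (model seed, participant
index), and each participant's four goal-level Bernoulli uniforms are
drawn upfront in a fixed order, so raising any single probability can only
add perturbations — agreement summaries are then monotone non-increasing in
each probability, a property the test suite checks on a seeded grid.

## Numerical and scale choices

- Band classification is exact interval arithmetic; no tolerances are
  involved beyond the 1e-9 slack allowed on contribution-share sums.
- The quantile calibration is closed-form (exact), not iterative.
- Degenerate inputs fail loudly: negative intakes, non-positive
  heights/weights, inconsistent quantile targets, non-increasing band
  boundaries (e.g. an SD so large that EAR − 2·SD ≤ 0) raise typed errors
  naming the offending nutrient. A permissive mode can instead skip
  nutrients with missing intakes, logging a warning.
- Test problem sizes: oracle equivalence uses all 3⁶ colorings of a
  six-nutrient registry plus 10,000 randomized 17-nutrient colorings;
  agreement properties use an 80-participant four-country cohort over a
  four-point probability grid; the determinism check runs a 350-profile
  cohort through the entire pipeline twice. These sizes give stable
  percentages while keeping the default suite fast.

## Known limitations

- Reference values, priority ranks, candidate food groups, guideline
  portions and message texts are configurable placeholders, not an
  authoritative clinical rule base.
- Only intake-based (level-1) advice is implemented; phenotype- or
  genotype-conditioned advice and physical-activity algorithms are out of
  scope.
- Vegetarian-aware message variants are not provided (the food-group
  predicate hook exists, but the default catalog has no such content).
- Percent agreement is reported raw; chance-corrected coefficients
  (e.g. kappa) are deliberately not computed.
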