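# Methods

This note records the modelling decisions behind `fbrlp`: what is computed,
which conventions were chosen where several were defensible, and what the
synthetic data do and do not establish.

## Intake computation and descriptive statistics

Per child and recall day, intake of energy and of the 13 nutrients (protein,
fat, thiamin, riboflavin, niacin, vitamin B6, folate, vitamin B12, vitamin C,
vitamin A, calcium, iron, zinc) is the sum over that day's records of
`amount_g × density_per_100g / 100`. Condiment records count toward intake
(they contribute nutrients) even though condiments never enter the LP food
list. A consumed food missing from the composition table aborts the run:
silently dropping it would bias every downstream stage.

With two recalls per child, daily-intake variance is decomposed with the
k = 2 replicate design: the within-person component s²w is the mean of the
per-child sample variances, the between-person component is
`max(0, Var(child means) − s²w/2)`. The truncation at zero is standard
variance-components practice — sampling noise routinely drives the raw
between component negative when true between-person spread is small — and
guarantees the reported CV%btn is never negative. With a single recall the
within-person CV is undefined and reported as missing. "% below EAR" is the
share of children whose across-recall mean falls below the estimated
average requirement (EAR = RNI / per-nutrient conversion factor).

## The percentile convention

One percentile definition is used everywhere (serving sizes, frequency
bounds, descriptive medians/quartiles): the weighted-average estimator with
(n+1) positioning — position `h = (n+1)p/100`, linear interpolation between
bracketing order statistics, clamped to the extremes when h falls outside
the ranks. The definition is load-bearing: with it, the 95th percentile of
a pooled weekly-frequency distribution is positive exactly when at least
6 of 124 observations (two recalls) or 3 of 62 (one recall) are positive,
which is the food-list inclusion rule. Clamping only matters at very small
n, where it is the least-surprising extrapolation. Medians with an even
count are the mean of the central pair.

## Frequency constructions

*Reported*: one observation per child-recall (both recalls enter the
distribution independently); a food with no record in a recall contributes
0 for that recall, on the reading that it was not consumed in the prior
week. A recorded food with a stated frequency of 0 is internally
inconsistent (it was eaten on ≥1 of the last 7 days) and is repaired to 1,
logged as a data-repair event.

*Estimated*: one observation per child — `7 × (days present / recall days)`,
i.e. {0, 3.5, 7} with two recalls, {0, 7} with one; children who never
consumed the food contribute 0, which realizes the consumer-proportion part
of the construction.

Subgroup and group distributions are the per-observation **sums** of member-
food values, over the same observation units as the food level. Sums are the
only aggregation compatible with group-level recommendations well above any
single food's 7/week cap (a vegetables group near 28/week, for instance),
and keeping the observation units aligned makes bounds comparable across
levels. Group distributions are built over the surviving food list (after
the positive-upper-percentile rule); dropped foods have essentially all-zero
distributions, so this choice is immaterial in practice but keeps every
bound tied to a food that exists in the model.

## Requirements

Energy uses the FAO/WHO/UNU weight-based quadratics (boys
`310.2 + 63.3W − 0.263W²`, girls `263.4 + 65.3W − 0.454W²`, kcal/day),
combined as the count-weighted mean over the sexes, evaluated at the
observed mean or at the reference body weight depending on the scenario.
The coefficients ship as editable configuration because published analyses
do not always state the exact variant used; for a mixed 26-boy/36-girl group
at 16.9 kg the default gives 1265.6 kcal/d, and at the 19.2 kg reference
weight the boys' equation gives 1428.6 kcal/d — both within 2% of the
benchmark values this package is validated against. The scenario runner
itself applies no special-casing: the reference-weight scenario uses the
same count-weighted combination as the reference scenario.

Fat goal: `fat_en% / 100 × energy / 9` grams (9 kcal/g). Protein goal:
0.70 g/kg body weight. 0.70 is a calibration choice — it reproduces the
benchmark 12 g (16.9 kg) and 13 g (19.2 kg) goals after rounding. The LP
always uses unrounded goals; reports round to whole grams. Micronutrient
goals are FAO/WHO RNIs for children 4–6 y, with iron at 5% and zinc at low
(15%) bioavailability as appropriate for an unrefined cereal-based,
high-phytate diet; all values are config-overridable.

## The LP

Decision variables are continuous weekly serving counts. Integer frequencies
would misrepresent the derivation (estimated frequencies are multiples of
3.5); integers appear only in reports, via rounding. The energy constraint
is a ±1% band rather than an equality: a hard equality makes continuous
solvers needlessly brittle and the tolerance is well below nutritional
relevance. All solves use HiGHS through `scipy.optimize.linprog` with a
fixed, sorted variable ordering, so results are bit-reproducible.

The best-optimised diet's objective is reconstructed as **capped adequacy**:
maximize `Σ_n min(1, intake_n / RNI_n)` over the 13 nutrients (linearized
with one auxiliary variable per nutrient), which formalizes "nutrient
adequacy for as many nutrients as possible" while giving no credit beyond
100%. Ties are resolved lexicographically: first by minimal L1 deviation of
the frequencies from the habitual diet (per-food median reported frequency,
clipped into its bounds), then by a rank-weighted objective that pushes
remaining degeneracy onto lexicographically-first food ids. The Optifood
software does not publish its internal objective in full, so this is a
reconstruction of the stated goal; it is isolated behind `DietModel.fit()`
so an alternative can be swapped in.

Problem nutrients come from per-nutrient maximized diets: a nutrient whose
maximum attainable intake stays below 100% RNI within the constraints is a
problem nutrient. Fat is assessed in energy-percent instead: the
fat-maximized diet is flagged independently for falling short of the en%
goal and for leaving the 25–35 en% admissible range. %RNI is computed on a
daily basis (weekly totals / 7 against daily RNI), which is equivalent to a
weekly/weekly ratio.

A brute-force grid enumerator (≤3 foods, default 0.5-serving step) provides
an independent oracle for both analyses in the test-suite; LP optima are
required to agree with it to within one grid step of objective slack.

## Scenario comparison

Per food group, the FBR change versus the reference is classified as
increased/decreased when it exceeds a negligible-change threshold of
1 serving/week (a documented tunable, not an assertion about any external
benchmark), negligible otherwise, and absent when a group leaves the model.
Problem-nutrient sets are diffed as new/resolved.

## Synthetic data

The generator emulates a 62-child (26 boys, 36 girls), two-recall survey
with 86 non-condiment foods over the ten groups plus a few condiments.
Foods fall into consumption tiers (15% staples, 60% moderate, 25% rare)
controlling consumer prevalence and the consumer's weekly frequency
distribution; recall-day presence is Bernoulli(F/7) per day — the minimal
mechanism that makes presence-based estimated frequencies a noisy, top-
biased transform of the reported F, so the reported-vs-estimated scenarios
genuinely contrast. Amounts are log-normal around group-typical medians
(σ = 0.5 on the log scale); densities are drawn within group-typical
ranges. Under the defaults roughly a quarter of foods fail the 3% filter
and several passing foods still have a zero 95th-percentile frequency, so
the food-list logic is exercised end to end.

Adequacy knobs rescale one nutrient's densities so its attainability is
known by construction. *Unattainable*: the every-food-at-7/week diet — an
upper bound on any feasible diet irrespective of the energy band — delivers
60% of the RNI. *Attainable*: the habitual mean diet (x_f = π_f·E[F_f]),
which sits near the centre of the derived bounds, delivers 180% of the RNI.
The margins are deliberately wide so that sampling noise in realized
servings and bounds cannot flip the designed answer.

What passing tests on synthetic data do **not** show: the generator has no
seasonality, no market prices, no intra-household allocation, no correlation
between foods within a child beyond shared prevalence tiers, and densities
are idealized (no recipe disaggregation, retention or waste factors). Tests
against it validate the machinery — derivation rules, LP behaviour,
sensitivity directions — not any substantive claim about a real population.

## Problem sizes and numerics

Default test and validation runs use the full 62-child × 86-food design;
the LP per scenario has ≲70 variables and solves in milliseconds, so a full
nine-scenario sensitivity run completes in seconds. Solver feasibility
tolerance is left at HiGHS defaults; bound satisfaction is asserted to
1e-6 servings/week. Stage-to-stage objective fixing in the lexicographic
fit uses a 1e-7 slack. Degenerate inputs (empty recall days, all-zero
frequency distributions, never-consumed foods, infeasible knob requests)
raise explicit errors or warnings as documented in the API docstrings.

## Known limitations

* The best-diet objective is a reconstruction (see above); different
  plausible objectives can select different diets among near-ties, though
  the problem-nutrient analysis is objective-free.
* Group-level bounds derived from sum distributions are not guaranteed
  jointly consistent with food-level bounds for adversarial data; the
  feasibility analysis exists precisely to diagnose such inputs.
* Cost constraints, meal patterns and expert refinement of draft FBR into
  final FBR are out of scope.
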