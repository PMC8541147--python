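# fbrlp — food-based recommendations by linear programming

`fbrlp` derives **draft food-based recommendations (FBR)** — recommended
weekly consumption frequencies per food group — and identifies **problem
nutrients** from 24 h dietary-recall data, and quantifies how sensitive both
outputs are to the choices made while turning recall data into model inputs.
It is aimed at nutrition researchers designing linear-programming (Optifood-
style) analyses for populations in low- and middle-income settings, where
dietary data are scarce and the derivation choices genuinely matter.

## The model

From recall records (child × recall day × food, grams consumed, reported
days/week frequency) the package derives, per scenario:

* a **food list** — non-condiment foods reported by ≥ a threshold share of
  children in at least one recall round (default 3%), keeping only foods
  whose upper-percentile weekly frequency is positive;
* a **serving size** per food — the median daily amount among consumers;
* **frequency bounds** — lower/upper percentiles (default 5th/95th, weighted-
  average definition with (n+1) positioning) of the weekly-frequency
  distribution at food, subgroup and group level.

The LP over weekly serving counts x_f is

```
food level        freq_min_f ≤ x_f ≤ freq_max_f
(sub)group level  lo_S ≤ Σ_{f∈S} x_f ≤ hi_S
energy band       7·E·(1−τ) ≤ Σ_f e_f·x_f ≤ 7·E·(1+τ)       (τ = 1%)
```

with E the FAO/WHO/UNU energy requirement for the target group and e_f the
energy per serving. Three analyses run per scenario: **(I)** a feasibility
check with arithmetic diagnoses; **(II)** the best-optimised diet — maximize
Σ_n min(1, intake_n/RNI_n) over the 13 nutrients, tie-broken by minimal L1
deviation from the habitual diet — whose group totals are the draft FBR; and
**(III)** one maximized diet per nutrient — a nutrient whose maximum stays
below 100% RNI is a *problem nutrient* (fat is tracked in en% against its
goal and its 25–35 en% range).

Nine scenarios (reference plus A–H) vary one derivation choice at a time:
reported vs presence-based ("estimated" 7/3.5/0) frequencies, two recalls vs
one, 3%/10%/no prevalence filter, 5–95th vs 10–90th percentile band,
observed vs reference body weight, 30 vs 25 en% fat goal.

Because the kind of survey data this targets is rarely shareable, the package
ships a synthetic-study generator (`fbrlp.simulate`) with designed ground
truth — including knobs that force a nutrient to be attainable or
unattainable so the problem-nutrient machinery can be validated against a
known answer.

## Worked example

```python
import fbrlp

cfg = fbrlp.SimulationConfig(seed=1, adequacy={"vitamin_a": "unattainable"})
dataset, system = fbrlp.simulate_study(cfg)
ref = fbrlp.run_scenario(dataset, system.composition, system.taxonomy, None, "reference")
print(ref.summary())
```

```
Scenario reference: 64 foods selected, 57 in food list
  energy requirement: 1287 kcal/d; fat goal 43 g (30 en%)
  draft FBR (servings/week by group):
    added_fats                      5
    added_sugars                    0
    bakery_breakfast_cereals        3
    dairy_products                  7
    fruits                         15
    grains_grain_products           0
    legumes_nuts_seeds              9
    meat_fish_eggs                 20
    starchy_roots_plant_foods       0
    vegetables                     31
  problem nutrients: vitamin_a
  fat in fat-maximized diet: 25 en%
```

Of 86 synthetic foods, 64 pass the 3% filter and 57 survive the positive-
95th-percentile rule. The energy requirement (1287 kcal/d) is the
count-weighted FAO/WHO/UNU value at the realized mean body weight, and the
fat goal is 30 en% of it in grams. The draft FBR mostly sits at each group's
maximum frequency — the LP pushes toward nutrient-dense foods as hard as the
habitual-diet bounds allow. Vitamin A, generated unattainable, is correctly
the sole problem nutrient. Narrowing the percentile band (scenario F) and
comparing:

```python
alt = fbrlp.run_scenario(dataset, system.composition, system.taxonomy, None, "F")
print(fbrlp.compare(ref, alt).group_changes)
```

```
{'added_fats': 'negligible', 'added_sugars': 'negligible',
 'bakery_breakfast_cereals': 'negligible', 'dairy_products': 'negligible',
 'fruits': 'decreased', 'grains_grain_products': 'increased',
 'legumes_nuts_seeds': 'decreased', 'meat_fish_eggs': 'decreased',
 'starchy_roots_plant_foods': 'negligible', 'vegetables': 'decreased'}
```

— tighter frequency bounds pull most recommended frequencies down toward the
average food pattern.

The same pipeline is scriptable from the shell (`fbrlp simulate`,
`fbrlp derive-inputs`, `fbrlp run-scenario`, `fbrlp run-all`,
`fbrlp compare`); file formats are documented in [FORMATS.md](FORMATS.md)
and the modelling choices in [docs/methods.md](docs/methods.md).

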