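# File formats

All tables are comma-separated UTF-8 text with a header row.

## Recall table (`recalls.csv`)

One row per (child, recall day, food) actually consumed; absence of a row
means the food was not consumed on that day.

| column               | type  | units / range | notes |
|----------------------|-------|---------------|-------|
| `child_id`           | str   |               | must appear in the children table when one is given |
| `recall_index`       | int   | 1 or 2        | recall day within the child |
| `food_id`            | str   |               | must exist in the taxonomy |
| `amount_g`           | float | g, > 0        | grams consumed on the recall day; non-positive rows are dropped with a warning |
| `reported_frequency` | float | days/week, 0–7 | days the food was eaten in the previous 7 days; a recorded 0 is repaired to 1 (the food was eaten on ≥1 day) and logged |

## Children table (`children.csv`, optional)

| column      | type  | notes |
|-------------|-------|-------|
| `child_id`  | str   | |
| `sex`       | str   | `m`/`f` (any string starting with m or f) |
| `weight_kg` | float | body weight, kg |

## Taxonomy table (`taxonomy.csv`)

| column        | type | notes |
|---------------|------|-------|
| `food_id`     | str  | unique |
| `name`        | str  | free text |
| `subgroup_id` | str  | each subgroup belongs to exactly one group |
| `group_id`    | str  | one of the ten canonical groups (see `fbrlp.GROUPS`) |
| `is_condiment`| bool | condiments count toward intake but are excluded from the LP food list |

## Composition table (`composition.csv`)

Indexed by `food_id`; all densities per 100 g edible portion, non-negative.

| column | units |
|--------|-------|
| `energy_kcal` | kcal |
| `protein`, `fat` | g |
| `thiamin`, `riboflavin`, `niacin`, `vitamin_b6` | mg |
| `folate` | µg (dietary folate) |
| `vitamin_b12` | µg |
| `vitamin_c` | mg |
| `vitamin_a` | µg RAE |
| `calcium`, `iron`, `zinc` | mg |

## Requirements config (YAML)

Sections: `energy_coefficients` (sex-specific quadratic `a + b·W + c·W²`,
kcal/day, W in kg), `rni` (daily RNI per micronutrient, units as above),
`ear_factors` (RNI/EAR conversion ratio per nutrient), `bioavailability`
(`iron`, `zinc` fractions), `fat_en_pct`, `fat_en_pct_range`,
`protein_g_per_kg`, `reference_weight_kg`.  Omitted structural sections fall
back to the built-in defaults (children 4–6 y); a supplied `rni` or
`ear_factors` section must be complete.

## Scenario spec (YAML)

Keys: `name`, `frequency_source` (`reported`|`estimated`), `recalls_used`
(`both`|`first_only`), `prevalence_threshold` (fraction of children, 0–1),
`percentile_band` (`[low, high]` percentiles), `energy_weight_basis`
(`mean_observed`|`reference`), `fat_en_pct`.

## Model-input exports

`food_list.csv`: `food_id, serving_g, freq_min, freq_max` (servings/week).
`bounds.csv`: `entity_id, level` (`subgroup`|`group`)`, freq_min, freq_max`
— bounds on the summed weekly frequency of member foods (group maxima may
exceed 7).
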