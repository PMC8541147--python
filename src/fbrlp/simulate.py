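"""Synthetic recall data with the statistical structure the pipeline assumes.

The generator emulates a two-recall 24 h dietary survey of young children in
a low-income rural setting: a modest food repertoire spread over the ten
food groups, a few staples consumed near-daily by almost everyone, many
moderately consumed foods and a tail of rarely consumed ones; high
within-person day-to-day variation; weekly frequencies reported on a 0-7
scale.

Generating process per child and food: the child is a *consumer* of the food
with probability pi_f; consumers carry a weekly frequency F drawn from a
per-food categorical distribution on {1..7}; each recall day shows the food
independently with probability F/7; shown foods get a log-normal amount and
``reported_frequency = F``.  Foods not shown on a day leave no record, which
reproduces the zero-imputation situation the reported-frequency pipeline
must handle, and makes presence-based (estimated) frequencies a noisy
transform of F — so reported and estimated scenarios genuinely differ.

Designed adequacy knobs rescale a nutrient's densities so that its
attainability under the LP is known by construction: an *unattainable*
nutrient stays below its RNI even in the every-food-every-day diet (an upper
bound on any feasible diet), an *attainable* nutrient exceeds its RNI
already in the habitual mean diet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .foods import GROUPS, NUTRIENTS, CompositionTable, FoodTaxonomy
from .recalls import RecallDataset
from .requirements import (
    DEFAULT_REQUIREMENTS_CONFIG,
    PopulationProfile,
    RequirementSet,
    build_requirement_set,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "FoodSystem",
    "simulate_food_system",
    "simulate_recalls",
    "simulate_study",
    "make_toy_fixture",
    "ToyFixture",
]

# per-group energy density range (kcal/100 g) and typical daily amount range (g)
_GROUP_ENERGY = {
    "added_fats": (800.0, 900.0),
    "added_sugars": (375.0, 400.0),
    "bakery_breakfast_cereals": (250.0, 450.0),
    "dairy_products": (45.0, 90.0),
    "fruits": (30.0, 100.0),
    "grains_grain_products": (110.0, 380.0),
    "legumes_nuts_seeds": (120.0, 380.0),
    "meat_fish_eggs": (90.0, 280.0),
    "starchy_roots_plant_foods": (70.0, 160.0),
    "vegetables": (20.0, 60.0),
}
_GROUP_AMOUNT = {
    "added_fats": (5.0, 15.0),
    "added_sugars": (5.0, 25.0),
    "bakery_breakfast_cereals": (30.0, 100.0),
    "dairy_products": (100.0, 250.0),
    "fruits": (50.0, 150.0),
    "grains_grain_products": (100.0, 250.0),
    "legumes_nuts_seeds": (40.0, 150.0),
    "meat_fish_eggs": (30.0, 120.0),
    "starchy_roots_plant_foods": (80.0, 200.0),
    "vegetables": (20.0, 120.0),
}
# base micronutrient density ranges per 100 g (units as the composition table)
_MICRO_BASE = {
    "protein": (0.5, 8.0),
    "fat": (0.2, 5.0),
    "thiamin": (0.01, 0.3),
    "riboflavin": (0.01, 0.3),
    "niacin": (0.1, 3.0),
    "vitamin_b6": (0.01, 0.4),
    "folate": (2.0, 60.0),
    "vitamin_b12": (0.0, 0.5),
    "vitamin_c": (0.0, 20.0),
    "vitamin_a": (0.0, 100.0),
    "calcium": (5.0, 120.0),
    "iron": (0.2, 3.0),
    "zinc": (0.1, 2.0),
}
# group-specific richness multipliers (unlisted nutrients default to 1)
_GROUP_RICHNESS = {
    "added_fats": {"fat": 18.0, "protein": 0.05, "vitamin_a": 2.0, "folate": 0.05,
                   "calcium": 0.05, "iron": 0.1, "zinc": 0.1, "vitamin_c": 0.0},
    "added_sugars": {"fat": 0.05, "protein": 0.02, "folate": 0.05, "vitamin_a": 0.0,
                     "vitamin_c": 0.0, "calcium": 0.1, "iron": 0.2, "zinc": 0.1},
    "bakery_breakfast_cereals": {"protein": 1.2, "fat": 1.5, "thiamin": 1.2, "iron": 1.2},
    "dairy_products": {"protein": 0.6, "fat": 0.8, "calcium": 8.0, "riboflavin": 4.0,
                       "vitamin_b12": 6.0, "vitamin_a": 1.5, "iron": 0.05, "vitamin_c": 0.1},
    "fruits": {"vitamin_c": 3.0, "vitamin_a": 1.5, "folate": 0.8, "protein": 0.2,
               "fat": 0.1, "vitamin_b12": 0.0, "calcium": 0.3, "zinc": 0.2},
    "grains_grain_products": {"protein": 1.2, "thiamin": 1.5, "niacin": 1.5,
                              "vitamin_b12": 0.0, "vitamin_a": 0.05, "vitamin_c": 0.05},
    "legumes_nuts_seeds": {"protein": 2.5, "folate": 2.5, "iron": 1.8, "zinc": 1.5,
                           "fat": 2.0, "vitamin_b12": 0.0, "vitamin_a": 0.1},
    "meat_fish_eggs": {"protein": 2.8, "fat": 2.0, "vitamin_b12": 10.0, "iron": 2.0,
                       "zinc": 2.5, "niacin": 2.0, "vitamin_a": 1.2, "vitamin_c": 0.1},
    "starchy_roots_plant_foods": {"vitamin_c": 1.5, "protein": 0.3, "fat": 0.1,
                                  "vitamin_b12": 0.0},
    "vegetables": {"vitamin_a": 3.0, "vitamin_c": 2.5, "folate": 2.0, "calcium": 1.2,
                   "iron": 1.2, "fat": 0.1, "protein": 0.4, "vitamin_b12": 0.0},
}
# share of n_foods per group (roughly a rural staple-centred repertoire)
_GROUP_SHARE = {
    "added_fats": 0.04,
    "added_sugars": 0.03,
    "bakery_breakfast_cereals": 0.07,
    "dairy_products": 0.05,
    "fruits": 0.12,
    "grains_grain_products": 0.14,
    "legumes_nuts_seeds": 0.10,
    "meat_fish_eggs": 0.12,
    "starchy_roots_plant_foods": 0.07,
    "vegetables": 0.26,
}
# consumption tiers: (probability of tier, prevalence range, weekly-frequency pmf on 1..7)
_TIERS = {
    "staple": (0.15, (0.70, 0.98), [0.02, 0.03, 0.05, 0.10, 0.15, 0.25, 0.40]),
    "moderate": (0.60, (0.08, 0.50), [0.30, 0.25, 0.15, 0.12, 0.08, 0.05, 0.05]),
    "rare": (0.25, (0.005, 0.04), [0.55, 0.25, 0.10, 0.05, 0.03, 0.01, 0.01]),
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults reproduce the assumed design."""

    n_children: int = 62
    n_boys: int = 26
    n_girls: int = 36
    n_recalls: int = 2
    n_foods: int = 86
    n_condiments: int = 3
    mean_weight_kg: float = 16.9
    sd_weight_kg: float = 2.2
    reference_weight_kg: float = 19.2
    amount_sigma: float = 0.5  # log-scale dispersion of daily amounts
    adequacy: dict[str, str] = field(default_factory=dict)  # nutrient -> attainable|unattainable
    unattainable_margin: float = 0.6  # fraction of RNI the max-bound diet delivers
    attainable_margin: float = 1.8  # multiple of RNI the habitual mean diet delivers
    seed: int = 0

    def __post_init__(self):
        if self.n_boys + self.n_girls != self.n_children:
            raise ValueError("n_boys + n_girls must equal n_children")
        if self.n_recalls not in (1, 2):
            raise ValueError("n_recalls must be 1 or 2")
        for nut, mode in self.adequacy.items():
            if nut not in NUTRIENTS:
                raise ValueError(f"unknown nutrient in adequacy knobs: {nut!r}")
            if mode not in ("attainable", "unattainable"):
                raise ValueError(f"adequacy mode must be attainable|unattainable, got {mode!r}")


@dataclass
class GroundTruth:
    """The generating parameters behind one synthetic food system.

    ``foods`` holds per food: tier, true consumer prevalence pi, frequency
    pmf over {1..7} and the true median daily amount.  ``attainability``
    records, per knob-controlled nutrient, whether the generated densities
    make 100% RNI reachable by construction.
    """

    foods: pd.DataFrame
    attainability: dict[str, bool] = field(default_factory=dict)
    requirements: RequirementSet | None = None


@dataclass
class FoodSystem:
    taxonomy: FoodTaxonomy
    composition: CompositionTable
    truth: GroundTruth


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed])


def simulate_food_system(config: SimulationConfig) -> FoodSystem:
    """Generate a taxonomy, composition table and ground truth.

    Foods are assigned to groups in fixed proportions (two subgroups per
    group), densities are drawn within group-typical ranges, and adequacy
    knobs rescale nutrient columns as documented in the module docstring.
    Raises ``ValueError`` for an unattainability knob on a nutrient whose
    generated density is everywhere zero (nothing to rescale).
    """
    rng = _rng(config.seed, 1)
    counts = _group_counts(config.n_foods)
    rows = []
    i = 0
    for gid in GROUPS:
        for k in range(counts[gid]):
            i += 1
            rows.append(
                {
                    "food_id": f"f{i:03d}",
                    "name": f"{gid} item {k + 1}",
                    "subgroup_id": f"{gid}_sub{k % 2 + 1}",
                    "group_id": gid,
                    "is_condiment": False,
                }
            )
    for c in range(config.n_condiments):
        rows.append(
            {
                "food_id": f"cond{c + 1:02d}",
                "name": f"condiment {c + 1}",
                "subgroup_id": "vegetables_seasonings",
                "group_id": "vegetables",
                "is_condiment": True,
            }
        )
    tax_table = pd.DataFrame(rows)
    taxonomy = FoodTaxonomy(tax_table)

    tier_names = list(_TIERS)
    tier_p = np.array([_TIERS[t][0] for t in tier_names])
    truth_rows = []
    comp_rows = []
    for row in rows:
        gid = row["group_id"]
        if row["is_condiment"]:
            tier = "staple"  # condiments are used near-daily in tiny amounts
            prev = rng.uniform(0.8, 0.98)
            pmf = np.array(_TIERS["staple"][2])
            amount = rng.uniform(1.0, 5.0)
        else:
            tier = tier_names[int(rng.choice(len(tier_names), p=tier_p))]
            lo, hi = _TIERS[tier][1]
            prev = rng.uniform(lo, hi)
            pmf = np.array(_TIERS[tier][2])
            amount = rng.uniform(*_GROUP_AMOUNT[gid])
        comp = {"food_id": row["food_id"]}
        if row["is_condiment"]:
            comp["energy_kcal"] = 0.0
            for nut in NUTRIENTS:
                comp[nut] = 0.0
        else:
            comp["energy_kcal"] = rng.uniform(*_GROUP_ENERGY[gid])
            rich = _GROUP_RICHNESS.get(gid, {})
            for nut in NUTRIENTS:
                lo, hi = _MICRO_BASE[nut]
                comp[nut] = rng.uniform(lo, hi) * rich.get(nut, 1.0)
        comp_rows.append(comp)
        truth_rows.append(
            {
                "food_id": row["food_id"],
                "group_id": gid,
                "is_condiment": row["is_condiment"],
                "tier": tier,
                "prevalence": prev,
                "freq_pmf": pmf.tolist(),
                "median_amount_g": amount,
            }
        )
    comp_table = pd.DataFrame(comp_rows).set_index("food_id")
    truth_foods = pd.DataFrame(truth_rows).set_index("food_id")

    profile = PopulationProfile(
        n_boys=config.n_boys,
        n_girls=config.n_girls,
        mean_weight_kg=config.mean_weight_kg,
        reference_weight_kg=config.reference_weight_kg,
    )
    requirements = build_requirement_set(profile, DEFAULT_REQUIREMENTS_CONFIG)

    attainability = _apply_adequacy_knobs(config, comp_table, truth_foods, requirements)
    composition = CompositionTable(comp_table.reset_index())
    return FoodSystem(
        taxonomy=taxonomy,
        composition=composition,
        truth=GroundTruth(
            foods=truth_foods, attainability=attainability, requirements=requirements
        ),
    )


def _group_counts(n_foods: int) -> dict[str, int]:
    counts = {g: int(np.floor(_GROUP_SHARE[g] * n_foods)) for g in GROUPS}
    # distribute the remainder to the largest-share groups
    rest = n_foods - sum(counts.values())
    order = sorted(GROUPS, key=lambda g: -_GROUP_SHARE[g])
    for g in order[:rest]:
        counts[g] += 1
    return counts


def _apply_adequacy_knobs(
    config: SimulationConfig,
    comp_table: pd.DataFrame,
    truth_foods: pd.DataFrame,
    requirements: RequirementSet,
) -> dict[str, bool]:
    """Rescale nutrient columns so knobbed nutrients have known attainability.

    Unattainable: the every-food-every-day diet (x_f = 7 for all foods, an
    upper bound on any feasible diet regardless of the energy band) delivers
    ``unattainable_margin`` x RNI.  Attainable: the habitual mean diet
    (x_f = pi_f x E[F_f]) delivers ``attainable_margin`` x RNI, so the
    maximized diet clears 100%.
    """
    non_cond = truth_foods.index[~truth_foods["is_condiment"]]
    amounts = truth_foods.loc[non_cond, "median_amount_g"].to_numpy()
    prev = truth_foods.loc[non_cond, "prevalence"].to_numpy()
    mean_freq = np.array(
        [float(np.dot(range(1, 8), pmf)) for pmf in truth_foods.loc[non_cond, "freq_pmf"]]
    )
    out: dict[str, bool] = {}
    for nut, mode in config.adequacy.items():
        dens = comp_table.loc[non_cond, nut].to_numpy()
        rni = requirements.rni[nut]
        if mode == "unattainable":
            # daily intake with every food at 7/week = sum(serving * density)/100
            total = float(np.dot(amounts, dens)) / 100.0
            if total <= 0:
                raise ValueError(
                    f"cannot force {nut} unattainable: generated densities are all zero"
                )
            scale = config.unattainable_margin * rni / total
            out[nut] = False
        else:
            # habitual mean daily intake = sum(pi * E[F] * serving * density)/(100*7)
            total = float(np.dot(prev * mean_freq * amounts, dens)) / 700.0
            if total <= 0:
                raise ValueError(
                    f"cannot force {nut} attainable: generated densities are all zero"
                )
            scale = config.attainable_margin * rni / total
            out[nut] = True
        comp_table.loc[non_cond, nut] = dens * scale
    return out


def simulate_recalls(food_system: FoodSystem, config: SimulationConfig) -> RecallDataset:
    """Draw a recall dataset from a food system (see module docstring)."""
    rng = _rng(config.seed, 2)
    truth = food_system.truth.foods
    n = config.n_children
    child_ids = [f"c{i + 1:03d}" for i in range(n)]
    sexes = ["m"] * config.n_boys + ["f"] * config.n_girls
    weights = np.clip(
        rng.normal(config.mean_weight_kg, config.sd_weight_kg, size=n), 8.0, None
    )
    children = pd.DataFrame({"child_id": child_ids, "sex": sexes, "weight_kg": weights})

    records = []
    consumer_draws = {}
    freq_draws = {}
    for food_id, row in truth.iterrows():
        consumer = rng.random(n) < row["prevalence"]
        pmf = np.asarray(row["freq_pmf"])
        freqs = rng.choice(np.arange(1, 8), size=n, p=pmf / pmf.sum())
        consumer_draws[food_id] = consumer
        freq_draws[food_id] = freqs
        for day in range(1, config.n_recalls + 1):
            shown = consumer & (rng.random(n) < freqs / 7.0)
            if not shown.any():
                continue
            idx = np.where(shown)[0]
            amounts = row["median_amount_g"] * np.exp(
                rng.normal(0.0, config.amount_sigma, size=idx.size)
            )
            for j, amt in zip(idx, amounts):
                records.append(
                    {
                        "child_id": child_ids[j],
                        "recall_index": day,
                        "food_id": food_id,
                        "amount_g": float(amt),
                        "reported_frequency": float(freqs[j]),
                    }
                )
    rec_frame = pd.DataFrame(
        records,
        columns=["child_id", "recall_index", "food_id", "amount_g", "reported_frequency"],
    )
    dataset = RecallDataset(
        rec_frame, children, n_recalls=config.n_recalls, taxonomy=food_system.taxonomy
    )
    # realized latent draws, for validating the generator against its own truth
    dataset.simulation_draws = {
        "consumer": pd.DataFrame(consumer_draws, index=child_ids),
        "frequency": pd.DataFrame(freq_draws, index=child_ids),
    }
    return dataset


def simulate_study(config: SimulationConfig) -> tuple[RecallDataset, FoodSystem]:
    """Convenience wrapper: food system + recall dataset in one call."""
    system = simulate_food_system(config)
    return simulate_recalls(system, config), system


# ---------------------------------------------------------------------------
# deterministic toy fixture


@dataclass
class ToyFixture:
    """A hand-set 10-child, 4-food dataset with oracle-verified results.

    The LP over the surviving 3-food list is small enough for exhaustive grid
    enumeration, so the expected best-optimised diet and problem-nutrient set
    stored here come from the brute-force oracle, not from the LP solver.
    """

    dataset: RecallDataset
    taxonomy: FoodTaxonomy
    composition: CompositionTable
    requirements: RequirementSet
    expected_food_bounds: dict[str, tuple[float, float, float]]  # food -> (serving, min, max)
    expected_group_bounds: dict[str, tuple[float, float]]
    expected_fbr: dict[str, float]
    expected_problem_nutrients: list[str]
    expected_objective: float


def make_toy_fixture() -> ToyFixture:
    """Build the deterministic toy fixture.

    Ten children, two recalls each.  A staple grain eaten daily by everyone
    (200 g, frequency 7), a leafy vegetable eaten by 8 of 10 children
    (80 g, frequency 4), milk consumed by 6 children — two of whom report it
    in the first recall only, exercising the assume-zero imputation — and a
    condiment (excluded from the LP food list).  Frequency bounds land on the
    0.5-serving grid, so the grid oracle covers the LP optimum exactly.
    """
    from .diet import DietModel, brute_force_best_diet, brute_force_maximized

    taxonomy = FoodTaxonomy(
        pd.DataFrame(
            [
                ("maize", "maize porridge", "maize_porridges", "grains_grain_products", False),
                ("kale", "kale, cooked", "leafy_vegetables", "vegetables", False),
                ("milk", "cow milk", "milks", "dairy_products", False),
                ("salt", "salt", "vegetables_seasonings", "vegetables", True),
            ],
            columns=["food_id", "name", "subgroup_id", "group_id", "is_condiment"],
        )
    )
    comp = pd.DataFrame(
        {
            "food_id": ["maize", "kale", "milk", "salt"],
            "energy_kcal": [360.0, 50.0, 60.0, 0.0],
            "protein": [8.0, 3.0, 3.3, 0.0],
            "fat": [3.0, 0.5, 3.0, 0.0],
            "thiamin": [0.4, 0.1, 0.04, 0.0],
            "riboflavin": [0.05, 0.2, 0.18, 0.0],
            "niacin": [1.0, 0.7, 0.1, 0.0],
            "vitamin_b6": [0.1, 0.15, 0.04, 0.0],
            "folate": [20.0, 120.0, 5.0, 0.0],
            "vitamin_b12": [0.0, 0.0, 0.45, 0.0],
            "vitamin_c": [0.0, 80.0, 1.0, 0.0],
            "vitamin_a": [0.0, 400.0, 30.0, 0.0],
            "calcium": [10.0, 150.0, 120.0, 0.0],
            "iron": [1.2, 2.5, 0.05, 0.0],
            "zinc": [1.0, 0.4, 0.4, 0.0],
        }
    )
    composition = CompositionTable(comp)

    children = [f"c{i:02d}" for i in range(1, 11)]
    rows = []
    for cid in children:
        for day in (1, 2):
            rows.append((cid, day, "maize", 200.0, 7.0))
            rows.append((cid, day, "salt", 2.0, 7.0))
    for cid in children[:8]:
        for day in (1, 2):
            rows.append((cid, day, "kale", 80.0, 4.0))
    for cid in children[:4]:
        for day in (1, 2):
            rows.append((cid, day, "milk", 150.0, 5.0))
    for cid in children[4:6]:
        rows.append((cid, 1, "milk", 150.0, 5.0))
    records = pd.DataFrame(
        rows, columns=["child_id", "recall_index", "food_id", "amount_g", "reported_frequency"]
    )
    child_meta = pd.DataFrame(
        {
            "child_id": children,
            "sex": ["m"] * 5 + ["f"] * 5,
            "weight_kg": [17.0] * 10,
        }
    )
    dataset = RecallDataset(records, child_meta, n_recalls=2, taxonomy=taxonomy)

    # hand-built requirements: energy chosen so the optimum lies at the
    # frequency maxima and on the 0.5-serving oracle grid
    energy = 810.0
    fat_goal = 0.30 * energy / 9.0
    protein_goal = 0.70 * 17.0
    rni = {
        "protein": protein_goal,
        "fat": fat_goal,
        "thiamin": 0.6,
        "riboflavin": 0.6,
        "niacin": 8.0,
        "vitamin_b6": 0.6,
        "folate": 200.0,
        "vitamin_b12": 1.2,
        "vitamin_c": 30.0,
        "vitamin_a": 450.0,
        "calcium": 600.0,
        "iron": 12.6,
        "zinc": 9.6,
    }
    requirements = RequirementSet(
        energy_kcal_day=energy,
        fat_en_pct=30.0,
        fat_goal_g=fat_goal,
        protein_goal_g=protein_goal,
        rni=rni,
    )

    # expectations derivable by hand from the (n+1)-percentile definition
    expected_food_bounds = {
        "maize": (200.0, 7.0, 7.0),
        "kale": (80.0, 0.0, 4.0),
        "milk": (150.0, 0.0, 5.0),
    }
    expected_group_bounds = {
        "grains_grain_products": (7.0, 7.0),
        "vegetables": (0.0, 4.0),
        "dairy_products": (0.0, 5.0),
    }

    # oracle-verified LP expectations
    from .model_input import ScenarioSpec, build_model_input

    model_input = build_model_input(dataset, composition, taxonomy, ScenarioSpec())
    model = DietModel(model_input, composition, requirements, taxonomy)
    oracle = brute_force_best_diet(model, step=0.5)
    expected_fbr = oracle.group_frequencies(rounded=True)
    problems = []
    for nut in NUTRIENTS:
        if nut == "fat":
            continue
        best = brute_force_maximized(model, nut, step=0.5)
        if best.pct_rni[nut] < 100.0:
            problems.append(nut)
    return ToyFixture(
        dataset=dataset,
        taxonomy=taxonomy,
        composition=composition,
        requirements=requirements,
        expected_food_bounds=expected_food_bounds,
        expected_group_bounds=expected_group_bounds,
        expected_fbr=expected_fbr,
        expected_problem_nutrients=problems,
        expected_objective=oracle.capped_adequacy(),
    )
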