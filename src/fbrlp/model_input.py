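"""Derivation of LP model inputs from a recall dataset under a scenario.

The model input for one scenario is: (1) a food list — non-condiment foods
reported by at least a threshold share of children in at least one recall
round; (2) a serving size per food — the median daily amount among consumers;
(3) minimum and maximum weekly consumption frequencies at food, subgroup and
group level — lower/upper percentiles of the scenario's weekly-frequency
distribution.

Two frequency constructions exist.  *Reported* frequencies use the child's
stated days-per-week for each recall independently (one observation per
child-recall; a food absent from a recall contributes 0 for that recall).
*Estimated* frequencies use only the food's presence across recall days: with
two recalls a child contributes 7, 3.5 or 0 according to whether the food
appeared on both days, one day or neither (one observation per child).

Foods whose upper percentile is 0 are dropped from the food list; (sub)group
bounds are kept only for entities retaining at least one food.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .foods import CompositionTable, FoodTaxonomy
from .recalls import RecallDataset
from .stats import percentile_weighted

__all__ = [
    "ScenarioSpec",
    "FrequencyDistribution",
    "FoodModelEntry",
    "ModelInput",
    "select_foods",
    "median_serving",
    "reported_freq_dist",
    "estimated_freq_dist",
    "percentile_weighted",
    "build_model_input",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the scenario grid.

    frequency_source : 'reported' or 'estimated'
    recalls_used     : 'both' or 'first_only'
    prevalence_threshold : minimum share of children consuming a food in at
        least one recall round (0 keeps every consumed non-condiment food)
    percentile_band  : (low, high) percentiles for freq_min / freq_max
    energy_weight_basis : 'mean_observed' or 'reference' body weight
    fat_en_pct       : fat goal as percent of energy
    """

    name: str = "reference"
    frequency_source: str = "reported"
    recalls_used: str = "both"
    prevalence_threshold: float = 0.03
    percentile_band: tuple[float, float] = (5.0, 95.0)
    energy_weight_basis: str = "mean_observed"
    fat_en_pct: float = 30.0

    def __post_init__(self):
        if self.frequency_source not in ("reported", "estimated"):
            raise ValueError(f"bad frequency_source {self.frequency_source!r}")
        if self.recalls_used not in ("both", "first_only"):
            raise ValueError(f"bad recalls_used {self.recalls_used!r}")
        if not 0.0 <= self.prevalence_threshold <= 1.0:
            raise ValueError("prevalence_threshold must be in [0, 1]")
        low, high = self.percentile_band
        if not 0.0 <= low < high <= 100.0:
            raise ValueError(f"bad percentile band {self.percentile_band}")
        if self.energy_weight_basis not in ("mean_observed", "reference"):
            raise ValueError(f"bad energy_weight_basis {self.energy_weight_basis!r}")

    def with_name(self, name: str) -> "ScenarioSpec":
        return replace(self, name=name)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "frequency_source": self.frequency_source,
            "recalls_used": self.recalls_used,
            "prevalence_threshold": self.prevalence_threshold,
            "percentile_band": list(self.percentile_band),
            "energy_weight_basis": self.energy_weight_basis,
            "fat_en_pct": self.fat_en_pct,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        band = d.get("percentile_band", (5.0, 95.0))
        d["percentile_band"] = tuple(float(v) for v in band)
        return cls(**d)


@dataclass
class FrequencyDistribution:
    """Weekly-frequency observations for one food, subgroup or group."""

    entity_id: str
    level: str  # 'food' | 'subgroup' | 'group'
    values: np.ndarray  # one per child-recall (reported) or per child (estimated)

    def percentile(self, p: float) -> float:
        return percentile_weighted(self.values, p)


@dataclass(frozen=True)
class FoodModelEntry:
    """LP parameters for one food: serving size and weekly frequency bounds."""

    food_id: str
    serving_g: float
    freq_min: float
    freq_max: float

    def __post_init__(self):
        if self.serving_g <= 0:
            raise ValueError(f"{self.food_id}: serving_g must be positive")
        if not 0 <= self.freq_min <= self.freq_max <= 7:
            raise ValueError(
                f"{self.food_id}: need 0 <= freq_min <= freq_max <= 7, "
                f"got ({self.freq_min}, {self.freq_max})"
            )


@dataclass
class ModelInput:
    """Complete LP input for one scenario.

    ``foods`` is sorted by food_id; subgroup/group bounds map entity id to
    (freq_min, freq_max) in servings/week (group maxima may exceed 7 since
    they bound sums over member foods).  ``n_foods_selected`` is the size of
    the prevalence-filtered candidate list before the positive-upper-
    percentile food-list rule.
    """

    foods: list[FoodModelEntry]
    subgroup_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    group_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    scenario: ScenarioSpec | None = None
    n_foods_selected: int = 0

    @property
    def food_ids(self) -> list[str]:
        return [f.food_id for f in self.foods]

    @property
    def n_foods(self) -> int:
        return len(self.foods)

    def entry(self, food_id: str) -> FoodModelEntry:
        for f in self.foods:
            if f.food_id == food_id:
                return f
        raise KeyError(food_id)

    def foods_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "food_id": f.food_id,
                    "serving_g": f.serving_g,
                    "freq_min": f.freq_min,
                    "freq_max": f.freq_max,
                }
                for f in self.foods
            ]
        )

    def bounds_table(self) -> pd.DataFrame:
        rows = [
            {"entity_id": k, "level": "subgroup", "freq_min": v[0], "freq_max": v[1]}
            for k, v in sorted(self.subgroup_bounds.items())
        ] + [
            {"entity_id": k, "level": "group", "freq_min": v[0], "freq_max": v[1]}
            for k, v in sorted(self.group_bounds.items())
        ]
        return pd.DataFrame(rows, columns=["entity_id", "level", "freq_min", "freq_max"])

    def to_csv(self, foods_path, bounds_path) -> None:
        self.foods_table().to_csv(foods_path, index=False)
        self.bounds_table().to_csv(bounds_path, index=False)


def select_foods(
    dataset: RecallDataset,
    taxonomy: FoodTaxonomy,
    threshold: float,
    recalls_used: str = "both",
) -> list[str]:
    """Non-condiment foods consumed by >= ``threshold`` share of children in
    at least one individual recall round.

    ``threshold = 0`` returns every consumed non-condiment food.  Returns a
    sorted list of food ids.
    """
    recs = dataset.records_in_scope(recalls_used)
    if recs.empty:
        raise ValueError("empty dataset: no recall records in scope")
    n_children = dataset.n_children
    selected = []
    for food_id, grp in recs.groupby("food_id"):
        if taxonomy.is_condiment(food_id):
            continue
        share_by_recall = grp.groupby("recall_index")["child_id"].nunique() / n_children
        if threshold == 0 or (share_by_recall >= threshold).any():
            selected.append(food_id)
    return sorted(selected)


def median_serving(
    dataset: RecallDataset, food_id: str, recalls_used: str = "both"
) -> float:
    """Median daily amount (g) among child-recall observations consuming the food."""
    recs = dataset.records_in_scope(recalls_used)
    amounts = recs.loc[recs["food_id"] == food_id, "amount_g"].to_numpy()
    if amounts.size == 0:
        raise ValueError(f"food {food_id!r} never consumed in the recalls in scope")
    return percentile_weighted(amounts, 50)


def _food_value_frame(
    dataset: RecallDataset, food_ids: list[str], recalls_used: str, source: str
) -> pd.DataFrame:
    """Per-observation weekly-frequency values, one column per food.

    Rows are child-recall observations (reported) or children (estimated);
    foods absent from an observation contribute 0.
    """
    recs = dataset.records_in_scope(recalls_used)
    recalls = [1] if recalls_used == "first_only" else list(range(1, dataset.n_recalls + 1))
    children = dataset.child_ids
    sub = recs[recs["food_id"].isin(food_ids)]
    if source == "reported":
        index = pd.MultiIndex.from_product(
            [children, recalls], names=["child_id", "recall_index"]
        )
        pivot = sub.pivot_table(
            index=["child_id", "recall_index"],
            columns="food_id",
            values="reported_frequency",
            aggfunc="max",
        )
        frame = pivot.reindex(index=index, columns=food_ids).fillna(0.0)
    elif source == "estimated":
        # days the food appeared, per child, over the recalls in scope
        days = (
            sub.groupby(["child_id", "food_id"])["recall_index"]
            .nunique()
            .unstack("food_id")
        )
        frame = days.reindex(index=children, columns=food_ids).fillna(0.0)
        frame = frame * (7.0 / len(recalls))
    else:
        raise ValueError(f"bad frequency source {source!r}")
    return frame


def reported_freq_dist(
    dataset: RecallDataset,
    entity_id: str,
    taxonomy: FoodTaxonomy,
    recalls_used: str = "both",
    level: str = "food",
    food_ids: list[str] | None = None,
) -> FrequencyDistribution:
    """Reported weekly-frequency distribution for a food or (sub)group.

    One value per child-recall observation; a food with no record in a recall
    contributes 0 for that recall (assumed not consumed in the prior week).
    (Sub)group values are sums of member-food values per observation; members
    default to all member foods of the entity but can be restricted with
    ``food_ids`` (e.g. to the scenario's food list).
    """
    members = _entity_members(entity_id, level, taxonomy, food_ids)
    frame = _food_value_frame(dataset, members, recalls_used, "reported")
    return FrequencyDistribution(entity_id, level, frame.sum(axis=1).to_numpy())


def estimated_freq_dist(
    dataset: RecallDataset,
    entity_id: str,
    taxonomy: FoodTaxonomy,
    recalls_used: str = "both",
    level: str = "food",
    food_ids: list[str] | None = None,
) -> FrequencyDistribution:
    """Estimated weekly-frequency distribution (presence-based).

    One value per child: 7 x (days the food appeared / recall days in scope),
    i.e. {0, 3.5, 7} with two recalls and {0, 7} with one.  Children who never
    consumed the food contribute 0.  (Sub)group values sum member foods.
    """
    members = _entity_members(entity_id, level, taxonomy, food_ids)
    frame = _food_value_frame(dataset, members, recalls_used, "estimated")
    return FrequencyDistribution(entity_id, level, frame.sum(axis=1).to_numpy())


def _entity_members(
    entity_id: str,
    level: str,
    taxonomy: FoodTaxonomy,
    food_ids: list[str] | None,
) -> list[str]:
    if level == "food":
        return [entity_id]
    members = taxonomy.members(entity_id, level)
    if food_ids is not None:
        members = [f for f in members if f in set(food_ids)]
    if not members:
        raise ValueError(f"{level} {entity_id!r} has no member foods in scope")
    return members


def build_model_input(
    dataset: RecallDataset,
    fct: CompositionTable,
    taxonomy: FoodTaxonomy,
    spec: ScenarioSpec,
) -> ModelInput:
    """Derive the complete LP model input for one scenario.

    Pipeline: prevalence-based food selection -> per-food serving sizes and
    frequency bounds at the scenario's percentile band -> drop foods whose
    upper percentile is 0 -> (sub)group bounds over the surviving food list.
    Raises ``ValueError`` if no food survives.
    """
    low, high = spec.percentile_band
    candidates = select_foods(dataset, taxonomy, spec.prevalence_threshold, spec.recalls_used)
    missing = [f for f in candidates if f not in fct]
    if missing:
        raise KeyError(f"selected food(s) missing from composition table: {missing}")

    frame = _food_value_frame(dataset, candidates, spec.recalls_used, spec.frequency_source)
    entries = []
    for food_id in candidates:
        vals = frame[food_id].to_numpy()
        fmax = percentile_weighted(vals, high)
        if fmax <= 0:
            continue
        fmin = percentile_weighted(vals, low)
        entries.append(
            FoodModelEntry(
                food_id=food_id,
                serving_g=median_serving(dataset, food_id, spec.recalls_used),
                freq_min=fmin,
                freq_max=fmax,
            )
        )
    if not entries:
        raise ValueError(f"empty model: no food has a positive {high}th percentile")
    entries.sort(key=lambda e: e.food_id)
    surviving = [e.food_id for e in entries]

    subgroup_bounds: dict[str, tuple[float, float]] = {}
    group_bounds: dict[str, tuple[float, float]] = {}
    surviving_frame = frame[surviving]
    tax = taxonomy.table.loc[surviving]
    for level, bounds in (("subgroup_id", subgroup_bounds), ("group_id", group_bounds)):
        for entity_id, members in tax.groupby(level).groups.items():
            summed = surviving_frame[list(members)].sum(axis=1).to_numpy()
            bounds[entity_id] = (
                percentile_weighted(summed, low),
                percentile_weighted(summed, high),
            )
    return ModelInput(
        foods=entries,
        subgroup_bounds=subgroup_bounds,
        group_bounds=group_bounds,
        scenario=spec,
        n_foods_selected=len(candidates),
    )
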