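"""Food taxonomy and food-composition containers.

Foods live in a strict two-level taxonomy: every food belongs to exactly one
subgroup and every subgroup to exactly one of ten canonical food groups
(added fats, added sugars, bakery and breakfast cereals, dairy products,
fruits, grains and grain products, legumes/nuts/seeds, meat/fish/eggs,
starchy roots and other starchy plant foods, vegetables).  Condiments are
flagged: they contribute to nutrient-intake computation but are excluded from
the LP food list.

Composition is per 100 g edible portion: energy (kcal) plus a fixed set of 13
nutrients.  Table layouts are documented in FORMATS.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "NUTRIENTS",
    "GROUPS",
    "Food",
    "FoodTaxonomy",
    "CompositionTable",
    "read_taxonomy",
    "read_composition",
]

#: The fixed nutrient set (keys of every composition entry), amounts per 100 g:
#: protein g, fat g, thiamin mg, riboflavin mg, niacin mg, vitamin B6 mg,
#: folate ug, vitamin B12 ug, vitamin C mg, vitamin A ug RAE, calcium mg,
#: iron mg, zinc mg.
NUTRIENTS: tuple[str, ...] = (
    "protein",
    "fat",
    "thiamin",
    "riboflavin",
    "niacin",
    "vitamin_b6",
    "folate",
    "vitamin_b12",
    "vitamin_c",
    "vitamin_a",
    "calcium",
    "iron",
    "zinc",
)

#: The ten canonical food groups.
GROUPS: tuple[str, ...] = (
    "added_fats",
    "added_sugars",
    "bakery_breakfast_cereals",
    "dairy_products",
    "fruits",
    "grains_grain_products",
    "legumes_nuts_seeds",
    "meat_fish_eggs",
    "starchy_roots_plant_foods",
    "vegetables",
)


@dataclass(frozen=True)
class Food:
    """A single food with its taxonomy position."""

    food_id: str
    name: str
    subgroup_id: str
    group_id: str
    is_condiment: bool = False


class FoodTaxonomy:
    """Validated food -> subgroup -> group mapping.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``food_id, name, subgroup_id, group_id, is_condiment``.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"food_id", "name", "subgroup_id", "group_id", "is_condiment"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
        table = table.copy()
        table["is_condiment"] = table["is_condiment"].astype(bool)
        if table["food_id"].duplicated().any():
            dups = table.loc[table["food_id"].duplicated(), "food_id"].tolist()
            raise ValueError(f"duplicate food_id in taxonomy: {dups}")
        bad_groups = set(table["group_id"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(
                f"unknown group_id(s) {sorted(bad_groups)}; valid groups: {list(GROUPS)}"
            )
        # a subgroup must not straddle two groups
        span = table.groupby("subgroup_id")["group_id"].nunique()
        straddling = span[span > 1].index.tolist()
        if straddling:
            raise ValueError(f"subgroup(s) mapped to more than one group: {straddling}")
        self._table = table.set_index("food_id", drop=False)

    @property
    def table(self) -> pd.DataFrame:
        return self._table

    @property
    def food_ids(self) -> list[str]:
        return self._table.index.tolist()

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._table.index

    def __len__(self) -> int:
        return len(self._table)

    def food(self, food_id: str) -> Food:
        row = self._table.loc[food_id]
        return Food(
            food_id=food_id,
            name=row["name"],
            subgroup_id=row["subgroup_id"],
            group_id=row["group_id"],
            is_condiment=bool(row["is_condiment"]),
        )

    def is_condiment(self, food_id: str) -> bool:
        return bool(self._table.at[food_id, "is_condiment"])

    def subgroup_of(self, food_id: str) -> str:
        return self._table.at[food_id, "subgroup_id"]

    def group_of(self, food_id: str) -> str:
        return self._table.at[food_id, "group_id"]

    def members(self, entity_id: str, level: str) -> list[str]:
        """Food ids belonging to a subgroup or group (sorted)."""
        if level == "subgroup":
            sel = self._table["subgroup_id"] == entity_id
        elif level == "group":
            sel = self._table["group_id"] == entity_id
        else:
            raise ValueError(f"level must be 'subgroup' or 'group', got {level!r}")
        return sorted(self._table.index[sel])

    def non_condiment_foods(self) -> list[str]:
        return sorted(self._table.index[~self._table["is_condiment"]])

    def to_csv(self, path) -> None:
        self._table.to_csv(path, index=False)


class CompositionTable:
    """Per-100 g energy and nutrient densities for a set of foods.

    Wraps a DataFrame indexed by food_id with columns ``energy_kcal`` plus the
    13 nutrients of :data:`NUTRIENTS`; all densities must be non-negative.
    """

    COLUMNS = ("energy_kcal",) + NUTRIENTS

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "food_id" in table.columns:
            table = table.set_index("food_id")
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"composition table missing columns: {sorted(missing)}")
        table = table[list(self.COLUMNS)].astype(float)
        if (table < 0).any().any():
            bad = table.index[(table < 0).any(axis=1)].tolist()
            raise ValueError(f"negative densities for food(s): {bad}")
        if table.index.duplicated().any():
            raise ValueError("duplicate food_id in composition table")
        self._table = table

    @property
    def table(self) -> pd.DataFrame:
        return self._table

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._table.index

    def energy(self, food_id: str) -> float:
        """Energy density, kcal per 100 g."""
        return float(self._table.at[food_id, "energy_kcal"])

    def density(self, food_id: str, nutrient: str) -> float:
        """Nutrient density per 100 g."""
        if nutrient not in NUTRIENTS:
            raise KeyError(f"unknown nutrient {nutrient!r}")
        return float(self._table.at[food_id, nutrient])

    def row(self, food_id: str) -> pd.Series:
        if food_id not in self._table.index:
            raise KeyError(f"food {food_id!r} missing from composition table")
        return self._table.loc[food_id]

    def to_csv(self, path) -> None:
        self._table.rename_axis("food_id").to_csv(path)


def read_taxonomy(path) -> FoodTaxonomy:
    """Read a food taxonomy from a comma-separated table (see FORMATS.md)."""
    return FoodTaxonomy(pd.read_csv(path))


def read_composition(path) -> CompositionTable:
    """Read a food-composition table from a comma-separated file (see FORMATS.md)."""
    return CompositionTable(pd.read_csv(path))
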