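import pandas as pd
import pytest

from fbrlp import (
    CompositionTable,
    FoodTaxonomy,
    RecallDataset,
    SimulationConfig,
    make_toy_fixture,
    simulate_study,
)
from fbrlp.foods import NUTRIENTS


@pytest.fixture(scope="session")
def toy():
    """Deterministic 10-child, 4-food fixture with oracle-verified results."""
    return make_toy_fixture()


@pytest.fixture(scope="session")
def toy_req_config():
    """Requirements config reproducing the toy fixture's hand-built goals:
    a constant 810 kcal/d energy equation at the toy's 17 kg children."""
    return {
        "energy_coefficients": {
            "boys": {"a": 810.0, "b": 0.0, "c": 0.0},
            "girls": {"a": 810.0, "b": 0.0, "c": 0.0},
        }
    }


@pytest.fixture(scope="session")
def sim():
    """A default-sized synthetic study (62 children, 86 foods)."""
    cfg = SimulationConfig(seed=1)
    dataset, system = simulate_study(cfg)
    return cfg, dataset, system


def minimal_taxonomy(food_rows):
    """Taxonomy from (food_id, subgroup, group, is_condiment) tuples."""
    return FoodTaxonomy(
        pd.DataFrame(
            [(f, f, sg, g, c) for f, sg, g, c in food_rows],
            columns=["food_id", "name", "subgroup_id", "group_id", "is_condiment"],
        )
    )


def composition_from(energies: dict[str, float], densities: dict[str, dict[str, float]]):
    """CompositionTable from sparse per-food nutrient dicts (rest zero)."""
    rows = []
    for fid, kcal in energies.items():
        row = {"food_id": fid, "energy_kcal": kcal}
        for nut in NUTRIENTS:
            row[nut] = densities.get(fid, {}).get(nut, 0.0)
        rows.append(row)
    return CompositionTable(pd.DataFrame(rows))


def dataset_from(rows, n_recalls=2, children=None, taxonomy=None):
    """RecallDataset from (child, recall, food, grams, freq) tuples."""
    frame = pd.DataFrame(
        rows,
        columns=["child_id", "recall_index", "food_id", "amount_g", "reported_frequency"],
    )
    return RecallDataset(frame, children, n_recalls=n_recalls, taxonomy=taxonomy)
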