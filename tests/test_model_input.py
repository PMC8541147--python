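"""Food selection, serving sizes, frequency distributions and LP-input bounds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fbrlp import (
    ScenarioSpec,
    build_model_input,
    estimated_freq_dist,
    median_serving,
    reported_freq_dist,
    select_foods,
)

from conftest import composition_from, dataset_from, minimal_taxonomy


def two_food_taxonomy():
    return minimal_taxonomy(
        [
            ("beans", "pulses", "legumes_nuts_seeds", False),
            ("peas", "pulses", "legumes_nuts_seeds", False),
            ("salt", "seasonings", "vegetables", True),
        ]
    )


def children_frame(n):
    import pandas as pd

    return pd.DataFrame({"child_id": [f"c{i:02d}" for i in range(n)]})


class TestSelectFoods:
    def make(self, eaters_r1, eaters_r2, n_children=62, food="beans"):
        rows = [(f"c{i:02d}", 1, food, 50, 2) for i in eaters_r1]
        rows += [(f"c{i:02d}", 2, food, 50, 2) for i in eaters_r2]
        rows += [(f"c{i:02d}", 1, "salt", 2, 7) for i in range(n_children)]
        return dataset_from(rows, children=children_frame(n_children))

    def test_threshold_met_in_one_recall(self):
        # 2 of 62 children in recall 1 is 3.2% >= 3%
        ds = self.make([0, 1], [])
        assert select_foods(ds, two_food_taxonomy(), 0.03) == ["beans"]

    def test_threshold_not_met_in_either_recall(self):
        # 1 of 62 in each recall separately is 1.6% < 3%
        ds = self.make([0], [1])
        assert select_foods(ds, two_food_taxonomy(), 0.03) == []

    def test_condiments_always_excluded(self):
        ds = self.make([0, 1, 2], [])
        assert "salt" not in select_foods(ds, two_food_taxonomy(), 0.0)

    def test_zero_threshold_keeps_all_consumed(self):
        ds = self.make([0], [1])
        assert select_foods(ds, two_food_taxonomy(), 0.0) == ["beans"]


class TestMedianServing:
    def test_consumer_median(self):
        ds = dataset_from(
            [("c00", 1, "beans", 50, 2), ("c01", 1, "beans", 100, 2), ("c02", 1, "beans", 150, 2)],
            children=children_frame(62),
        )
        assert median_serving(ds, "beans") == 100.0

    def test_even_count_averages(self):
        ds = dataset_from([("a", 1, "beans", 50, 2), ("b", 1, "beans", 100, 2)])
        assert median_serving(ds, "beans") == 75.0

    def test_non_consumers_excluded(self):
        # one consumer among 62 children: the median is that child's amount
        ds = dataset_from(
            [("c00", 1, "beans", 100, 2)] + [(f"c{i:02d}", 1, "salt", 2, 7) for i in range(62)],
            children=children_frame(62),
        )
        assert median_serving(ds, "beans") == 100.0

    def test_never_consumed_errors(self):
        ds = dataset_from([("a", 1, "beans", 100, 2)])
        with pytest.raises(ValueError, match="never consumed"):
            median_serving(ds, "peas")


class TestFrequencyDistributions:
    def test_reported_missing_recall_counts_zero(self):
        # frequency 4 in recall 1, no record in recall 2 -> values {4, 0}
        tax = two_food_taxonomy()
        ds = dataset_from([("a", 1, "beans", 50, 4)])
        dist = reported_freq_dist(ds, "beans", tax)
        assert sorted(dist.values.tolist()) == [0.0, 4.0]

    def test_subgroup_sums_member_foods(self):
        tax = two_food_taxonomy()
        ds = dataset_from([("a", 1, "beans", 50, 3), ("a", 1, "peas", 50, 2)])
        dist = reported_freq_dist(ds, "pulses", tax, level="subgroup")
        # recall 1 observation sums to 5; recall 2 has nothing -> 0
        assert sorted(dist.values.tolist()) == [0.0, 5.0]

    def test_child_without_group_foods_contributes_zero(self):
        tax = two_food_taxonomy()
        ds = dataset_from(
            [("a", 1, "beans", 50, 3), ("b", 1, "salt", 2, 7)],
            children=children_frame(2).assign(child_id=["a", "b"]),
        )
        dist = reported_freq_dist(
            ds, "legumes_nuts_seeds", tax, level="group", food_ids=["beans"]
        )
        assert len(dist.values) == 4  # 2 children x 2 recalls
        assert sorted(dist.values.tolist()) == [0.0, 0.0, 0.0, 3.0]

    @pytest.mark.parametrize(
        "recall_days, expected",
        [((1, 2), 7.0), ((1,), 3.5), ((), 0.0)],
        ids=["both-days", "one-day", "neither"],
    )
    def test_estimated_values(self, recall_days, expected):
        tax = two_food_taxonomy()
        rows = [("a", d, "beans", 50, 2) for d in recall_days]
        rows += [("a", 1, "salt", 2, 7)]  # keeps the child in the dataset
        ds = dataset_from(rows)
        dist = estimated_freq_dist(ds, "beans", tax)
        assert dist.values.tolist() == [expected]

    def test_estimated_single_recall_values(self):
        tax = two_food_taxonomy()
        ds = dataset_from([("a", 1, "beans", 50, 2), ("b", 1, "salt", 2, 7)])
        dist = estimated_freq_dist(ds, "beans", tax, recalls_used="first_only")
        assert sorted(dist.values.tolist()) == [0.0, 7.0]

    def test_estimated_values_on_grid(self, sim):
        """Estimated food-level values lie in {0, 3.5, 7} with two recalls."""
        _, dataset, system = sim
        for food in dataset.consumed_foods()[:20]:
            vals = estimated_freq_dist(dataset, food, system.taxonomy).values
            assert set(np.unique(vals)) <= {0.0, 3.5, 7.0}

    def test_group_values_conserve_member_sums(self, toy):
        """Per observation, the group value equals the sum of member-food values."""
        tax = toy.taxonomy
        members = ["kale"]  # vegetables group, salt excluded from the list
        g = reported_freq_dist(
            toy.dataset, "vegetables", tax, level="group", food_ids=members
        )
        f = reported_freq_dist(toy.dataset, "kale", tax)
        np.testing.assert_array_equal(g.values, f.values)


class TestBuildModelInput:
    def test_toy_bounds_match_hand_derivation(self, toy):
        mi = build_model_input(toy.dataset, toy.composition, toy.taxonomy, ScenarioSpec())
        got = {e.food_id: (e.serving_g, e.freq_min, e.freq_max) for e in mi.foods}
        assert got == toy.expected_food_bounds
        assert mi.group_bounds == toy.expected_group_bounds
        assert mi.n_foods_selected == 3

    def test_daily_staple_degenerate_bounds(self, toy):
        mi = build_model_input(toy.dataset, toy.composition, toy.taxonomy, ScenarioSpec())
        maize = mi.entry("maize")
        assert (maize.freq_min, maize.freq_max) == (7.0, 7.0)

    def test_rarely_seen_food_dropped_from_list(self):
        # 62 children; one food seen once -> 95th percentile of its reported
        # distribution is 0, so it leaves the food list
        tax = two_food_taxonomy()
        rows = [(f"c{i:02d}", d, "beans", 50, 7) for i in range(62) for d in (1, 2)]
        rows += [("c00", 1, "peas", 30, 1)]
        ds = dataset_from(rows, children=children_frame(62))
        fct = composition_from({"beans": 100, "peas": 80}, {})
        mi = build_model_input(ds, fct, tax, ScenarioSpec(prevalence_threshold=0.0))
        assert mi.food_ids == ["beans"]
        assert mi.n_foods_selected == 2

    def test_empty_model_errors(self):
        tax = two_food_taxonomy()
        rows = [("c00", 1, "peas", 30, 1)] + [
            (f"c{i:02d}", 1, "salt", 2, 7) for i in range(62)
        ]
        ds = dataset_from(rows, children=children_frame(62))
        fct = composition_from({"peas": 80, "salt": 0}, {})
        with pytest.raises(ValueError, match="empty model"):
            build_model_input(ds, fct, tax, ScenarioSpec(prevalence_threshold=0.0))

    def test_band_nesting(self, sim):
        """(10,90) bounds are contained in (5,95) bounds for every entity."""
        _, dataset, system = sim
        wide = build_model_input(
            dataset, system.composition, system.taxonomy, ScenarioSpec()
        )
        narrow = build_model_input(
            dataset,
            system.composition,
            system.taxonomy,
            ScenarioSpec(percentile_band=(10.0, 90.0)),
        )
        wide_foods = {e.food_id: e for e in wide.foods}
        for e in narrow.foods:
            w = wide_foods[e.food_id]
            assert w.freq_min - 1e-9 <= e.freq_min <= e.freq_max <= w.freq_max + 1e-9
        for entity, (lo, hi) in narrow.group_bounds.items():
            wlo, whi = wide.group_bounds[entity]
            assert wlo - 1e-9 <= lo and hi <= whi + 1e-9

    def test_deterministic(self, sim):
        _, dataset, system = sim
        spec = ScenarioSpec()
        a = build_model_input(dataset, system.composition, system.taxonomy, spec)
        b = build_model_input(dataset, system.composition, system.taxonomy, spec)
        assert a.foods == b.foods
        assert a.group_bounds == b.group_bounds
        assert a.subgroup_bounds == b.subgroup_bounds


@given(
    data=st.lists(
        st.tuples(st.integers(0, 7), st.integers(0, 7)), min_size=4, max_size=40
    )
)
@settings(deadline=None, max_examples=100)
def test_band_nesting_property(data):
    """Percentile monotonicity: any inner band is contained in any outer band."""
    from fbrlp.stats import percentile_weighted

    values = [float(a) for pair in data for a in pair]
    inner = (percentile_weighted(values, 10), percentile_weighted(values, 90))
    outer = (percentile_weighted(values, 5), percentile_weighted(values, 95))
    assert outer[0] <= inner[0] <= inner[1] <= outer[1]
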