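"""LP assembly, feasibility diagnosis, best/maximized diets and the oracle."""

import numpy as np
import pandas as pd
import pytest

from fbrlp import (
    DietModel,
    FoodModelEntry,
    ModelInput,
    RequirementSet,
    brute_force_best_diet,
    brute_force_maximized,
)
from fbrlp.foods import NUTRIENTS

from conftest import composition_from, minimal_taxonomy

BIG = 1e9  # an RNI no toy diet can reach: the nutrient is effectively inert


def hand_model(
    foods,
    energy_kcal_day,
    tau=0.0,
    rni_overrides=None,
    subgroup_bounds=None,
    group_bounds=None,
):
    """DietModel from (food_id, serving_g, fmin, fmax, kcal/100g, densities)."""
    tax = minimal_taxonomy(
        [(f[0], f"{f[0]}_sub", "vegetables", False) for f in foods]
    )
    fct = composition_from({f[0]: f[4] for f in foods}, {f[0]: f[5] for f in foods})
    entries = [
        FoodModelEntry(food_id=f[0], serving_g=f[1], freq_min=f[2], freq_max=f[3])
        for f in foods
    ]
    mi = ModelInput(
        foods=entries,
        subgroup_bounds=subgroup_bounds or {},
        group_bounds=group_bounds or {},
    )
    rni = {n: BIG for n in NUTRIENTS}
    rni.update(rni_overrides or {})
    req = RequirementSet(
        energy_kcal_day=energy_kcal_day,
        fat_en_pct=30.0,
        fat_goal_g=max(rni["fat"], 1e-9) if rni["fat"] < BIG else BIG,
        protein_goal_g=rni["protein"],
        rni=rni,
    )
    return DietModel(mi, fct, req, tax, energy_tolerance=tau)


class TestAssembly:
    def test_two_foods_no_aggregates(self):
        m = hand_model(
            [("a", 100, 0, 7, 100, {}), ("b", 100, 0, 7, 100, {})], energy_kcal_day=100
        )
        assert m.n_variables() == 2
        a_ub, _ = m._base_inequalities()
        assert a_ub.shape == (2, 2)  # the two energy rows only

    def test_subgroup_bound_adds_row_pair(self):
        m = hand_model(
            [("a", 100, 0, 7, 100, {}), ("b", 100, 0, 7, 100, {})],
            energy_kcal_day=100,
            subgroup_bounds={"a_sub": (0.0, 5.0)},
        )
        a_ub, _ = m._base_inequalities()
        assert a_ub.shape == (4, 2)

    def test_zero_tolerance_band_degenerates(self):
        m = hand_model([("a", 100, 0, 7, 100, {})], energy_kcal_day=100, tau=0.0)
        lo, hi = m.energy_band
        assert lo == hi == 700.0

    def test_missing_composition_errors(self):
        tax = minimal_taxonomy([("a", "a_sub", "vegetables", False)])
        fct = composition_from({"b": 100}, {})
        mi = ModelInput(foods=[FoodModelEntry("a", 100, 0, 7)])
        rni = {n: 1.0 for n in NUTRIENTS}
        req = RequirementSet(100, 30, 1, 1, rni)
        with pytest.raises(KeyError, match="a"):
            DietModel(mi, fct, req, tax)


class TestFeasibility:
    def one_food(self, energy_kcal_day, tau=0.01):
        # 100 kcal per serving, bounds 0-7
        return hand_model(
            [("a", 100, 0, 7, 100, {})], energy_kcal_day=energy_kcal_day, tau=tau
        )

    def test_unreachable_energy_diagnosed(self):
        # max attainable 700 kcal/week < lower band of a 1400 kcal/week target
        verdict = self.one_food(200).check_feasibility()
        assert not verdict.feasible
        assert any("maximum attainable energy below band" in d for d in verdict.diagnoses)

    def test_reachable_energy_feasible(self):
        verdict = self.one_food(500 / 7).check_feasibility()
        assert verdict.feasible

    def test_exact_band_with_attainable_target(self):
        verdict = self.one_food(500 / 7, tau=0.0).check_feasibility()
        assert verdict.feasible

    def test_group_bound_conflict_diagnosed(self):
        m = hand_model(
            [("a", 100, 4, 7, 100, {})],
            energy_kcal_day=500 / 7,
            group_bounds={"vegetables": (0.0, 2.0)},
        )
        verdict = m.check_feasibility()
        assert not verdict.feasible
        assert any("minima sum" in d for d in verdict.diagnoses)


class TestBestDiet:
    def test_scarce_nutrient_pushes_to_max(self):
        # 10% of weekly RNI per serving; energy pins x at 7
        m = hand_model(
            [("a", 100, 0, 7, 100, {"iron": 0.7})],
            energy_kcal_day=100,
            rni_overrides={"iron": 1.0},
        )
        sol = m.fit()
        assert sol.x["a"] == pytest.approx(7.0, abs=1e-6)
        assert sol.pct_rni["iron"] == pytest.approx(70.0, abs=1e-4)
        oracle = brute_force_best_diet(m, step=0.5)
        assert oracle.x["a"] == 7.0

    def test_adequacy_dominates_anchor(self):
        # 25% weekly RNI per serving, energy-free food: adequacy caps at x=4,
        # and the anchor at 3 pulls x down only to that cap
        m = hand_model(
            [("a", 100, 0, 7, 0, {"iron": 1.75})],
            energy_kcal_day=0,
            rni_overrides={"iron": 1.0},
        )
        sol = m.fit(habit_anchor={"a": 3.0})
        assert sol.x["a"] == pytest.approx(4.0, abs=1e-6)
        oracle = brute_force_best_diet(m, step=0.5, habit_anchor={"a": 3.0})
        assert oracle.x["a"] == 4.0

    def test_anchor_tie_break_and_lexicographic_stage(self):
        # two interchangeable foods; anchor (5, 0); all minimal-L1 optima keep
        # the anchored food at or above its anchor, never the mirror image
        foods = [
            ("a", 100, 0, 7, 100, {"iron": 0.7}),
            ("b", 100, 0, 7, 100, {"iron": 0.7}),
        ]
        m = hand_model(foods, energy_kcal_day=100, rni_overrides={"iron": 1.0})
        sol = m.fit(habit_anchor={"a": 5.0, "b": 0.0})
        total = sol.x.sum()
        assert total == pytest.approx(7.0, abs=1e-6)
        l1 = abs(sol.x["a"] - 5.0) + abs(sol.x["b"])
        assert l1 == pytest.approx(2.0, abs=1e-6)  # the attainable minimum
        assert sol.x["a"] >= 5.0 - 1e-6  # mirror (2, 5) rejected
        # the lexicographic stage prefers mass on the first food
        assert sol.x["a"] >= sol.x["b"]

    def test_infeasible_fit_directs_to_feasibility(self):
        m = hand_model([("a", 100, 0, 7, 100, {})], energy_kcal_day=200)
        with pytest.raises(ValueError, match="check_feasibility"):
            m.fit()


class TestMaximized:
    def two_food_model(self):
        # X: 100 kcal + 10% weekly RNI per serving; Y: 200 kcal + 2%
        return hand_model(
            [
                ("x", 100, 0, 7, 100, {"iron": 0.7}),
                ("y", 100, 0, 7, 200, {"iron": 0.14}),
            ],
            energy_kcal_day=200,
            tau=0.0,
            rni_overrides={"iron": 1.0},
        )

    def test_energy_constrained_maximum(self):
        m = self.two_food_model()
        sol = m.fit_maximized("iron")
        assert sol.x["x"] == pytest.approx(7.0, abs=1e-6)
        assert sol.x["y"] == pytest.approx(3.5, abs=1e-6)
        assert sol.pct_rni["iron"] == pytest.approx(77.0, abs=1e-4)
        report = m.problem_nutrients()
        assert "iron" in report.problem_nutrients
        oracle = brute_force_maximized(m, "iron", step=0.5)
        assert oracle.pct_rni["iron"] == pytest.approx(77.0, abs=1e-6)

    def test_zero_density_nutrient(self):
        m = self.two_food_model()
        assert m.fit_maximized("zinc").pct_rni["zinc"] == 0.0

    def test_relaxing_bounds_cannot_decrease_maximum(self):
        tight = hand_model(
            [("x", 100, 0, 3.5, 100, {"iron": 0.7}), ("y", 100, 0, 7, 200, {"iron": 0.14})],
            energy_kcal_day=200,
            tau=0.0,
            rni_overrides={"iron": 1.0},
        )
        loose = self.two_food_model()
        assert (
            loose.fit_maximized("iron").pct_rni["iron"]
            >= tight.fit_maximized("iron").pct_rni["iron"] - 1e-9
        )

    def test_fat_flags_follow_thresholds(self):
        # a diet at ~10 en% fat: below the 30 en% goal AND outside 25-35
        m = hand_model(
            [("x", 100, 0, 7, 100, {"fat": 1.2})],
            energy_kcal_day=100,
            rni_overrides={"fat": 25.0},
        )
        report = m.problem_nutrients()
        assert report.fat_below_goal
        assert report.fat_outside_range
        assert "fat" not in report.problem_nutrients


class TestModuleConsistency:
    def test_full_adequacy_iff_no_problem_nutrients(self, toy):
        # abundant single-food system: objective reaches 13, no problems
        dens = {n: 2.0 for n in NUTRIENTS}
        m = hand_model(
            [("a", 100, 0, 7, 100, dens)],
            energy_kcal_day=100,
            rni_overrides={n: 1.0 for n in NUTRIENTS},
        )
        sol = m.fit()
        report = m.problem_nutrients()
        assert sol.objective == pytest.approx(13.0, abs=1e-6)
        assert report.problem_nutrients == []
        # the scarce toy fixture: problems exist and the objective is < 13
        from fbrlp import ScenarioSpec, build_model_input

        mi = build_model_input(toy.dataset, toy.composition, toy.taxonomy, ScenarioSpec())
        toy_model = DietModel(mi, toy.composition, toy.requirements, toy.taxonomy)
        toy_sol = toy_model.fit()
        toy_report = toy_model.problem_nutrients()
        assert toy_report.problem_nutrients != []
        assert toy_sol.objective < 13.0 - 1e-6

    def test_solutions_respect_all_bounds(self, toy):
        from fbrlp import ScenarioSpec, build_model_input

        mi = build_model_input(toy.dataset, toy.composition, toy.taxonomy, ScenarioSpec())
        m = DietModel(mi, toy.composition, toy.requirements, toy.taxonomy)
        for sol in [m.fit(), m.fit_maximized("vitamin_a"), m.fit_maximized("calcium")]:
            assert (sol.x.to_numpy() >= m.lower - 1e-6).all()
            assert (sol.x.to_numpy() <= m.upper + 1e-6).all()
            lo, hi = m.energy_band
            assert lo - 1e-6 <= sol.weekly_energy_kcal <= hi + 1e-6
            for vec, blo, bhi, _ in m.aggregate_rows:
                s = float(vec @ sol.x.to_numpy())
                assert blo - 1e-6 <= s <= bhi + 1e-6


class TestBruteForce:
    def test_guard_against_many_foods(self):
        foods = [(f"f{i}", 100, 0, 7, 100, {}) for i in range(4)]
        m = hand_model(foods, energy_kcal_day=400)
        with pytest.raises(ValueError, match="3 foods"):
            brute_force_best_diet(m, step=0.5)

    def test_infeasible_grid_returns_none(self):
        m = hand_model([("a", 100, 0, 7, 100, {})], energy_kcal_day=200)
        assert brute_force_best_diet(m, step=0.5) is None
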