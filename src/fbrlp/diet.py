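"""Linear-programming diet model (the three Optifood-style analyses).

:class:`DietModel` is built from a :class:`~fbrlp.model_input.ModelInput`,
a composition table and a :class:`~fbrlp.requirements.RequirementSet`.  The
decision variables are continuous weekly serving frequencies x_f, one per
food in the model input, with

* food-level bounds        freq_min_f <= x_f <= freq_max_f,
* subgroup/group bounds    lo_S <= sum_{f in S} x_f <= hi_S,
* an energy band           7 E (1 - tau) <= sum_f e_f x_f <= 7 E (1 + tau),

where e_f = serving_g x energy density / 100 is the energy per serving and E
the daily energy requirement (tau defaults to 1%; a hard equality makes
continuous solvers needlessly brittle).

Three analyses are exposed:

* ``check_feasibility``  — zero-objective solve with arithmetic diagnoses
  (analysis I: can the input generate any diet at all?);
* ``fit``                — the best-optimised diet (analysis II): maximize the
  sum over the 13 nutrients of capped adequacy a_n = min(1, intake_n/RNI_n),
  tie-broken by minimal L1 deviation from the habitual diet and then by a
  lexicographic preference for earlier food ids;
* ``fit_maximized`` / ``problem_nutrients`` — per-nutrient maximized diets
  (analysis III); a nutrient whose maximized diet stays below 100% RNI is a
  problem nutrient.  Fat is reported in en% against its goal and its 25-35
  en% admissible range rather than as a problem nutrient.

Everything is deterministic: variables are ordered by sorted food id and the
HiGHS solver is run with fixed options.  A brute-force grid enumerator over
at most 3 foods serves as an independent oracle in the test-suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .foods import NUTRIENTS, CompositionTable
from .model_input import ModelInput
from .requirements import RequirementSet

__all__ = [
    "DietModel",
    "DietResults",
    "FeasibilityResult",
    "ProblemNutrientReport",
    "brute_force_best_diet",
    "brute_force_maximized",
]

_BOUND_TOL = 1e-6
_STAGE_TOL = 1e-7


@dataclass
class FeasibilityResult:
    """Verdict of the feasibility analysis with arithmetic diagnoses."""

    feasible: bool
    diagnoses: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.feasible


@dataclass
class ProblemNutrientReport:
    """Per-nutrient maxima and problem flags (analysis III).

    ``max_pct_rni`` maps each non-fat nutrient to the %RNI its maximized diet
    reaches; ``problem_nutrients`` are those below 100%.  Fat is tracked in
    en%: ``fat_en_pct`` from the fat-maximized diet, with independent flags
    for falling short of the en% goal and for leaving the admissible range.
    """

    max_pct_rni: dict[str, float]
    problem_nutrients: list[str]
    fat_en_pct: float
    fat_below_goal: bool
    fat_outside_range: bool
    solutions: dict[str, "DietResults"] = field(default_factory=dict)

    def is_problem(self, nutrient: str) -> bool:
        return nutrient in self.problem_nutrients

    def summary(self) -> pd.DataFrame:
        rows = []
        for nut in NUTRIENTS:
            if nut == "fat":
                rows.append(
                    {
                        "nutrient": "fat",
                        "max_pct_rni": np.nan,
                        "fat_en_pct": self.fat_en_pct,
                        "is_problem": False,
                        "fat_below_goal": self.fat_below_goal,
                        "fat_outside_range": self.fat_outside_range,
                    }
                )
            else:
                rows.append(
                    {
                        "nutrient": nut,
                        "max_pct_rni": self.max_pct_rni[nut],
                        "fat_en_pct": np.nan,
                        "is_problem": nut in self.problem_nutrients,
                        "fat_below_goal": False,
                        "fat_outside_range": False,
                    }
                )
        return pd.DataFrame(rows).set_index("nutrient")


class DietResults:
    """A solved weekly diet: frequencies, energy, nutrients and adequacy.

    Attributes
    ----------
    x : pandas.Series
        Servings/week per food (index sorted food_id).
    weekly_energy_kcal, daily_nutrients, pct_rni, fat_en_pct : see accessors.
    objective : float or None
        Stage-1 capped-adequacy sum for best-diet fits (max 13).
    """

    def __init__(
        self,
        model: "DietModel",
        x: np.ndarray,
        status: str = "optimal",
        objective: float | None = None,
    ):
        self.model = model
        self.status = status
        self.x = pd.Series(np.asarray(x, dtype=float), index=model.food_ids, name="servings_week")
        self.objective = objective
        self.weekly_energy_kcal = float(model.energy_per_serving @ self.x.to_numpy())
        weekly_nut = model.nutrient_per_serving @ self.x.to_numpy()
        self.daily_nutrients = pd.Series(weekly_nut / 7.0, index=list(NUTRIENTS))
        rni = model.requirements.rni
        self.pct_rni = pd.Series(
            {n: 100.0 * self.daily_nutrients[n] / rni[n] for n in NUTRIENTS}
        )
        daily_energy = self.weekly_energy_kcal / 7.0
        self.fat_en_pct = (
            100.0 * 9.0 * self.daily_nutrients["fat"] / daily_energy if daily_energy > 0 else 0.0
        )

    @property
    def daily_energy_kcal(self) -> float:
        return self.weekly_energy_kcal / 7.0

    def group_frequencies(self, rounded: bool = True) -> dict[str, float]:
        """Draft FBR view: total servings/week per food group."""
        out: dict[str, float] = {}
        for gid, members in self.model.group_members.items():
            tot = float(self.x[members].sum())
            out[gid] = float(round(tot)) if rounded else tot
        return out

    def capped_adequacy(self) -> float:
        """sum_n min(1, intake_n / RNI_n) over the 13 nutrients."""
        return float(np.minimum(1.0, self.pct_rni.to_numpy() / 100.0).sum())

    def summary(self) -> str:
        lines = [
            f"Diet solution ({self.status})",
            f"  energy: {self.daily_energy_kcal:.0f} kcal/d "
            f"(requirement {self.model.requirements.energy_kcal_day:.0f})",
            f"  fat: {self.fat_en_pct:.1f} en%",
            f"  capped adequacy: {self.capped_adequacy():.3f} / 13",
            "  servings/week:",
        ]
        for fid, val in self.x.items():
            lines.append(f"    {fid:<24s} {val:6.2f}")
        lines.append("  %RNI (daily):")
        for nut in NUTRIENTS:
            lines.append(f"    {nut:<24s} {self.pct_rni[nut]:6.1f}")
        return "\n".join(lines)


class DietModel:
    """LP over weekly food frequencies for one scenario's model input.

    Parameters
    ----------
    model_input : ModelInput
    fct : CompositionTable
        Must cover every food in the model input.
    requirements : RequirementSet
    taxonomy : FoodTaxonomy
        Supplies subgroup/group membership for the aggregate bounds.
    energy_tolerance : float
        Half-width tau of the relative energy band, in [0, 0.05].
    """

    def __init__(
        self,
        model_input: ModelInput,
        fct: CompositionTable,
        requirements: RequirementSet,
        taxonomy,
        energy_tolerance: float = 0.01,
    ):
        if model_input.n_foods == 0:
            raise ValueError("model input contains no foods")
        if not 0.0 <= energy_tolerance <= 0.05:
            raise ValueError("energy_tolerance must be in [0, 0.05]")
        self.model_input = model_input
        self.requirements = requirements
        self._taxonomy = taxonomy
        self.energy_tolerance = energy_tolerance
        self.food_ids = sorted(model_input.food_ids)

        entries = {e.food_id: e for e in model_input.foods}
        self.lower = np.array([entries[f].freq_min for f in self.food_ids])
        self.upper = np.array([entries[f].freq_max for f in self.food_ids])
        self.serving_g = np.array([entries[f].serving_g for f in self.food_ids])

        missing = [f for f in self.food_ids if f not in fct]
        if missing:
            raise KeyError(f"food(s) missing from composition table: {missing}")
        #: kcal per serving, by food
        self.energy_per_serving = np.array(
            [entries[f].serving_g * fct.energy(f) / 100.0 for f in self.food_ids]
        )
        #: (13, n_foods) nutrient amount per serving
        self.nutrient_per_serving = np.array(
            [
                [entries[f].serving_g * fct.density(f, n) / 100.0 for f in self.food_ids]
                for n in NUTRIENTS
            ]
        )

        e = requirements.energy_kcal_day
        self.energy_band = (7.0 * e * (1.0 - energy_tolerance), 7.0 * e * (1.0 + energy_tolerance))

        # aggregate (two-sided) rows: indicator vector, lo, hi, label
        self.aggregate_rows: list[tuple[np.ndarray, float, float, str]] = []
        idx = {f: i for i, f in enumerate(self.food_ids)}
        self.group_members: dict[str, list[str]] = {}
        for level, bounds in (
            ("subgroup", model_input.subgroup_bounds),
            ("group", model_input.group_bounds),
        ):
            for entity_id in sorted(bounds):
                lo, hi = bounds[entity_id]
                members = self._members_of(entity_id, level)
                if not members:
                    continue
                vec = np.zeros(len(self.food_ids))
                for f in members:
                    vec[idx[f]] = 1.0
                self.aggregate_rows.append((vec, lo, hi, f"{level}:{entity_id}"))
                if level == "group":
                    self.group_members[entity_id] = members

    def _members_of(self, entity_id: str, level: str) -> list[str]:
        members = self._taxonomy.members(entity_id, level)
        return [f for f in members if f in set(self.food_ids)]

    # -- construction -------------------------------------------------

    def n_variables(self) -> int:
        return len(self.food_ids)

    # -- solving ------------------------------------------------------

    def _solve(self, c, a_ub=None, b_ub=None, a_eq=None, b_eq=None, bounds=None):
        res = linprog(
            c,
            A_ub=a_ub,
            b_ub=b_ub,
            A_eq=a_eq,
            b_eq=b_eq,
            bounds=bounds,
            method="highs",
        )
        return res

    def _base_inequalities(self, n_extra: int = 0):
        """A_ub x <= b_ub for aggregate rows and energy band, on variables
        (x, extras); food-level bounds go through variable bounds."""
        n = len(self.food_ids)
        rows = []
        rhs = []
        for vec, lo, hi, _ in self.aggregate_rows:
            rows.append(np.concatenate([vec, np.zeros(n_extra)]))
            rhs.append(hi)
            rows.append(np.concatenate([-vec, np.zeros(n_extra)]))
            rhs.append(-lo)
        e_lo, e_hi = self.energy_band
        rows.append(np.concatenate([self.energy_per_serving, np.zeros(n_extra)]))
        rhs.append(e_hi)
        rows.append(np.concatenate([-self.energy_per_serving, np.zeros(n_extra)]))
        rhs.append(-e_lo)
        return np.array(rows), np.array(rhs)

    def _x_bounds(self):
        return [(lo, hi) for lo, hi in zip(self.lower, self.upper)]

    def check_feasibility(self) -> FeasibilityResult:
        """Analysis I: can any diet satisfy all bounds and the energy band?

        Solves a zero-objective LP; on infeasibility, attaches the simple
        arithmetic diagnoses that pinpoint the usual causes.
        """
        n = len(self.food_ids)
        a_ub, b_ub = self._base_inequalities()
        res = self._solve(np.zeros(n), a_ub, b_ub, bounds=self._x_bounds())
        if res.status == 0:
            return FeasibilityResult(True)
        diagnoses = []
        e_lo, e_hi = self.energy_band
        min_energy = float(self.energy_per_serving @ self.lower)
        max_energy = float(self.energy_per_serving @ self.upper)
        if min_energy > e_hi:
            diagnoses.append(
                f"minimum attainable energy above band ({min_energy:.0f} > {e_hi:.0f} kcal/week)"
            )
        if max_energy < e_lo:
            diagnoses.append(
                f"maximum attainable energy below band ({max_energy:.0f} < {e_lo:.0f} kcal/week)"
            )
        for vec, lo, hi, label in self.aggregate_rows:
            min_sum = float(vec @ self.lower)
            max_sum = float(vec @ self.upper)
            if min_sum > hi:
                diagnoses.append(
                    f"{label}: member minima sum {min_sum:.2f} exceeds upper bound {hi:.2f}"
                )
            if max_sum < lo:
                diagnoses.append(
                    f"{label}: member maxima sum {max_sum:.2f} below lower bound {lo:.2f}"
                )
        if not diagnoses:
            diagnoses.append("infeasible by interaction of constraints (no single cause)")
        return FeasibilityResult(False, diagnoses)

    def fit(self, habit_anchor: dict[str, float] | None = None) -> DietResults:
        """Analysis II: the best-optimised diet (draft FBR).

        Lexicographic objective — stage 1 maximizes the capped-adequacy sum
        over the 13 nutrients; stage 2, holding that optimum, minimizes the
        L1 distance of the frequencies from ``habit_anchor`` (per-food median
        habitual frequency; all-zero when omitted); stage 3 resolves
        remaining ties toward lexicographically-first food ids.
        """
        verdict = self.check_feasibility()
        if not verdict:
            raise ValueError(
                "model input generates no feasible diet; run check_feasibility "
                f"for diagnosis: {verdict.diagnoses}"
            )
        n = len(self.food_ids)
        k = len(NUTRIENTS)
        rni = self.requirements.rni
        # variables: x (n), a (k adequacy, in [0, 1])
        a_ub, b_ub = self._base_inequalities(n_extra=k)
        adequacy_rows = []
        adequacy_rhs = []
        for j, nut in enumerate(NUTRIENTS):
            # a_j - intake_j / rni_j <= 0  with intake_j = (c_j . x) / 7
            row = np.zeros(n + k)
            row[n + j] = 1.0
            row[:n] = -self.nutrient_per_serving[j] / (7.0 * rni[nut])
            adequacy_rows.append(row)
            adequacy_rhs.append(0.0)
        a_ub = np.vstack([a_ub, np.array(adequacy_rows)])
        b_ub = np.concatenate([b_ub, np.array(adequacy_rhs)])
        bounds = self._x_bounds() + [(0.0, 1.0)] * k

        c1 = np.concatenate([np.zeros(n), -np.ones(k)])
        res1 = self._solve(c1, a_ub, b_ub, bounds=bounds)
        if res1.status != 0:
            raise RuntimeError(f"stage-1 solve failed: {res1.message}")
        opt1 = -res1.fun

        # stage 2: fix stage-1 objective, minimize L1 deviation from anchor
        anchor = np.array(
            [float((habit_anchor or {}).get(f, 0.0)) for f in self.food_ids]
        )
        # variables: x (n), a (k), u (n), v (n) with x - u + v = anchor
        n_extra = k + 2 * n
        a_ub2, b_ub2 = self._base_inequalities(n_extra=n_extra)
        rows2 = []
        rhs2 = []
        for j, nut in enumerate(NUTRIENTS):
            row = np.zeros(n + n_extra)
            row[n + j] = 1.0
            row[:n] = -self.nutrient_per_serving[j] / (7.0 * rni[nut])
            rows2.append(row)
            rhs2.append(0.0)
        # -(sum a) <= -(opt1 - tol)
        row = np.zeros(n + n_extra)
        row[n : n + k] = -1.0
        rows2.append(row)
        rhs2.append(-(opt1 - _STAGE_TOL))
        a_ub2 = np.vstack([a_ub2, np.array(rows2)])
        b_ub2 = np.concatenate([b_ub2, np.array(rhs2)])
        a_eq = np.zeros((n, n + n_extra))
        for i in range(n):
            a_eq[i, i] = 1.0
            a_eq[i, n + k + i] = -1.0
            a_eq[i, n + k + n + i] = 1.0
        b_eq = anchor
        bounds2 = self._x_bounds() + [(0.0, 1.0)] * k + [(0.0, None)] * (2 * n)
        c2 = np.concatenate([np.zeros(n + k), np.ones(2 * n)])
        res2 = self._solve(c2, a_ub2, b_ub2, a_eq, b_eq, bounds2)
        if res2.status != 0:
            raise RuntimeError(f"stage-2 solve failed: {res2.message}")
        opt2 = res2.fun

        # stage 3: fix stages 1-2, prefer mass on lexicographically-first foods
        row = np.zeros(n + n_extra)
        row[n + k :] = 1.0
        a_ub3 = np.vstack([a_ub2, row])
        b_ub3 = np.concatenate([b_ub2, [opt2 + _STAGE_TOL]])
        c3 = np.concatenate([np.arange(1, n + 1, dtype=float), np.zeros(n_extra)])
        res3 = self._solve(c3, a_ub3, b_ub3, a_eq, b_eq, bounds2)
        res_final = res3 if res3.status == 0 else res2
        x = res_final.x[:n]
        return DietResults(self, x, status="optimal", objective=float(opt1))

    def fit_maximized(self, nutrient: str) -> DietResults:
        """Analysis III component: maximize one nutrient's weekly intake."""
        if nutrient not in NUTRIENTS:
            raise ValueError(f"unknown nutrient {nutrient!r}")
        verdict = self.check_feasibility()
        if not verdict:
            raise ValueError(
                f"model input generates no feasible diet: {verdict.diagnoses}"
            )
        n = len(self.food_ids)
        j = NUTRIENTS.index(nutrient)
        a_ub, b_ub = self._base_inequalities()
        c = -self.nutrient_per_serving[j]
        res = self._solve(c, a_ub, b_ub, bounds=self._x_bounds())
        if res.status != 0:
            raise RuntimeError(f"maximized solve failed for {nutrient}: {res.message}")
        return DietResults(self, res.x, status="optimal")

    def problem_nutrients(self) -> ProblemNutrientReport:
        """Analysis III: per-nutrient maximized diets and problem flags."""
        max_pct: dict[str, float] = {}
        solutions: dict[str, DietResults] = {}
        problems: list[str] = []
        for nut in NUTRIENTS:
            sol = self.fit_maximized(nut)
            solutions[nut] = sol
            if nut == "fat":
                continue
            max_pct[nut] = float(sol.pct_rni[nut])
            if max_pct[nut] < 100.0:
                problems.append(nut)
        fat_sol = solutions["fat"]
        fat_en = fat_sol.fat_en_pct
        lo, hi = self.requirements.fat_en_pct_range
        return ProblemNutrientReport(
            max_pct_rni=max_pct,
            problem_nutrients=problems,
            fat_en_pct=fat_en,
            fat_below_goal=fat_en < self.requirements.fat_en_pct,
            fat_outside_range=not (lo <= fat_en <= hi),
            solutions=solutions,
        )

def _feasible_grid(model: DietModel, step: float):
    """Yield feasible grid points of a <=3-food model."""
    n = len(model.food_ids)
    if n > 3:
        raise ValueError("brute force limited to 3 foods")
    axes = []
    for lo, hi in zip(model.lower, model.upper):
        count = int(round((hi - lo) / step))
        if abs(lo + count * step - hi) > 1e-9:
            raise ValueError("step must divide all bounds")
        axes.append(lo + step * np.arange(count + 1))
    e_lo, e_hi = model.energy_band
    for point in itertools.product(*axes):
        x = np.array(point)
        energy = float(model.energy_per_serving @ x)
        if energy < e_lo - 1e-9 or energy > e_hi + 1e-9:
            continue
        ok = True
        for vec, lo, hi, _ in model.aggregate_rows:
            s = float(vec @ x)
            if s < lo - 1e-9 or s > hi + 1e-9:
                ok = False
                break
        if ok:
            yield x


def brute_force_best_diet(
    model: DietModel,
    step: float = 0.5,
    habit_anchor: dict[str, float] | None = None,
) -> DietResults | None:
    """Grid-enumeration oracle for the best-optimised diet (<=3 foods).

    Returns the grid point with maximal capped adequacy, ties broken by the
    smaller L1 distance from the anchor and then lexicographically (earlier
    foods larger first).  Returns ``None`` when no grid point is feasible.
    """
    anchor = np.array([float((habit_anchor or {}).get(f, 0.0)) for f in model.food_ids])
    best = None
    best_key = None
    for x in _feasible_grid(model, step):
        sol = DietResults(model, x)
        key = (
            -round(sol.capped_adequacy(), 9),
            round(float(np.abs(x - anchor).sum()), 9),
            tuple(-x),  # prefer larger x on earlier foods
        )
        if best_key is None or key < best_key:
            best, best_key = sol, key
    return best


def brute_force_maximized(
    model: DietModel, nutrient: str, step: float = 0.5
) -> DietResults | None:
    """Grid-enumeration oracle for a single-nutrient maximized diet."""
    j = NUTRIENTS.index(nutrient)
    best = None
    best_val = -np.inf
    for x in _feasible_grid(model, step):
        val = float(model.nutrient_per_serving[j] @ x)
        if val > best_val + 1e-12:
            best_val = val
            best = DietResults(model, x)
    return best
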