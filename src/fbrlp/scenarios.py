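"""Scenario presets, end-to-end runs and sensitivity comparisons.

A scenario changes exactly one aspect of how LP model inputs or requirements
are derived, relative to the reference:

=========  ==================================================================
reference  reported frequencies, both recalls, 3% prevalence filter,
           5th-95th percentile band, observed mean body weight, 30 en% fat
A          estimated (presence-based) frequencies
B          first recall only
C          estimated frequencies + first recall only
D          10% prevalence filter
E          no prevalence filter (all consumed non-condiment foods)
F          10th-90th percentile band
G          reference body weight for the energy/protein requirement
H          25 en% fat goal
=========  ==================================================================

``run_scenario`` executes the full pipeline for one scenario: model-input
derivation, feasibility check, best-optimised diet (draft FBR) and
problem-nutrient identification.  ``compare`` classifies per-group FBR
changes against the reference (increased / decreased / negligible / absent)
and diffs the problem-nutrient sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .diet import DietModel, DietResults, ProblemNutrientReport
from .foods import GROUPS, CompositionTable, FoodTaxonomy
from .model_input import ModelInput, ScenarioSpec, build_model_input, reported_freq_dist
from .recalls import RecallDataset
from .requirements import PopulationProfile, RequirementSet, build_requirement_set, load_requirements
from .stats import percentile_weighted

__all__ = [
    "SCENARIO_IDS",
    "preset",
    "ScenarioResult",
    "ComparisonReport",
    "run_scenario",
    "run_all",
    "compare",
]

_REFERENCE = ScenarioSpec(name="reference")

_PRESETS: dict[str, ScenarioSpec] = {
    "reference": _REFERENCE,
    "A": replace(_REFERENCE, name="A", frequency_source="estimated"),
    "B": replace(_REFERENCE, name="B", recalls_used="first_only"),
    "C": replace(_REFERENCE, name="C", frequency_source="estimated", recalls_used="first_only"),
    "D": replace(_REFERENCE, name="D", prevalence_threshold=0.10),
    "E": replace(_REFERENCE, name="E", prevalence_threshold=0.0),
    "F": replace(_REFERENCE, name="F", percentile_band=(10.0, 90.0)),
    "G": replace(_REFERENCE, name="G", energy_weight_basis="reference"),
    "H": replace(_REFERENCE, name="H", fat_en_pct=25.0),
}

SCENARIO_IDS = tuple(_PRESETS)


def preset(scenario_id: str) -> ScenarioSpec:
    """The ScenarioSpec for one of the named scenarios."""
    try:
        return _PRESETS[scenario_id]
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario_id!r}; valid ids: {list(_PRESETS)}"
        ) from None


@dataclass
class ScenarioResult:
    """Everything one scenario run produces."""

    scenario_id: str
    spec: ScenarioSpec
    model_input: ModelInput
    requirements: RequirementSet
    n_foods_consumed: int  # foods passing the prevalence filter
    n_foods_in_list: int  # foods surviving the positive-upper-percentile rule
    best_diet: DietResults
    fbr: dict[str, float]  # group -> servings/week, rounded
    problem_report: ProblemNutrientReport

    @property
    def problem_nutrients(self) -> list[str]:
        return self.problem_report.problem_nutrients

    def summary(self) -> str:
        lines = [
            f"Scenario {self.scenario_id}: "
            f"{self.n_foods_consumed} foods selected, {self.n_foods_in_list} in food list",
            f"  energy requirement: {self.requirements.energy_kcal_day:.0f} kcal/d; "
            f"fat goal {self.requirements.rounded_goals()['fat_goal_g']} g "
            f"({self.requirements.fat_en_pct:.0f} en%)",
            "  draft FBR (servings/week by group):",
        ]
        for gid in GROUPS:
            if gid in self.fbr:
                lines.append(f"    {gid:<28s} {self.fbr[gid]:4.0f}")
        probs = ", ".join(self.problem_nutrients) or "none"
        lines.append(f"  problem nutrients: {probs}")
        lines.append(f"  fat in fat-maximized diet: {self.problem_report.fat_en_pct:.0f} en%")
        return "\n".join(lines)


@dataclass
class ComparisonReport:
    """Per-group FBR change classes and problem-nutrient diff vs. reference."""

    reference_id: str
    alternative_id: str
    group_changes: dict[str, str]  # group -> increased|decreased|negligible|absent
    new_problem_nutrients: list[str] = field(default_factory=list)
    resolved_problem_nutrients: list[str] = field(default_factory=list)
    negligible_threshold: float = 1.0

    def summary(self) -> pd.DataFrame:
        rows = [
            {"group": g, "change": c} for g, c in sorted(self.group_changes.items())
        ]
        return pd.DataFrame(rows)


def _profile_from_dataset(dataset: RecallDataset, config: dict) -> PopulationProfile:
    children = dataset.children
    if "sex" in children.columns:
        sexes = children["sex"].astype(str).str.lower().str[0]
        n_boys = int((sexes == "m").sum())
        n_girls = int((sexes == "f").sum())
    else:
        n_boys, n_girls = dataset.n_children, 0
    if "weight_kg" in children.columns and children["weight_kg"].notna().any():
        mean_weight = float(children["weight_kg"].mean())
    else:
        raise ValueError(
            "dataset has no child body weights; supply a PopulationProfile explicitly"
        )
    return PopulationProfile(
        n_boys=n_boys,
        n_girls=n_girls,
        mean_weight_kg=mean_weight,
        reference_weight_kg=float(config.get("reference_weight_kg", 19.2)),
    )


def run_scenario(
    dataset: RecallDataset,
    fct: CompositionTable,
    taxonomy: FoodTaxonomy,
    req_config: dict | None,
    spec: ScenarioSpec | str,
    profile: PopulationProfile | None = None,
    energy_tolerance: float = 0.01,
) -> ScenarioResult:
    """Run the full pipeline for one scenario.

    Derives the model input, checks feasibility (aborting with the diagnosis
    if none exists), fits the best-optimised diet anchored at each food's
    median habitual frequency, and identifies problem nutrients.
    """
    if isinstance(spec, str):
        spec = preset(spec)
    cfg = load_requirements(req_config)
    if profile is None:
        profile = _profile_from_dataset(dataset, cfg)
    try:
        requirements = build_requirement_set(
            profile, cfg, basis=spec.energy_weight_basis, fat_en_pct=spec.fat_en_pct
        )
        model_input = build_model_input(dataset, fct, taxonomy, spec)
        model = DietModel(
            model_input, fct, requirements, taxonomy, energy_tolerance=energy_tolerance
        )
        verdict = model.check_feasibility()
        if not verdict:
            raise ValueError(f"infeasible model input: {verdict.diagnoses}")
        anchor = _habit_anchor(dataset, taxonomy, model_input, spec)
        best = model.fit(habit_anchor=anchor)
        report = model.problem_nutrients()
    except Exception as exc:
        raise type(exc)(f"[scenario {spec.name}] {exc}") from exc
    return ScenarioResult(
        scenario_id=spec.name,
        spec=spec,
        model_input=model_input,
        requirements=requirements,
        n_foods_consumed=model_input.n_foods_selected,
        n_foods_in_list=model_input.n_foods,
        best_diet=best,
        fbr=best.group_frequencies(rounded=True),
        problem_report=report,
    )


def _habit_anchor(
    dataset: RecallDataset,
    taxonomy: FoodTaxonomy,
    model_input: ModelInput,
    spec: ScenarioSpec,
) -> dict[str, float]:
    """Median reported weekly frequency per food, clipped into its bounds."""
    anchor = {}
    for entry in model_input.foods:
        dist = reported_freq_dist(
            dataset, entry.food_id, taxonomy, recalls_used=spec.recalls_used
        )
        med = percentile_weighted(dist.values, 50)
        anchor[entry.food_id] = float(np.clip(med, entry.freq_min, entry.freq_max))
    return anchor


def run_all(
    dataset: RecallDataset,
    fct: CompositionTable,
    taxonomy: FoodTaxonomy,
    req_config: dict | None = None,
    scenario_ids: tuple[str, ...] = SCENARIO_IDS,
    profile: PopulationProfile | None = None,
) -> dict[str, ScenarioResult]:
    """Run every requested scenario; returns results keyed by scenario id."""
    return {
        sid: run_scenario(dataset, fct, taxonomy, req_config, sid, profile=profile)
        for sid in scenario_ids
    }


def compare(
    reference: ScenarioResult,
    alternative: ScenarioResult,
    negligible_threshold: float = 1.0,
) -> ComparisonReport:
    """Classify per-group FBR changes and diff problem nutrients.

    A group present in both runs is 'increased'/'decreased' when the weekly
    frequency moved by more than ``negligible_threshold`` servings/week,
    otherwise 'negligible'.  A group absent from one of the two models is
    marked 'absent'.
    """
    ref_groups = set(reference.fbr)
    alt_groups = set(alternative.fbr)
    changes: dict[str, str] = {}
    for gid in sorted(ref_groups | alt_groups):
        if gid not in ref_groups or gid not in alt_groups:
            changes[gid] = "absent"
            continue
        delta = alternative.fbr[gid] - reference.fbr[gid]
        if abs(delta) <= negligible_threshold:
            changes[gid] = "negligible"
        elif delta > 0:
            changes[gid] = "increased"
        else:
            changes[gid] = "decreased"
    ref_probs = set(reference.problem_nutrients)
    alt_probs = set(alternative.problem_nutrients)
    return ComparisonReport(
        reference_id=reference.scenario_id,
        alternative_id=alternative.scenario_id,
        group_changes=changes,
        new_problem_nutrients=sorted(alt_probs - ref_probs),
        resolved_problem_nutrients=sorted(ref_probs - alt_probs),
        negligible_threshold=negligible_threshold,
    )
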