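"""Energy and nutrient requirements for the target population.

Energy requirement comes from the FAO/WHO/UNU weight-based quadratic
equations for children (kcal/day as a function of body weight W in kg),
combined across sexes as a count-weighted mean:

    boys : 310.2 + 63.3 W - 0.263 W^2
    girls: 263.4 + 65.3 W - 0.454 W^2

The fat goal is a percentage of energy converted to grams at 9 kcal/g; the
protein goal is a g/kg body-weight coefficient.  Nutrient goals are FAO/WHO
recommended nutrient intakes (RNI) for 13 nutrients, assuming low iron (5%)
and moderate-low zinc (15%) bioavailability as appropriate for an unrefined
cereal-based diet high in phytate.  Estimated average requirements (EAR),
used only for the descriptive "% below EAR" statistic, are RNI divided by a
per-nutrient conversion factor.

All numeric tables ship as editable configuration; the defaults below target
children 4-6 years of age.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .foods import NUTRIENTS

__all__ = [
    "PopulationProfile",
    "RequirementSet",
    "DEFAULT_REQUIREMENTS_CONFIG",
    "energy_requirement",
    "macronutrient_goals",
    "load_requirements",
    "build_requirement_set",
]

#: Default requirements configuration (children 4-6 y).  Iron RNI assumes 5%
#: bioavailability, zinc RNI low bioavailability (15% absorption).  EAR
#: factors are RNI/EAR conversion ratios in the IoM style (CV 10% -> 1.2 for
#: most nutrients; vitamin A uses a wider ratio).
DEFAULT_REQUIREMENTS_CONFIG: dict = {
    "energy_coefficients": {
        # kcal/day = a + b*W + c*W^2, FAO/WHO/UNU 2004 weight-based equations
        "boys": {"a": 310.2, "b": 63.3, "c": -0.263},
        "girls": {"a": 263.4, "b": 65.3, "c": -0.454},
    },
    "fat_en_pct": 30.0,
    "fat_en_pct_range": [25.0, 35.0],
    "protein_g_per_kg": 0.70,
    "reference_weight_kg": 19.2,
    "bioavailability": {"iron": 0.05, "zinc": 0.15},
    "rni": {
        # daily RNI, children 4-6 y (units as in the composition table)
        "thiamin": 0.6,        # mg
        "riboflavin": 0.6,     # mg
        "niacin": 8.0,         # mg
        "vitamin_b6": 0.6,     # mg
        "folate": 200.0,       # ug
        "vitamin_b12": 1.2,    # ug
        "vitamin_c": 30.0,     # mg
        "vitamin_a": 450.0,    # ug RAE
        "calcium": 600.0,      # mg
        "iron": 12.6,          # mg, 5% bioavailability
        "zinc": 9.6,           # mg, low bioavailability
    },
    "ear_factors": {
        "protein": 1.2,
        "fat": 1.0,
        "thiamin": 1.2,
        "riboflavin": 1.2,
        "niacin": 1.2,
        "vitamin_b6": 1.2,
        "folate": 1.25,
        "vitamin_b12": 1.2,
        "vitamin_c": 1.2,
        "vitamin_a": 1.45,
        "calcium": 1.2,
        "iron": 1.2,
        "zinc": 1.2,
    },
}


@dataclass(frozen=True)
class PopulationProfile:
    """Sex composition and body weights of the target group."""

    n_boys: int
    n_girls: int
    mean_weight_kg: float
    reference_weight_kg: float

    def __post_init__(self):
        if self.n_boys < 0 or self.n_girls < 0 or self.n_boys + self.n_girls < 1:
            raise ValueError("need non-negative sex counts summing to >= 1")
        if self.mean_weight_kg <= 0 or self.reference_weight_kg <= 0:
            raise ValueError("body weights must be positive")

    def weight(self, basis: str) -> float:
        if basis == "mean_observed":
            return self.mean_weight_kg
        if basis == "reference":
            return self.reference_weight_kg
        raise ValueError(f"basis must be 'mean_observed' or 'reference', got {basis!r}")


@dataclass
class RequirementSet:
    """Assembled goals driving the LP and the descriptive statistics.

    ``rni`` covers all 13 nutrients: the micronutrient RNIs from config plus
    the computed (unrounded) fat and protein goals, so adequacy ratios are
    defined uniformly.  Reports round macronutrient goals to whole grams;
    the LP always uses the unrounded values.
    """

    energy_kcal_day: float
    fat_en_pct: float
    fat_goal_g: float
    protein_goal_g: float
    rni: dict[str, float]
    ear: dict[str, float] = field(default_factory=dict)
    iron_bioavailability: float = 0.05
    zinc_bioavailability: float = 0.15
    fat_en_pct_range: tuple[float, float] = (25.0, 35.0)

    def __post_init__(self):
        missing = [n for n in NUTRIENTS if n not in self.rni]
        if missing:
            raise ValueError(f"requirement set missing RNI for: {missing}")
        nonpos = [n for n, v in self.rni.items() if v <= 0]
        if nonpos:
            raise ValueError(f"non-positive RNI for: {nonpos}")

    def rounded_goals(self) -> dict[str, int]:
        """Reporting view: fat and protein goals to the nearest gram."""
        return {
            "fat_goal_g": int(round(self.fat_goal_g)),
            "protein_goal_g": int(round(self.protein_goal_g)),
        }


def energy_requirement(
    profile: PopulationProfile,
    basis: str = "mean_observed",
    coefficients: dict | None = None,
) -> float:
    """Population energy requirement, kcal/day.

    Evaluates the sex-specific quadratic at the body weight selected by
    ``basis`` and combines the two sexes as a count-weighted mean.
    """
    coeffs = coefficients or DEFAULT_REQUIREMENTS_CONFIG["energy_coefficients"]
    w = profile.weight(basis)
    if w <= 0:
        raise ValueError("body weight must be positive")

    def quad(sex: str) -> float:
        c = coeffs[sex]
        return c["a"] + c["b"] * w + c["c"] * w * w

    total = profile.n_boys + profile.n_girls
    return (profile.n_boys * quad("boys") + profile.n_girls * quad("girls")) / total


def macronutrient_goals(
    energy_kcal_day: float,
    fat_en_pct: float,
    protein_g_per_kg: float,
    weight_kg: float,
) -> tuple[float, float]:
    """Unrounded fat and protein goals in grams/day.

    fat_goal_g = fat_en_pct/100 * energy / 9 (9 kcal per g fat);
    protein_goal_g = protein_g_per_kg * weight_kg.  Reports round to whole
    grams; the LP uses these unrounded values.
    """
    if energy_kcal_day <= 0:
        raise ValueError("energy must be positive")
    if not 25.0 <= fat_en_pct <= 35.0:
        raise ValueError(f"fat_en_pct must be within [25, 35], got {fat_en_pct}")
    fat_goal = fat_en_pct / 100.0 * energy_kcal_day / 9.0
    protein_goal = protein_g_per_kg * weight_kg
    return fat_goal, protein_goal


def load_requirements(config=None) -> dict:
    """Load and validate a requirements config (path, YAML text, dict or None).

    ``None`` returns a copy of the built-in defaults.  Otherwise structural
    sections absent from the config (energy coefficients, bioavailability,
    fat range, protein coefficient) fall back to the defaults, but the
    ``rni`` and ``ear_factors`` sections — when supplied — must themselves be
    complete: an RNI for every micronutrient (the 11 nutrients other than
    protein and fat, whose goals are computed) and an EAR factor for every
    nutrient.  Raises ``ValueError`` listing any missing keys.
    """
    if config is None:
        return copy.deepcopy(DEFAULT_REQUIREMENTS_CONFIG)
    if isinstance(config, dict):
        cfg = copy.deepcopy(config)
    else:
        text = Path(config).read_text() if Path(str(config)).exists() else str(config)
        cfg = yaml.safe_load(text)
        if not isinstance(cfg, dict):
            raise ValueError("requirements config must be a mapping")
    merged = copy.deepcopy(DEFAULT_REQUIREMENTS_CONFIG)
    for key, val in cfg.items():
        merged[key] = val  # nutrient tables are replaced wholesale, not merged
    micronutrients = [n for n in NUTRIENTS if n not in ("protein", "fat")]
    missing = [n for n in micronutrients if n not in merged["rni"]]
    if missing:
        raise ValueError(f"requirements config missing RNI for: {missing}")
    missing_f = [n for n in NUTRIENTS if n not in merged["ear_factors"]]
    if missing_f:
        raise ValueError(f"requirements config missing EAR factor for: {missing_f}")
    return merged


def build_requirement_set(
    profile: PopulationProfile,
    config: dict | None = None,
    basis: str = "mean_observed",
    fat_en_pct: float | None = None,
) -> RequirementSet:
    """Assemble the full requirement set for a scenario.

    ``basis`` selects observed-mean vs. reference body weight for both the
    energy equation and the protein goal; ``fat_en_pct`` overrides the config
    fat goal (e.g. 25 en% in the low-fat scenario).
    """
    cfg = load_requirements(config)
    fat_pct = float(fat_en_pct if fat_en_pct is not None else cfg["fat_en_pct"])
    energy = energy_requirement(profile, basis, cfg["energy_coefficients"])
    weight = profile.weight(basis)
    fat_goal, protein_goal = macronutrient_goals(
        energy, fat_pct, cfg["protein_g_per_kg"], weight
    )
    rni = dict(cfg["rni"])
    rni["fat"] = fat_goal
    rni["protein"] = protein_goal
    ear = {n: rni[n] / cfg["ear_factors"][n] for n in NUTRIENTS}
    return RequirementSet(
        energy_kcal_day=energy,
        fat_en_pct=fat_pct,
        fat_goal_g=fat_goal,
        protein_goal_g=protein_goal,
        rni=rni,
        ear=ear,
        iron_bioavailability=cfg["bioavailability"]["iron"],
        zinc_bioavailability=cfg["bioavailability"]["zinc"],
        fat_en_pct_range=tuple(cfg["fat_en_pct_range"]),
    )
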