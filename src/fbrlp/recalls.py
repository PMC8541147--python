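"""24 h dietary-recall datasets, nutrient-intake computation and summaries.

A recall dataset holds one row per (child, recall day, food) with the grams
consumed on that day and the child-reported number of days in the previous
week the food was eaten (0-7).  Absence of a row encodes non-consumption on
that recall day.  Children are observed on one or two non-consecutive recall
days.

Intake per child-day is the composition-weighted sum over that day's records;
descriptive summaries decompose intake variance into within- and
between-person components from the two replicate days.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .foods import NUTRIENTS, CompositionTable, FoodTaxonomy
from .stats import percentile_weighted, variance_components

__all__ = [
    "RecallRecord",
    "RecallDataset",
    "IntakeSummary",
    "read_recalls",
    "child_day_intake",
    "intake_summary",
]

logger = logging.getLogger(__name__)

RECALL_COLUMNS = ("child_id", "recall_index", "food_id", "amount_g", "reported_frequency")


@dataclass(frozen=True)
class RecallRecord:
    """One food consumed by one child on one recall day."""

    child_id: str
    recall_index: int
    food_id: str
    amount_g: float
    reported_frequency: float  # days/week in [1, 7] when a record exists


class RecallDataset:
    """Validated collection of recall records plus child metadata.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``child_id, recall_index, food_id, amount_g,
        reported_frequency``.
    children : pandas.DataFrame, optional
        Indexed by or containing ``child_id``; optional columns ``sex``
        ('m'/'f') and ``weight_kg``.  When omitted, the child list is derived
        from the records.
    n_recalls : int
        Recalls per child (1 or 2).
    taxonomy : FoodTaxonomy, optional
        When given, every food_id must be known.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        children: pd.DataFrame | None = None,
        n_recalls: int = 2,
        taxonomy: FoodTaxonomy | None = None,
    ):
        if n_recalls not in (1, 2):
            raise ValueError(f"n_recalls must be 1 or 2, got {n_recalls}")
        missing = set(RECALL_COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"recall table missing columns: {sorted(missing)}")
        records = records.loc[:, list(RECALL_COLUMNS)].copy()
        records["child_id"] = records["child_id"].astype(str)
        records["food_id"] = records["food_id"].astype(str)
        records["recall_index"] = records["recall_index"].astype(int)
        records["amount_g"] = records["amount_g"].astype(float)
        records["reported_frequency"] = records["reported_frequency"].astype(float)

        bad_idx = ~records["recall_index"].isin(range(1, n_recalls + 1))
        if bad_idx.any():
            rows = records.index[bad_idx].tolist()
            raise ValueError(
                f"recall_index outside 1..{n_recalls} in row(s) {rows}"
            )
        freq = records["reported_frequency"]
        out = (freq < 0) | (freq > 7)
        if out.any():
            row = records.index[out][0]
            raise ValueError(
                f"reported_frequency outside [0, 7] in row {row} "
                f"(value {freq.loc[row]})"
            )
        if taxonomy is not None:
            unknown = ~records["food_id"].isin(taxonomy.food_ids)
            if unknown.any():
                row = records.index[unknown][0]
                raise ValueError(
                    f"unknown food_id {records.at[row, 'food_id']!r} in row {row}"
                )
        nonpos = records["amount_g"] <= 0
        if nonpos.any():
            logger.warning(
                "dropping %d recall row(s) with non-positive amount_g", int(nonpos.sum())
            )
            records = records.loc[~nonpos]
        # a recorded food was eaten on >=1 of the last 7 days; a stated
        # frequency of 0 is internally inconsistent and repaired to 1
        zero_freq = records["reported_frequency"] == 0
        if zero_freq.any():
            logger.warning(
                "data repair: %d record(s) with reported_frequency 0 set to 1",
                int(zero_freq.sum()),
            )
            records.loc[zero_freq, "reported_frequency"] = 1.0

        if children is None:
            children = pd.DataFrame({"child_id": sorted(records["child_id"].unique())})
        children = children.copy()
        if "child_id" in children.columns:
            children["child_id"] = children["child_id"].astype(str)
            children = children.set_index("child_id")
        else:
            children.index = children.index.astype(str)
        orphans = set(records["child_id"]) - set(children.index)
        if orphans:
            raise ValueError(f"records reference unknown child_id(s): {sorted(orphans)}")

        self._records = records.reset_index(drop=True)
        self._children = children.sort_index()
        self.n_recalls = n_recalls

    @property
    def records(self) -> pd.DataFrame:
        return self._records

    @property
    def children(self) -> pd.DataFrame:
        return self._children

    @property
    def child_ids(self) -> list[str]:
        return self._children.index.tolist()

    @property
    def n_children(self) -> int:
        return len(self._children)

    def consumed_foods(self, recalls_used: str = "both") -> list[str]:
        """All food ids with >=1 record in the recalls in scope (sorted)."""
        recs = self.records_in_scope(recalls_used)
        return sorted(recs["food_id"].unique())

    def records_in_scope(self, recalls_used: str = "both") -> pd.DataFrame:
        """Records restricted to both recalls or the first only."""
        if recalls_used == "both":
            return self._records
        if recalls_used == "first_only":
            return self._records[self._records["recall_index"] == 1]
        raise ValueError(f"recalls_used must be 'both' or 'first_only', got {recalls_used!r}")

    def subset_first_recall(self) -> "RecallDataset":
        """A one-recall dataset containing only each child's first recall."""
        return RecallDataset(
            self.records_in_scope("first_only"),
            self._children.reset_index(),
            n_recalls=1,
        )

    def to_csv(self, path) -> None:
        self._records.to_csv(path, index=False)


@dataclass
class IntakeSummary:
    """Descriptive intake statistics per nutrient (and energy).

    ``table`` is indexed by 'energy' + the 13 nutrients with columns
    ``median, p25, p75`` (per-child mean daily intake), ``cv_within`` and
    ``cv_between`` (%, NaN when undefined) and ``pct_below_ear`` (% of
    children whose across-recall mean is below the estimated average
    requirement; NaN where no EAR was supplied).
    """

    table: pd.DataFrame
    n_children: int = 0
    n_recalls: int = 2
    notes: list[str] = field(default_factory=list)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.round(2).to_string()


def read_recalls(
    path,
    taxonomy: FoodTaxonomy,
    children_path=None,
    n_recalls: int = 2,
) -> RecallDataset:
    """Read a recall table (comma-separated, see FORMATS.md) and validate it.

    Rows with non-positive ``amount_g`` are dropped with a warning; an unknown
    ``food_id`` or a ``reported_frequency`` outside [0, 7] raises ``ValueError``
    naming the offending row.
    """
    records = pd.read_csv(path)
    children = pd.read_csv(children_path) if children_path is not None else None
    return RecallDataset(records, children, n_recalls=n_recalls, taxonomy=taxonomy)


def child_day_intake(
    dataset: RecallDataset,
    fct: CompositionTable,
    child_id: str,
    recall_index: int,
) -> pd.Series:
    """Energy and nutrient intake for one child on one recall day.

    intake = sum over the day's records of amount_g x density_per_100g / 100.
    Returns a Series indexed 'energy' + nutrients.  An empty record set yields
    an all-zero vector with a warning; a consumed food missing from the
    composition table raises ``KeyError``.
    """
    recs = dataset.records
    day = recs[(recs["child_id"] == str(child_id)) & (recs["recall_index"] == recall_index)]
    out = pd.Series(0.0, index=["energy", *NUTRIENTS])
    if day.empty:
        warnings.warn(
            f"child {child_id!r} has no records for recall {recall_index}; "
            "intake reported as zero",
            stacklevel=2,
        )
        return out
    for _, rec in day.iterrows():
        comp = fct.row(rec["food_id"])  # KeyError if missing
        scale = rec["amount_g"] / 100.0
        out["energy"] += scale * comp["energy_kcal"]
        for nut in NUTRIENTS:
            out[nut] += scale * comp[nut]
    return out


def _intake_matrix(dataset: RecallDataset, fct: CompositionTable) -> dict[str, np.ndarray]:
    """(n_children x n_recalls) daily-intake matrix per nutrient, vectorised."""
    recs = dataset.records
    missing = set(recs["food_id"]) - set(fct.table.index)
    if missing:
        raise KeyError(f"consumed food(s) missing from composition table: {sorted(missing)}")
    comp = fct.table.loc[recs["food_id"]].to_numpy()  # rows align with records
    contrib = comp * (recs["amount_g"].to_numpy()[:, None] / 100.0)
    frame = pd.DataFrame(contrib, columns=["energy", *NUTRIENTS])
    frame["child_id"] = recs["child_id"].to_numpy()
    frame["recall_index"] = recs["recall_index"].to_numpy()
    sums = frame.groupby(["child_id", "recall_index"]).sum()
    children = dataset.child_ids
    out: dict[str, np.ndarray] = {}
    full_index = pd.MultiIndex.from_product(
        [children, range(1, dataset.n_recalls + 1)], names=["child_id", "recall_index"]
    )
    sums = sums.reindex(full_index, fill_value=0.0)
    for col in ["energy", *NUTRIENTS]:
        out[col] = sums[col].to_numpy().reshape(len(children), dataset.n_recalls)
    return out


def intake_summary(
    dataset: RecallDataset,
    fct: CompositionTable,
    ear_table: dict[str, float] | None = None,
) -> IntakeSummary:
    """Median/quartiles of per-child mean intake, CV decomposition and %<EAR.

    With two recalls per child the variance of daily intake is decomposed
    using the k=2 replicate design: the within-person component is the mean of
    per-child sample variances and the between-person component is the
    variance of child means minus half the within component, truncated at
    zero.  CVs are expressed as percentages of the grand mean.  With a single
    recall the within-person CV is undefined and reported as NaN.
    """
    if dataset.n_children < 2:
        raise ValueError("intake summary needs at least 2 children")
    ear_table = ear_table or {}
    mats = _intake_matrix(dataset, fct)
    rows = []
    notes: list[str] = []
    for nut in ["energy", *NUTRIENTS]:
        mat = mats[nut]
        child_means = mat.mean(axis=1)
        median = percentile_weighted(child_means, 50)
        p25 = percentile_weighted(child_means, 25)
        p75 = percentile_weighted(child_means, 75)
        if dataset.n_recalls >= 2:
            s2w, s2b, grand = variance_components(mat)
            cv_w = 100.0 * np.sqrt(s2w) / grand if grand > 0 else np.nan
            cv_b = 100.0 * np.sqrt(s2b) / grand if grand > 0 else np.nan
        else:
            cv_w = np.nan
            grand = float(child_means.mean())
            s2b = float(np.var(child_means, ddof=1))
            cv_b = 100.0 * np.sqrt(s2b) / grand if grand > 0 else np.nan
            if nut == "energy":
                notes.append("single recall: within-person CV undefined")
        ear = ear_table.get(nut)
        pct_below = (
            100.0 * float(np.mean(child_means < ear)) if ear is not None else np.nan
        )
        rows.append(
            {
                "median": median,
                "p25": p25,
                "p75": p75,
                "cv_within": cv_w,
                "cv_between": cv_b,
                "pct_below_ear": pct_below,
            }
        )
    table = pd.DataFrame(rows, index=["energy", *NUTRIENTS])
    return IntakeSummary(
        table=table,
        n_children=dataset.n_children,
        n_recalls=dataset.n_recalls,
        notes=notes,
    )
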