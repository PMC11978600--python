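"""Data-cleaning rules for the long-format feature tables.

Order of the cognitive cleaning pipeline is fixed: coverage filter (tests with
too few participants at some administered visit), constancy filter (tests
whose 5th-95th percentile band is a single value), extreme-outlier removal
(values beyond five interquartile ranges from the quartiles), then removal of
participants left with no cognitive data. MRI volumes are divided by the
participant's intracranial volume; MRI/EEG observations are kept only for
participants who survive cognitive preprocessing. No step imputes anything.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "validate_feature_table",
    "filter_low_coverage_tests",
    "filter_constant_tests",
    "iqr_outlier_mask",
    "filter_iqr_outliers",
    "drop_empty_participants",
    "icv_normalize",
    "match_modalities",
    "preprocess_cognitive",
]

LONG_COLUMNS = ["participant_id", "visit_index", "age", "variable", "value"]


@dataclass
class QCReport:
    """Bookkeeping for one cleaning step (or a whole pipeline)."""

    variables_removed: list[str] = field(default_factory=list)
    values_removed: int = 0
    participants_removed: list[str] = field(default_factory=list)
    n_rows_before: int = 0
    n_rows_after: int = 0
    notes: list[str] = field(default_factory=list)

    def merge(self, other: "QCReport") -> "QCReport":
        return QCReport(
            variables_removed=self.variables_removed + other.variables_removed,
            values_removed=self.values_removed + other.values_removed,
            participants_removed=self.participants_removed + other.participants_removed,
            n_rows_before=self.n_rows_before or other.n_rows_before,
            n_rows_after=other.n_rows_after,
            notes=self.notes + other.notes,
        )

    def to_dict(self) -> dict:
        return {
            "variables_removed": list(self.variables_removed),
            "values_removed": int(self.values_removed),
            "participants_removed": list(self.participants_removed),
            "n_rows_before": int(self.n_rows_before),
            "n_rows_after": int(self.n_rows_after),
            "notes": list(self.notes),
        }


def validate_feature_table(table: pd.DataFrame, allow_empty: bool = True) -> None:
    missing = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if not allow_empty and table.empty:
        raise ValueError("feature table is empty")
    dup = table.duplicated(subset=["participant_id", "visit_index", "variable"])
    if dup.any():
        bad = table.loc[dup, ["participant_id", "visit_index", "variable"]].iloc[0]
        raise ValueError(
            f"duplicate (participant, visit, variable) entries, e.g. {tuple(bad)}"
        )
    if not table.empty and not table["visit_index"].isin([1, 2, 3]).all():
        raise ValueError("visit_index values must be in {1, 2, 3}")


def filter_low_coverage_tests(
    table: pd.DataFrame, min_n: int = 75
) -> tuple[pd.DataFrame, QCReport]:
    """Keep a variable only if every visit at which it was administered has at
    least ``min_n`` participants with a non-missing value."""
    validate_feature_table(table, allow_empty=False)
    obs = table.dropna(subset=["value"])
    counts = obs.groupby(["variable", "visit_index"])["participant_id"].nunique()
    bad = sorted(counts[counts < min_n].index.get_level_values("variable").unique())
    out = table[~table["variable"].isin(bad)].reset_index(drop=True)
    report = QCReport(
        variables_removed=bad,
        n_rows_before=len(table),
        n_rows_after=len(out),
        notes=[f"coverage filter: min {min_n} participants per administered visit"],
    )
    return out, report


def filter_constant_tests(
    table: pd.DataFrame, pct_lo: float = 5.0, pct_hi: float = 95.0
) -> tuple[pd.DataFrame, QCReport]:
    """Remove variables whose values within the [pct_lo, pct_hi] percentile
    band (pooled over visits, linear-interpolation quantiles) are all equal."""
    if not 0 <= pct_lo < pct_hi <= 100:
        raise ValueError(f"need 0 <= lo < hi <= 100, got ({pct_lo}, {pct_hi})")
    validate_feature_table(table)
    bad = []
    for var, grp in table.dropna(subset=["value"]).groupby("variable"):
        vals = grp["value"].to_numpy(dtype=float)
        lo, hi = np.percentile(vals, [pct_lo, pct_hi])  # linear interpolation
        band = vals[(vals >= lo) & (vals <= hi)]
        if band.size == 0 or np.unique(band).size == 1:
            bad.append(var)
    out = table[~table["variable"].isin(bad)].reset_index(drop=True)
    report = QCReport(
        variables_removed=sorted(bad),
        n_rows_before=len(table),
        n_rows_after=len(out),
        notes=[f"constancy filter on [{pct_lo}, {pct_hi}] percentile band"],
    )
    return out, report


def iqr_outlier_mask(values, multiplier: float = 5.0) -> np.ndarray:
    """True where a value lies outside [Q1 - m*IQR, Q3 + m*IQR].

    Quartiles use linear interpolation. Fewer than 4 finite values: nothing is
    flagged (a warning is logged). NaNs are never flagged.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    mask = np.zeros(values.shape, dtype=bool)
    if finite.sum() < 4:
        logger.warning("iqr_outlier_mask: %d finite values (<4); nothing flagged",
                       int(finite.sum()))
        return mask
    q1, q3 = np.percentile(values[finite], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    mask[finite] = (values[finite] < lo) | (values[finite] > hi)
    return mask


def filter_iqr_outliers(
    table: pd.DataFrame, multiplier: float = 5.0, per_visit: bool = False
) -> tuple[pd.DataFrame, QCReport]:
    """Drop individual values beyond the IQR fences, per variable.

    Visits are pooled by default; ``per_visit=True`` computes the fences within
    each (variable, visit) group instead.
    """
    validate_feature_table(table)
    table = table.reset_index(drop=True)
    keys = ["variable", "visit_index"] if per_visit else ["variable"]
    drop = np.zeros(len(table), dtype=bool)
    for _, grp in table.groupby(keys):
        drop[grp.index] = iqr_outlier_mask(grp["value"].to_numpy(), multiplier)
    out = table[~drop].reset_index(drop=True)
    report = QCReport(
        values_removed=int(drop.sum()),
        n_rows_before=len(table),
        n_rows_after=len(out),
        notes=[f"IQR filter: {multiplier}x IQR fences, "
               + ("per visit" if per_visit else "visits pooled")],
    )
    return out, report


def drop_empty_participants(table: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Remove participants with no non-missing value in any visit."""
    validate_feature_table(table)
    observed = set(table.dropna(subset=["value"])["participant_id"].unique())
    all_ids = set(table["participant_id"].unique())
    gone = sorted(all_ids - observed)
    out = table[~table["participant_id"].isin(gone)].reset_index(drop=True)
    report = QCReport(
        participants_removed=gone,
        n_rows_before=len(table),
        n_rows_after=len(out),
        notes=["dropped participants with entirely missing data"],
    )
    return out, report


def icv_normalize(volumes: pd.DataFrame, icv: pd.Series) -> pd.DataFrame:
    """Divide each regional volume by the participant's intracranial volume.

    Participants with missing or non-positive ICV are excluded from the output
    (logged); the result is a dimensionless volume fraction.
    """
    validate_feature_table(volumes)
    icv = icv.astype(float)
    usable = icv[icv > 0]
    bad = sorted(set(volumes["participant_id"].unique()) - set(usable.index))
    if bad:
        logger.warning("icv_normalize: excluding %d participants with missing or "
                       "non-positive ICV: %s", len(bad), bad[:5])
    out = volumes[volumes["participant_id"].isin(usable.index)].copy()
    out["value"] = out["value"].to_numpy() / usable.reindex(out["participant_id"]).to_numpy()
    return out.reset_index(drop=True)


def match_modalities(
    cognitive: pd.DataFrame, *others: pd.DataFrame
) -> tuple[pd.DataFrame, ...]:
    """Restrict every secondary table to participants present in the cognitive
    table. Raises if a secondary table shares no participants at all."""
    validate_feature_table(cognitive)
    keep = set(cognitive["participant_id"].unique())
    out = []
    for tbl in others:
        validate_feature_table(tbl)
        if not tbl.empty and keep.isdisjoint(tbl["participant_id"].unique()):
            raise ValueError("modality table shares no participants with the cognitive table")
        out.append(tbl[tbl["participant_id"].isin(keep)].reset_index(drop=True))
    return (cognitive,) + tuple(out)


def preprocess_cognitive(
    table: pd.DataFrame,
    min_n: int = 75,
    pct_lo: float = 5.0,
    pct_hi: float = 95.0,
    iqr_multiplier: float = 5.0,
    iqr_per_visit: bool = False,
) -> tuple[pd.DataFrame, QCReport]:
    """The full cognitive cleaning pipeline, in the fixed order:
    coverage -> constancy -> IQR outliers -> empty-participant removal."""
    out, report = filter_low_coverage_tests(table, min_n=min_n)
    out, r2 = filter_constant_tests(out, pct_lo=pct_lo, pct_hi=pct_hi)
    out, r3 = filter_iqr_outliers(out, multiplier=iqr_multiplier, per_visit=iqr_per_visit)
    out, r4 = drop_empty_participants(out)
    return out, report.merge(r2).merge(r3).merge(r4)
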