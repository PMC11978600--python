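"""Long-format table I/O with schema validation.

The on-disk interchange format is a long CSV with columns participant_id,
visit_index, age, variable, value — one row per observation, missingness
explicit (absent rows or NaN values). QC reports and run manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import LONG_COLUMNS, QCReport, validate_feature_table

__all__ = ["read_long_table", "write_long_table", "write_qc_report", "write_json"]


def read_long_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format feature table.

    Raises with the offending columns on schema mismatch and on duplicate
    (participant, visit, variable) keys; an empty file with a valid header
    yields an empty table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, dtype={"participant_id": str})
    extra = [c for c in table.columns if c not in LONG_COLUMNS]
    missing = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing or extra:
        raise ValueError(
            f"{path}: schema mismatch (missing columns {missing}, unexpected {extra})"
        )
    if not table.empty:
        table["visit_index"] = table["visit_index"].astype(int)
        table["age"] = table["age"].astype(float)
        table["value"] = table["value"].astype(float)
    validate_feature_table(table)
    return table[LONG_COLUMNS]


def write_long_table(table: pd.DataFrame, path: str | Path) -> Path:
    validate_feature_table(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[LONG_COLUMNS].to_csv(path, index=False)
    return path


def write_qc_report(report: QCReport, path: str | Path) -> Path:
    return write_json(report.to_dict(), path)


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=default))
    return path
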