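"""Validated reading and writing of the case-table CSV schema.

Column order is fixed and documented: case_id, time_of_death, sex, age,
pmi, cause_class, cause_subcategory, brain_injury, expr_bmal1, expr_nr1d1,
ct_bmal1, ct_nr1d1.  Ct columns may be empty.  Clock times are decimal
hours.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CAUSE_CLASS

__all__ = ["COLUMNS", "MANDATORY_COLUMNS", "read_cohort", "write_cohort", "SchemaError"]

COLUMNS = [
    "case_id",
    "time_of_death",
    "sex",
    "age",
    "pmi",
    "cause_class",
    "cause_subcategory",
    "brain_injury",
    "expr_bmal1",
    "expr_nr1d1",
    "ct_bmal1",
    "ct_nr1d1",
]

MANDATORY_COLUMNS = COLUMNS[:10]  # Ct columns optional


class SchemaError(ValueError):
    """Raised when a case table is missing mandatory columns."""


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a case table in the documented column order."""
    df = cohort.copy()
    for c in ("ct_bmal1", "ct_nr1d1"):
        if c not in df.columns:
            df[c] = np.nan
    df[COLUMNS].to_csv(path, index=False)


def _row_error(row: pd.Series) -> str | None:
    if not 0 <= row["time_of_death"] < 24:
        return "time_of_death outside [0, 24)"
    if row["sex"] not in ("male", "female"):
        return f"unknown sex {row['sex']!r}"
    if not row["age"] >= 0:
        return "negative or missing age"
    if not 0 < row["pmi"] <= 96:
        return "pmi outside (0, 96]"
    if row["cause_class"] not in ("intrinsic", "extrinsic"):
        return f"unknown cause_class {row['cause_class']!r}"
    known_class = CAUSE_CLASS.get(row["cause_subcategory"])
    if known_class is not None and known_class != row["cause_class"]:
        return "cause_class inconsistent with cause_subcategory"
    if row["brain_injury"] not in ("none", "acute", "chronic"):
        return f"unknown brain_injury {row['brain_injury']!r}"
    if row["brain_injury"] != "none" and row["cause_subcategory"] != "head_injury":
        return "brain injury course set for a non-head-injury case"
    for c in ("expr_bmal1", "expr_nr1d1"):
        if not np.isfinite(row[c]) or row[c] <= 0:
            return "non-positive expression"
    return None


def read_cohort(path: str | Path) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Read and validate a case-table CSV.

    Returns ``(cohort, errors)`` where ``errors`` collects
    ``(csv_line_number, reason)`` for every rejected row.  Missing
    mandatory columns raise :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype={"case_id": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    for c in ("ct_bmal1", "ct_nr1d1"):
        if c not in df.columns:
            df[c] = np.nan
    for c in ("time_of_death", "age", "pmi", "expr_bmal1", "expr_nr1d1",
              "ct_bmal1", "ct_nr1d1"):
        df[c] = pd.to_numeric(df[c], errors="coerce")

    errors: list[tuple[int, str]] = []
    keep = np.ones(len(df), dtype=bool)
    for i, (_, row) in enumerate(df.iterrows()):
        reason = _row_error(row)
        if reason is not None:
            keep[i] = False
            errors.append((i + 2, reason))  # +2: header line and 1-based count
    return df.loc[keep, COLUMNS].reset_index(drop=True), errors
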