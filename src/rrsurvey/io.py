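"""Respondent CSV reading/writing with schema validation.

The on-disk schema is one row per respondent:

    id, arm, education, marital_status, nationality, crime, conduct,
    age, sentence_months, oc_score,
    resp_theft, resp_drugs, resp_violence, resp_speeding, resp_arson
    [, true_theft, ..., true_arson]          (synthetic cohorts only)

Header required, UTF-8, no missing values in observed-response columns.
Categorical labels are matched case-insensitively against the documented
vocabularies.  Optional per-item severity columns ``yboc_item_1`` ..
``yboc_item_10`` trigger recomputation of ``oc_score``; mismatches are
logged, the recomputed total wins.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ARMS, BEHAVIOURS, CATEGORICAL_LEVELS, RESPONSE_COLUMNS, TRUE_COLUMNS
from .scales import N_ITEMS, total_severity

__all__ = ["read_respondents", "write_respondents", "SCHEMA_COLUMNS"]

logger = logging.getLogger(__name__)

SCHEMA_COLUMNS = (
    ("id", "arm")
    + tuple(CATEGORICAL_LEVELS)
    + ("age", "sentence_months", "oc_score")
    + RESPONSE_COLUMNS
)

_YBOC_ITEM_COLS = tuple(f"yboc_item_{i}" for i in range(1, N_ITEMS + 1))

AGE_BOUNDS = (18, 55)  # survey inclusion criteria


class RespondentValidationError(ValueError):
    """A respondent file violated the schema; message lists row and column."""


def _fail(row, column, message):
    raise RespondentValidationError(f"row {row}, column {column!r}: {message}")


def read_respondents(path) -> pd.DataFrame:
    """Read and validate a respondent CSV.

    Row numbers in error messages are 1-based data rows (the header is
    row 0).  Returns a DataFrame with normalized (lower-case) categorical
    labels.
    """
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise RespondentValidationError(
            f"{path.name}: header is missing required columns {missing}"
        )

    vocabularies = {"arm": ARMS, **CATEGORICAL_LEVELS}
    for col, levels in vocabularies.items():
        values = df[col].astype(str).str.strip().str.lower()
        allowed = set(levels)
        for idx, v in values.items():
            if v not in allowed:
                _fail(idx + 1, col, f"unknown label {v!r} (allowed: {sorted(allowed)})")
        df[col] = values

    for col in RESPONSE_COLUMNS:
        if df[col].isna().any():
            row = int(df[col].isna().idxmax()) + 1
            _fail(row, col, "missing value in an observed-response column")
        for idx, v in df[col].items():
            if v not in (0, 1):
                _fail(idx + 1, col, f"non-binary response {v!r}")
        df[col] = df[col].astype(np.int8)

    for idx, v in df["age"].items():
        if not AGE_BOUNDS[0] <= v <= AGE_BOUNDS[1]:
            _fail(idx + 1, "age", f"age {v} outside inclusion range {AGE_BOUNDS}")
    for idx, v in df["sentence_months"].items():
        if v < 0:
            _fail(idx + 1, "sentence_months", f"negative sentence {v}")
    for idx, v in df["oc_score"].items():
        if not 0 <= v <= 40:
            _fail(idx + 1, "oc_score", f"severity score {v} outside 0-40")

    if all(c in df.columns for c in _YBOC_ITEM_COLS):
        recomputed = df[list(_YBOC_ITEM_COLS)].apply(
            lambda r: total_severity(r.tolist()), axis=1
        )
        mismatch = recomputed != df["oc_score"]
        if mismatch.any():
            logger.warning(
                "oc_score mismatches item totals in %d rows (e.g. row %d); "
                "using recomputed totals",
                int(mismatch.sum()), int(mismatch.idxmax()) + 1,
            )
        df["oc_score"] = recomputed

    for col in TRUE_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(np.int8)
    return df


def write_respondents(cohort: pd.DataFrame, path) -> None:
    """Write a respondent cohort in the documented CSV schema."""
    cols = [c for c in SCHEMA_COLUMNS if c in cohort.columns]
    cols += [c for c in TRUE_COLUMNS if c in cohort.columns]
    missing = [c for c in SCHEMA_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks schema columns {missing}")
    cohort[cols].to_csv(path, index=False, encoding="utf-8")
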