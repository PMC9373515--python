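"""Reading and writing the delimiter-separated interchange tables.

Three tables flow between pipeline stages:

* ``recalls`` — one row per food line of a 24-h recall
  (individual_id, day_index, meal_code, food_code, grams);
* ``food_composition`` — one row per food code with its group label and
  per-100-g nutrient amounts;
* ``individuals`` — one row per surveyed person with covariates and the
  sampling weight.

Comma is the default delimiter; tab-separated files are accepted via
``sep="\\t"`` (or ``sep=None`` to sniff).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RowParseError, SchemaError
from .vocab import (
    FCT_KEY_COLUMNS,
    INDIVIDUAL_COLUMNS,
    NUTRIENT_COLUMNS,
    RECALL_COLUMNS,
)

_RECALL_DTYPES = {
    "individual_id": str,
    "food_code": str,
}


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def _coerce_numeric(df: pd.DataFrame, column: str, what: str) -> pd.Series:
    coerced = pd.to_numeric(df[column], errors="coerce")
    bad = coerced.isna() & df[column].notna()
    if bad.any():
        # +2: one for the header line, one for 0-based indexing.
        line = int(df.index[bad][0]) + 2
        raise RowParseError(
            f"{what}: unparseable value {df.loc[df.index[bad][0], column]!r} "
            f"in column '{column}' at line {line}",
            line_number=line,
        )
    return coerced


def read_recalls(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a 24-h recall table; rejects rows with negative grams."""
    df = pd.read_csv(path, sep=sep, dtype=_RECALL_DTYPES)
    _require_columns(df, RECALL_COLUMNS, "recall table")
    for col in ("day_index", "meal_code", "grams"):
        df[col] = _coerce_numeric(df, col, "recall table")
    if len(df):
        neg = df["grams"] < 0
        if neg.any():
            line = int(df.index[neg][0]) + 2
            raise RowParseError(
                f"recall table: negative grams ({df.loc[df.index[neg][0], 'grams']}) "
                f"at line {line}",
                line_number=line,
            )
        if (df["meal_code"] < 1).any():
            line = int(df.index[df["meal_code"] < 1][0]) + 2
            raise RowParseError(
                f"recall table: meal_code must be >= 1 at line {line}",
                line_number=line,
            )
        df["day_index"] = df["day_index"].astype(int)
        df["meal_code"] = df["meal_code"].astype(int)
    else:
        df = df.astype({"day_index": int, "meal_code": int, "grams": float})
    return df[list(RECALL_COLUMNS)]


def read_food_composition(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a per-100-g food-composition table (FCT-style)."""
    df = pd.read_csv(path, sep=sep, dtype={"food_code": str})
    _require_columns(df, FCT_KEY_COLUMNS + ("energy_kcal",), "food composition table")
    for col in NUTRIENT_COLUMNS:
        if col not in df.columns:
            df[col] = 0.0
        else:
            df[col] = _coerce_numeric(df, col, "food composition table").fillna(0.0)
        if (df[col] < 0).any():
            raise RowParseError(
                f"food composition table: negative amount in column '{col}'"
            )
    if df["food_code"].duplicated().any():
        dupes = df.loc[df["food_code"].duplicated(), "food_code"].tolist()
        raise RowParseError(f"duplicate food codes: {dupes}")
    return df[list(FCT_KEY_COLUMNS) + list(NUTRIENT_COLUMNS)]


def read_individuals(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read the individual covariate table."""
    df = pd.read_csv(path, sep=sep, dtype={"id": str})
    _require_columns(
        df, ("id", "age_group", "sex", "sampling_weight"), "individuals table"
    )
    for col in INDIVIDUAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["sampling_weight"] = _coerce_numeric(df, "sampling_weight", "individuals table")
    if (df["sampling_weight"] <= 0).any():
        raise RowParseError("individuals table: sampling_weight must be > 0")
    return df[list(INDIVIDUAL_COLUMNS)]


def write_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)
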