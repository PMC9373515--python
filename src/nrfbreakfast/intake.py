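"""Nutrient-intake aggregation from recall lines and a composition table.

Amounts are scaled linearly from the per-100-g composition entries:
``intake = sum(grams / 100 * per100g)``. Aggregations are additive over
any partition of the lines, which the tests exercise as an invariant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import UnknownFoodError
from .vocab import BREAKFAST_MEAL_CODE, NUTRIENT_COLUMNS

NUTRIENTS = list(NUTRIENT_COLUMNS)


def _resolve(lines: pd.DataFrame, fct: pd.DataFrame) -> pd.DataFrame:
    """Merge lines with the composition table, scaling to grams consumed."""
    unknown = set(lines["food_code"]) - set(fct["food_code"])
    if unknown:
        raise UnknownFoodError(unknown)
    merged = lines.merge(fct[["food_code"] + NUTRIENTS], on="food_code", how="left")
    scale = merged["grams"].to_numpy() / 100.0
    merged[NUTRIENTS] = merged[NUTRIENTS].to_numpy() * scale[:, None]
    return merged


def compute_intake(lines: pd.DataFrame, fct: pd.DataFrame) -> pd.Series:
    """Total nutrient vector of a set of recall lines.

    Returns a Series over the controlled nutrient vocabulary; an empty
    line set yields the zero vector.
    """
    if len(lines) == 0:
        return pd.Series(0.0, index=NUTRIENTS)
    return _resolve(lines, fct)[NUTRIENTS].sum()


def per_day_intakes(
    recalls: pd.DataFrame,
    fct: pd.DataFrame,
    meal_code: int | None = None,
) -> pd.DataFrame:
    """Per person-day nutrient totals, optionally for one meal code.

    The person-day grid comes from the *full* recall table, so a day on
    which an individual recorded other meals but nothing for the
    requested meal appears with zero intake (this is what makes absent
    breakfasts classifiable as skipping rather than missing data).
    """
    grid = recalls[["individual_id", "day_index"]].drop_duplicates()
    sel = recalls if meal_code is None else recalls[recalls["meal_code"] == meal_code]
    if len(sel):
        sums = (
            _resolve(sel, fct)
            .groupby(["individual_id", "day_index"], sort=False)[NUTRIENTS]
            .sum()
            .reset_index()
        )
        out = grid.merge(sums, on=["individual_id", "day_index"], how="left")
    else:
        out = grid.copy()
        for col in NUTRIENTS:
            out[col] = np.nan
    out[NUTRIENTS] = out[NUTRIENTS].fillna(0.0)
    return out.sort_values(["individual_id", "day_index"], ignore_index=True)


def mean_intakes(
    recalls: pd.DataFrame,
    fct: pd.DataFrame,
    meal_code: int | None = None,
) -> pd.DataFrame:
    """Per-individual intakes averaged over the available recall days."""
    per_day = per_day_intakes(recalls, fct, meal_code=meal_code)
    return (
        per_day.groupby("individual_id", sort=True)[NUTRIENTS].mean().reset_index()
    )


def breakfast_intakes(recalls: pd.DataFrame, fct: pd.DataFrame) -> pd.DataFrame:
    """Per-individual breakfast intake, averaged over available days."""
    return mean_intakes(recalls, fct, meal_code=BREAKFAST_MEAL_CODE)


def daily_intakes(recalls: pd.DataFrame, fct: pd.DataFrame) -> pd.DataFrame:
    """Per-individual all-meal daily intake, averaged over available days."""
    return mean_intakes(recalls, fct, meal_code=None)
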