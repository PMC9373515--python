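"""Food-group consumption at breakfast and tertile-stratified summaries.

An individual is a consumer of a food group at breakfast when they ate
at least 10 g of it (averaged breakfast window); the mean intake
reported per group is the mean among its consumers. Group consumption is
associated with diet-quality tertiles through the rank-biserial
correlation of the binary consumer score against the tertile rank.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import UnknownFoodError
from .stats import rank_biserial, weighted_mean_se
from .vocab import BREAKFAST_MEAL_CODE, TERTILE_LABELS

CONSUMER_THRESHOLD_G = 10.0


def consumer_score(grams: float) -> int:
    """1 if at least 10 g of the group was consumed, else 0."""
    if grams < 0:
        raise ValueError(f"grams must be non-negative, got {grams}")
    return int(grams >= CONSUMER_THRESHOLD_G)


def breakfast_group_grams(recalls: pd.DataFrame, fct: pd.DataFrame) -> pd.DataFrame:
    """Per-individual breakfast grams per food group (wide, zero-filled).

    Grams are summed within each recall day's breakfast then averaged
    over the individual's available days.
    """
    unknown = set(recalls["food_code"]) - set(fct["food_code"])
    if unknown:
        raise UnknownFoodError(unknown)
    grid = recalls[["individual_id", "day_index"]].drop_duplicates()
    bf = recalls[recalls["meal_code"] == BREAKFAST_MEAL_CODE].merge(
        fct[["food_code", "food_group"]], on="food_code"
    )
    per_day = (
        bf.groupby(["individual_id", "day_index", "food_group"])["grams"]
        .sum()
        .unstack("food_group", fill_value=0.0)
        .reset_index()
    )
    per_day = grid.merge(per_day, on=["individual_id", "day_index"], how="left").fillna(0.0)
    out = per_day.drop(columns="day_index").groupby("individual_id", sort=True).mean()
    # every group in the composition table appears, eaten at breakfast or not
    for group in fct["food_group"].unique():
        if group not in out.columns:
            out[group] = 0.0
    return out.sort_index(axis=1)


def top_groups(percent_consumers: pd.Series, k: int = 10) -> list[str]:
    """The k most-consumed groups by percent consumers, ties alphabetical."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(percent_consumers) < k:
        warnings.warn(
            f"only {len(percent_consumers)} food groups available (< k={k}); "
            "returning all"
        )
    order = percent_consumers.reset_index()
    order.columns = ["food_group", "pct"]
    order = order.sort_values(
        ["pct", "food_group"], ascending=[False, True], kind="mergesort"
    )
    return order["food_group"].head(k).tolist()


def tertile_group_table(
    recalls: pd.DataFrame,
    fct: pd.DataFrame,
    tertiles: pd.Series,
    individuals: pd.DataFrame,
    weighted: bool = True,
    k: int = 10,
) -> pd.DataFrame:
    """Group intake x tertile summary for one age group's consumers.

    ``tertiles`` is indexed by individual_id. Returns one row per
    (food_group, tertile) among the top-k groups, with the weighted mean
    intake among consumers (+/- SE), the weighted percent consumers
    (+/- SE), and the group's rank-biserial association p-value across
    tertiles.
    """
    grams = breakfast_group_grams(recalls, fct)
    grams = grams.loc[grams.index.intersection(tertiles.index)]
    if grams.empty:
        raise ValueError("no individuals with both recalls and tertile labels")
    tert = tertiles.loc[grams.index]
    for label in TERTILE_LABELS:
        if (tert == label).sum() == 0:
            raise ValueError(f"tertile {label} is empty")
    w_all = (
        individuals.set_index("id")["sampling_weight"].reindex(grams.index)
        if weighted
        else pd.Series(1.0, index=grams.index)
    )
    overall_pct = {}
    for group in grams.columns:
        scores = (grams[group] >= CONSUMER_THRESHOLD_G).astype(int)
        overall_pct[group] = weighted_mean_se(scores, w_all).value * 100.0
    selected = top_groups(pd.Series(overall_pct), k=k)
    tert_rank = tert.map({"T1": 1, "T2": 2, "T3": 3})
    rows = []
    for group in selected:
        scores = (grams[group] >= CONSUMER_THRESHOLD_G).astype(int)
        r, p = rank_biserial(scores.to_numpy(), tert_rank.to_numpy())
        for label in TERTILE_LABELS:
            in_t = tert == label
            consumers = in_t & (scores == 1)
            if consumers.any():
                mean_est = weighted_mean_se(
                    grams.loc[consumers, group], w_all[consumers]
                )
                mean_g, mean_se = mean_est.value, mean_est.se
            else:
                mean_g, mean_se = np.nan, np.nan
            pct_est = weighted_mean_se(scores[in_t], w_all[in_t])
            rows.append(
                {
                    "food_group": group,
                    "tertile": label,
                    "mean_intake_g": mean_g,
                    "mean_intake_se": mean_se,
                    "percent_consumers": pct_est.value * 100.0,
                    "percent_consumers_se": pct_est.se * 100.0,
                    "rank_biserial_r": r,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
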