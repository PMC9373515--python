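"""Breakfast consumer / skipper classification and regularity tables.

A breakfast skipper is an individual whose breakfast (meal code 1)
supplies less than 50 kcal — including no breakfast at all; everyone at
or above 50 kcal is a regular consumer. The classification energy is the
mean over the individual's available recall days by default (habitual
framing); ``day_mode="day1"`` restricts to the first recall.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .intake import mean_intakes, per_day_intakes
from .stats import weighted_chi2
from .vocab import BREAKFAST_MEAL_CODE, ENERGY

SKIPPER_THRESHOLD_KCAL = 50.0

CONSUMER = "consumer"
SKIPPER = "skipper"


class BreakfastClassifier(BaseEstimator):
    """Threshold classifier on breakfast energy.

    Parameters
    ----------
    threshold : float, default 50.0
        Energy (kcal) below which an individual is a skipper.
    day_mode : {"mean", "day1"}, default "mean"
        Whether the rule applies to the mean over available days or to
        day 1 only.
    """

    def __init__(self, threshold: float = SKIPPER_THRESHOLD_KCAL, day_mode: str = "mean"):
        self.threshold = threshold
        self.day_mode = day_mode

    def fit(self, X=None, y=None):
        if self.day_mode not in ("mean", "day1"):
            raise ValueError("day_mode must be 'mean' or 'day1'")
        return self

    def predict(self, X) -> np.ndarray:
        """Map breakfast energies (kcal) to status labels."""
        energy = np.asarray(X, dtype=float).ravel()
        return np.where(energy < self.threshold, SKIPPER, CONSUMER)

    def classify_recalls(self, recalls: pd.DataFrame, fct: pd.DataFrame) -> pd.DataFrame:
        """Classify every individual appearing in a recall table.

        Returns one row per individual: ``individual_id``,
        ``breakfast_energy_kcal`` (the classification energy) and
        ``status``. Days with recalls but no breakfast lines count as
        0 kcal breakfasts.
        """
        self.fit()
        if self.day_mode == "day1":
            day1 = recalls[recalls["day_index"] == 1]
            per = per_day_intakes(day1, fct, meal_code=BREAKFAST_MEAL_CODE)
            energy = per.groupby("individual_id", sort=True)[ENERGY].mean()
        else:
            mean = mean_intakes(recalls, fct, meal_code=BREAKFAST_MEAL_CODE)
            energy = mean.set_index("individual_id")[ENERGY]
        out = energy.rename("breakfast_energy_kcal").reset_index()
        out["status"] = self.predict(out["breakfast_energy_kcal"])
        return out


def classify(
    recalls: pd.DataFrame,
    fct: pd.DataFrame,
    threshold: float = SKIPPER_THRESHOLD_KCAL,
    day_mode: str = "mean",
) -> pd.DataFrame:
    """Functional wrapper over :class:`BreakfastClassifier`."""
    return BreakfastClassifier(threshold=threshold, day_mode=day_mode).classify_recalls(
        recalls, fct
    )


def regularity_table(
    statuses: pd.DataFrame,
    individuals: pd.DataFrame,
    stratifier: str,
    weighted: bool = True,
) -> tuple[pd.DataFrame, float, float]:
    """Cross-tabulate breakfast status against one covariate.

    Returns ``(table, chi2, p)`` where ``table`` has one row per stratum
    with weighted counts and row percentages per status. The chi-square
    is computed on the weighted table rescaled to the unweighted sample
    size (no design-based correction); a degenerate margin yields
    ``p = nan``.
    """
    if stratifier not in individuals.columns:
        raise KeyError(f"'{stratifier}' is not a covariate of the individuals table")
    merged = statuses.merge(
        individuals[["id", stratifier, "sampling_weight"]],
        left_on="individual_id",
        right_on="id",
        how="inner",
    ).dropna(subset=[stratifier])
    empty = set(individuals[stratifier].dropna().unique()) - set(merged[stratifier])
    if empty:
        warnings.warn(f"strata with no observations excluded: {sorted(map(str, empty))}")
    weights = merged["sampling_weight"] if weighted else None
    stat, p, scaled = weighted_chi2(merged[stratifier], merged["status"], weights)
    table = scaled.copy()
    for status in (SKIPPER, CONSUMER):
        if status not in table.columns:
            table[status] = 0.0
    table = table[[SKIPPER, CONSUMER]]
    totals = table.sum(axis=1)
    pct = table.div(totals, axis=0) * 100.0
    out = pd.DataFrame(
        {
            "stratum": table.index,
            "n_skippers": table[SKIPPER].to_numpy(),
            "pct_skippers": pct[SKIPPER].to_numpy(),
            "n_consumers": table[CONSUMER].to_numpy(),
            "pct_consumers": pct[CONSUMER].to_numpy(),
        }
    ).reset_index(drop=True)
    return out, stat, p
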