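"""Contribution of breakfast to daily intake and to recommendations.

Two percentages per nutrient: breakfast intake as a share of the daily
intake, and intake (breakfast or daily) as a share of the daily
recommendation, with a 20% benchmark flag on the breakfast figure — a
meal supplying one of three-plus daily eating occasions should carry at
least 20% of each nutrient's recommendation.

Population-level figures default to ratios of weighted mean intakes
(robust to near-zero individual denominators); the mean of individual
ratios is available as ``mode="individual"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, NRFBreakfastError
from .references import ReferenceTable
from .stats import weighted_mean_se
from .vocab import ENERGY, SCORED_NUTRIENTS

BENCHMARK_PCT = 20.0


def pct_daily(breakfast_intake: float, daily_intake: float) -> float:
    """Breakfast intake as a percentage of daily intake."""
    if daily_intake == 0:
        if breakfast_intake > 0:
            raise NRFBreakfastError(
                "breakfast intake positive while daily intake is zero"
            )
        return float("nan")
    return 100.0 * breakfast_intake / daily_intake


def pct_recommendation(intake: float, recommendation: float) -> float:
    """Intake as a percentage of the daily recommendation (uncapped)."""
    if recommendation <= 0:
        raise ConfigError(f"recommendation must be > 0, got {recommendation}")
    return 100.0 * intake / recommendation


def benchmark_report(
    breakfast_intakes: pd.DataFrame,
    daily_intakes: pd.DataFrame,
    reference: ReferenceTable | None = None,
    weights: pd.Series | None = None,
    restrict_ids=None,
    nutrients=None,
    population: str = "",
    mode: str = "aggregate",
) -> pd.DataFrame:
    """Per-nutrient contribution report for one population.

    ``breakfast_intakes``/``daily_intakes`` are per-individual frames
    (``individual_id`` + nutrient columns); ``restrict_ids`` restricts
    the population (e.g. to tertile-3 members); ``weights`` is indexed
    by individual_id. Returns one row per nutrient with
    ``pct_of_daily_intake``, ``pct_of_recommendation_breakfast``,
    ``pct_of_recommendation_daily`` and ``meets_20pct``.
    """
    if mode not in ("aggregate", "individual"):
        raise ValueError("mode must be 'aggregate' or 'individual'")
    reference = reference or ReferenceTable.default()
    bf = breakfast_intakes.set_index("individual_id")
    daily = daily_intakes.set_index("individual_id")
    ids = bf.index.intersection(daily.index)
    if restrict_ids is not None:
        ids = ids.intersection(pd.Index(restrict_ids))
    if len(ids) == 0:
        raise ValueError("restricted population is empty")
    bf, daily = bf.loc[ids], daily.loc[ids]
    w = (
        pd.Series(1.0, index=ids)
        if weights is None
        else weights.reindex(ids)
    )
    if nutrients is None:
        nutrients = [ENERGY] + [
            n for n in SCORED_NUTRIENTS if n in reference.recommendation
        ]
    rows = []
    for nutrient in nutrients:
        rec = reference.recommendation.get(nutrient)
        mean_bf = weighted_mean_se(bf[nutrient], w).value
        mean_daily = weighted_mean_se(daily[nutrient], w).value
        if mode == "aggregate":
            share = pct_daily(mean_bf, mean_daily)
        else:
            ratio = np.where(
                daily[nutrient] > 0, bf[nutrient] / daily[nutrient], np.nan
            )
            ok = ~np.isnan(ratio)
            share = (
                100.0 * weighted_mean_se(ratio[ok], w[ok]).value if ok.any() else np.nan
            )
        pct_rec_bf = pct_recommendation(mean_bf, rec) if rec else np.nan
        pct_rec_daily = pct_recommendation(mean_daily, rec) if rec else np.nan
        rows.append(
            {
                "population": population,
                "nutrient": nutrient,
                "pct_of_daily_intake": share,
                "pct_of_recommendation_breakfast": pct_rec_bf,
                "pct_of_recommendation_daily": pct_rec_daily,
                "meets_20pct": bool(pct_rec_bf >= BENCHMARK_PCT)
                if not np.isnan(pct_rec_bf)
                else False,
            }
        )
    return pd.DataFrame(rows)
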