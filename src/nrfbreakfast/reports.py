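"""End-to-end pipeline and assembly of the survey-shaped report tables.

Five report families, mirroring how breakfast-quality survey analyses
are usually presented:

* ``regularity`` — breakfast consumer/skipper counts and percentages per
  covariate stratum with a chi-square association p-value, per age group;
* ``food_groups`` — top-10 food-group intake and percent consumers by
  diet-quality tertile, per age group;
* ``nrf_by_age`` — mean NRF9.3 score and usual energy/nutrient intakes at
  breakfast by age group (weighted mean ± SE);
* ``nutrients_by_tertile`` — usual breakfast intakes across tertiles with
  the linear trend test, per age group;
* ``contributions`` — long-format percentage contribution of breakfast to
  daily intake and to recommendations, 20% benchmark flagged, for the
  whole group and the tertile-3 (healthiest-breakfast) subgroup.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .classify import CONSUMER, classify, regularity_table
from .contributions import benchmark_report
from .errors import DependencyError
from .food_groups import tertile_group_table
from .intake import daily_intakes, per_day_intakes
from .outliers import qc_stratified
from .references import ReferenceTable, ReferenceTables
from .scoring import assign_tertiles, score_breakfast
from .stats import trend_test, weighted_mean_se
from .usual_intake import usual_intake_table
from .vocab import (
    AGE_GROUPS,
    BREAKFAST_MEAL_CODE,
    ENERGY,
    MICRONUTRIENTS,
    NUTRIENT_COLUMNS,
    SCORED_NUTRIENTS,
)

STRATIFIERS = ("sex", "urbanity", "wealth_quintile", "education", "nutrition_status")

#: Nutrients carried through the descriptive tables.
REPORT_NUTRIENTS = (ENERGY,) + SCORED_NUTRIENTS + (
    "total_fat_g", "mufa_g", "pufa_g", "carbohydrate_g",
    "thiamin_mg", "riboflavin_mg", "niacin_mg", "phosphorus_mg", "cholesterol_mg",
)


def run_pipeline(
    individuals: pd.DataFrame,
    recalls: pd.DataFrame,
    fct: pd.DataFrame,
    reference: ReferenceTable | ReferenceTables | None = None,
    weighted: bool = True,
    seed: int | None = 0,
    qc: bool = True,
) -> dict[str, pd.DataFrame]:
    """Run every stage in memory and return the report bundle.

    Stages: classification -> regularity tables; outlier QC of
    micronutrients (per sex x age stratum, seeded); NRF9.3 scoring of
    consumers' breakfast windows -> within-age-group tertiles; food-group
    tables; usual-intake shrinkage -> age-group and tertile nutrient
    tables with trend tests; contribution reports.
    """
    refs = (
        reference
        if isinstance(reference, ReferenceTables)
        else ReferenceTables(default=reference or ReferenceTable.default())
    )
    weights_by_id = individuals.set_index("id")["sampling_weight"]
    rng = np.random.default_rng(seed)

    statuses = classify(recalls, fct)
    statuses = statuses.merge(
        individuals[["id", "age_group"]], left_on="individual_id", right_on="id"
    ).drop(columns="id")

    regularity_rows = []
    for group in AGE_GROUPS:
        sub = statuses[statuses["age_group"] == group]
        if sub.empty:
            continue
        for stratifier in STRATIFIERS:
            if individuals[stratifier].dropna().empty:
                continue
            table, stat, p = regularity_table(
                sub, individuals, stratifier, weighted=weighted
            )
            table.insert(0, "stratifier", stratifier)
            table.insert(0, "age_group", group)
            table["chi2"] = stat
            table["p_value"] = p
            regularity_rows.append(table)
    regularity = pd.concat(regularity_rows, ignore_index=True)

    consumers = statuses.loc[statuses["status"] == CONSUMER, "individual_id"]
    consumer_recalls = recalls[recalls["individual_id"].isin(consumers)]

    # per person-day breakfast intakes feed both QC and shrinkage
    bf_per_day = per_day_intakes(consumer_recalls, fct, meal_code=BREAKFAST_MEAL_CODE)
    bf_per_day = bf_per_day.merge(
        individuals[["id", "sex", "age_group"]], left_on="individual_id", right_on="id"
    ).drop(columns="id")
    if qc:
        bf_per_day, qc_audit = qc_stratified(
            bf_per_day, MICRONUTRIENTS, ("sex", "age_group"), rng=rng
        )
    else:
        qc_audit = pd.DataFrame()

    bf_mean = (
        bf_per_day.groupby("individual_id", sort=True)[list(NUTRIENT_COLUMNS)]
        .mean()
        .reset_index()
    )
    scorable = bf_mean[bf_mean[ENERGY] > 0]
    scores = score_breakfast(scorable, reference=refs.default)
    scores = scores.merge(
        individuals[["id", "age_group"]], left_on="individual_id", right_on="id"
    ).drop(columns="id")

    tertiles_by_group: dict[str, pd.Series] = {}
    for group in AGE_GROUPS:
        sub = scores[scores["age_group"] == group]
        if len(sub) >= 3:
            tertiles_by_group[group] = assign_tertiles(
                sub.set_index("individual_id")["score"]
            )
    scores["tertile"] = scores["individual_id"].map(
        pd.concat(tertiles_by_group.values()) if tertiles_by_group else pd.Series(dtype=object)
    )

    food_group_rows = []
    for group, tert in tertiles_by_group.items():
        ids = tert.index
        table = tertile_group_table(
            consumer_recalls[consumer_recalls["individual_id"].isin(ids)],
            fct, tert, individuals, weighted=weighted,
        )
        table.insert(0, "age_group", group)
        food_group_rows.append(table)
    food_groups = pd.concat(food_group_rows, ignore_index=True)

    # usual breakfast intakes by shrinkage, per age group
    usual_by_group: dict[str, pd.DataFrame] = {}
    nrf_rows, tertile_rows = [], []
    for group, tert in tertiles_by_group.items():
        sub_days = bf_per_day[bf_per_day["individual_id"].isin(tert.index)]
        usual, _ = usual_intake_table(
            sub_days, REPORT_NUTRIENTS,
            weights=weights_by_id if weighted else None,
        )
        usual_by_group[group] = usual
        w = (
            weights_by_id.reindex(usual["individual_id"]).to_numpy()
            if weighted else None
        )
        sub_scores = scores[scores["age_group"] == group].set_index("individual_id")
        score_w = (
            weights_by_id.reindex(sub_scores.index).to_numpy() if weighted else None
        )
        est = weighted_mean_se(sub_scores["score"], score_w)
        nrf_rows.append({
            "age_group": group, "quantity": "nrf93_score",
            "mean": est.value, "se": est.se, "n": est.n,
        })
        tert_of = tert.reindex(usual["individual_id"]).to_numpy()
        for nutrient in REPORT_NUTRIENTS:
            est = weighted_mean_se(usual[nutrient], w)
            nrf_rows.append({
                "age_group": group, "quantity": nutrient,
                "mean": est.value, "se": est.se, "n": est.n,
            })
            trend = trend_test(
                usual[nutrient], tert_of, w, nutrient=nutrient
            )
            row = {"age_group": group, "nutrient": nutrient,
                   "all_mean": est.value, "all_se": est.se}
            for label in ("T1", "T2", "T3"):
                mask = tert_of == label
                t_est = weighted_mean_se(
                    usual.loc[mask, nutrient], None if w is None else w[mask]
                )
                row[f"{label}_mean"] = t_est.value
                row[f"{label}_se"] = t_est.se
            row.update({
                "trend_slope": trend.slope, "trend_p": trend.p_value,
                "trend_direction": trend.direction,
            })
            tertile_rows.append(row)
    nrf_by_age = pd.DataFrame(nrf_rows)
    nutrients_by_tertile = pd.DataFrame(tertile_rows)

    daily = daily_intakes(consumer_recalls, fct)
    contribution_rows = []
    for group, tert in tertiles_by_group.items():
        ref = refs.for_stratum(age_group=group)
        for label, ids in (
            ("all", tert.index),
            ("tertile_3", tert.index[tert == "T3"]),
        ):
            rep = benchmark_report(
                bf_mean, daily, reference=ref,
                weights=weights_by_id if weighted else None,
                restrict_ids=ids,
                population=f"{group}/{label}",
            )
            contribution_rows.append(rep)
    contributions = pd.concat(contribution_rows, ignore_index=True)

    return {
        "statuses": statuses,
        "regularity": regularity,
        "scores": scores,
        "food_groups": food_groups,
        "nrf_by_age": nrf_by_age,
        "nutrients_by_tertile": nutrients_by_tertile,
        "contributions": contributions,
        "qc_audit": qc_audit,
    }


#: Files each report stage depends on, for the file-based flow.
_STAGE_FILES = {
    "data_model_io": ("individuals.csv", "recalls.csv", "food_composition.csv"),
    "nrf_scoring": ("scores.csv",),
    "breakfast_classification": ("statuses.csv",),
}


def build_reports(artifact_dir: str | Path, out_dir: str | Path | None = None,
                  weighted: bool = True, seed: int | None = 0) -> dict[str, pd.DataFrame]:
    """File-based report assembly: read stage outputs, write report CSVs.

    Raises :class:`DependencyError` naming the stage whose artifact is
    missing.
    """
    from . import io as nio

    artifact_dir = Path(artifact_dir)
    for stage, files in _STAGE_FILES.items():
        if stage == "data_model_io":
            for fname in files:
                if not (artifact_dir / fname).exists():
                    raise DependencyError(stage, fname)
    individuals = nio.read_individuals(artifact_dir / "individuals.csv")
    recalls = nio.read_recalls(artifact_dir / "recalls.csv")
    fct = nio.read_food_composition(artifact_dir / "food_composition.csv")
    for stage in ("breakfast_classification", "nrf_scoring"):
        for fname in _STAGE_FILES[stage]:
            if not (artifact_dir / fname).exists():
                raise DependencyError(stage, fname)
    bundle = run_pipeline(individuals, recalls, fct, weighted=weighted, seed=seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in bundle.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
    return bundle
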