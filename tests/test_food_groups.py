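"""Food-group consumer scoring and tertile-stratified summaries."""

import numpy as np
import pandas as pd
import pytest

from nrfbreakfast import (
    classify,
    consumer_score,
    tertile_group_table,
    top_groups,
)
from nrfbreakfast.food_groups import breakfast_group_grams
from nrfbreakfast.scoring import assign_tertiles
from tests.conftest import make_recalls


class TestConsumerScore:
    @pytest.mark.parametrize(
        "grams,expected", [(10.0, 1), (9.99, 0), (0.0, 0), (250.0, 1)]
    )
    def test_10g_threshold(self, grams, expected):
        assert consumer_score(grams) == expected

    def test_negative_grams_rejected(self):
        with pytest.raises(ValueError):
            consumer_score(-1.0)


class TestTopGroups:
    def test_ranked_by_percent_consumers_descending(self):
        pct = pd.Series({"RICE": 80.0, "COFFEE": 50.0, "SUGARS": 20.0})
        assert top_groups(pct, k=2) == ["RICE", "COFFEE"]

    def test_ties_break_alphabetically(self):
        pct = pd.Series({"B_GROUP": 50.0, "A_GROUP": 50.0, "C_GROUP": 10.0})
        assert top_groups(pct, k=2) == ["A_GROUP", "B_GROUP"]

    def test_fewer_groups_than_k_warns_and_returns_all(self):
        pct = pd.Series({"RICE": 80.0})
        with pytest.warns(UserWarning):
            assert top_groups(pct, k=10) == ["RICE"]

    def test_dominant_menu_item_ranks_first(self, sim_small):
        individuals, recalls, fct, _ = sim_small
        grams = breakfast_group_grams(recalls, fct)
        pct = (grams >= 10.0).mean() * 100.0
        # rice is eaten by essentially everyone at breakfast in the menu
        assert top_groups(pct, k=1) == ["RICE"]


class TestBreakfastGroupGrams:
    def test_grams_averaged_over_available_days(self, tiny_fct):
        lines = make_recalls(
            [("i1", 1, 1, "A", 100.0), ("i1", 2, 1, "A", 50.0), ("i1", 2, 2, "B", 99.0)]
        )
        grams = breakfast_group_grams(lines, tiny_fct)
        assert grams.loc["i1", "RICE"] == pytest.approx(75.0)
        # lunch food does not count toward breakfast groups
        assert grams.loc["i1", "CHICKEN EGG"] == 0.0


class TestTertileGroupTable:
    def test_constant_consumption_everywhere(self, tiny_fct):
        n = 9
        rows = [(f"i{k}", 1, 1, "A", 100.0) for k in range(n)]
        recalls = make_recalls(rows)
        tert = assign_tertiles(
            pd.Series(np.arange(n, dtype=float), index=[f"i{k}" for k in range(n)])
        )
        individuals = pd.DataFrame(
            {"id": [f"i{k}" for k in range(n)], "sampling_weight": 1.0}
        )
        table = tertile_group_table(recalls, tiny_fct, tert, individuals, k=3)
        rice = table[table["food_group"] == "RICE"]
        np.testing.assert_allclose(rice["mean_intake_g"], 100.0)
        np.testing.assert_allclose(rice["percent_consumers"], 100.0)

    def test_group_consumed_only_by_t3_separates(self, tiny_fct):
        n = 30
        ids = [f"i{k:02d}" for k in range(n)]
        rows = [(i, 1, 1, "A", 100.0) for i in ids]
        tert = assign_tertiles(
            pd.Series(np.arange(n, dtype=float), index=ids)
        )
        rows += [(i, 1, 1, "B", 60.0) for i in tert.index[tert == "T3"]]
        recalls = make_recalls(rows)
        individuals = pd.DataFrame({"id": ids, "sampling_weight": 1.0})
        table = tertile_group_table(recalls, tiny_fct, tert, individuals, k=3)
        egg = table[table["food_group"] == "CHICKEN EGG"].set_index("tertile")
        assert egg.loc["T1", "percent_consumers"] == 0.0
        assert egg.loc["T2", "percent_consumers"] == 0.0
        assert egg.loc["T3", "percent_consumers"] == pytest.approx(100.0)
        assert egg["p_value"].iloc[0] < 0.01

    def test_percent_consumers_equals_weighted_mean_of_scores(self, sim_small):
        individuals, recalls, fct, _ = sim_small
        statuses = classify(recalls, fct)
        cons = statuses.loc[statuses["status"] == "consumer", "individual_id"]
        sub = recalls[recalls["individual_id"].isin(cons)]
        grams = breakfast_group_grams(sub, fct)
        ids = grams.index
        tert = assign_tertiles(pd.Series(np.arange(len(ids), dtype=float), index=ids))
        table = tertile_group_table(sub, fct, tert, individuals, weighted=True)
        w = individuals.set_index("id")["sampling_weight"]
        rice_t1 = table.query("food_group=='RICE' and tertile=='T1'").iloc[0]
        in_t1 = tert.index[tert == "T1"]
        scores = (grams.loc[in_t1, "RICE"] >= 10.0).astype(float)
        expected = float(np.average(scores, weights=w.loc[in_t1])) * 100.0
        assert rice_t1["percent_consumers"] == pytest.approx(expected)

    def test_empty_tertile_is_an_error(self, tiny_fct):
        recalls = make_recalls([(f"i{k}", 1, 1, "A", 100.0) for k in range(6)])
        tert = pd.Series(
            ["T1", "T1", "T1", "T2", "T2", "T2"],
            index=[f"i{k}" for k in range(6)],
        )
        individuals = pd.DataFrame(
            {"id": [f"i{k}" for k in range(6)], "sampling_weight": 1.0}
        )
        with pytest.raises(ValueError, match="T3"):
            tertile_group_table(recalls, tiny_fct, tert, individuals)
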