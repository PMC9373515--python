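"""Contribution of breakfast to daily intake and recommendations."""

import numpy as np
import pandas as pd
import pytest

from nrfbreakfast import ReferenceTable, benchmark_report, pct_daily, pct_recommendation
from nrfbreakfast.errors import ConfigError, NRFBreakfastError
from nrfbreakfast.vocab import ENERGY, NUTRIENT_COLUMNS, QUALIFYING_NUTRIENTS


class TestScalarOperations:
    def test_quarter_share(self):
        assert pct_daily(20.0, 80.0) == pytest.approx(25.0)

    def test_breakfast_equal_daily_is_100(self):
        assert pct_daily(33.0, 33.0) == pytest.approx(100.0)

    def test_both_zero_is_missing(self):
        assert np.isnan(pct_daily(0.0, 0.0))

    def test_positive_breakfast_zero_daily_is_inconsistent(self):
        with pytest.raises(NRFBreakfastError):
            pct_daily(1.0, 0.0)

    def test_protein_vs_printed_dv(self):
        assert pct_recommendation(13.5, 50.0) == pytest.approx(27.0)

    def test_zero_intake_is_zero_pct(self):
        assert pct_recommendation(0.0, 50.0) == 0.0

    def test_nonpositive_recommendation_rejected(self):
        with pytest.raises(ConfigError):
            pct_recommendation(10.0, 0.0)

    def test_diet_at_dv_amounts_is_100pct_everywhere(self, reference):
        for nutrient in QUALIFYING_NUTRIENTS:
            assert pct_recommendation(
                reference.dv[nutrient], reference.recommendation[nutrient]
            ) == pytest.approx(100.0)


def _intake_frame(ids, fill):
    df = pd.DataFrame({"individual_id": ids})
    for col in NUTRIENT_COLUMNS:
        df[col] = 0.0
    for col, val in fill.items():
        df[col] = val
    return df


class TestBenchmarkReport:
    def test_population_eating_25pct_of_recommendation_meets_benchmark(self, reference):
        ids = [f"i{k}" for k in range(5)]
        bf = _intake_frame(ids, {
            ENERGY: 500.0,
            **{n: 0.25 * reference.dv[n] for n in QUALIFYING_NUTRIENTS},
        })
        daily = _intake_frame(ids, {
            ENERGY: 2000.0,
            **{n: reference.dv[n] for n in QUALIFYING_NUTRIENTS},
        })
        rep = benchmark_report(bf, daily, reference)
        qualifying = rep[rep["nutrient"].isin(QUALIFYING_NUTRIENTS)]
        assert qualifying["meets_20pct"].all()
        assert qualifying["pct_of_recommendation_breakfast"].tolist() == pytest.approx(
            [25.0] * 9
        )

    def test_low_fiber_fails_benchmark(self, reference):
        ids = ["i1"]
        bf = _intake_frame(ids, {ENERGY: 400.0, "fiber_g": 0.07 * 25.0})
        daily = _intake_frame(ids, {ENERGY: 2000.0, "fiber_g": 25.0})
        rep = benchmark_report(bf, daily, reference).set_index("nutrient")
        assert rep.loc["fiber_g", "pct_of_recommendation_breakfast"] == pytest.approx(7.0)
        assert not rep.loc["fiber_g", "meets_20pct"]

    def test_aggregate_share_matches_raw_totals_oracle(self, reference):
        rng = np.random.default_rng(4)
        n = 40
        ids = [f"i{k}" for k in range(n)]
        bf = _intake_frame(ids, {ENERGY: rng.uniform(100, 500, n)})
        extra = rng.uniform(500, 1500, n)
        daily = _intake_frame(ids, {ENERGY: bf[ENERGY] + extra})
        w = pd.Series(rng.uniform(0.5, 2.0, n), index=ids)
        rep = benchmark_report(bf, daily, reference, weights=w).set_index("nutrient")
        oracle = 100.0 * np.sum(w.to_numpy() * bf[ENERGY].to_numpy()) / np.sum(
            w.to_numpy() * daily[ENERGY].to_numpy()
        )
        assert rep.loc[ENERGY, "pct_of_daily_intake"] == pytest.approx(oracle)

    def test_breakfast_share_never_exceeds_daily_share(self, reference):
        rng = np.random.default_rng(6)
        n = 25
        ids = [f"i{k}" for k in range(n)]
        fills_bf, fills_daily = {}, {}
        for col in (ENERGY,) + QUALIFYING_NUTRIENTS:
            b = rng.uniform(1, 50, n)
            fills_bf[col] = b
            fills_daily[col] = b + rng.uniform(0, 100, n)
        rep = benchmark_report(
            _intake_frame(ids, fills_bf), _intake_frame(ids, fills_daily), reference
        )
        assert (
            rep["pct_of_recommendation_breakfast"]
            <= rep["pct_of_recommendation_daily"] + 1e-9
        ).all()

    def test_empty_restriction_is_an_error(self, reference):
        ids = ["i1"]
        bf = _intake_frame(ids, {ENERGY: 100.0})
        daily = _intake_frame(ids, {ENERGY: 400.0})
        with pytest.raises(ValueError, match="empty"):
            benchmark_report(bf, daily, reference, restrict_ids=["zzz"])

    def test_individual_mode_close_to_aggregate_for_homogeneous_data(self, reference):
        ids = [f"i{k}" for k in range(10)]
        bf = _intake_frame(ids, {ENERGY: 100.0})
        daily = _intake_frame(ids, {ENERGY: 400.0})
        agg = benchmark_report(bf, daily, reference, mode="aggregate")
        ind = benchmark_report(bf, daily, reference, mode="individual")
        assert agg.loc[0, "pct_of_daily_intake"] == pytest.approx(
            ind.loc[0, "pct_of_daily_intake"]
        )
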