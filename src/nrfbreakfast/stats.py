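"""Survey-weighted descriptive statistics and the tests used in the reports.

Weights are treated as expansion factors normalized to mean 1; design
effects of the original multistage sampling are deliberately ignored
(simple weighted estimates only). The chi-square test on a weighted
contingency table uses the naive rescaling to the unweighted sample
size; the tertile trend test is a weighted least-squares slope with
heteroscedasticity-robust (HC1) standard errors, which stays calibrated
when the weights are expansion factors rather than precision weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

ALPHA = 0.05


@dataclass(frozen=True)
class WeightedEstimate:
    value: float
    se: float
    n: int
    sum_weights: float


@dataclass(frozen=True)
class TrendResult:
    nutrient: str
    direction: str  # "increasing" | "decreasing" | "none"
    slope: float
    p_value: float


def normalize_weights(weights, n: int | None = None) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return w / w.mean()


def weighted_mean_se(values, weights=None) -> WeightedEstimate:
    """Weighted mean with its linearized standard error.

    With weights normalized to mean 1, ``se = sqrt(n/(n-1) *
    sum(w^2 (x - mean)^2)) / sum(w)``; the small-sample factor makes the
    estimator collapse to the classical ``s/sqrt(n)`` at equal weights.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("no observations")
    w = np.ones(n) if weights is None else normalize_weights(weights)
    if w.size != n:
        raise ValueError("values and weights length mismatch")
    sw = w.sum()
    mean = float(np.sum(w * x) / sw)
    if n == 1:
        return WeightedEstimate(mean, 0.0, 1, float(sw))
    se = float(np.sqrt(n / (n - 1) * np.sum((w * (x - mean)) ** 2)) / sw)
    return WeightedEstimate(mean, se, n, float(sw))


def weighted_crosstab(rows, cols, weights=None) -> pd.DataFrame:
    """Sum of weights per (row, col) cell."""
    rows = pd.Series(np.asarray(rows), name="row")
    cols = pd.Series(np.asarray(cols), name="col")
    w = (
        np.ones(len(rows))
        if weights is None
        else normalize_weights(weights)
    )
    df = pd.DataFrame({"row": rows, "col": cols, "w": w})
    return df.pivot_table(
        index="row", columns="col", values="w", aggfunc="sum", fill_value=0.0
    )


def kish_effective_n(weights) -> float:
    """Kish effective sample size ``(sum w)^2 / sum w^2``."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / np.sum(w**2))


def weighted_chi2(rows, cols, weights=None) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-square of association on a weighted contingency table.

    The weighted cell totals are rescaled so they sum to the Kish
    effective sample size (equal to n under equal weights), then tested
    without continuity correction — a first-order correction for the
    extra variance unequal expansion factors add, short of a full
    design-based adjustment. Degenerate tables (a single row or column
    level) return ``(nan, nan, table)``.
    """
    table = weighted_crosstab(rows, cols, weights)
    n = (
        len(np.asarray(rows))
        if weights is None
        else kish_effective_n(weights)
    )
    scaled = table * (n / table.to_numpy().sum())
    if min(scaled.shape) < 2:
        return float("nan"), float("nan"), scaled
    stat, p, _, _ = sps.chi2_contingency(scaled.to_numpy(), correction=False)
    return float(stat), float(p), scaled


_TERTILE_INDEX = {"T1": 1, "T2": 2, "T3": 3, 1: 1, 2: 2, 3: 3}


def trend_test(values, tertile_labels, weights=None, nutrient: str = "",
               robust: bool = True) -> TrendResult:
    """Linear trend of a quantity across tertiles (index 1, 2, 3).

    The slope of a weighted least-squares fit of the value on the
    tertile index; two-sided p-value from the slope's t statistic with
    HC1 robust standard errors by default. Constant values return a zero
    slope with direction "none".
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray([_TERTILE_INDEX[v] for v in np.asarray(tertile_labels)], float)
    if set(t) != {1.0, 2.0, 3.0}:
        raise ValueError("all three tertile levels must be present")
    if np.ptp(y) == 0:
        return TrendResult(nutrient, "none", 0.0, 1.0)
    w = np.ones_like(y) if weights is None else normalize_weights(weights)
    model = sm.WLS(y, sm.add_constant(t), weights=w)
    fit = model.fit(cov_type="HC1") if robust else model.fit()
    slope = float(fit.params[1])
    p = float(fit.pvalues[1])
    if p < ALPHA:
        direction = "increasing" if slope > 0 else "decreasing"
    else:
        direction = "none"
    return TrendResult(nutrient, direction, slope, p)


def rank_biserial(binary, ordinal) -> tuple[float, float]:
    """Rank-biserial correlation between a 0/1 score and an ordinal factor.

    Mann-Whitney formulation: ``r = 2 U1 / (n1 n0) - 1`` where ``U1``
    compares the ordinal ranks of the scorers (1) against the
    non-scorers (0); the p-value is the two-sided Mann-Whitney test
    (normal approximation with tie correction). Degenerate inputs (a
    single class) return ``(nan, nan)``.
    """
    b = np.asarray(binary)
    o = np.asarray(ordinal, dtype=float)
    x, y = o[b == 1], o[b == 0]
    if len(x) == 0 or len(y) == 0:
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # heavy ties are expected here
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    r = 2.0 * float(res.statistic) / (len(x) * len(y)) - 1.0
    return r, float(res.pvalue)
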