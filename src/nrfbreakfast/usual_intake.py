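"""Usual-intake estimation by within/between variance shrinkage.

Two short recalls per person confound habitual intake with day-to-day
noise. On a transformed scale (log1p by default, because intakes are
skewed and may be zero), the within-person variance is estimated from
the paired-day differences of the replicated subsample,

    sigma2_w = mean over 2-day individuals of (x_i1 - x_i2)^2 / 2,

the between-person variance by moment matching,

    sigma2_b = max(0, var(person means) - sigma2_w * mean(1/k_i)),

and each person's usual intake is the best linear predictor

    usual_i = m + (mean_i - m) * sigma2_b / (sigma2_b + sigma2_w / k_i),

back-transformed to the original scale. This is an explicitly simplified
best-linear-predictor estimator: it reproduces the variance-removal
behaviour of measurement-error deconvolution software without its
spline-based distribution estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .stats import normalize_weights

_TRANSFORMS = {
    "log1p": (np.log1p, np.expm1),
    "none": (lambda x: x, lambda x: x),
}


@dataclass(frozen=True)
class VarianceDecomposition:
    nutrient: str
    grand_mean: float  # on the transformed scale
    between_person_variance: float
    within_person_variance: float
    transform: str
    n_two_day: int


def _as_day_matrix(day1, day2) -> np.ndarray:
    x = np.column_stack(
        [np.asarray(day1, dtype=float), np.asarray(day2, dtype=float)]
    )
    if np.isnan(x[:, 0]).any():
        raise ValueError("day-1 intakes must be present for every individual")
    return x


def decompose(
    day1,
    day2,
    weights=None,
    transform: str = "log1p",
    nutrient: str = "",
) -> VarianceDecomposition:
    """Estimate the variance components from per-day intakes.

    ``day2`` is NaN for individuals with a single recall day. Requires
    at least one (ideally >= 30) individual with both days.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    fwd = _TRANSFORMS[transform][0]
    x = _as_day_matrix(day1, day2)
    t = fwd(x)
    two_day = ~np.isnan(t[:, 1])
    n2 = int(two_day.sum())
    if n2 == 0:
        raise ValueError("no individuals with two recall days; shrinkage impossible")
    if n2 < 30:
        warnings.warn(
            f"only {n2} individuals with two days; variance components are unstable"
        )
    diffs = t[two_day, 0] - t[two_day, 1]
    sigma2_w = float(np.mean(diffs**2) / 2.0)
    person_means = np.where(two_day, np.nanmean(t, axis=1), t[:, 0])
    k = np.where(two_day, 2.0, 1.0)
    w = np.ones(len(t)) if weights is None else normalize_weights(weights)
    grand_mean = float(np.sum(w * person_means) / np.sum(w))
    var_pm = float(np.var(person_means, ddof=1)) if len(t) > 1 else 0.0
    sigma2_b = max(0.0, var_pm - sigma2_w * float(np.mean(1.0 / k)))
    return VarianceDecomposition(
        nutrient, grand_mean, sigma2_b, sigma2_w, transform, n2
    )


def shrink(person_mean, k_days, decomposition: VarianceDecomposition):
    """Best-linear-predictor usual intake on the original scale.

    ``person_mean`` is on the original scale; ``k_days`` in {1, 2}. With
    no within-person noise the shrinkage factor is 1 (usual = observed);
    with no between-person variance it is 0 (usual = grand mean).
    """
    fwd, back = _TRANSFORMS[decomposition.transform]
    pm = fwd(np.asarray(person_mean, dtype=float))
    k = np.asarray(k_days, dtype=float)
    s2b, s2w = decomposition.between_person_variance, decomposition.within_person_variance
    denom = s2b + s2w / k
    factor = np.where(denom > 0, s2b / np.where(denom > 0, denom, 1.0), 1.0)
    usual_t = decomposition.grand_mean + (pm - decomposition.grand_mean) * factor
    return back(usual_t)


class UsualIntakeShrinker(BaseEstimator, TransformerMixin):
    """Transformer from per-day intakes to usual-intake estimates.

    ``X`` is an (n, 2) array of day-1 and day-2 intakes on the original
    scale, with NaN in column 2 for single-day individuals. ``scale``
    names the transform applied before decomposition ("log1p" or
    "none"); it is not called ``transform`` to avoid shadowing the
    transformer method.

    Fitted attributes: ``grand_mean_`` (transformed scale),
    ``between_variance_``, ``within_variance_``, ``n_two_day_``.
    """

    def __init__(self, scale: str = "log1p", nutrient: str = ""):
        self.scale = scale
        self.nutrient = nutrient

    def fit(self, X, y=None, sample_weight=None):
        x = np.asarray(X, dtype=float)
        self.decomposition_ = decompose(
            x[:, 0], x[:, 1], weights=sample_weight,
            transform=self.scale, nutrient=self.nutrient,
        )
        self.grand_mean_ = self.decomposition_.grand_mean
        self.between_variance_ = self.decomposition_.between_person_variance
        self.within_variance_ = self.decomposition_.within_person_variance
        self.n_two_day_ = self.decomposition_.n_two_day
        return self

    def transform(self, X):
        x = np.asarray(X, dtype=float)
        two_day = ~np.isnan(x[:, 1])
        k = np.where(two_day, 2.0, 1.0)
        # person means are averaged on the transformed scale, as in fit
        fwd, back = _TRANSFORMS[self.scale]
        pm_t = np.where(two_day, np.nanmean(fwd(x), axis=1), fwd(x[:, 0]))
        return shrink(back(pm_t), k, self.decomposition_)


def usual_intake_table(
    per_day: pd.DataFrame,
    nutrients,
    weights: pd.Series | None = None,
    transform: str = "log1p",
) -> tuple[pd.DataFrame, dict[str, VarianceDecomposition]]:
    """Usual intakes for several nutrients from a per person-day table.

    ``per_day`` carries ``individual_id``, ``day_index`` and nutrient
    columns. Returns a per-individual frame of usual intakes plus the
    per-nutrient decompositions (for audit).
    """
    wide = per_day.pivot_table(
        index="individual_id", columns="day_index", values=list(nutrients)
    )
    ids = wide.index
    w = None if weights is None else weights.loc[ids].to_numpy()
    out = pd.DataFrame({"individual_id": ids})
    decomps: dict[str, VarianceDecomposition] = {}
    for nutrient in nutrients:
        d1 = wide[(nutrient, 1)].to_numpy()
        d2 = (
            wide[(nutrient, 2)].to_numpy()
            if (nutrient, 2) in wide.columns
            else np.full(len(ids), np.nan)
        )
        shrinker = UsualIntakeShrinker(scale=transform, nutrient=nutrient)
        x = np.column_stack([d1, d2])
        shrinker.fit(x, sample_weight=w)
        out[nutrient] = shrinker.transform(x)
        decomps[nutrient] = shrinker.decomposition_
    return out, decomps
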