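"""NRF9.3 nutrient-density scoring and within-group tertile assignment.

The Nutrient-Rich Food index NRF9.3 scores an intake window by first
normalizing every nutrient amount to 2000 kcal of that window, then

``NR  = sum over 9 qualifying nutrients of min(1, normalized / DV)``
``LIM = sum over 3 limiting   nutrients of max(0, normalized / MRV - 1)``
``NRF9.3 = (NR - LIM) x 100``

Qualifying fractions are capped at 100 %DV so an extreme intake of one
nutrient cannot compensate for a deficiency in another; only the portion
of a limiting nutrient in excess of its MRV counts against the score.
The maximum attainable score is 900 (all nine DVs met, no excess).
Because the normalization divides by the window's own energy, the score
is invariant to scaling the whole intake vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ScoringError
from .references import ReferenceTable
from .vocab import ENERGY, LIMITING_NUTRIENTS, QUALIFYING_NUTRIENTS, TERTILE_LABELS

NORMALIZATION_KCAL = 2000.0


@dataclass
class NRFResult:
    individual_id: str | None
    nr: float
    lim: float
    score: float
    scoring_energy_kcal: float
    tertile: str | None = None


def nrf93(
    intake,
    reference: ReferenceTable | None = None,
    cap_nr: bool = True,
    individual_id: str | None = None,
) -> NRFResult:
    """Score one intake window (a mapping/Series over the nutrient vocabulary).

    Raises :class:`ScoringError` on non-positive energy — a zero-energy
    window is unscorable, not a zero score; callers exclude skippers
    before scoring.
    """
    reference = reference or ReferenceTable.default()
    energy = float(intake[ENERGY])
    if not energy > 0:
        raise ScoringError(f"cannot score a window with energy {energy} kcal")
    factor = NORMALIZATION_KCAL / energy
    nr = 0.0
    for nutrient in QUALIFYING_NUTRIENTS:
        fraction = float(intake[nutrient]) * factor / reference.dv[nutrient]
        nr += min(1.0, fraction) if cap_nr else fraction
    lim = 0.0
    for nutrient in LIMITING_NUTRIENTS:
        fraction = float(intake[nutrient]) * factor / reference.mrv[nutrient]
        lim += max(0.0, fraction - 1.0)
    return NRFResult(individual_id, nr, lim, (nr - lim) * 100.0, energy)


class NRFScorer(BaseEstimator, TransformerMixin):
    """Vectorized NRF9.3 scorer over a DataFrame of intake windows.

    Parameters
    ----------
    reference : ReferenceTable, optional
        DV/MRV amounts; defaults to the built-in table.
    cap_nr : bool, default True
        Cap each qualifying fraction at 100 %DV. The uncapped mode exists
        for sensitivity analysis only.
    """

    def __init__(self, reference: ReferenceTable | None = None, cap_nr: bool = True):
        self.reference = reference
        self.cap_nr = cap_nr

    def fit(self, X=None, y=None):
        self.reference_ = self.reference or ReferenceTable.default()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return a frame with ``nr``, ``lim``, ``score``, ``scoring_energy_kcal``."""
        if not hasattr(self, "reference_"):
            self.fit()
        ref = self.reference_
        energy = X[ENERGY].to_numpy(dtype=float)
        if np.any(energy <= 0):
            raise ScoringError("all scored windows must have positive energy")
        factor = NORMALIZATION_KCAL / energy
        nr = np.zeros(len(X))
        for nutrient in QUALIFYING_NUTRIENTS:
            frac = X[nutrient].to_numpy(dtype=float) * factor / ref.dv[nutrient]
            nr += np.minimum(1.0, frac) if self.cap_nr else frac
        lim = np.zeros(len(X))
        for nutrient in LIMITING_NUTRIENTS:
            frac = X[nutrient].to_numpy(dtype=float) * factor / ref.mrv[nutrient]
            lim += np.maximum(0.0, frac - 1.0)
        out = pd.DataFrame(
            {
                "nr": nr,
                "lim": lim,
                "score": (nr - lim) * 100.0,
                "scoring_energy_kcal": energy,
            },
            index=X.index,
        )
        if "individual_id" in X.columns:
            out.insert(0, "individual_id", X["individual_id"].to_numpy())
        return out


def assign_tertiles(scores: pd.Series) -> pd.Series:
    """Split one age group's scores into rank-based tertiles T1 <= T2 <= T3.

    Individuals are ranked by score ascending with stable tie-breaking
    by id (the Series index); ranks split at ``ceil(n/3)`` and
    ``ceil(2n/3)``. Sizes never differ by more than one and every T3
    score is >= every T1 score. Requires n >= 3.
    """
    n = len(scores)
    if n < 3:
        raise ValueError(f"need at least 3 individuals to form tertiles, got {n}")
    order = scores.reset_index()
    order.columns = ["individual_id", "score"]
    order = order.sort_values(["score", "individual_id"], kind="mergesort")
    c1, c2 = math.ceil(n / 3), math.ceil(2 * n / 3)
    labels = np.empty(n, dtype=object)
    labels[:c1] = TERTILE_LABELS[0]
    labels[c1:c2] = TERTILE_LABELS[1]
    labels[c2:] = TERTILE_LABELS[2]
    return pd.Series(labels, index=order["individual_id"].to_numpy(), name="tertile").loc[
        scores.index
    ]


class TertileAssigner(BaseEstimator):
    """Estimator facade over :func:`assign_tertiles` (fit_predict only)."""

    def fit(self, X, y=None):
        scores = X if isinstance(X, pd.Series) else pd.Series(np.asarray(X, float))
        self.tertiles_ = assign_tertiles(scores)
        boundaries = self.tertiles_.groupby(self.tertiles_).size()
        self.sizes_ = boundaries.to_dict()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).tertiles_


def score_breakfast(
    intakes: pd.DataFrame,
    reference: ReferenceTable | None = None,
    cap_nr: bool = True,
) -> pd.DataFrame:
    """Score per-individual breakfast intakes (one row per individual).

    ``intakes`` must carry ``individual_id`` plus the nutrient columns;
    rows with non-positive energy must have been excluded upstream.
    """
    scorer = NRFScorer(reference=reference, cap_nr=cap_nr).fit()
    return scorer.transform(intakes)
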