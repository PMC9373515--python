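"""Implausible-intake outlier substitution per sex x age-group stratum.

A micronutrient intake is implausible when it exceeds 1.5 times the 99th
percentile of the observed stratum distribution; such values are
replaced by a draw from Uniform(P95, 1.5 x P99). Both percentiles are
computed once, from the pre-replacement values, with linear
interpolation between order statistics. Energy is never cleaned by this
rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import QCError

MIN_STRATUM_SIZE = 20


@dataclass(frozen=True)
class OutlierRule:
    detection_multiplier: float = 1.5
    upper_reference_percentile: float = 99.0
    substitution_lower_percentile: float = 95.0

    def __post_init__(self):
        if not self.detection_multiplier > 1:
            raise ValueError("detection multiplier must exceed 1")
        for p in (self.upper_reference_percentile, self.substitution_lower_percentile):
            if not 0 < p < 100:
                raise ValueError("percentiles must lie in (0, 100)")


class OutlierSubstituter(BaseEstimator, TransformerMixin):
    """Percentile-threshold substitution transformer for one stratum.

    Fitted attributes
    -----------------
    upper_threshold_ : float
        ``detection_multiplier x P99`` of the training values.
    substitution_lower_ : float
        P95 of the training values (lower bound of the uniform draw).
    """

    def __init__(self, rule: OutlierRule | None = None, random_state=None):
        self.rule = rule
        self.random_state = random_state

    def fit(self, X, y=None):
        rule = self.rule or OutlierRule()
        values = np.asarray(X, dtype=float).ravel()
        if values.size == 0:
            raise ValueError("cannot fit on an empty stratum")
        p99 = float(np.percentile(values, rule.upper_reference_percentile))
        p95 = float(np.percentile(values, rule.substitution_lower_percentile))
        upper = rule.detection_multiplier * p99
        if p95 > upper:
            raise QCError(
                "substitution interval is empty: "
                f"P{rule.substitution_lower_percentile}={p95:.6g} exceeds "
                f"{rule.detection_multiplier} x P{rule.upper_reference_percentile}"
                f"={upper:.6g}"
            )
        self.rule_ = rule
        self.upper_threshold_ = upper
        self.substitution_lower_ = p95
        return self

    def transform(self, X):
        values = np.asarray(X, dtype=float).ravel()
        rng = np.random.default_rng(self.random_state)
        mask = values > self.upper_threshold_
        cleaned = values.copy()
        cleaned[mask] = rng.uniform(
            self.substitution_lower_, self.upper_threshold_, size=int(mask.sum())
        )
        self.n_replaced_ = int(mask.sum())
        self.replaced_mask_ = mask
        return cleaned


def qc_nutrient(
    values,
    rule: OutlierRule | None = None,
    rng: np.random.Generator | int | None = None,
    ids=None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Clean one stratum's intake vector; returns (cleaned, audit log).

    The audit log records, per replacement: id, old and new value, the
    detection threshold and the substitution lower bound. Non-outlier
    values pass through bit-identically.
    """
    rule = rule or OutlierRule()
    values = np.asarray(values, dtype=float).ravel()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sub = OutlierSubstituter(rule=rule)
    sub.fit(values)
    mask = values > sub.upper_threshold_
    cleaned = values.copy()
    cleaned[mask] = rng.uniform(
        sub.substitution_lower_, sub.upper_threshold_, size=int(mask.sum())
    )
    ids = np.arange(values.size) if ids is None else np.asarray(ids)
    audit = pd.DataFrame(
        {
            "id": ids[mask],
            "old_value": values[mask],
            "new_value": cleaned[mask],
            "upper_threshold": sub.upper_threshold_,
            "substitution_lower": sub.substitution_lower_,
        }
    )
    return cleaned, audit


def qc_stratified(
    df: pd.DataFrame,
    value_columns,
    strata_columns=("sex", "age_group"),
    rule: OutlierRule | None = None,
    rng: np.random.Generator | int | None = None,
    id_column: str = "individual_id",
    min_stratum_size: int = MIN_STRATUM_SIZE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the substitution rule per nutrient within each stratum.

    Strata smaller than ``min_stratum_size`` are skipped with a warning
    (their percentiles would be unstable). Returns the cleaned frame and
    a combined audit log.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = df.copy()
    audits = []
    for key, idx in df.groupby(list(strata_columns), dropna=False).groups.items():
        if len(idx) < min_stratum_size:
            warnings.warn(
                f"stratum {key} has {len(idx)} individuals (< {min_stratum_size}); "
                "outlier substitution skipped"
            )
            continue
        for col in value_columns:
            cleaned, audit = qc_nutrient(
                df.loc[idx, col], rule=rule, rng=rng, ids=df.loc[idx, id_column]
            )
            out.loc[idx, col] = cleaned
            if len(audit):
                audit.insert(0, "nutrient", col)
                audit.insert(0, "stratum", str(key))
                audits.append(audit)
    audit_log = (
        pd.concat(audits, ignore_index=True)
        if audits
        else pd.DataFrame(
            columns=[
                "stratum", "nutrient", "id", "old_value", "new_value",
                "upper_threshold", "substitution_lower",
            ]
        )
    )
    return out, audit_log
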