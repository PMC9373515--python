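"""Reference daily values (DV) and maximum recommended values (MRV).

The default table is the single adult reference printed with the NRF9.3
model: nine qualifying-nutrient DVs and three limiting-nutrient MRVs.
Stratum-specific tables (per age group, optionally per sex) can be
supplied through a YAML override file; the ``recommendation`` map, used
for percentage-of-recommendation reporting, defaults to the DV/MRV
amounts plus a 2000 kcal energy reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError
from .vocab import ENERGY, LIMITING_NUTRIENTS, QUALIFYING_NUTRIENTS

#: Daily values of the nine qualifying nutrients.
DEFAULT_DV = {
    "protein_g": 50.0,
    "fiber_g": 25.0,
    "vitamin_a_re_ug": 1500.0,
    "vitamin_c_mg": 60.0,
    "vitamin_d_ug": 10.0,
    "calcium_mg": 1000.0,
    "iron_mg": 18.0,
    "potassium_mg": 3500.0,
    "magnesium_mg": 400.0,
}

#: Maximum recommended values of the three limiting nutrients.
DEFAULT_MRV = {
    "total_sugar_g": 50.0,
    "saturated_fat_g": 20.0,
    "sodium_mg": 2400.0,
}

DEFAULT_ENERGY_RECOMMENDATION_KCAL = 2000.0


@dataclass(frozen=True)
class ReferenceTable:
    """DV/MRV amounts plus the recommendation map used for % reporting."""

    dv: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DV))
    mrv: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MRV))
    recommendation: Mapping[str, float] | None = None

    def __post_init__(self):
        if set(self.dv) != set(QUALIFYING_NUTRIENTS):
            raise ConfigError(
                "dv must contain exactly the nine qualifying nutrients; got "
                f"{sorted(self.dv)}"
            )
        if set(self.mrv) != set(LIMITING_NUTRIENTS):
            raise ConfigError(
                "mrv must contain exactly the three limiting nutrients; got "
                f"{sorted(self.mrv)}"
            )
        for name, amount in {**self.dv, **self.mrv}.items():
            if not amount > 0:
                raise ConfigError(f"reference amount for {name} must be > 0")
        if self.recommendation is None:
            rec = {**self.dv, **self.mrv, ENERGY: DEFAULT_ENERGY_RECOMMENDATION_KCAL}
            object.__setattr__(self, "recommendation", rec)
        else:
            for name, amount in self.recommendation.items():
                if not amount > 0:
                    raise ConfigError(f"recommendation for {name} must be > 0")

    @classmethod
    def default(cls) -> "ReferenceTable":
        return cls()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceTables":
        """Load a reference file; returns a :class:`ReferenceTables` bundle."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        default = cls(
            dv=raw.get("dv", dict(DEFAULT_DV)),
            mrv=raw.get("mrv", dict(DEFAULT_MRV)),
            recommendation=raw.get("recommendation"),
        )
        overrides = {}
        for key, sub in (raw.get("overrides") or {}).items():
            overrides[key] = cls(
                dv={**default.dv, **(sub.get("dv") or {})},
                mrv={**default.mrv, **(sub.get("mrv") or {})},
                recommendation=(
                    {**default.recommendation, **(sub.get("recommendation") or {})}
                    if sub.get("recommendation")
                    else None
                ),
            )
        return ReferenceTables(default=default, overrides=overrides)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "dv": dict(self.dv),
            "mrv": dict(self.mrv),
            "recommendation": dict(self.recommendation),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


@dataclass(frozen=True)
class ReferenceTables:
    """A default table plus optional per-stratum overrides.

    Override keys are either an age group (``adults_19_59``) or an
    ``age_group/sex`` pair (``adults_19_59/female``).
    """

    default: ReferenceTable = field(default_factory=ReferenceTable)
    overrides: Mapping[str, ReferenceTable] = field(default_factory=dict)

    def for_stratum(self, age_group: str | None = None, sex: str | None = None) -> ReferenceTable:
        if age_group and sex and f"{age_group}/{sex}" in self.overrides:
            return self.overrides[f"{age_group}/{sex}"]
        if age_group and age_group in self.overrides:
            return self.overrides[age_group]
        return self.default
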