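"""Synthetic meal-coded 24-h recall survey generator.

Emulates the structure of a two-day non-consecutive recall survey with
four analysis age groups: every individual contributes day 1, a random
half contribute a second day, meal code 1 is breakfast, and a small
configurable fraction of individuals are breakfast skippers (breakfast
energy below 50 kcal on every recalled day).

Portion model. For food *f* at meal *m* on day *d* of person *i*,

    grams = exp(mu_{f,m} + shift_{age} + b_i + w_{id} + eps)

with a person-level effect ``b_i ~ N(0, person_effect_sd^2)`` shared
across the person's days, a day-level effect ``w_id ~ N(0,
day_effect_sd^2)``, and per-line noise ``eps ~ N(0, portion_noise_sd^2)``.
Breakfast food selection is a person-level *habit* (a Bernoulli draw per
person per food, eaten on every recalled day); lunch, dinner and snack
selection is re-drawn per day. Habitual breakfasts keep the day-to-day
variance of log breakfast energy close to ``day_effect_sd^2`` so the
usual-intake variance decomposition can recover both components; the
compositional variance of who habitually eats what loads on the
between-person component instead.

Skippers are simulated by thinning breakfast rather than deleting the
meal: 30% of skippers record no breakfast lines at all, the rest keep
their single lowest-energy breakfast line rescaled below 50 kcal — so
the energy rule itself, not mere missingness, drives classification.
Conversely the rare consumer day drawn under 50 kcal (~0.1%) is rescaled
to a 55–120 kcal floor so the generator's truth labels are exact.

Sampling weights are drawn from a shifted gamma (0.4 + Gamma(6, 0.1))
and rescaled to mean 1: enough variability to exercise weighted
estimators without claiming to reproduce any real survey design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .vocab import (
    AGE_GROUP_BOUNDS,
    AGE_GROUPS,
    BREAKFAST_MEAL_CODE,
    EDUCATION_LEVELS,
    NUTRIENT_COLUMNS,
    SEXES,
    URBANITY,
    WEALTH_QUINTILES,
)

SKIPPER_ENERGY_CEILING_KCAL = 50.0


@dataclass(frozen=True)
class FoodSpec:
    """One menu food: per-100-g nutrients and per-meal portion parameters.

    ``meals`` maps meal code -> (selection probability, mu of log grams).
    """

    food_code: str
    food_group: str
    nutrients: Mapping[str, float]
    meals: Mapping[int, tuple[float, float]]

    @property
    def energy_per_100g(self) -> float:
        return float(self.nutrients.get("energy_kcal", 0.0))


def _log(g: float) -> float:
    return math.log(g)


#: Built-in menu mirroring the food groups most commonly seen at a
#: Philippine breakfast table (rice, coffee + sugar, egg, dried/fresh
#: fish, bread, vegetables, milk, chocolate drinks, meat, fruit).
#: Nutrients are plausible per-100-g amounts for the named foods; this
#: is a synthetic fixture, not an excerpt of any food-composition table.
DEFAULT_MENU: tuple[FoodSpec, ...] = (
    FoodSpec("F001", "RICE", {
        "energy_kcal": 130, "protein_g": 2.7, "carbohydrate_g": 28.2,
        "fiber_g": 0.4, "total_sugar_g": 0.1, "total_fat_g": 0.3,
        "saturated_fat_g": 0.1, "sodium_mg": 1, "potassium_mg": 35,
        "calcium_mg": 10, "iron_mg": 0.2, "magnesium_mg": 12,
        "phosphorus_mg": 43, "thiamin_mg": 0.02, "riboflavin_mg": 0.01,
        "niacin_mg": 0.4,
    }, {1: (1.0, _log(180)), 2: (1.0, _log(210)), 3: (1.0, _log(200))}),
    FoodSpec("F002", "CHICKEN EGG", {
        "energy_kcal": 155, "protein_g": 12.6, "total_fat_g": 10.6,
        "saturated_fat_g": 3.3, "mufa_g": 4.1, "pufa_g": 1.4,
        "cholesterol_mg": 373, "vitamin_a_re_ug": 160, "vitamin_d_ug": 2.2,
        "calcium_mg": 50, "iron_mg": 1.2, "sodium_mg": 124,
        "potassium_mg": 126, "magnesium_mg": 10, "phosphorus_mg": 172,
        "riboflavin_mg": 0.5, "total_sugar_g": 1.1,
    }, {1: (0.55, _log(50)), 3: (0.15, _log(50))}),
    FoodSpec("F003", "COFFEE", {
        "energy_kcal": 2, "potassium_mg": 49, "magnesium_mg": 3,
        "niacin_mg": 0.2, "sodium_mg": 2,
    }, {1: (0.75, _log(150)), 4: (0.3, _log(150))}),
    FoodSpec("F004", "SUGARS", {
        "energy_kcal": 387, "total_sugar_g": 100, "carbohydrate_g": 100,
    }, {1: (0.7, _log(8)), 4: (0.4, _log(10))}),
    FoodSpec("F005", "COOKING OIL", {
        "energy_kcal": 884, "total_fat_g": 100, "saturated_fat_g": 82,
        "mufa_g": 6, "pufa_g": 2,
    }, {1: (0.5, _log(4)), 2: (0.8, _log(6)), 3: (0.8, _log(6))}),
    FoodSpec("F006", "FRESH FISH", {
        "energy_kcal": 123, "protein_g": 20.5, "total_fat_g": 4.5,
        "saturated_fat_g": 1.2, "mufa_g": 1.7, "pufa_g": 1.1,
        "cholesterol_mg": 52, "calcium_mg": 51, "iron_mg": 0.7,
        "sodium_mg": 72, "potassium_mg": 292, "magnesium_mg": 30,
        "phosphorus_mg": 162, "niacin_mg": 5.6, "vitamin_d_ug": 4.1,
    }, {1: (0.3, _log(40)), 2: (0.6, _log(60)), 3: (0.55, _log(60))}),
    FoodSpec("F007", "GREEN LEAFY VEGETABLES", {
        "energy_kcal": 19, "protein_g": 2.6, "fiber_g": 2.1,
        "vitamin_a_re_ug": 315, "vitamin_c_mg": 16, "calcium_mg": 77,
        "iron_mg": 1.7, "potassium_mg": 312, "magnesium_mg": 71,
        "sodium_mg": 113, "carbohydrate_g": 3.1,
    }, {1: (0.15, _log(30)), 2: (0.45, _log(45)), 3: (0.45, _log(45))}),
    FoodSpec("F008", "OTHER VEGETABLES", {
        "energy_kcal": 34, "fiber_g": 1.2, "vitamin_a_re_ug": 57,
        "vitamin_c_mg": 9, "potassium_mg": 230, "magnesium_mg": 14,
        "calcium_mg": 24, "iron_mg": 0.6, "carbohydrate_g": 7.7,
        "total_sugar_g": 2.8,
    }, {1: (0.18, _log(40)), 2: (0.5, _log(55)), 3: (0.5, _log(55))}),
    FoodSpec("F009", "OTHER CEREAL PRODUCTS", {
        "energy_kcal": 310, "protein_g": 8.5, "carbohydrate_g": 57,
        "fiber_g": 2.4, "total_sugar_g": 6, "total_fat_g": 5,
        "saturated_fat_g": 1.7, "sodium_mg": 430, "calcium_mg": 35,
        "iron_mg": 2.6, "thiamin_mg": 0.35, "riboflavin_mg": 0.2,
        "niacin_mg": 3.5, "magnesium_mg": 22, "potassium_mg": 110,
        "phosphorus_mg": 90,
    }, {1: (0.3, _log(20)), 4: (0.5, _log(50)), 5: (0.35, _log(40))}),
    FoodSpec("F010", "POWDERED MILK", {
        "energy_kcal": 496, "protein_g": 26, "total_fat_g": 26,
        "saturated_fat_g": 16, "total_sugar_g": 38, "carbohydrate_g": 38,
        "calcium_mg": 912, "vitamin_a_re_ug": 257, "vitamin_d_ug": 7.5,
        "potassium_mg": 1330, "magnesium_mg": 85, "sodium_mg": 371,
        "riboflavin_mg": 1.2, "phosphorus_mg": 776, "iron_mg": 0.5,
    }, {1: (0.15, _log(10)), 4: (0.2, _log(15))}),
    FoodSpec("F011", "CACAO AND CHOCOLATE BASED BEVERAGES", {
        "energy_kcal": 390, "total_sugar_g": 65, "carbohydrate_g": 80,
        "total_fat_g": 4, "saturated_fat_g": 2.4, "calcium_mg": 130,
        "iron_mg": 4, "potassium_mg": 460, "magnesium_mg": 50,
        "sodium_mg": 140,
    }, {1: (0.12, _log(15)), 4: (0.25, _log(18))}),
    FoodSpec("F012", "FRESH MEAT", {
        "energy_kcal": 247, "protein_g": 16.9, "total_fat_g": 19.6,
        "saturated_fat_g": 7, "mufa_g": 8.8, "pufa_g": 2.1,
        "cholesterol_mg": 71, "sodium_mg": 57, "potassium_mg": 302,
        "magnesium_mg": 19, "iron_mg": 0.9, "phosphorus_mg": 181,
        "niacin_mg": 4.4, "thiamin_mg": 0.6,
    }, {1: (0.08, _log(40)), 2: (0.5, _log(65)), 3: (0.55, _log(65))}),
    FoodSpec("F013", "FRUITS", {
        "energy_kcal": 89, "carbohydrate_g": 22.8, "total_sugar_g": 12.2,
        "fiber_g": 2.6, "vitamin_c_mg": 8.7, "potassium_mg": 358,
        "magnesium_mg": 27, "vitamin_a_re_ug": 3,
    }, {1: (0.06, _log(60)), 4: (0.3, _log(80)), 5: (0.2, _log(80))}),
)

#: Log-scale portion shift per age group (children eat less, adults more).
DEFAULT_AGE_SHIFT = {
    "children_6_12": -0.35,
    "adolescents_13_18": 0.05,
    "adults_19_59": 0.10,
    "elderly_60_plus": -0.10,
}

#: Skipping is rarer among the young (~2%) than among adults (~4%).
DEFAULT_SKIPPER_PROBABILITY = {
    "children_6_12": 0.02,
    "adolescents_13_18": 0.02,
    "adults_19_59": 0.04,
    "elderly_60_plus": 0.04,
}


@dataclass
class SimulationConfig:
    n_individuals: Mapping[str, int] = field(
        default_factory=lambda: {g: 2000 for g in AGE_GROUPS}
    )
    skipper_probability: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SKIPPER_PROBABILITY)
    )
    day2_fraction: float = 0.5
    person_effect_sd: float = 0.4
    day_effect_sd: float = 0.3
    portion_noise_sd: float = 0.1
    seed: int | None = None
    food_menu: tuple[FoodSpec, ...] = DEFAULT_MENU
    age_shift: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_SHIFT)
    )
    no_breakfast_fraction_of_skippers: float = 0.3

    def validate(self) -> None:
        for g, n in self.n_individuals.items():
            if g not in AGE_GROUPS:
                raise ConfigError(f"unknown age group {g!r}")
            if n < 1:
                raise ConfigError(f"n_individuals[{g}] must be positive")
        probs = list(self.skipper_probability.values()) + [
            self.day2_fraction,
            self.no_breakfast_fraction_of_skippers,
        ]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        for sd in (self.person_effect_sd, self.day_effect_sd, self.portion_noise_sd):
            if not sd > 0:
                raise ConfigError("effect SDs must be > 0")
        if not self.food_menu:
            raise ConfigError("food menu must be non-empty")
        groups = {f.food_group for f in self.food_menu}
        if len(groups) < 10:
            raise ConfigError(
                f"food menu must cover >= 10 food groups, covers {len(groups)}"
            )


def menu_to_fct(menu=DEFAULT_MENU) -> pd.DataFrame:
    """Food-composition table (per 100 g) for a menu."""
    rows = []
    for food in menu:
        row = {"food_code": food.food_code, "food_group": food.food_group}
        for col in NUTRIENT_COLUMNS:
            row[col] = float(food.nutrients.get(col, 0.0))
        rows.append(row)
    return pd.DataFrame(rows)


def _draw_individuals(config: SimulationConfig, rng) -> pd.DataFrame:
    frames = []
    offset = 0
    for group in AGE_GROUPS:
        n = int(config.n_individuals.get(group, 0))
        if n == 0:
            continue
        lo, hi = AGE_GROUP_BOUNDS[group]
        ids = [f"P{offset + i + 1:06d}" for i in range(n)]
        offset += n
        adultish = group in ("adults_19_59", "elderly_60_plus")
        frames.append(pd.DataFrame({
            "id": ids,
            "age_years": rng.integers(lo, hi + 1, n),
            "age_group": group,
            "sex": rng.choice(SEXES, n),
            "urbanity": rng.choice(URBANITY, n, p=[0.67, 0.33]),
            "wealth_quintile": rng.choice(WEALTH_QUINTILES, n),
            "education": rng.choice(EDUCATION_LEVELS, n, p=[0.45, 0.35, 0.15, 0.05])
            if adultish else None,
            "nutrition_status": rng.choice(
                ["underweight", "normal", "overweight", "obese"],
                n, p=[0.15, 0.6, 0.18, 0.07],
            ),
        }))
    individuals = pd.concat(frames, ignore_index=True)
    w = 0.4 + rng.gamma(shape=6.0, scale=0.1, size=len(individuals))
    individuals["sampling_weight"] = w / w.mean()
    return individuals


def simulate(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (individuals, recalls, truth) for a configured survey.

    The truth record stores the generator parameters and, per
    individual, the skipper flag, person effect and day-2 availability —
    everything a downstream recovery test needs.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config.seed = seed
    config.validate()
    rng = np.random.default_rng(config.seed)

    individuals = _draw_individuals(config, rng)
    n = len(individuals)
    age_group = individuals["age_group"].to_numpy()
    b = rng.normal(0.0, config.person_effect_sd, n)
    has_day2 = rng.random(n) < config.day2_fraction
    p_skip = np.array([config.skipper_probability.get(g, 0.0) for g in age_group])
    skipper = rng.random(n) < p_skip
    no_breakfast = skipper & (rng.random(n) < config.no_breakfast_fraction_of_skippers)
    shift = np.array([config.age_shift.get(g, 0.0) for g in age_group])

    # person-day grid: day 1 for everyone, day 2 for the replicated half
    person_idx = np.concatenate([np.arange(n), np.flatnonzero(has_day2)])
    day_index = np.concatenate([np.ones(n, int), np.full(int(has_day2.sum()), 2)])
    w_day = rng.normal(0.0, config.day_effect_sd, len(person_idx))
    n_pd = len(person_idx)

    # breakfast habits: one Bernoulli per person per food, stable across days
    habit = {}
    for food in config.food_menu:
        if BREAKFAST_MEAL_CODE in food.meals:
            p, _ = food.meals[BREAKFAST_MEAL_CODE]
            habit[food.food_code] = rng.random(n) < p

    chunks = []
    for food in config.food_menu:
        for meal, (p, mu) in sorted(food.meals.items()):
            if meal == BREAKFAST_MEAL_CODE:
                present = habit[food.food_code][person_idx]
            else:
                present = rng.random(n_pd) < p
            idx = np.flatnonzero(present)
            if idx.size == 0:
                continue
            eps = rng.normal(0.0, config.portion_noise_sd, idx.size)
            grams = np.exp(
                mu
                + shift[person_idx[idx]]
                + b[person_idx[idx]]
                + w_day[idx]
                + eps
            )
            chunks.append(pd.DataFrame({
                "individual_id": individuals["id"].to_numpy()[person_idx[idx]],
                "day_index": day_index[idx],
                "meal_code": meal,
                "food_code": food.food_code,
                "grams": grams,
                "_pd": idx,
            }))
    recalls = pd.concat(chunks, ignore_index=True)

    # enforce the energy-based ground truth for skippers and consumers
    energy_per_g = {
        f.food_code: f.energy_per_100g / 100.0 for f in config.food_menu
    }
    is_bf = recalls["meal_code"].to_numpy() == BREAKFAST_MEAL_CODE
    line_energy = recalls["grams"].to_numpy() * recalls["food_code"].map(
        energy_per_g
    ).to_numpy()
    skip_by_pd = skipper[person_idx]
    nobf_by_pd = no_breakfast[person_idx]
    bf = pd.DataFrame({
        "_pd": recalls.loc[is_bf, "_pd"].to_numpy(),
        "row": np.flatnonzero(is_bf),
        "energy": line_energy[is_bf],
    })
    totals = bf.groupby("_pd")["energy"].sum()
    pd_ids = totals.index.to_numpy()
    tot = totals.to_numpy()
    low = pd_ids[(tot > 0) & (tot < SKIPPER_ENERGY_CEILING_KCAL) & ~skip_by_pd[pd_ids]]
    affected = set(pd_ids[skip_by_pd[pd_ids]]) | set(low)
    drop_rows: list[np.ndarray] = []
    scale = np.ones(len(recalls))
    for pd_key, sub in bf[bf["_pd"].isin(affected)].groupby("_pd"):
        pdi = int(pd_key)
        total = sub["energy"].sum()
        if skip_by_pd[pdi]:
            if nobf_by_pd[pdi]:
                drop_rows.append(sub["row"].to_numpy())
            else:
                keep = sub["energy"].idxmin()
                drop_rows.append(sub.drop(index=keep)["row"].to_numpy())
                kept_energy = sub.loc[keep, "energy"]
                target = rng.uniform(5.0, 45.0)
                if kept_energy > 0:
                    scale[sub.loc[keep, "row"]] = target / kept_energy
        elif total < SKIPPER_ENERGY_CEILING_KCAL and total > 0:
            # rare consumer day drawn below the rule: rescale to a floor
            scale[sub["row"].to_numpy()] = rng.uniform(55.0, 120.0) / total
    recalls["grams"] = recalls["grams"].to_numpy() * scale
    if drop_rows:
        recalls = recalls.drop(index=np.concatenate(drop_rows))
    recalls = (
        recalls.drop(columns="_pd")
        .sort_values(["individual_id", "day_index", "meal_code", "food_code"],
                     kind="mergesort")
        .reset_index(drop=True)
    )

    truth = {
        "person_effect_sd": config.person_effect_sd,
        "day_effect_sd": config.day_effect_sd,
        "portion_noise_sd": config.portion_noise_sd,
        "day2_fraction": config.day2_fraction,
        "skipper_probability": dict(config.skipper_probability),
        "seed": config.seed,
        "individuals": {
            "id": individuals["id"].tolist(),
            "age_group": individuals["age_group"].tolist(),
            "skipper": skipper.tolist(),
            "no_breakfast": no_breakfast.tolist(),
            "person_effect": b.tolist(),
            "has_day2": has_day2.tolist(),
        },
    }
    return individuals, recalls, truth
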