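"""Controlled vocabulary for nutrients and covariates.

Nutrient names carry their unit as a suffix (``_g``, ``_mg``, ``_ug``,
``_kcal``) so that amounts from different tables cannot be mixed across
units silently. Vitamin A is expressed in retinol equivalents (RE, µg).
"""

from __future__ import annotations

ENERGY = "energy_kcal"

#: The nine qualifying nutrients of the NRF9.3 nutrient-density score.
QUALIFYING_NUTRIENTS = (
    "protein_g",
    "fiber_g",
    "vitamin_a_re_ug",
    "vitamin_c_mg",
    "vitamin_d_ug",
    "calcium_mg",
    "iron_mg",
    "potassium_mg",
    "magnesium_mg",
)

#: The three limiting nutrients. Total sugar stands in for added sugar,
#: which 24-h recall surveys typically do not code.
LIMITING_NUTRIENTS = (
    "total_sugar_g",
    "saturated_fat_g",
    "sodium_mg",
)

SCORED_NUTRIENTS = QUALIFYING_NUTRIENTS + LIMITING_NUTRIENTS

#: Auxiliary nutrients reported in descriptive tables but not scored.
AUXILIARY_NUTRIENTS = (
    "total_fat_g",
    "mufa_g",
    "pufa_g",
    "carbohydrate_g",
    "thiamin_mg",
    "riboflavin_mg",
    "niacin_mg",
    "phosphorus_mg",
    "cholesterol_mg",
)

NUTRIENT_COLUMNS = (ENERGY,) + SCORED_NUTRIENTS + AUXILIARY_NUTRIENTS

#: Micronutrients subject to implausible-intake outlier substitution.
MICRONUTRIENTS = (
    "vitamin_a_re_ug",
    "vitamin_c_mg",
    "vitamin_d_ug",
    "calcium_mg",
    "iron_mg",
    "potassium_mg",
    "magnesium_mg",
    "thiamin_mg",
    "riboflavin_mg",
    "niacin_mg",
    "phosphorus_mg",
)

AGE_GROUPS = (
    "children_6_12",
    "adolescents_13_18",
    "adults_19_59",
    "elderly_60_plus",
)

AGE_GROUP_BOUNDS = {
    "children_6_12": (6, 12),
    "adolescents_13_18": (13, 18),
    "adults_19_59": (19, 59),
    "elderly_60_plus": (60, 95),
}

SEXES = ("male", "female")
URBANITY = ("rural", "urban")
WEALTH_QUINTILES = ("poorest", "poor", "middle", "rich", "richest")
EDUCATION_LEVELS = ("elementary", "high_school", "college", "vocational")

BREAKFAST_MEAL_CODE = 1
MEAL_CODES = (1, 2, 3, 4, 5)

TERTILE_LABELS = ("T1", "T2", "T3")

RECALL_COLUMNS = ("individual_id", "day_index", "meal_code", "food_code", "grams")
INDIVIDUAL_COLUMNS = (
    "id",
    "age_years",
    "age_group",
    "sex",
    "urbanity",
    "wealth_quintile",
    "education",
    "nutrition_status",
    "sampling_weight",
)
FCT_KEY_COLUMNS = ("food_code", "food_group")


def age_group_of(age_years: float) -> str:
    """Map an age in years onto the survey's four analysis age groups."""
    for group, (lo, hi) in AGE_GROUP_BOUNDS.items():
        if lo <= age_years <= hi:
            return group
    if age_years > 60:
        return "elderly_60_plus"
    raise ValueError(f"age {age_years} is outside the surveyed range (6+)")
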