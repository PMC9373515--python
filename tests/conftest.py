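import numpy as np
import pandas as pd
import pytest

from nrfbreakfast import ReferenceTable, SimulationConfig, menu_to_fct, simulate
from nrfbreakfast.vocab import AGE_GROUPS, NUTRIENT_COLUMNS


@pytest.fixture
def reference():
    return ReferenceTable.default()


@pytest.fixture
def tiny_fct():
    """Three simple foods with round per-100-g numbers for hand checks."""
    rows = [
        {"food_code": "A", "food_group": "RICE", "energy_kcal": 100.0,
         "protein_g": 10.0, "total_sugar_g": 2.0},
        {"food_code": "B", "food_group": "CHICKEN EGG", "energy_kcal": 150.0,
         "protein_g": 12.0, "calcium_mg": 50.0},
        {"food_code": "C", "food_group": "COFFEE", "energy_kcal": 2.0,
         "potassium_mg": 50.0},
    ]
    df = pd.DataFrame(rows)
    for col in NUTRIENT_COLUMNS:
        if col not in df.columns:
            df[col] = 0.0
    return df.fillna(0.0)


def make_recalls(rows):
    """Rows: (individual_id, day_index, meal_code, food_code, grams)."""
    return pd.DataFrame(
        rows,
        columns=["individual_id", "day_index", "meal_code", "food_code", "grams"],
    )


@pytest.fixture
def energy_only_fct():
    """One food that is pure energy: 100 kcal per 100 g, nothing else."""
    df = pd.DataFrame(
        [{"food_code": "E", "food_group": "RICE", "energy_kcal": 100.0}]
    )
    for col in NUTRIENT_COLUMNS:
        if col not in df.columns:
            df[col] = 0.0
    return df


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated survey shared across tests (deterministic)."""
    config = SimulationConfig(
        n_individuals={g: 150 for g in AGE_GROUPS}, seed=42
    )
    individuals, recalls, truth = simulate(config)
    return individuals, recalls, menu_to_fct(config.food_menu), truth


def random_intakes(rng, n):
    """Random positive nutrient vectors with positive energy."""
    df = pd.DataFrame(
        rng.uniform(0.0, 1.0, size=(n, len(NUTRIENT_COLUMNS))),
        columns=list(NUTRIENT_COLUMNS),
    )
    scales = {
        "energy_kcal": 2500.0, "protein_g": 120.0, "fiber_g": 60.0,
        "vitamin_a_re_ug": 4000.0, "vitamin_c_mg": 200.0, "vitamin_d_ug": 30.0,
        "calcium_mg": 2500.0, "iron_mg": 50.0, "potassium_mg": 8000.0,
        "magnesium_mg": 1000.0, "total_sugar_g": 150.0,
        "saturated_fat_g": 60.0, "sodium_mg": 6000.0,
    }
    for col, s in scales.items():
        df[col] *= s
    df["energy_kcal"] += 50.0  # keep energy strictly positive
    return df
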