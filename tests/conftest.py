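import numpy as np
import pytest

from plantshift.food_composition import (
    AminoAcidVector,
    DigestibilityTable,
    FoodDatabase,
    FoodItem,
    ReferencePattern,
    who_2007_pattern,
)
from plantshift.synthetic_data import GeneratorConfig, generate_bundle


def make_profile(per_g_ratios: dict[str, float], protein_g_per_100g: float,
                 pattern: ReferencePattern) -> AminoAcidVector:
    """Build an AA profile whose mg-per-g-protein ratios vs the pattern are given.

    Unlisted IAAs default to ratio 1.2 (comfortably non-limiting); the
    dispensable remainder tops the profile up to the requested protein mass.
    """
    from plantshift.food_composition import IAA_KEYS

    per_g = {k: per_g_ratios.get(k, 1.2) * pattern[k] for k in IAA_KEYS}
    iaa_sum = sum(per_g.values())
    assert iaa_sum < 1000.0
    return AminoAcidVector(
        **{f"{k}_mg": per_g[k] * protein_g_per_100g for k in IAA_KEYS},
        dispensable_aa_mg=(1000.0 - iaa_sum) * protein_g_per_100g,
    )


@pytest.fixture(scope="session")
def pattern() -> ReferencePattern:
    return who_2007_pattern()


@pytest.fixture(scope="session")
def small_db(pattern) -> FoodDatabase:
    """A hand-built 8-item database covering all scenario-relevant classes."""
    items = [
        FoodItem("beef", "beef steak", "meat",
                 make_profile({"lys": 1.3}, 21.0, pattern),
                 frozenset({"meat"}), 1.0, kcal_per_100g=200.0),
        FoodItem("cod", "cod fillet", "fish",
                 make_profile({"lys": 1.25}, 18.0, pattern),
                 frozenset({"fish"}), 1.0, kcal_per_100g=105.0),
        FoodItem("milk", "semi-skimmed milk", "dairy",
                 make_profile({"lys": 1.35}, 3.5, pattern),
                 frozenset({"dairy"}), 1.0, kcal_per_100g=47.0),
        FoodItem("gouda", "Gouda cheese 48+", "cheese",
                 make_profile({"lys": 1.3}, 24.0, pattern),
                 frozenset({"cheese"}), 1.0,
                 label_protein_g_per_100g=22.9, kcal_per_100g=369.0),
        FoodItem("bread", "wholemeal bread", "cereal",
                 make_profile({"lys": 0.6}, 10.0, pattern),
                 frozenset(), 0.0, kcal_per_100g=235.0),
        FoodItem("lentils", "boiled lentils", "legume",
                 make_profile({"lys": 1.35, "saa": 0.8}, 8.0, pattern),
                 frozenset(), 0.0, kcal_per_100g=110.0),
        FoodItem("burger", "plant burger", "meat_substitute",
                 make_profile({"lys": 0.85}, 14.0, pattern),
                 frozenset(), 0.0, kcal_per_100g=220.0),
        FoodItem("cake", "sponge cake", "sweet",
                 make_profile({"lys": 0.7}, 5.0, pattern),
                 frozenset({"minor_animal_content"}), 0.1, kcal_per_100g=400.0),
    ]
    digestibility = DigestibilityTable({
        "meat": 0.93, "fish": 0.92, "dairy": 0.95, "cheese": 0.94,
        "cereal": 0.82, "legume": 0.78, "meat_substitute": 0.80, "sweet": 0.85,
    })
    return FoodDatabase(items, digestibility)


@pytest.fixture(scope="session")
def bundle500():
    """One synthetic survey of 500 participants shared across the suite."""
    return generate_bundle(GeneratorConfig(n_participants=500, seed=42))


@pytest.fixture(scope="session")
def bundle2000():
    """Large synthetic survey for calibration and recovery checks."""
    return generate_bundle(GeneratorConfig(n_participants=2000, seed=123))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
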