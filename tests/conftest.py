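import numpy as np
import pandas as pd
import pytest

from plantshift import (
    GeneratorConfig,
    generate_food_table,
    generate_recalls,
    load_reference_pattern,
)
from plantshift.aminoacids import IAA_SET, AminoAcidProfile
from plantshift.composition import FoodItem, FoodTable


@pytest.fixture(scope="session")
def ref():
    return load_reference_pattern()


@pytest.fixture(scope="session")
def small_cfg():
    return GeneratorConfig(n_participants=40, seed=11)


@pytest.fixture(scope="session")
def catalog(small_cfg):
    """(foods, replacement tables) from the synthetic catalogue."""
    return generate_food_table(small_cfg)


@pytest.fixture(scope="session")
def small_study(small_cfg, catalog):
    foods, tables = catalog
    return generate_recalls(small_cfg, foods), foods, tables


def make_item(
    item_id="x",
    group="g",
    protein_g=10.0,
    density=None,
    digestibility=0.9,
    plant_fraction=1.0,
    kcal=100.0,
    conformity=None,
):
    """Hand-built food item; density is mg IAA per g protein."""
    density = density or {k: 50.0 for k in IAA_SET}
    return FoodItem(
        item_id=item_id,
        name=item_id,
        group=group,
        profile=AminoAcidProfile.from_density(density, protein_g),
        digestibility=digestibility,
        plant_fraction=plant_fraction,
        kcal_per_100g=kcal,
        conformity=conformity
        or {"pescetarian": True, "vegetarian": True, "vegan": True},
    )


@pytest.fixture
def make_food_item():
    return make_item


def naive_meal_score(events, items, ref):
    """Independent loop-based re-implementation of per-meal scoring.

    ``events``: list of (grams, item_id); ``items``: dict id -> FoodItem.
    Returns (total_g, digestible_g, similarity, utilizable_g).
    """
    total_g = 0.0
    digestible_g = 0.0
    dig_iaa = {k: 0.0 for k in IAA_SET}
    for grams, item_id in events:
        item = items[item_id]
        protein_g = grams / 100.0 * item.profile.total_aa_mg / 1000.0
        total_g += protein_g
        digestible_g += protein_g * item.digestibility
        for k in IAA_SET:
            dig_iaa[k] += grams / 100.0 * item.profile.values[k] * item.digestibility
    if digestible_g == 0:
        return total_g, digestible_g, 1.0, 0.0
    similarity = 1.0
    worst = None
    for k in IAA_SET:
        ratio = (dig_iaa[k] / digestible_g) / ref.values[k]
        if worst is None or ratio < worst:
            worst = ratio
    if worst < 1.0:
        similarity = worst
    return total_g, digestible_g, similarity, similarity * digestible_g
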