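import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plantshift import (
    daily_summaries,
    event_protein,
    meal_similarity,
    meal_summaries,
    meal_summary,
    plant_protein_share,
)
from plantshift.aminoacids import IAA_SET
from plantshift.composition import FoodTable
from plantshift.errors import ValidationError
from plantshift.recalls import ConsumptionEvent, MealOccasion, RecallDataset
from conftest import make_item, naive_meal_score


def _meal(*events):
    return MealOccasion(occasion="lunch", events=tuple(
        ConsumptionEvent(f"e{i}", iid, g) for i, (g, iid) in enumerate(events)
    ))


def test_event_protein_published_egg(catalog):
    """100 g of an item with 12.3 g amino acids per 100 g is 12.3 g protein."""
    foods, _ = catalog
    total, dig, vec = event_protein(ConsumptionEvent("e", "chicken_egg", 100.0),
                                    foods["chicken_egg"])
    assert total == pytest.approx(12.3)
    assert dig == pytest.approx(12.3 * foods["chicken_egg"].digestibility)


def test_event_protein_zero_grams(catalog):
    foods, _ = catalog
    total, dig, vec = event_protein(ConsumptionEvent("e", "chicken_egg", 0.0),
                                    foods["chicken_egg"])
    assert total == 0 and dig == 0 and (vec == 0).all()


def test_event_protein_hand_arithmetic():
    """200 g at digestibility 0.9 with 500 mg lysine/100 g -> 900 mg digestible."""
    density = {k: 50.0 for k in IAA_SET}
    item = make_item(protein_g=10.0, digestibility=0.9)
    # override lysine to 500 mg per 100 g = 50 mg/g * 10 g protein (already)
    _, _, vec = event_protein(ConsumptionEvent("e", "x", 200.0), item)
    lys = vec[IAA_SET.index("lys")]
    assert lys == pytest.approx(2 * 500 * 0.9)


def test_similarity_at_reference_is_capped(ref):
    vec = ref.as_array() * 10.0  # densities exactly the reference, 10 g protein
    sim, limiting = meal_similarity(vec, 10.0, ref)
    assert sim == 1.0 and limiting is None


def test_similarity_lysine_half(ref):
    vec = ref.as_array() * 2.0 * 10.0  # all ratios 2
    vec[IAA_SET.index("lys")] = ref.values["lys"] * 0.5 * 10.0
    sim, limiting = meal_similarity(vec, 10.0, ref)
    assert sim == pytest.approx(0.5)
    assert limiting == "lys"


def test_similarity_empty_meal(ref):
    sim, limiting = meal_similarity(np.zeros(9), 0.0, ref)
    assert sim == 1.0 and limiting is None
    s = meal_summary(_meal(), FoodTable([]), ref)
    assert s.utilizable_g == 0.0 and s.similarity == 1.0


def test_similarity_rejects_negative(ref):
    with pytest.raises(ValidationError):
        meal_similarity(np.full(9, -1.0), 1.0, ref)


def test_meal_singleton_equals_event(catalog, ref):
    foods, _ = catalog
    s = meal_summary(_meal((120.0, "beef_steak")), foods, ref)
    total, dig, vec = event_protein(
        ConsumptionEvent("e", "beef_steak", 120.0), foods["beef_steak"]
    )
    sim, _ = meal_similarity(vec, dig, ref)
    assert s.total_g == pytest.approx(total)
    assert s.utilizable_g == pytest.approx(sim * dig)


def test_pooling_credits_complementation(ref):
    """Lysine-poor cereal + lysine-rich legume pooled beat separate scoring."""
    cereal = make_item(
        item_id="cereal",
        density={"his": 22, "ile": 36, "leu": 68, "lys": 26, "saa": 39,
                 "aaa": 77, "thr": 29, "trp": 11, "val": 44},
    )
    legume = make_item(
        item_id="legume",
        density={"his": 27, "ile": 43, "leu": 72, "lys": 70, "saa": 30,
                 "aaa": 80, "thr": 36, "trp": 9, "val": 47},
    )
    foods = FoodTable([cereal, legume])
    pooled = meal_summary(_meal((100.0, "cereal"), (100.0, "legume")), foods, ref)
    alone_c = meal_summary(_meal((100.0, "cereal")), foods, ref)
    alone_l = meal_summary(_meal((100.0, "legume")), foods, ref)
    grams_weighted = (alone_c.similarity + alone_l.similarity) / 2
    assert pooled.similarity > grams_weighted
    assert pooled.utilizable_g >= alone_c.utilizable_g + alone_l.utilizable_g


def test_split_events_equal_one_event(catalog, ref):
    foods, _ = catalog
    split = meal_summary(_meal((50.0, "gouda_48"), (50.0, "gouda_48")), foods, ref)
    whole = meal_summary(_meal((100.0, "gouda_48")), foods, ref)
    assert split.total_g == pytest.approx(whole.total_g)
    assert split.similarity == pytest.approx(whole.similarity)
    assert split.utilizable_g == pytest.approx(whole.utilizable_g)


def test_daily_additivity_and_per_kg(catalog, ref):
    foods, _ = catalog
    parts = pd.DataFrame(
        [["a", "male", 70, 75.0, 178.0, "high", 1.0]],
        columns=["pid", "sex", "age_years", "weight_kg", "height_cm",
                 "education", "survey_weight"],
    )
    events = pd.DataFrame(
        [["a", 1, occ, f"e{i}", "gouda_48", g]
         for i, (occ, g) in enumerate(
             [("breakfast", 50.0), ("lunch", 100.0), ("dinner", 150.0)])],
        columns=["pid", "day_index", "occasion", "event_id", "item_id", "grams"],
    )
    ds = RecallDataset(parts, events)
    meals = meal_summaries(ds, foods, ref)
    day = daily_summaries(ds, foods, ref)
    assert day.loc[0, "utilizable_g"] == pytest.approx(meals["utilizable_g"].sum())
    assert day.loc[0, "utilizable_g_per_kg"] == pytest.approx(
        day.loc[0, "utilizable_g"] / 75.0
    )
    # permuting event order leaves the result unchanged
    ds2 = RecallDataset(parts, events.iloc[::-1])
    day2 = daily_summaries(ds2, foods, ref)
    assert day2.loc[0, "utilizable_g"] == pytest.approx(day.loc[0, "utilizable_g"])


def test_plant_share_symmetry(ref):
    animal = make_item(item_id="an", plant_fraction=0.0)
    plant = make_item(item_id="pl", plant_fraction=1.0)
    foods = FoodTable([animal, plant])
    parts = pd.DataFrame(
        [["a", "male", 70, 75.0, 178.0, "high", 1.0]],
        columns=["pid", "sex", "age_years", "weight_kg", "height_cm",
                 "education", "survey_weight"],
    )
    events = pd.DataFrame(
        [["a", 1, "lunch", "e1", "an", 100.0],
         ["a", 1, "lunch", "e2", "pl", 100.0]],
        columns=["pid", "day_index", "occasion", "event_id", "item_id", "grams"],
    )
    share = plant_protein_share(RecallDataset(parts, events), foods)
    assert share["male"] == pytest.approx(0.5)
    all_plant = events.assign(item_id="pl")
    share2 = plant_protein_share(RecallDataset(parts, all_plant), foods)
    assert share2["male"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# properties

# per-IAA densities capped at 100 mg/g so their sum stays below the
# 1000 mg/g protein mass bound
_density = st.fixed_dictionaries(
    {k: st.floats(5.0, 100.0) for k in IAA_SET}
)
_meal_events = st.lists(
    st.tuples(st.floats(1.0, 400.0), _density,
              st.floats(0.5, 1.0), st.floats(1.0, 40.0)),
    min_size=1, max_size=4,
)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(_meal_events)
def test_ordering_chain_property(ref, events):
    """0 <= utilizable <= digestible <= total for any random meal."""
    items = {}
    evs = []
    for i, (grams, density, dig, protein) in enumerate(events):
        iid = f"i{i}"
        items[iid] = make_item(item_id=iid, density=density, digestibility=dig,
                               protein_g=protein)
        evs.append((grams, iid))
    foods = FoodTable(items.values())
    meal = _meal(*evs)
    s = meal_summary(meal, foods, ref)
    assert 0 <= s.utilizable_g <= s.digestible_g * (1 + 1e-12)
    assert s.digestible_g <= s.total_g * (1 + 1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(_meal_events, st.floats(0.1, 10.0))
def test_scaling_property(ref, events, c):
    """Scaling all grams by c scales masses by c and keeps similarity."""
    items = {}
    evs, evs_scaled = [], []
    for i, (grams, density, dig, protein) in enumerate(events):
        iid = f"i{i}"
        items[iid] = make_item(item_id=iid, density=density, digestibility=dig,
                               protein_g=protein)
        evs.append((grams, iid))
        evs_scaled.append((grams * c, iid))
    foods = FoodTable(items.values())
    a = meal_summary(_meal(*evs), foods, ref)
    b = meal_summary(_meal(*evs_scaled), foods, ref)
    assert b.similarity == pytest.approx(a.similarity, rel=1e-9)
    assert b.total_g == pytest.approx(c * a.total_g, rel=1e-9)
    assert b.utilizable_g == pytest.approx(c * a.utilizable_g, rel=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(_meal_events, _meal_events)
def test_pooling_superadditive_property(ref, events_a, events_b):
    """utilizable(A u B) >= utilizable(A) + utilizable(B)."""
    items = {}
    evs_a, evs_b = [], []
    for tag, events, out in (("a", events_a, evs_a), ("b", events_b, evs_b)):
        for i, (grams, density, dig, protein) in enumerate(events):
            iid = f"{tag}{i}"
            items[iid] = make_item(item_id=iid, density=density,
                                   digestibility=dig, protein_g=protein)
            out.append((grams, iid))
    foods = FoodTable(items.values())
    a = meal_summary(_meal(*evs_a), foods, ref)
    b = meal_summary(_meal(*evs_b), foods, ref)
    ab = meal_summary(_meal(*evs_a, *evs_b), foods, ref)
    assert ab.utilizable_g >= a.utilizable_g + b.utilizable_g - 1e-9


def test_vectorised_matches_naive_oracle(catalog, ref):
    """Frame-based scoring agrees with the loop oracle on random meals."""
    foods, _ = catalog
    rng = np.random.default_rng(42)
    ids = [it.item_id for it in foods if it.profile.total_aa_mg > 0]
    items = {i: foods[i] for i in ids}
    rows, expected = [], []
    for m in range(50):
        chosen = rng.choice(ids, size=rng.integers(1, 4), replace=True)
        evs = [(float(rng.uniform(5, 300)), str(i)) for i in chosen]
        for j, (g, i) in enumerate(evs):
            rows.append(["a", 1 + m % 2, "lunch" if m % 3 else "dinner",
                         f"m{m}e{j}", i, g])
        expected.append(naive_meal_score(evs, items, ref))
    # score meal-by-meal through the object API
    for m, exp in enumerate(expected):
        evs = [(r[5], r[4]) for r in rows if r[3].startswith(f"m{m}e")]
        s = meal_summary(_meal(*evs), foods, ref)
        assert s.similarity == pytest.approx(exp[2], rel=1e-9)
        assert s.utilizable_g == pytest.approx(exp[3], rel=1e-9)
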