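import numpy as np
import pandas as pd
import pytest

from plantshift import apply_scenario, classify_event, replacement_counts
from plantshift.composition import FoodTable, ReplacementTable
from plantshift.errors import CoverageError
from plantshift.recalls import RecallDataset
from plantshift.scenarios import (
    REPLACEMENT_TABLE_FOR,
    SCENARIOS,
    select_flexitarian_events,
)
from conftest import make_item


def _dataset(event_rows, participants=None):
    parts = pd.DataFrame(
        participants
        or [["a", "male", 70, 80.0, 178.0, "high", 1.0],
            ["b", "female", 68, 65.0, 162.0, "low", 1.0]],
        columns=["pid", "sex", "age_years", "weight_kg", "height_cm",
                 "education", "survey_weight"],
    )
    events = pd.DataFrame(
        event_rows,
        columns=["pid", "day_index", "occasion", "event_id", "item_id", "grams"],
    )
    return RecallDataset(parts, events)


def test_classification_rules(catalog):
    foods, _ = catalog
    assert classify_event(foods["salmon"], SCENARIOS["pescetarian"]) == "conforming"
    assert classify_event(foods["salmon"], SCENARIOS["vegetarian"]) == "non_conforming"
    assert classify_event(foods["gouda_48"], SCENARIOS["vegan"]) == "non_conforming"
    assert classify_event(foods["gouda_48"], SCENARIOS["vegetarian"]) == "conforming"
    for item in foods:
        assert classify_event(item, SCENARIOS["original"]) == "conforming"


def test_flexitarian_selection_boundaries(catalog):
    foods, _ = catalog
    rows = [["a", 1, "dinner", f"e{i}", "beef_steak", 100.0] for i in range(10)]
    rows += [["a", 1, "lunch", "bread", "white_bread", 50.0]]
    ds = _dataset(rows)
    assert select_flexitarian_events(ds, foods, 0.0, 1) == set()
    full = select_flexitarian_events(ds, foods, 1.0, 1)
    assert full == {f"e{i}" for i in range(10)}  # bread is not eligible
    assert len(select_flexitarian_events(ds, foods, 0.4, 1)) == 4


def test_vegan_on_plant_dataset_is_fixed_point(catalog):
    foods, tables = catalog
    ds = _dataset([["a", 1, "lunch", "e0", "white_bread", 60.0],
                   ["b", 2, "dinner", "e1", "lentils_boiled", 150.0]])
    out, log = apply_scenario(ds, foods, tables["vegan"], SCENARIOS["vegan"], seed=5)
    assert len(log) == 0
    pd.testing.assert_frame_equal(out.events, ds.events)


def test_forced_single_alternative(catalog, ref):
    foods, _ = catalog
    repl = ReplacementTable("vegan", {"meat_or_fish": ("tofu",)})
    ds = _dataset([["a", 1, "dinner", "e0", "beef_steak", 137.5]])
    out, log = apply_scenario(ds, foods, repl, SCENARIOS["vegan"], seed=0)
    assert out.events.loc[0, "item_id"] == "tofu"
    assert out.events.loc[0, "grams"] == 137.5  # gram-for-gram
    assert len(log) == 1
    assert log.records.loc[0, "old_item"] == "beef_steak"
    # the input dataset is untouched
    assert ds.events.loc[0, "item_id"] == "beef_steak"


def test_apply_is_deterministic_and_mass_conserving(small_study):
    ds, foods, tables = small_study
    spec = SCENARIOS["vegan"]
    out1, log1 = apply_scenario(ds, foods, tables["vegan"], spec, seed=33)
    out2, log2 = apply_scenario(ds, foods, tables["vegan"], spec, seed=33)
    pd.testing.assert_frame_equal(out1.events, out2.events)
    pd.testing.assert_frame_equal(log1.records, log2.records)
    # gram-for-gram: per person-day total grams identical
    g0 = ds.events.groupby(["pid", "day_index"])["grams"].sum()
    g1 = out1.events.groupby(["pid", "day_index"])["grams"].sum()
    pd.testing.assert_series_equal(g0, g1)
    # untouched events are bit-identical
    untouched = ~ds.events["event_id"].isin(log1.records["event_id"])
    pd.testing.assert_frame_equal(
        ds.events[untouched], out1.events[untouched]
    )


@pytest.mark.parametrize("scenario", ["pescetarian", "vegetarian", "vegan"])
def test_full_conformity_after_replacement(small_study, scenario):
    """With replace_fraction=1 no non-conforming event remains."""
    ds, foods, tables = small_study
    spec = SCENARIOS[scenario]
    out, _ = apply_scenario(ds, foods, tables[scenario], spec, seed=2)
    ff = foods.to_frame()
    conforming = set(ff.index[ff[f"conform_{scenario}"].astype(bool)])
    assert out.events["item_id"].isin(conforming).all()


def test_monotone_replacement_effort(small_study):
    """flex40 <= flex80 <= vegetarian <= vegan and pescetarian <= vegetarian."""
    ds, foods, tables = small_study
    counts = {}
    for scenario in ("flexitarian40", "flexitarian80", "pescetarian",
                     "vegetarian", "vegan"):
        repl = tables[REPLACEMENT_TABLE_FOR[scenario]]
        _, log = apply_scenario(ds, foods, repl, SCENARIOS[scenario], seed=4)
        counts[scenario] = len(log)
    assert counts["flexitarian40"] <= counts["flexitarian80"]
    assert counts["flexitarian80"] <= counts["vegetarian"]
    assert counts["pescetarian"] <= counts["vegetarian"]
    assert counts["vegetarian"] <= counts["vegan"]


def test_missing_alternatives_raise_coverage_error(catalog):
    foods, _ = catalog
    repl = ReplacementTable("vegan", {"cheese": ("tofu",)})  # no meat coverage
    ds = _dataset([["a", 1, "dinner", "e0", "beef_steak", 100.0]])
    with pytest.raises(CoverageError, match="meat_or_fish"):
        apply_scenario(ds, foods, repl, SCENARIOS["vegan"], seed=0)


def test_replacement_counts_by_sex(small_study):
    ds, foods, tables = small_study
    _, log = apply_scenario(ds, foods, tables["vegan"], SCENARIOS["vegan"], seed=9)
    counts = replacement_counts(log, ds.participants)
    assert counts["male"] + counts["female"] == len(log)
    empty, _ = apply_scenario(ds, foods, None, SCENARIOS["original"], seed=0)
    assert replacement_counts(_, ds.participants) == {"male": 0, "female": 0}
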