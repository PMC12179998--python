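import numpy as np
import pandas as pd
import pytest

from plantshift import (
    load_food_table,
    load_reference_pattern,
    load_replacement_table,
    resolve_missing_profiles,
    write_food_table,
)
from plantshift.aminoacids import IAA_SET, AminoAcidProfile, ReferencePattern
from plantshift.composition import (
    CONFORMITY_SCENARIOS,
    FoodTable,
    ReplacementTable,
    replacement_tables_to_frame,
)
from plantshift.errors import (
    SchemaError,
    UnresolvedItemError,
    ValidationError,
)
from conftest import make_item


def test_food_table_roundtrip(catalog, tmp_path):
    """Writing a food table and re-reading yields identical items."""
    foods, _ = catalog
    path = tmp_path / "foods.csv"
    write_food_table(foods, path)
    reloaded = load_food_table(path)
    assert len(reloaded) == len(foods)
    for a, b in zip(foods, reloaded):  # order preserved
        assert a.item_id == b.item_id
        assert a.group == b.group
        assert a.digestibility == pytest.approx(b.digestibility)
        assert a.plant_fraction == pytest.approx(b.plant_fraction)
        assert a.kcal_per_100g == pytest.approx(b.kcal_per_100g)
        assert a.conformity == dict(b.conformity)
        assert a.profile.total_aa_mg == pytest.approx(b.profile.total_aa_mg)
        for k in IAA_SET:
            assert a.profile.values[k] == pytest.approx(b.profile.values[k])


def test_egg_row_matches_published_composition(catalog):
    """The chicken egg entry carries 12.3 g protein and 128 kcal per 100 g."""
    foods, _ = catalog
    egg = foods["chicken_egg"]
    assert egg.kcal_per_100g == 128
    assert egg.profile.protein_g_per_100g == pytest.approx(12.3)


def test_zero_digestibility_rejected():
    with pytest.raises(ValidationError, match="digestibility"):
        make_item(item_id="bad", digestibility=0.0)


def test_missing_column_names_the_column(tmp_path, catalog):
    foods, _ = catalog
    path = tmp_path / "foods.csv"
    write_food_table(foods, path)
    df = pd.read_csv(path).drop(columns=["digestibility"])
    df.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="digestibility"):
        load_food_table(path)


def test_group_vocabulary_enforced(catalog, tmp_path):
    foods, _ = catalog
    path = tmp_path / "foods.csv"
    write_food_table(foods, path)
    with pytest.raises(ValidationError, match="vocabulary"):
        load_food_table(path, group_vocabulary=["bread"])


def test_resolve_missing_profiles():
    from dataclasses import replace

    donor = make_item(item_id="donor", digestibility=0.8)
    orphan = replace(make_item(item_id="orphan"), profile=None, digestibility=None)
    foods = FoodTable([donor, orphan])
    resolved, log = resolve_missing_profiles(foods, {"orphan": "donor"})
    assert log == [("orphan", "donor")]
    item = resolved["orphan"]
    assert item.profile is donor.profile
    assert item.digestibility == donor.digestibility
    # idempotent: a second pass changes nothing and logs nothing
    again, log2 = resolve_missing_profiles(resolved, {"orphan": "donor"})
    assert log2 == []
    assert again["orphan"].profile is donor.profile


def test_resolve_identity_when_all_complete(catalog):
    foods, _ = catalog
    resolved, log = resolve_missing_profiles(foods, {})
    assert log == []
    assert [i.item_id for i in resolved] == [i.item_id for i in foods]


def test_resolve_reports_uncovered_items():
    """5 items, 2 without profile, mapping covers 1 -> error lists the other."""
    from dataclasses import replace

    items = [make_item(item_id=f"i{k}") for k in range(3)]
    missing = [
        replace(make_item(item_id=f"m{k}"), profile=None, digestibility=None)
        for k in range(2)
    ]
    foods = FoodTable(items + missing)
    with pytest.raises(UnresolvedItemError) as err:
        resolve_missing_profiles(foods, {"m0": "i0"})
    assert err.value.item_ids == ["m1"]


def test_replacement_table_loading(catalog, tmp_path):
    foods, tables = catalog
    path = tmp_path / "replacements.csv"
    replacement_tables_to_frame(tables).to_csv(path, index=False)
    veg = load_replacement_table(path, "vegetarian", foods)
    # cheese conforms to a vegetarian diet: Gouda is a valid alternative
    assert "gouda_48" in veg.alternatives("meat_or_fish")
    assert all(len(alts) <= 12 for alts in veg.entries.values())


def test_dairy_alternative_rejected_under_vegan(catalog):
    foods, _ = catalog
    bad = ReplacementTable("vegan", {"meat_or_fish": ("gouda_48",)})
    with pytest.raises(ValidationError, match="non-conforming"):
        bad.validate(foods)


def test_thirteen_alternatives_rejected(catalog):
    foods, _ = catalog
    too_many = tuple(["tofu"] * 13)
    with pytest.raises(ValidationError, match="1..12"):
        ReplacementTable("vegan", {"meat_or_fish": too_many}).validate(foods)


def test_all_replacement_entries_conform(catalog):
    """Exhaustive conformity check of every packaged replacement table."""
    foods, tables = catalog
    for scen, table in tables.items():
        for group, alts in table.entries.items():
            for item_id in alts:
                assert foods[item_id].conforms(scen), (scen, group, item_id)


def test_default_reference_pattern():
    ref = load_reference_pattern()
    assert set(ref.values) == set(IAA_SET)
    assert all(v > 0 for v in ref.values.values())


def test_reference_pattern_errors(tmp_path):
    import yaml

    partial = {k: 30.0 for k in IAA_SET if k != "trp"}
    p = tmp_path / "ref.yaml"
    p.write_text(yaml.safe_dump(partial))
    with pytest.raises(SchemaError, match="trp"):
        load_reference_pattern(p)
    with pytest.raises(ValidationError, match="> 0"):
        ReferencePattern({**{k: 30.0 for k in IAA_SET}, "lys": 0.0})


def test_profile_invariants():
    with pytest.raises(ValidationError, match="exceeds total"):
        AminoAcidProfile(values={k: 200.0 for k in IAA_SET}, total_aa_mg=1000.0)
    with pytest.raises(ValidationError):
        AminoAcidProfile(values={**{k: 0.0 for k in IAA_SET}, "lys": -1.0},
                         total_aa_mg=100.0)
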