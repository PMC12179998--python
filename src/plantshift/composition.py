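"""Food-composition data: items, conformity flags, replacement tables.

The composition table is the currency of the whole pipeline: one row per
food item carrying its amino-acid profile (mg/100 g), a food-group label,
a per-group protein digestibility factor, the fraction of its protein that
is plant-derived, energy density, and per-scenario conformity flags that
say whether the item is allowed in a pescetarian / vegetarian / vegan diet.

File contracts (UTF-8 CSV, decimal point):

* food table: ``item_id,name,group,kcal_per_100g,digestibility,
  plant_fraction,total_aa_mg,his,ile,leu,lys,saa,aaa,thr,trp,val,
  conform_pescetarian,conform_vegetarian,conform_vegan``.
  Amino-acid columns may be left empty for items whose profile is unknown;
  those must be resolved via :func:`resolve_missing_profiles` before use.
* replacement table: ``scenario,group,rank,item_id`` (long form; ``rank``
  orders the up-to-12 alternatives within a group).
* reference pattern: YAML/JSON mapping of the nine IAA names to mg per g
  protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .aminoacids import (
    DEFAULT_REFERENCE,
    IAA_SET,
    AminoAcidProfile,
    ReferencePattern,
)
from .errors import (
    ReferentialError,
    SchemaError,
    UnresolvedItemError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Scenarios for which every food item carries a conformity flag.
CONFORMITY_SCENARIOS: tuple[str, ...] = ("pescetarian", "vegetarian", "vegan")

#: Maximum number of replacement alternatives per food group.
MAX_ALTERNATIVES = 12

_FOOD_COLUMNS = (
    ["item_id", "name", "group", "kcal_per_100g", "digestibility",
     "plant_fraction", "total_aa_mg"]
    + list(IAA_SET)
    + [f"conform_{s}" for s in CONFORMITY_SCENARIOS]
)


@dataclass(frozen=True)
class FoodItem:
    """A food with its amino-acid profile and scenario conformity flags.

    ``profile`` may be ``None`` for items whose amino-acid content is not
    yet known; such items must be resolved against a donor item before any
    protein computation.
    """

    item_id: str
    name: str
    group: str
    profile: AminoAcidProfile | None
    digestibility: float | None
    plant_fraction: float
    kcal_per_100g: float
    conformity: Mapping[str, bool]  # scenario -> conforming?

    def __post_init__(self) -> None:
        if self.digestibility is not None and not (0 < self.digestibility <= 1):
            raise ValidationError(
                f"item {self.item_id!r}: digestibility must be in (0, 1], "
                f"got {self.digestibility}"
            )
        if not (0 <= self.plant_fraction <= 1):
            raise ValidationError(
                f"item {self.item_id!r}: plant_fraction must be in [0, 1]"
            )
        missing = [s for s in CONFORMITY_SCENARIOS if s not in self.conformity]
        if missing:
            raise ValidationError(
                f"item {self.item_id!r}: missing conformity flags for {missing}"
            )

    @property
    def has_profile(self) -> bool:
        return self.profile is not None and self.digestibility is not None

    def conforms(self, scenario: str) -> bool:
        try:
            return bool(self.conformity[scenario])
        except KeyError:
            raise ValidationError(
                f"item {self.item_id!r}: no conformity flag for scenario {scenario!r}"
            ) from None


class FoodTable:
    """Ordered collection of :class:`FoodItem`, indexable by item id."""

    def __init__(self, items: Iterable[FoodItem], group_vocabulary: Sequence[str] | None = None):
        self._items: dict[str, FoodItem] = {}
        for it in items:
            if it.item_id in self._items:
                raise ValidationError(f"duplicate item_id {it.item_id!r}")
            self._items[it.item_id] = it
        if group_vocabulary is not None:
            vocab = set(group_vocabulary)
            bad = [it.item_id for it in self._items.values() if it.group not in vocab]
            if bad:
                raise ValidationError(f"items with group outside vocabulary: {bad}")
        self._frame: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items.values())

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._items

    def __getitem__(self, item_id: str) -> FoodItem:
        try:
            return self._items[item_id]
        except KeyError:
            raise ReferentialError(f"unknown item_id {item_id!r}") from None

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for it in self:
            seen.setdefault(it.group, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        """Food table as a DataFrame (cached); one row per item, mg units."""
        if self._frame is None:
            rows = []
            for it in self:
                row: dict[str, object] = {
                    "item_id": it.item_id,
                    "name": it.name,
                    "group": it.group,
                    "kcal_per_100g": it.kcal_per_100g,
                    "digestibility": it.digestibility,
                    "plant_fraction": it.plant_fraction,
                    "total_aa_mg": it.profile.total_aa_mg if it.profile else float("nan"),
                }
                for k in IAA_SET:
                    row[k] = it.profile.values[k] if it.profile else float("nan")
                for s in CONFORMITY_SCENARIOS:
                    row[f"conform_{s}"] = it.conformity[s]
                rows.append(row)
            self._frame = pd.DataFrame(rows, columns=_FOOD_COLUMNS).set_index(
                "item_id", drop=False
            )
        return self._frame


@dataclass(frozen=True)
class ReplacementTable:
    """Per-scenario map from food group to its ordered alternative items."""

    scenario: str
    entries: Mapping[str, tuple[str, ...]]

    def alternatives(self, group: str) -> tuple[str, ...]:
        return self.entries.get(group, ())

    def validate(self, foods: FoodTable) -> None:
        """Check existence, conformity and the 12-alternative cap."""
        for group, alts in self.entries.items():
            if not 1 <= len(alts) <= MAX_ALTERNATIVES:
                raise ValidationError(
                    f"replacement table {self.scenario!r}, group {group!r}: "
                    f"{len(alts)} alternatives (must be 1..{MAX_ALTERNATIVES})"
                )
            for item_id in alts:
                item = foods[item_id]
                if not item.conforms(self.scenario):
                    raise ValidationError(
                        f"replacement table {self.scenario!r}, group {group!r}: "
                        f"alternative {item_id!r} is non-conforming under {self.scenario!r}"
                    )


# ---------------------------------------------------------------------------
# loaders / writers


def _parse_conform(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("conforming", "true", "yes", "1"):
        return True
    if s in ("non_conforming", "nonconforming", "false", "no", "0"):
        return False
    raise ValidationError(f"unparseable conformity flag {value!r}")


def load_food_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    group_vocabulary: Sequence[str] | None = None,
) -> FoodTable:
    """Read and validate a food-composition CSV.

    Parameters
    ----------
    path
        CSV file with the documented food-table columns.
    schema
        Optional mapping from required column name to the name actually
        used in the file (for adapting foreign headers).
    group_vocabulary
        If given, every item's group must belong to it.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in _FOOD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"food table {path}: missing columns {missing}")

    items: list[FoodItem] = []
    for _, row in df.iterrows():
        item_id = str(row["item_id"])
        aa_fields = [row["total_aa_mg"], *(row[k] for k in IAA_SET)]
        if any(pd.isna(v) for v in aa_fields):
            profile = None
        else:
            profile = AminoAcidProfile(
                values={k: float(row[k]) for k in IAA_SET},
                total_aa_mg=float(row["total_aa_mg"]),
            )
        digestibility = None if pd.isna(row["digestibility"]) else float(row["digestibility"])
        items.append(
            FoodItem(
                item_id=item_id,
                name=str(row["name"]),
                group=str(row["group"]),
                profile=profile,
                digestibility=digestibility,
                plant_fraction=float(row["plant_fraction"]),
                kcal_per_100g=float(row["kcal_per_100g"]),
                conformity={
                    s: _parse_conform(row[f"conform_{s}"]) for s in CONFORMITY_SCENARIOS
                },
            )
        )
    logger.info("loaded %d food items from %s", len(items), path)
    return FoodTable(items, group_vocabulary=group_vocabulary)


def write_food_table(foods: FoodTable, path: str | Path) -> None:
    """Write a food table back to CSV (round-trips with :func:`load_food_table`)."""
    df = foods.to_frame().copy()
    for s in CONFORMITY_SCENARIOS:
        df[f"conform_{s}"] = df[f"conform_{s}"].map(
            {True: "conforming", False: "non_conforming"}
        )
    df.to_csv(path, index=False)


def resolve_missing_profiles(
    foods: FoodTable, mapping: Mapping[str, str]
) -> tuple[FoodTable, list[tuple[str, str]]]:
    """Fill in profiles of items lacking amino-acid data from donor items.

    Items without a profile inherit the mapped donor's profile *and*
    digestibility. Items already complete are returned untouched. The
    second return value logs every (item, donor) substitution performed.
    Idempotent: a second application with the same mapping is a no-op.
    """
    unresolved = [
        it.item_id for it in foods if not it.has_profile and it.item_id not in mapping
    ]
    if unresolved:
        raise UnresolvedItemError(unresolved)

    resolved: list[FoodItem] = []
    log: list[tuple[str, str]] = []
    for it in foods:
        if it.has_profile:
            resolved.append(it)
            continue
        donor = foods[mapping[it.item_id]]
        if not donor.has_profile:
            raise ValidationError(
                f"donor {donor.item_id!r} for {it.item_id!r} lacks a complete profile"
            )
        resolved.append(
            replace(it, profile=donor.profile, digestibility=donor.digestibility)
        )
        log.append((it.item_id, donor.item_id))
        logger.info("profile of %s inherited from %s", it.item_id, donor.item_id)
    return FoodTable(resolved), log


def load_replacement_table(
    path: str | Path, scenario: str, foods: FoodTable
) -> ReplacementTable:
    """Read one scenario's replacement table from a long CSV.

    The file may hold several scenarios; only rows matching ``scenario``
    are used. Alternatives are ordered by their ``rank`` column, must
    exist in ``foods``, be conforming under ``scenario``, and number at
    most 12 per group.
    """
    df = pd.read_csv(path)
    required = ["scenario", "group", "rank", "item_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"replacement table {path}: missing columns {missing}")
    sub = df[df["scenario"] == scenario]
    entries: dict[str, tuple[str, ...]] = {}
    for group, g in sub.sort_values("rank").groupby("group", sort=False):
        entries[str(group)] = tuple(str(i) for i in g["item_id"])
    table = ReplacementTable(scenario=scenario, entries=entries)
    table.validate(foods)
    return table


def replacement_tables_to_frame(tables: Mapping[str, ReplacementTable]) -> pd.DataFrame:
    """Serialize replacement tables to the long CSV layout."""
    rows = []
    for scen, table in tables.items():
        for group, alts in table.entries.items():
            for rank, item_id in enumerate(alts, start=1):
                rows.append(
                    {"scenario": scen, "group": group, "rank": rank, "item_id": item_id}
                )
    return pd.DataFrame(rows, columns=["scenario", "group", "rank", "item_id"])


def load_reference_pattern(path: str | Path | None = None) -> ReferencePattern:
    """Load an amino-acid reference pattern from YAML/JSON.

    With ``path=None`` the packaged WHO/FAO/UNU 2007 adult pattern is
    returned. The file must define all nine IAA keys with positive values;
    an optional ``source_label`` names the pattern.
    """
    if path is None:
        return DEFAULT_REFERENCE
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"reference pattern {path}: expected a mapping")
    label = str(raw.pop("source_label", Path(path).stem))
    missing = [k for k in IAA_SET if k not in raw]
    if missing:
        raise SchemaError(f"reference pattern {path}: missing IAA keys {missing}")
    return ReferencePattern(
        values={k: float(raw[k]) for k in IAA_SET}, source_label=label
    )
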