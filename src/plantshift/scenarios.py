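"""Rule-based diet-scenario transformation of recall datasets.

Six scenarios: the *original* diet (no change), *flexitarian-40* and
*flexitarian-80* (a random 40% / 80% of meat-and-fish consumption events
replaced with vegetarian alternatives), *pescetarian* (all meat replaced,
fish kept), *vegetarian* (all meat and fish replaced) and *vegan* (all
animal-based products replaced).

Replacements are gram-for-gram: a targeted event keeps its consumed
quantity and only swaps its food item for an alternative drawn uniformly
at random from the up-to-12 alternatives registered for the event's food
group. Alternatives are drawn independently per event (the same product
consumed twice may map to different alternatives). One seeded generator
per :func:`apply_scenario` call drives, in order, the flexitarian event
selection (if any) and then the per-event alternative draws, so runs are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import FoodItem, FoodTable, ReplacementTable
from .errors import CoverageError, DomainError, ValidationError
from .recalls import RecallDataset

#: Conformity flag governing flexitarian eligibility: "meat and fish"
#: products are exactly those not allowed in a vegetarian diet.
_MEAT_FISH_KEY = "vegetarian"


@dataclass(frozen=True)
class ScenarioSpec:
    """A sustainability scenario: what to replace and how much of it."""

    scenario_id: str
    replace_fraction: float
    conformity_key: str | None  # None for the original diet

    def __post_init__(self) -> None:
        if self.scenario_id != "original" and not (0 < self.replace_fraction <= 1):
            raise ValidationError(
                f"scenario {self.scenario_id!r}: replace_fraction must be in (0, 1]"
            )


#: The supported scenarios. Flexitarian scenarios replace a random subset
#: of meat/fish events with *vegetarian* alternatives.
SCENARIOS: dict[str, ScenarioSpec] = {
    "original": ScenarioSpec("original", 1.0, None),
    "flexitarian40": ScenarioSpec("flexitarian40", 0.4, _MEAT_FISH_KEY),
    "flexitarian80": ScenarioSpec("flexitarian80", 0.8, _MEAT_FISH_KEY),
    "pescetarian": ScenarioSpec("pescetarian", 1.0, "pescetarian"),
    "vegetarian": ScenarioSpec("vegetarian", 1.0, "vegetarian"),
    "vegan": ScenarioSpec("vegan", 1.0, "vegan"),
}

#: Which replacement table each scenario draws alternatives from
#: (flexitarian and pescetarian diets use the vegetarian alternatives).
REPLACEMENT_TABLE_FOR: dict[str, str | None] = {
    "original": None,
    "flexitarian40": "vegetarian",
    "flexitarian80": "vegetarian",
    "pescetarian": "pescetarian",
    "vegetarian": "vegetarian",
    "vegan": "vegan",
}

LOG_COLUMNS = ["pid", "day_index", "occasion", "event_id", "old_item", "new_item", "grams"]


@dataclass(frozen=True)
class ReplacementLog:
    """One record per replaced event; grams are unchanged by construction."""

    scenario_id: str
    records: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)


def classify_event(item: FoodItem, spec: ScenarioSpec) -> str:
    """Classify a food item under a scenario: ``conforming`` or
    ``non_conforming``. The original diet accepts everything."""
    if spec.conformity_key is None:
        return "conforming"
    return "conforming" if item.conforms(spec.conformity_key) else "non_conforming"


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _eligible_meat_fish_ids(ds: RecallDataset, foods: FoodTable) -> list[str]:
    ff = foods.to_frame()
    nonconf = set(ff.index[~ff[f"conform_{_MEAT_FISH_KEY}"].astype(bool)])
    mask = ds.events["item_id"].isin(nonconf)
    return ds.events.loc[mask, "event_id"].tolist()


def select_flexitarian_events(
    ds: RecallDataset,
    foods: FoodTable,
    fraction: float,
    seed: int | np.random.Generator,
) -> set[str]:
    """Randomly select a fraction of all meat/fish consumption events.

    Events are pooled across the whole dataset and sampled uniformly
    without replacement; the sample size is ``round(fraction x
    n_eligible)`` with round-half-up. Deterministic given the seed.
    """
    if not 0 <= fraction <= 1:
        raise DomainError(f"fraction must be in [0, 1], got {fraction}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eligible = _eligible_meat_fish_ids(ds, foods)
    if not eligible:
        return set()
    k = _round_half_up(fraction * len(eligible))
    if k == 0:
        return set()
    chosen = rng.choice(len(eligible), size=k, replace=False)
    return {eligible[i] for i in chosen}


def apply_scenario(
    ds: RecallDataset,
    foods: FoodTable,
    repl: ReplacementTable | None,
    spec: ScenarioSpec,
    seed: int = 0,
    selected_events: set[str] | None = None,
) -> tuple[RecallDataset, ReplacementLog]:
    """Transform a recall dataset into a scenario.

    Targeted events (non-conforming under the scenario's conformity key;
    for flexitarian scenarios only the randomly selected meat/fish subset)
    have their item replaced by a uniform draw from the alternatives
    registered for their food group. Grams are unchanged, untouched events
    are bit-identical, the input dataset is not mutated, and the log holds
    one record per replaced event.
    """
    rng = np.random.default_rng(seed)
    out = ds.copy()
    out.provenance = f"{ds.provenance}|scenario={spec.scenario_id}".lstrip("|")
    empty_log = pd.DataFrame(columns=LOG_COLUMNS)

    if spec.conformity_key is None:  # original diet: no replacement
        return out, ReplacementLog(spec.scenario_id, empty_log)

    ff = foods.to_frame()
    nonconf_items = set(ff.index[~ff[f"conform_{spec.conformity_key}"].astype(bool)])
    target_mask = out.events["item_id"].isin(nonconf_items)

    is_flexitarian = spec.replace_fraction < 1
    if is_flexitarian:
        if selected_events is None:
            selected_events = select_flexitarian_events(
                ds, foods, spec.replace_fraction, rng
            )
        target_mask &= out.events["event_id"].isin(selected_events)

    targets = out.events.index[target_mask]
    if len(targets) == 0:
        return out, ReplacementLog(spec.scenario_id, empty_log)

    if repl is None:
        raise CoverageError(
            f"scenario {spec.scenario_id!r} requires a replacement table"
        )
    groups_needed = set(out.events.loc[targets, "item_id"].map(ff["group"]))
    uncovered = sorted(g for g in groups_needed if not repl.alternatives(g))
    if uncovered:
        raise CoverageError(
            f"scenario {spec.scenario_id!r}: no replacement alternatives for "
            f"food groups {uncovered}"
        )

    records = []
    new_items = out.events["item_id"].copy()
    for idx in targets:  # dataset order; one uniform draw per event
        row = out.events.loc[idx]
        group = ff.loc[row["item_id"], "group"]
        alts = repl.alternatives(group)
        new_item = alts[int(rng.integers(len(alts)))]
        new_items.loc[idx] = new_item
        records.append(
            {
                "pid": row["pid"], "day_index": row["day_index"],
                "occasion": row["occasion"], "event_id": row["event_id"],
                "old_item": row["item_id"], "new_item": new_item,
                "grams": row["grams"],
            }
        )
    out.events["item_id"] = new_items
    log = pd.DataFrame(records, columns=LOG_COLUMNS)
    return out, ReplacementLog(spec.scenario_id, log)


def replacement_counts(
    log: ReplacementLog, participants: pd.DataFrame
) -> dict[str, int]:
    """Number of food replacements per sex; sums to the log length."""
    if len(log) == 0:
        return {"male": 0, "female": 0}
    sex = participants.set_index("pid")["sex"]
    counts = log.records["pid"].map(sex).value_counts()
    return {
        "male": int(counts.get("male", 0)),
        "female": int(counts.get("female", 0)),
    }
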