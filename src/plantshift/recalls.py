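"""Participants and repeated 24-h recalls with meal-occasion structure.

A recall dataset couples a participant table (sex, age, anthropometry,
survey weight) with two non-consecutive recall days per participant, each
day split into at most seven meal occasions (breakfast, lunch, dinner and
four snack moments). The occasion is the scoring window for amino-acid
complementation, so occasion labels outside the seven-slot vocabulary are
rejected rather than silently binned.

File contracts (UTF-8 CSV):

* participants: ``pid,sex,age_years,weight_kg,height_cm,education,survey_weight``
* events (long): ``pid,day_index,occasion,event_id,item_id,grams``
* days (optional): ``pid,day_index,weekday,season``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .composition import FoodTable
from .errors import (
    EmptyInputError,
    ReferentialError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: The seven meal-occasion slots (three meals, four in-between moments).
OCCASIONS: tuple[str, ...] = (
    "breakfast", "lunch", "dinner", "snack1", "snack2", "snack3", "snack4",
)

SEXES: tuple[str, ...] = ("male", "female")
EDUCATION_LEVELS: tuple[str, ...] = ("low", "middle", "high")

PARTICIPANT_COLUMNS = [
    "pid", "sex", "age_years", "weight_kg", "height_cm", "education", "survey_weight",
]
EVENT_COLUMNS = ["pid", "day_index", "occasion", "event_id", "item_id", "grams"]
DAY_COLUMNS = ["pid", "day_index", "weekday", "season"]


@dataclass(frozen=True)
class Participant:
    pid: str
    sex: str
    age_years: int
    weight_kg: float
    height_cm: float
    education: str
    survey_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"participant {self.pid!r}: sex must be one of {SEXES}")
        if not self.weight_kg > 0:
            raise ValidationError(f"participant {self.pid!r}: weight_kg must be > 0")
        if not self.height_cm > 0:
            raise ValidationError(f"participant {self.pid!r}: height_cm must be > 0")
        if not self.survey_weight > 0:
            raise ValidationError(f"participant {self.pid!r}: survey_weight must be > 0")

    @property
    def bmi(self) -> float:
        return self.weight_kg / (self.height_cm / 100.0) ** 2


@dataclass(frozen=True)
class ConsumptionEvent:
    event_id: str
    item_id: str
    grams: float

    def __post_init__(self) -> None:
        if self.grams < 0:
            raise ValidationError(f"event {self.event_id!r}: grams must be >= 0")


@dataclass(frozen=True)
class MealOccasion:
    """One eating moment: an occasion slot with its consumption events."""

    occasion: str
    events: tuple[ConsumptionEvent, ...]

    def __post_init__(self) -> None:
        if self.occasion not in OCCASIONS:
            raise ValidationError(
                f"unknown meal occasion {self.occasion!r}; must be one of {OCCASIONS}"
            )


@dataclass(frozen=True)
class RecallDay:
    pid: str
    day_index: int
    occasions: tuple[MealOccasion, ...]
    weekday: str = "unknown"
    season: str = "unknown"

    def __post_init__(self) -> None:
        slots = [m.occasion for m in self.occasions]
        if len(slots) != len(set(slots)):
            raise ValidationError(
                f"recall day ({self.pid}, {self.day_index}): duplicate occasion slots"
            )


class RecallDataset:
    """Participants x recall days x meal occasions x consumption events.

    Internally the dataset is frame-backed for vectorised scoring:
    ``participants`` (one row per participant, indexed by pid), ``events``
    (long, one row per consumption event) and ``days`` (day metadata).
    """

    def __init__(
        self,
        participants: pd.DataFrame,
        events: pd.DataFrame,
        days: pd.DataFrame | None = None,
        provenance: str = "",
    ):
        self.participants = participants.reset_index(drop=True).copy()
        self.events = events.reset_index(drop=True).copy()
        if days is None:
            days = (
                self.events[["pid", "day_index"]].drop_duplicates().assign(
                    weekday="unknown", season="unknown"
                )
            )
        self.days = days.reset_index(drop=True).copy()
        self.provenance = provenance
        self._validate_structure()

    # -- validation ---------------------------------------------------------

    def _validate_structure(self) -> None:
        for col in PARTICIPANT_COLUMNS:
            if col not in self.participants.columns:
                raise SchemaError(f"participants: missing column {col!r}")
        for col in EVENT_COLUMNS:
            if col not in self.events.columns:
                raise SchemaError(f"events: missing column {col!r}")
        if self.participants["pid"].duplicated().any():
            dup = self.participants.loc[self.participants["pid"].duplicated(), "pid"]
            raise ValidationError(f"duplicate participant ids: {sorted(set(dup))}")

        bad_sex = ~self.participants["sex"].isin(SEXES)
        if bad_sex.any():
            raise ValidationError(
                f"participants with unknown sex: {self.participants.loc[bad_sex, 'pid'].tolist()}"
            )
        for col, msg in [("weight_kg", "weight_kg"), ("survey_weight", "survey_weight")]:
            nonpos = ~(self.participants[col] > 0)
            if nonpos.any():
                raise ValidationError(
                    f"participants with non-positive {msg}: "
                    f"{self.participants.loc[nonpos, 'pid'].tolist()}"
                )

        known = set(self.participants["pid"])
        orphan = set(self.days["pid"]) - known
        if orphan:
            raise ReferentialError(f"recall days for unknown participants: {sorted(orphan)}")
        orphan_ev = set(self.events["pid"]) - known
        if orphan_ev:
            raise ReferentialError(f"events for unknown participants: {sorted(orphan_ev)}")

        bad_occ = ~self.events["occasion"].isin(OCCASIONS)
        if bad_occ.any():
            labels = sorted(set(self.events.loc[bad_occ, "occasion"]))
            raise ValidationError(f"unknown meal occasions in events: {labels}")
        neg = self.events["grams"] < 0
        if neg.any():
            rows = self.events.index[neg].tolist()
            raise ValidationError(f"negative grams in event rows {rows}")
        if len(self.events) == 0:
            logger.warning("recall dataset has participants but zero events")

    def validate_items(self, foods: FoodTable) -> None:
        """Check that every consumed item resolves against the food table."""
        unknown = ~self.events["item_id"].isin(foods.to_frame().index)
        if unknown.any():
            bad = self.events.loc[unknown, ["item_id"]]
            detail = ", ".join(
                f"{iid!r} (row {idx})" for idx, iid in bad["item_id"].head(10).items()
            )
            raise ReferentialError(f"events reference unknown items: {detail}")

    # -- accessors ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def n_days(self) -> int:
        return len(self.events[["pid", "day_index"]].drop_duplicates())

    def participant(self, pid: str) -> Participant:
        row = self.participants.loc[self.participants["pid"] == pid]
        if row.empty:
            raise ReferentialError(f"unknown participant {pid!r}")
        r = row.iloc[0]
        return Participant(
            pid=str(r["pid"]), sex=str(r["sex"]), age_years=int(r["age_years"]),
            weight_kg=float(r["weight_kg"]), height_cm=float(r["height_cm"]),
            education=str(r["education"]), survey_weight=float(r["survey_weight"]),
        )

    def iter_days(self) -> Iterable[RecallDay]:
        """Object view of the event frame, one :class:`RecallDay` at a time."""
        meta = self.days.set_index(["pid", "day_index"])
        for (pid, day), g in self.events.groupby(["pid", "day_index"], sort=True):
            occasions = []
            for occ, og in g.groupby("occasion", sort=False):
                events = tuple(
                    ConsumptionEvent(str(r.event_id), str(r.item_id), float(r.grams))
                    for r in og.itertuples()
                )
                occasions.append(MealOccasion(occasion=str(occ), events=events))
            weekday, season = "unknown", "unknown"
            if (pid, day) in meta.index:
                weekday = str(meta.loc[(pid, day), "weekday"])
                season = str(meta.loc[(pid, day), "season"])
            yield RecallDay(
                pid=str(pid), day_index=int(day), occasions=tuple(occasions),
                weekday=weekday, season=season,
            )

    def copy(self) -> "RecallDataset":
        return RecallDataset(
            self.participants, self.events, self.days, provenance=self.provenance
        )


# ---------------------------------------------------------------------------
# i/o


def load_recalls(
    participants_path: str | Path,
    events_path: str | Path,
    foods: FoodTable | None = None,
    days_path: str | Path | None = None,
    provenance: str = "",
) -> RecallDataset:
    """Load and validate a recall dataset from CSV files."""
    participants = pd.read_csv(participants_path, dtype={"pid": str})
    events = pd.read_csv(
        events_path, dtype={"pid": str, "event_id": str, "item_id": str}
    )
    days = pd.read_csv(days_path, dtype={"pid": str}) if days_path else None
    ds = RecallDataset(participants, events, days, provenance=provenance)
    if foods is not None:
        ds.validate_items(foods)
    return ds


def write_recalls(ds: RecallDataset, out_dir: str | Path) -> None:
    """Write participants/events/days CSVs (round-trips with :func:`load_recalls`)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.participants[PARTICIPANT_COLUMNS].to_csv(out / "participants.csv", index=False)
    ds.events[EVENT_COLUMNS].to_csv(out / "events.csv", index=False)
    ds.days[DAY_COLUMNS].to_csv(out / "days.csv", index=False)


# ---------------------------------------------------------------------------
# descriptives


def dataset_summary(ds: RecallDataset) -> dict:
    """Per-sex descriptive block: n (%), median (IQR) age, mean (SD) BMI,
    education counts.

    Strata with no participants are reported with ``n=0`` and no
    statistics. Counts are invariant to row order.
    """
    if len(ds) == 0:
        raise EmptyInputError("dataset_summary: empty dataset")
    p = ds.participants
    total = len(p)
    out: dict[str, dict] = {}
    for sex in SEXES:
        sub = p[p["sex"] == sex]
        block: dict[str, object] = {"n": int(len(sub)), "pct": 100.0 * len(sub) / total}
        if len(sub) > 0:
            age = sub["age_years"].to_numpy(dtype=float)
            bmi = (
                sub["weight_kg"].to_numpy(dtype=float)
                / (sub["height_cm"].to_numpy(dtype=float) / 100.0) ** 2
            )
            block.update(
                age_median=float(np.median(age)),
                age_iqr=(float(np.percentile(age, 25)), float(np.percentile(age, 75))),
                bmi_mean=float(np.mean(bmi)),
                bmi_sd=float(np.std(bmi, ddof=1)) if len(sub) > 1 else 0.0,
                education={
                    lvl: int((sub["education"] == lvl).sum()) for lvl in EDUCATION_LEVELS
                },
            )
        out[sex] = block
    return out
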