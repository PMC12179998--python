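"""Total, digestible and utilizable protein per event, meal and day.

Three protein metrics, all on the amino-acid-mass basis:

* **total**: grams of amino acids consumed (quantity);
* **digestible**: total multiplied by each food's per-group digestibility
  factor (quantity after absorption losses);
* **utilizable**: digestible multiplied by the meal's *similarity factor*,
  a per-occasion PDCAAS-style score. Amino-acid complementation is only
  credited within one meal occasion: the digestible IAA masses of all
  foods in an occasion are pooled, expressed per gram of digestible
  protein, divided by the reference pattern, and the minimum ratio over
  the nine IAA groups (capped at 1) is the similarity factor. The IAA
  attaining the uncapped minimum is the limiting amino acid.

Daily figures are sums over the day's seven occasions; per-kilogram
variants divide by the participant's body weight.

The invariant chain ``0 <= utilizable <= digestible <= total`` holds for
every meal and day. A zero-protein meal has similarity 1 by convention
(utilizable stays 0 through the multiplication), avoiding 0/0 without
affecting any aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aminoacids import IAA_SET, ReferencePattern
from .composition import FoodItem, FoodTable
from .errors import ValidationError
from .recalls import ConsumptionEvent, MealOccasion, RecallDataset

_DIG_COLS = [f"dig_{k}_mg" for k in IAA_SET]


@dataclass(frozen=True)
class MealProteinSummary:
    """Protein quality bookkeeping for one meal occasion."""

    occasion: str
    total_g: float
    digestible_g: float
    similarity: float
    limiting_iaa: str | None
    utilizable_g: float


@dataclass(frozen=True)
class DailyProteinSummary:
    pid: str
    day_index: int
    total_g: float
    digestible_g: float
    utilizable_g: float
    total_g_per_kg: float
    digestible_g_per_kg: float
    utilizable_g_per_kg: float
    meals: tuple[MealProteinSummary, ...]


# ---------------------------------------------------------------------------
# event level


def event_protein(
    event: ConsumptionEvent, item: FoodItem
) -> tuple[float, float, np.ndarray]:
    """Protein contributed by one consumption event.

    Returns ``(total_g, digestible_g, digestible_iaa_mg)`` where the IAA
    vector follows :data:`~plantshift.aminoacids.IAA_SET` order. Linear in
    grams; 0 g contributes zeros.
    """
    if not item.has_profile:
        raise ValidationError(f"item {item.item_id!r} has no amino-acid profile")
    scale = event.grams / 100.0
    total_g = scale * item.profile.total_aa_mg / 1000.0
    digestible_g = total_g * item.digestibility
    digestible_iaa_mg = scale * item.profile.as_array() * item.digestibility
    return total_g, digestible_g, digestible_iaa_mg


# ---------------------------------------------------------------------------
# meal level


def meal_similarity(
    digestible_iaa_mg: np.ndarray,
    digestible_g: float,
    ref: ReferencePattern,
) -> tuple[float, str | None]:
    """Similarity factor of a meal and its limiting amino acid.

    ``ratio_i = (digestible IAA_i mg / digestible protein g) / ref_i``;
    the similarity factor is ``min(1, min_i ratio_i)``. When no ratio
    falls below 1 there is no limiting amino acid and the factor is capped
    at 100%. A zero-protein meal returns ``(1.0, None)``.
    """
    vec = np.asarray(digestible_iaa_mg, dtype=float)
    if vec.shape != (len(IAA_SET),):
        raise ValidationError(f"expected {len(IAA_SET)} IAA values, got {vec.shape}")
    if (vec < 0).any():
        raise ValidationError("negative amino-acid mass")
    if digestible_g < 0:
        raise ValidationError("negative digestible protein")
    if digestible_g == 0:
        return 1.0, None
    ratios = (vec / digestible_g) / ref.as_array()
    i_min = int(np.argmin(ratios))
    if ratios[i_min] >= 1.0:
        return 1.0, None
    return float(ratios[i_min]), IAA_SET[i_min]


def meal_summary(
    meal: MealOccasion, foods: FoodTable, ref: ReferencePattern
) -> MealProteinSummary:
    """Score one meal occasion: pool digestible IAA over events, then score.

    Pooling before scoring is what credits within-meal amino-acid
    complementation (e.g. lysine-poor bread with lysine-rich legumes).
    """
    total_g = 0.0
    digestible_g = 0.0
    pooled = np.zeros(len(IAA_SET))
    for event in meal.events:
        t, d, vec = event_protein(event, foods[event.item_id])
        total_g += t
        digestible_g += d
        pooled += vec
    similarity, limiting = meal_similarity(pooled, digestible_g, ref)
    return MealProteinSummary(
        occasion=meal.occasion,
        total_g=total_g,
        digestible_g=digestible_g,
        similarity=similarity,
        limiting_iaa=limiting,
        utilizable_g=similarity * digestible_g,
    )


# ---------------------------------------------------------------------------
# dataset level (vectorised)


def _event_frame(ds: RecallDataset, foods: FoodTable) -> pd.DataFrame:
    """Events joined with composition, with per-event protein columns."""
    ds.validate_items(foods)
    food_cols = ["total_aa_mg", "digestibility", "plant_fraction", "kcal_per_100g",
                 "group", *IAA_SET]
    ff = foods.to_frame()[food_cols]
    if ff["total_aa_mg"].isna().any():
        bad = ff.index[ff["total_aa_mg"].isna()].tolist()
        raise ValidationError(f"items without amino-acid profile: {bad}")
    ev = ds.events.merge(ff, left_on="item_id", right_index=True, how="left")
    scale = ev["grams"].to_numpy() / 100.0
    ev["total_g"] = scale * ev["total_aa_mg"].to_numpy() / 1000.0
    ev["digestible_g"] = ev["total_g"] * ev["digestibility"]
    ev["kcal"] = scale * ev["kcal_per_100g"].to_numpy()
    ev["plant_g"] = ev["total_g"] * ev["plant_fraction"]
    dig = scale[:, None] * ev[list(IAA_SET)].to_numpy() * ev["digestibility"].to_numpy()[:, None]
    ev[_DIG_COLS] = dig
    return ev


def meal_summaries(
    ds: RecallDataset, foods: FoodTable, ref: ReferencePattern
) -> pd.DataFrame:
    """Per (pid, day_index, occasion) protein summaries for a whole dataset.

    Columns: ``total_g, digestible_g, similarity, limiting_iaa,
    utilizable_g``. Vectorised equivalent of calling :func:`meal_summary`
    on every occasion.
    """
    ev = _event_frame(ds, foods)
    keys = ["pid", "day_index", "occasion"]
    agg = ev.groupby(keys, sort=True)[["total_g", "digestible_g", "kcal", *_DIG_COLS]].sum()
    dig_g = agg["digestible_g"].to_numpy()
    dig_iaa = agg[_DIG_COLS].to_numpy()
    refv = ref.as_array()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = dig_iaa / dig_g[:, None] / refv[None, :]
    # zero-protein occasions: similarity 1 by convention
    ratios[dig_g == 0] = np.inf
    i_min = np.argmin(ratios, axis=1)
    r_min = ratios[np.arange(len(ratios)), i_min]
    similarity = np.minimum(r_min, 1.0)
    limiting = np.where(r_min < 1.0, np.array(IAA_SET, dtype=object)[i_min], None)
    out = agg[["total_g", "digestible_g", "kcal"]].copy()
    out["similarity"] = similarity
    out["limiting_iaa"] = limiting
    out["utilizable_g"] = similarity * dig_g
    return out.reset_index()


def daily_summaries(
    ds: RecallDataset, foods: FoodTable, ref: ReferencePattern
) -> pd.DataFrame:
    """Per (pid, day_index) daily summaries.

    Daily figures are the sums over that day's meal summaries (utilizable
    protein is scored per occasion, then summed). Adds per-kg variants
    (divided by the participant's body weight), daily kcal, plus the
    participant's sex and survey weight for downstream estimation.
    """
    meals = meal_summaries(ds, foods, ref)
    day = (
        meals.groupby(["pid", "day_index"], sort=True)[
            ["total_g", "digestible_g", "utilizable_g", "kcal"]
        ]
        .sum()
        .reset_index()
    )
    pinfo = ds.participants.set_index("pid")[["sex", "weight_kg", "survey_weight"]]
    if pinfo["weight_kg"].isna().any():
        raise ValidationError("participants with missing body weight")
    day = day.merge(pinfo, left_on="pid", right_index=True, how="left")
    for m in ("total", "digestible", "utilizable"):
        day[f"{m}_g_per_kg"] = day[f"{m}_g"] / day["weight_kg"]
    return day


def plant_protein_share(ds: RecallDataset, foods: FoodTable) -> dict[str, float]:
    """Per-sex fraction of total protein mass that is plant-derived."""
    ev = _event_frame(ds, foods)
    ev = ev.merge(
        ds.participants.set_index("pid")[["sex"]], left_on="pid", right_index=True
    )
    out: dict[str, float] = {}
    for sex, g in ev.groupby("sex"):
        tot = g["total_g"].sum()
        out[str(sex)] = float(g["plant_g"].sum() / tot) if tot > 0 else float("nan")
    return out
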