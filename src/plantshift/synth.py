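"""Synthetic survey-like food tables, replacement tables and recall data.

The restricted Dutch national food-consumption microdata (two
non-consecutive 24-h recalls for ~600 community-dwelling adults aged
65-79) cannot be redistributed, so this module generates datasets with
the same *statistical structure*: per-sex body weights, seven meal
occasions per day with dinner carrying the largest protein share, ~62%
of protein from animal sources, median intakes near 0.96 (men) / 0.94
(women) g protein per kg body weight per day, and lognormal
between-/within-person variation of daily protein.

The food catalogue is built from archetypes (meat/fish with complete
amino-acid profiles, dairy and egg, lysine-limited cereals, lysine-rich
but SAA-limited legumes, soy-based processed alternatives). Replacement
alternatives carry the names, protein and energy densities of the
published vegetarian/vegan replacement lists; their IAA profiles follow
their archetype. Everything is deterministic given the seed.

Daily protein is generated on the log scale (person effect + day noise),
allocated to occasions by fixed protein shares, and realised as
food-item grams; the dinner main-course protein fraction is solved so
the expected animal-protein share equals the configured target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aminoacids import IAA_SET, AminoAcidProfile
from .composition import (
    CONFORMITY_SCENARIOS,
    FoodItem,
    FoodTable,
    ReplacementTable,
    replacement_tables_to_frame,
    write_food_table,
)
from .errors import CalibrationError, ValidationError
from .recalls import OCCASIONS, RecallDataset, write_recalls

# ---------------------------------------------------------------------------
# archetypes

#: IAA density per archetype, mg per g protein. The cereal archetype is
#: lysine-limited (26 < 45 mg/g reference), the legume archetype is
#: lysine-rich but sulphur-AA-limited — the complementation pair that
#: meal-level pooling is designed to credit.
ARCHETYPE_DENSITY: dict[str, dict[str, float]] = {
    "meat":      {"his": 27, "ile": 47, "leu": 81, "lys": 84, "saa": 38, "aaa": 76, "thr": 44, "trp": 12, "val": 50},
    "dairy":     {"his": 27, "ile": 49, "leu": 95, "lys": 78, "saa": 33, "aaa": 93, "thr": 44, "trp": 13, "val": 60},
    "egg":       {"his": 24, "ile": 53, "leu": 86, "lys": 72, "saa": 52, "aaa": 93, "thr": 47, "trp": 13, "val": 61},
    "cereal":    {"his": 22, "ile": 36, "leu": 68, "lys": 26, "saa": 39, "aaa": 77, "thr": 29, "trp": 11, "val": 44},
    "legume":    {"his": 27, "ile": 43, "leu": 72, "lys": 64, "saa": 18, "aaa": 80, "thr": 36, "trp":  9, "val": 47},
    "soy":       {"his": 25, "ile": 45, "leu": 77, "lys": 61, "saa": 24, "aaa": 84, "thr": 38, "trp": 12, "val": 47},
    "veg_alt":   {"his": 24, "ile": 42, "leu": 74, "lys": 52, "saa": 26, "aaa": 80, "thr": 36, "trp": 10, "val": 46},
    "vegetable": {"his": 20, "ile": 34, "leu": 55, "lys": 52, "saa": 26, "aaa": 60, "thr": 34, "trp": 10, "val": 45},
    "nut":       {"his": 25, "ile": 35, "leu": 66, "lys": 36, "saa": 21, "aaa": 89, "thr": 27, "trp": 10, "val": 42},
}

#: Protein digestibility factor per food group (opaque per-group fraction).
GROUP_DIGESTIBILITY: dict[str, float] = {
    "meat_or_fish": 0.94,
    "sandwich_filling_meat": 0.93,
    "bread": 0.84,
    "dairy_drink": 0.95,
    "dairy_dessert": 0.95,
    "cheese": 0.95,
    "egg": 0.95,
    "side_veg": 0.75,
    "legume": 0.78,
    "nut": 0.85,
    "bakery_trace": 0.85,
    "veg_replacement": 0.88,
    "sandwich_filling_veg": 0.88,
    "vegan_replacement": 0.90,
    "beverage": 1.0,
}

# (item_id, name, group, archetype, protein g/100g, kcal/100g,
#  plant_fraction, conform_pescetarian, conform_vegetarian, conform_vegan)
_CATALOG: list[tuple] = [
    # --- base foods of the reference diet ---------------------------------
    ("beef_steak", "Beef steak", "meat_or_fish", "meat", 26.5, 135, 0.0, False, False, False),
    ("pork_chop", "Pork chop", "meat_or_fish", "meat", 27.0, 160, 0.0, False, False, False),
    ("chicken_breast", "Chicken breast", "meat_or_fish", "meat", 27.0, 107, 0.0, False, False, False),
    ("minced_beef", "Minced beef", "meat_or_fish", "meat", 25.0, 235, 0.0, False, False, False),
    ("salmon", "Salmon fillet", "meat_or_fish", "meat", 20.4, 182, 0.0, True, False, False),
    ("cod", "Cod fillet", "meat_or_fish", "meat", 17.5, 80, 0.0, True, False, False),
    ("ham", "Cooked ham", "sandwich_filling_meat", "meat", 20.0, 110, 0.0, False, False, False),
    ("chicken_fillet_cold", "Chicken fillet (cold cut)", "sandwich_filling_meat", "meat", 22.0, 100, 0.0, False, False, False),
    ("white_bread", "White bread", "bread", "cereal", 8.9, 265, 1.0, True, True, True),
    ("brown_bread", "Brown/wholemeal bread", "bread", "cereal", 10.5, 235, 1.0, True, True, True),
    ("white_roll", "Roll white soft", "bread", "cereal", 9.7, 262, 1.0, True, True, True),
    ("milk_semi", "Semi-skimmed milk", "dairy_drink", "dairy", 3.5, 46, 0.0, True, True, False),
    ("buttermilk", "Buttermilk", "dairy_drink", "dairy", 3.4, 37, 0.0, True, True, False),
    ("yoghurt_full", "Yoghurt full fat", "dairy_dessert", "dairy", 3.9, 72, 0.0, True, True, False),
    ("custard_vanilla", "Custard vanilla", "dairy_dessert", "dairy", 3.0, 90, 0.0, True, True, False),
    ("quark_lowfat", "Quark low fat", "dairy_dessert", "dairy", 9.0, 60, 0.0, True, True, False),
    ("fruit_yoghurt", "Fruit yoghurt", "dairy_dessert", "dairy", 3.5, 90, 0.0, True, True, False),
    ("gouda_48", "Gouda cheese 48+", "cheese", "dairy", 22.9, 369, 0.0, True, True, False),
    ("cheese_30", "Cheese 30+", "cheese", "dairy", 31.9, 306, 0.0, True, True, False),
    ("chicken_egg", "Chicken egg", "egg", "egg", 12.3, 128, 0.0, True, True, False),
    ("potato_boiled", "Potato boiled", "side_veg", "vegetable", 1.9, 93, 1.0, True, True, True),
    ("broccoli", "Broccoli boiled", "side_veg", "vegetable", 3.0, 34, 1.0, True, True, True),
    ("peas_boiled", "Garden peas boiled", "side_veg", "legume", 5.4, 81, 1.0, True, True, True),
    ("peanuts", "Peanuts salted", "nut", "nut", 25.0, 620, 1.0, True, True, True),
    # trace animal content (cake, sprinkles): left unchanged even in the
    # vegan scenario, hence conform_vegan=True and plant share < 100%
    ("cake_slice", "Cake slice", "bakery_trace", "cereal", 5.0, 370, 0.95, True, True, True),
    ("biscuit", "Biscuit", "bakery_trace", "cereal", 7.0, 480, 0.95, True, True, True),
    ("chocolate_sprinkles", "Chocolate sprinkles", "bakery_trace", "cereal", 5.8, 446, 0.97, True, True, True),
    # --- vegetarian replacement alternatives ------------------------------
    ("mozzarella", "Mozzarella cheese", "cheese", "dairy", 18.7, 253, 0.0, True, True, False),
    ("veg_hamburger", "Vegetarian hamburger", "veg_replacement", "veg_alt", 17.7, 192, 0.9, True, True, False),
    ("veg_schnitzel", "Vegetarian schnitzel", "veg_replacement", "veg_alt", 15.2, 226, 0.9, True, True, False),
    ("beyond_burger", "Plant based burger beyond meat", "veg_replacement", "soy", 15.0, 252, 1.0, True, True, True),
    ("veg_meatballs", "Vegetarian meatballs", "veg_replacement", "veg_alt", 17.1, 169, 0.9, True, True, False),
    ("veg_burger_cheese", "Vegetarian burger with cheese", "veg_replacement", "veg_alt", 15.9, 231, 0.8, True, True, False),
    ("veg_meatball", "Vegetarian meatball", "veg_replacement", "veg_alt", 16.9, 243, 0.9, True, True, False),
    ("valess_schnitzel", "Valess schnitzel", "veg_replacement", "veg_alt", 12.3, 188, 0.5, True, True, False),
    ("veg_sausage", "Vegetarian sausage", "veg_replacement", "veg_alt", 13.3, 259, 0.9, True, True, False),
    ("veg_burger", "Vegetarian burger", "veg_replacement", "veg_alt", 11.0, 210, 1.0, True, True, True),
    ("egg_salad", "Egg salad", "sandwich_filling_veg", "egg", 7.3, 255, 0.2, True, True, False),
    ("peanut_butter", "Peanut butter", "sandwich_filling_veg", "nut", 20.0, 651, 1.0, True, True, True),
    ("hummus", "Hummus", "sandwich_filling_veg", "legume", 7.7, 322, 1.0, True, True, True),
    ("cheese_salad", "Cheese salad", "sandwich_filling_veg", "dairy", 9.0, 422, 0.2, True, True, False),
    ("cream_cheese", "Cream cheese", "sandwich_filling_veg", "dairy", 5.3, 291, 0.0, True, True, False),
    ("cheese_spread", "Cheese spread", "sandwich_filling_veg", "dairy", 14.3, 231, 0.0, True, True, False),
    ("vegan_luncheon", "Vegan luncheon", "sandwich_filling_veg", "soy", 8.2, 156, 1.0, True, True, True),
    # --- vegan replacement alternatives -----------------------------------
    ("lentils_boiled", "Lentils green/brown boiled", "legume", "legume", 21.0, 306, 1.0, True, True, True),
    ("beyond_burger_v", "Plant based burger Beyond Meat", "vegan_replacement", "soy", 17.0, 252, 1.0, True, True, True),
    ("falafel", "Falafel unprepared", "vegan_replacement", "legume", 6.8, 208, 1.0, True, True, True),
    ("vegan_bean_burger", "Vegan bean burger", "vegan_replacement", "legume", 16.0, 191, 1.0, True, True, True),
    ("sausage_beyond", "Sausage beyond meat", "vegan_replacement", "soy", 17.0, 233, 1.0, True, True, True),
    ("tofu", "Tahoe soya curd", "vegan_replacement", "soy", 11.6, 113, 1.0, True, True, True),
    ("vegan_chicken_burger", "Vegan chicken burger", "vegan_replacement", "soy", 13.0, 220, 1.0, True, True, True),
    ("plant_chicken_vivera", "Plant based chicken vivera", "vegan_replacement", "soy", 15.0, 166, 1.0, True, True, True),
    ("vegan_chicken", "Vegan chicken", "vegan_replacement", "soy", 21.0, 142, 1.0, True, True, True),
    ("vegan_swedish_balls", "Vegan swedish balls", "vegan_replacement", "soy", 9.6, 158, 1.0, True, True, True),
    ("vegan_veg_burger", "Vegan vegetable burger", "vegan_replacement", "soy", 11.0, 116, 1.0, True, True, True),
    ("plant_chicken_tenders", "Plant based chicken tenders", "vegan_replacement", "soy", 15.0, 202, 1.0, True, True, True),
    ("quorn_luncheon", "Luncheon meat quorn", "vegan_replacement", "soy", 7.1, 89, 1.0, True, True, True),
    ("vegan_bacon", "Vegan bacon", "vegan_replacement", "soy", 5.5, 140, 1.0, True, True, True),
    ("vegan_grill_sausage", "Vegan grill sausage", "vegan_replacement", "soy", 8.3, 163, 1.0, True, True, True),
    ("tahin", "Sesame paste tahin", "vegan_replacement", "nut", 21.9, 602, 1.0, True, True, True),
    ("melt_me_cheese", "Melt me smoky cheese", "vegan_replacement", "soy", 8.3, 270, 1.0, True, True, True),
    ("soy_drink", "Drink soya original alpro", "vegan_replacement", "soy", 3.0, 39, 1.0, True, True, True),
    ("oat_drink", "Original plant-based not milk", "vegan_replacement", "cereal", 2.2, 34, 1.0, True, True, True),
    ("tea", "Tea", "beverage", "vegetable", 0.0, 0, 1.0, True, True, True),
    ("coffee", "Coffee", "beverage", "vegetable", 0.0, 0, 1.0, True, True, True),
    ("water", "Water", "beverage", "vegetable", 0.0, 0, 1.0, True, True, True),
    ("soy_quark", "Plant based alternative quark", "vegan_replacement", "soy", 2.7, 119, 1.0, True, True, True),
    ("soy_quark_protein", "Plant based alternative quark soya", "vegan_replacement", "soy", 5.7, 54, 1.0, True, True, True),
    ("soy_yoghurt_fruit", "Yoghurt soybased fruit", "vegan_replacement", "soy", 3.7, 134, 1.0, True, True, True),
    ("havergurt_greek", "Havergurt greek style", "vegan_replacement", "cereal", 3.3, 145, 1.0, True, True, True),
    ("soy_yoghurt", "Yoghurt soybased", "vegan_replacement", "soy", 4.0, 47, 1.0, True, True, True),
    ("havergurt_blueberry", "Havergurt blue berry", "vegan_replacement", "cereal", 1.3, 101, 1.0, True, True, True),
    ("soy_dessert", "Dessert soya alpro", "vegan_replacement", "soy", 3.1, 85, 1.0, True, True, True),
    ("coconut_ice", "Ice cream coconutmilk", "vegan_replacement", "nut", 1.2, 85, 1.0, True, True, True),
]

_VEGETARIAN_ENTRIES: dict[str, tuple[str, ...]] = {
    "meat_or_fish": (
        "chicken_egg", "mozzarella", "veg_hamburger", "veg_schnitzel",
        "beyond_burger", "veg_meatballs", "veg_burger_cheese", "veg_meatball",
        "valess_schnitzel", "gouda_48", "veg_sausage", "veg_burger",
    ),
    "sandwich_filling_meat": (
        "egg_salad", "gouda_48", "peanut_butter", "hummus", "cheese_salad",
        "cream_cheese", "chicken_egg", "cheese_30", "cheese_spread",
        "vegan_luncheon",
    ),
}

_VEGAN_ENTRIES: dict[str, tuple[str, ...]] = {
    "meat_or_fish": (
        "lentils_boiled", "beyond_burger_v", "falafel", "vegan_bean_burger",
        "sausage_beyond", "tofu", "vegan_chicken_burger",
        "plant_chicken_vivera", "vegan_chicken", "vegan_swedish_balls",
        "vegan_veg_burger", "plant_chicken_tenders",
    ),
    "sandwich_filling_meat": (
        "peanut_butter", "quorn_luncheon", "hummus", "vegan_bacon",
        "vegan_luncheon", "vegan_grill_sausage", "tahin", "melt_me_cheese",
    ),
    "cheese": ("melt_me_cheese", "hummus", "peanut_butter", "tahin", "vegan_luncheon"),
    "egg": ("hummus", "tofu", "vegan_luncheon", "falafel"),
    "dairy_drink": ("soy_drink", "oat_drink", "tea", "coffee", "water"),
    "dairy_dessert": (
        "soy_quark", "soy_quark_protein", "soy_yoghurt_fruit", "havergurt_greek",
        "soy_yoghurt", "havergurt_blueberry", "soy_dessert", "coconut_ice",
    ),
}

# occasion -> (animal slot pool, animal protein fraction of the occasion,
#              plant slot pool). Dinner's animal fraction is solved from
# the configured animal-protein share target.
_SLOT_DESIGN: dict[str, dict] = {
    "breakfast": {
        "animal_pool": ("milk_semi", "buttermilk", "yoghurt_full", "quark_lowfat"),
        "animal_frac": 0.45,
        "plant_pool": ("white_bread", "brown_bread", "white_roll"),
    },
    "lunch": {
        "animal_pool": ("gouda_48", "cheese_30", "chicken_egg", "ham", "chicken_fillet_cold"),
        "animal_frac": 0.55,
        "plant_pool": ("white_bread", "brown_bread", "white_roll"),
    },
    "dinner": {
        "animal_pool": ("beef_steak", "pork_chop", "chicken_breast", "minced_beef", "salmon", "cod"),
        "animal_frac": None,  # solved from target_animal_protein_share
        "plant_pool": ("potato_boiled", "broccoli", "peas_boiled"),
    },
    "snack1": {
        "animal_pool": ("custard_vanilla", "fruit_yoghurt", "yoghurt_full"),
        "animal_frac": 1.0,
        "plant_pool": (),
    },
    "snack2": {
        "animal_pool": ("gouda_48", "cheese_30"),
        "animal_frac": 1.0,
        "plant_pool": (),
    },
    "snack3": {
        "animal_pool": (),
        "animal_frac": 0.0,
        "plant_pool": ("peanuts", "cake_slice", "biscuit"),
    },
    "snack4": {
        "animal_pool": (),
        "animal_frac": 0.0,
        "plant_pool": ("cake_slice", "biscuit", "chocolate_sprinkles"),
    },
}

#: Protein share of each meal occasion (dinner carries the most).
DEFAULT_OCCASION_SHARES: dict[str, float] = {
    "breakfast": 0.17, "lunch": 0.24, "dinner": 0.40,
    "snack1": 0.06, "snack2": 0.06, "snack3": 0.05, "snack4": 0.02,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic survey.

    Defaults mirror the emulated survey stratum: ~600 adults aged 65-79,
    two recall days, ~62% animal protein, median habitual intake 0.96
    (men) / 0.94 (women) g/kg bw/day, unit survey weights.
    """

    n_participants: int = 607
    seed: int = 0
    sex_ratio: float = 0.51  # fraction male
    age_range: tuple[int, int] = (65, 79)
    weight_mean_kg: Mapping[str, float] = field(
        default_factory=lambda: {"male": 82.0, "female": 70.0}
    )
    weight_sd_kg: Mapping[str, float] = field(
        default_factory=lambda: {"male": 11.0, "female": 11.0}
    )
    height_mean_cm: Mapping[str, float] = field(
        default_factory=lambda: {"male": 176.0, "female": 163.0}
    )
    height_sd_cm: Mapping[str, float] = field(
        default_factory=lambda: {"male": 7.0, "female": 6.0}
    )
    education_probs: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"male": (0.31, 0.29, 0.40), "female": (0.45, 0.28, 0.27)}
    )
    target_animal_protein_share: float = 0.62
    target_intake_g_per_kg: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.96, "female": 0.94}
    )
    occasion_protein_shares: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OCCASION_SHARES)
    )
    between_person_cv: float = 0.20
    within_person_cv: float = 0.28
    survey_weight_range: tuple[float, float] | None = None  # None -> all 1.0
    archetype_densities: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in ARCHETYPE_DENSITY.items()}
    )
    group_digestibility: Mapping[str, float] = field(
        default_factory=lambda: dict(GROUP_DIGESTIBILITY)
    )

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        if not 0 <= self.sex_ratio <= 1:
            raise ValidationError("sex_ratio must be in [0, 1]")
        shares = sum(self.occasion_protein_shares.values())
        if abs(shares - 1.0) > 1e-6:
            raise ValidationError(f"occasion protein shares must sum to 1, got {shares}")
        if set(self.occasion_protein_shares) != set(OCCASIONS):
            raise ValidationError("occasion_protein_shares must cover the 7 occasions")
        if self.between_person_cv < 0 or self.within_person_cv < 0:
            raise ValidationError("CVs must be >= 0")
        if not 0 <= self.target_animal_protein_share <= 1:
            raise ValidationError("target_animal_protein_share must be in [0, 1]")


# ---------------------------------------------------------------------------
# food table


def generate_food_table(
    cfg: GeneratorConfig,
) -> tuple[FoodTable, dict[str, ReplacementTable]]:
    """Build the synthetic food catalogue and per-scenario replacement tables.

    Deterministic given the config (the catalogue itself is fixed; only
    archetype densities and digestibility factors respond to the config).
    Returns the food table and replacement tables keyed by scenario
    (``pescetarian``, ``vegetarian``, ``vegan``; flexitarian scenarios
    use the vegetarian table).
    """
    items = []
    for (iid, name, group, arch, protein, kcal, plant, c_p, c_v, c_vn) in _CATALOG:
        density = cfg.archetype_densities[arch]
        profile = AminoAcidProfile.from_density(density, protein) if protein > 0 else (
            AminoAcidProfile(values={k: 0.0 for k in IAA_SET}, total_aa_mg=0.0)
        )
        items.append(
            FoodItem(
                item_id=iid, name=name, group=group, profile=profile,
                digestibility=cfg.group_digestibility[group],
                plant_fraction=plant, kcal_per_100g=float(kcal),
                conformity={"pescetarian": c_p, "vegetarian": c_v, "vegan": c_vn},
            )
        )
    foods = FoodTable(items)

    tables = {
        "vegetarian": ReplacementTable("vegetarian", dict(_VEGETARIAN_ENTRIES)),
        "pescetarian": ReplacementTable("pescetarian", dict(_VEGETARIAN_ENTRIES)),
        "vegan": ReplacementTable("vegan", dict(_VEGAN_ENTRIES)),
    }
    for t in tables.values():
        t.validate(foods)
    return foods, tables


def _dinner_animal_fraction(cfg: GeneratorConfig) -> float:
    """Solve the dinner main-course protein fraction from the animal-share target."""
    shares = cfg.occasion_protein_shares
    fixed_animal = sum(
        shares[occ] * _SLOT_DESIGN[occ]["animal_frac"]
        for occ in OCCASIONS
        if occ != "dinner"
    )
    dinner_share = shares["dinner"]
    if dinner_share <= 0:
        raise CalibrationError("dinner protein share must be > 0")
    frac = (cfg.target_animal_protein_share - fixed_animal) / dinner_share
    if not 0.0 <= frac <= 1.0:
        raise CalibrationError(
            f"target animal-protein share {cfg.target_animal_protein_share} is "
            f"infeasible for the occasion menu (dinner fraction {frac:.3f} "
            f"outside [0, 1])"
        )
    return frac


# ---------------------------------------------------------------------------
# recall data


def generate_recalls(cfg: GeneratorConfig, foods: FoodTable) -> RecallDataset:
    """Generate ``n_participants`` x 2 recall days x 7 occasions.

    Daily protein for person *i*, day *j* is ``weight_i x target_{sex} x
    exp(b_i + w_ij)`` with ``b_i ~ N(0, s_b)``, ``w_ij ~ N(0, s_w)`` and
    ``s = sqrt(ln(1 + cv^2))``, so the person-level median of intake per
    kg equals the per-sex target. Each occasion's protein is split into
    an animal and a plant slot; one food item per slot is drawn uniformly
    from the slot pool, and its grams are set to deliver the slot protein.
    """
    rng = np.random.default_rng(cfg.seed)
    dinner_frac = _dinner_animal_fraction(cfg)
    ff = foods.to_frame()
    protein_per_100g = (ff["total_aa_mg"] / 1000.0).to_dict()

    sigma_b = float(np.sqrt(np.log1p(cfg.between_person_cv**2)))
    sigma_w = float(np.sqrt(np.log1p(cfg.within_person_cv**2)))

    n = cfg.n_participants
    n_male = int(round(cfg.sex_ratio * n))
    sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))

    participants = []
    events = []
    days = []
    weekdays = ("mon", "tue", "wed", "thu", "fri", "sat", "sun")
    seasons = ("winter", "spring", "summer", "autumn")

    for i in range(n):
        pid = f"p{i:04d}"
        sex = str(sexes[i])
        weight = float(np.clip(
            rng.normal(cfg.weight_mean_kg[sex], cfg.weight_sd_kg[sex]), 45.0, 135.0
        ))
        height = float(np.clip(
            rng.normal(cfg.height_mean_cm[sex], cfg.height_sd_cm[sex]), 140.0, 210.0
        ))
        age = int(rng.integers(cfg.age_range[0], cfg.age_range[1] + 1))
        education = ("low", "middle", "high")[
            int(rng.choice(3, p=np.asarray(cfg.education_probs[sex]) /
                           np.sum(cfg.education_probs[sex])))
        ]
        if cfg.survey_weight_range is None:
            survey_weight = 1.0
        else:
            lo, hi = cfg.survey_weight_range
            survey_weight = float(rng.uniform(lo, hi))
        participants.append(
            {"pid": pid, "sex": sex, "age_years": age, "weight_kg": round(weight, 1),
             "height_cm": round(height, 1), "education": education,
             "survey_weight": survey_weight}
        )

        b_i = rng.normal(0.0, sigma_b) if sigma_b > 0 else 0.0
        for day_index in (1, 2):
            w_ij = rng.normal(0.0, sigma_w) if sigma_w > 0 else 0.0
            day_protein = (
                round(weight, 1) * cfg.target_intake_g_per_kg[sex] * np.exp(b_i + w_ij)
            )
            days.append(
                {"pid": pid, "day_index": day_index,
                 "weekday": str(rng.choice(weekdays)),
                 "season": str(rng.choice(seasons))}
            )
            for occ in OCCASIONS:
                occ_protein = day_protein * cfg.occasion_protein_shares[occ]
                design = _SLOT_DESIGN[occ]
                a_frac = design["animal_frac"] if occ != "dinner" else dinner_frac
                for slot, pool, frac in (
                    ("a", design["animal_pool"], a_frac),
                    ("b", design["plant_pool"], 1.0 - a_frac),
                ):
                    if not pool or frac <= 0:
                        continue
                    item_id = str(pool[int(rng.integers(len(pool)))])
                    slot_protein = occ_protein * frac
                    grams = 100.0 * slot_protein / protein_per_100g[item_id]
                    events.append(
                        {"pid": pid, "day_index": day_index, "occasion": occ,
                         "event_id": f"{pid}-d{day_index}-{occ}-{slot}",
                         "item_id": item_id, "grams": float(grams)}
                    )

    ds = RecallDataset(
        participants=pd.DataFrame(participants),
        events=pd.DataFrame(events),
        days=pd.DataFrame(days),
        provenance=f"synthetic(seed={cfg.seed}, n={n})",
    )
    ds.validate_items(foods)
    return ds


def write_study(cfg: GeneratorConfig, out_dir: str | Path) -> None:
    """Generate and write the full CSV family (foods, replacements, recalls)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    foods, tables = generate_food_table(cfg)
    write_food_table(foods, out / "foods.csv")
    replacement_tables_to_frame(tables).to_csv(out / "replacements.csv", index=False)
    ds = generate_recalls(cfg, foods)
    write_recalls(ds, out)
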