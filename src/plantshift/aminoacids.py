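"""Indispensable amino acids (IAA) and reference scoring patterns.

Protein quality scoring works on nine IAA groups. Methionine+cysteine
(sulphur amino acids, SAA) and phenylalanine+tyrosine (aromatic amino
acids, AAA) are stored pre-combined because adult scoring patterns define
their requirements jointly.

All amino-acid masses in this package are bookkept in **mg**; grams appear
only at reporting time. Protein mass is defined as the total amino-acid
mass of a food (not nitrogen x 6.25, which overestimates protein for most
food groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import SchemaError, ValidationError

#: The nine IAA scoring groups, in canonical order.
IAA_SET: tuple[str, ...] = (
    "his", "ile", "leu", "lys", "saa", "aaa", "thr", "trp", "val",
)

#: WHO/FAO/UNU (2007) adult amino-acid scoring pattern, mg per g protein.
#: This is the shipped default reference; any pattern with the nine IAA
#: keys can be supplied instead (see :func:`plantshift.composition.load_reference_pattern`).
WHO_2007_ADULT_PATTERN: dict[str, float] = {
    "his": 15.0,
    "ile": 30.0,
    "leu": 59.0,
    "lys": 45.0,
    "saa": 22.0,
    "aaa": 38.0,
    "thr": 23.0,
    "trp": 6.0,
    "val": 39.0,
}


@dataclass(frozen=True)
class ReferencePattern:
    """Amino-acid reference pattern, mg IAA per g protein.

    Meal amino-acid densities are divided by this pattern to obtain the
    per-IAA adequacy ratios whose minimum (capped at 1) is the meal's
    similarity factor.
    """

    values: Mapping[str, float]
    source_label: str = "WHO/FAO/UNU 2007 adult"

    def __post_init__(self) -> None:
        missing = [k for k in IAA_SET if k not in self.values]
        if missing:
            raise SchemaError(f"reference pattern missing IAA keys: {missing}")
        extra = set(self.values) - set(IAA_SET)
        if extra:
            raise SchemaError(f"reference pattern has unknown keys: {sorted(extra)}")
        for k in IAA_SET:
            if not self.values[k] > 0:
                raise ValidationError(
                    f"reference pattern value for {k!r} must be > 0, got {self.values[k]}"
                )

    def as_array(self) -> np.ndarray:
        """Pattern as a float array in :data:`IAA_SET` order."""
        return np.array([self.values[k] for k in IAA_SET], dtype=float)


DEFAULT_REFERENCE = ReferencePattern(WHO_2007_ADULT_PATTERN)


@dataclass(frozen=True)
class AminoAcidProfile:
    """IAA content of a food, mg per 100 g edible portion.

    ``total_aa_mg`` is the total amino-acid mass per 100 g and serves as
    the protein mass basis for all downstream protein arithmetic.
    """

    values: Mapping[str, float]
    total_aa_mg: float

    def __post_init__(self) -> None:
        missing = [k for k in IAA_SET if k not in self.values]
        if missing:
            raise SchemaError(f"amino-acid profile missing IAA keys: {missing}")
        for k in IAA_SET:
            if self.values[k] < 0:
                raise ValidationError(f"amino-acid value for {k!r} must be >= 0")
        if self.total_aa_mg < 0:
            raise ValidationError("total_aa_mg must be >= 0")
        iaa_sum = float(sum(self.values[k] for k in IAA_SET))
        # small numeric slack: IAA masses are a subset of total AA mass
        if iaa_sum > self.total_aa_mg * (1 + 1e-9) + 1e-9:
            raise ValidationError(
                f"sum of IAA ({iaa_sum:.1f} mg) exceeds total_aa_mg ({self.total_aa_mg:.1f} mg)"
            )

    @property
    def protein_g_per_100g(self) -> float:
        """Protein (total AA mass) in g per 100 g."""
        return self.total_aa_mg / 1000.0

    def as_array(self) -> np.ndarray:
        """IAA mg/100 g as a float array in :data:`IAA_SET` order."""
        return np.array([self.values[k] for k in IAA_SET], dtype=float)

    @classmethod
    def from_density(
        cls, density_mg_per_g_protein: Mapping[str, float], protein_g_per_100g: float
    ) -> "AminoAcidProfile":
        """Build a profile from IAA density (mg per g protein) and protein content."""
        values = {
            k: density_mg_per_g_protein[k] * protein_g_per_100g for k in IAA_SET
        }
        return cls(values=values, total_aa_mg=protein_g_per_100g * 1000.0)
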