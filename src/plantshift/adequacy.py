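"""Quality-adjusted EAR and prevalence of inadequate protein intake.

The classic Estimated Average Requirement for protein (0.66 g of
high-quality protein per kg body weight per day) ignores digestibility
and amino-acid composition, so it cannot be compared directly with
*utilizable* protein intake. The reference diet's own median quality loss
(1 - utilizable/total per person-day) is therefore removed from the EAR:
``adjusted_EAR = 0.66 x (1 - median_loss)``. Prevalence of inadequate
intake is the EAR cut-point method applied to the *usual-intake*
distribution of utilizable protein (g/kg bw/day): the weighted fraction
of usual intakes below the adjusted EAR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CompletenessError, DomainError, ValidationError
from ._stats import weighted_median_iqr
from .usual import UsualIntakeDistribution

logger = logging.getLogger(__name__)

#: EAR for high-quality protein, g/kg body weight/day.
REFERENCE_EAR_G_PER_KG = 0.66


@dataclass(frozen=True)
class AdequacyResult:
    scenario: str
    sex: str
    ear_reference_g_per_kg: float
    quality_loss_median: float
    quality_loss_iqr: tuple[float, float]
    adjusted_ear_g_per_kg: float
    prevalence_below_ear: float  # percent

    def __post_init__(self) -> None:
        if not 0 <= self.quality_loss_median <= 1:
            raise ValidationError("quality_loss_median must be in [0, 1]")
        if self.adjusted_ear_g_per_kg > self.ear_reference_g_per_kg + 1e-12:
            raise ValidationError("adjusted EAR cannot exceed the reference EAR")
        if not 0 <= self.prevalence_below_ear <= 100:
            raise ValidationError("prevalence must be in [0, 100]")


def quality_loss(
    day_summaries: pd.DataFrame,
    weight_col: str = "survey_weight",
) -> tuple[float, tuple[float, float]]:
    """Median (IQR) fractional loss between total and utilizable protein.

    Computed over person-days of the *reference* (original) diet:
    ``loss = 1 - utilizable_g / total_g`` per person-day, summarised as
    the survey-weighted median and (p25, p75). Zero-protein days are
    excluded with a warning.
    """
    df = day_summaries
    for col in ("total_g", "utilizable_g"):
        if col not in df.columns:
            raise ValidationError(f"day summaries missing column {col!r}")
    w = df[weight_col] if weight_col in df.columns else pd.Series(1.0, index=df.index)
    ok = df["total_g"] > 0
    if (~ok).any():
        logger.warning("quality_loss: excluding %d zero-protein day(s)", int((~ok).sum()))
    if not ok.any():
        raise ValidationError("quality_loss: no person-days with positive protein")
    loss = 1.0 - df.loc[ok, "utilizable_g"] / df.loc[ok, "total_g"]
    med, iqr = weighted_median_iqr(loss.to_numpy(), w[ok].to_numpy())
    return med, iqr


def adjusted_ear(
    reference_ear: float, median_loss: float, decimals: int = 2
) -> tuple[float, float]:
    """Quality-adjusted EAR: ``reference_ear x (1 - median_loss)``.

    Returns ``(rounded, exact)``: the reporting value rounded to
    ``decimals`` and the unrounded value used internally.
    """
    if not reference_ear > 0:
        raise DomainError("reference EAR must be > 0")
    if not 0 <= median_loss < 1:
        raise DomainError(f"median loss must be in [0, 1), got {median_loss}")
    exact = reference_ear * (1.0 - median_loss)
    return round(exact, decimals), exact


def prevalence_below(dist: UsualIntakeDistribution, cutoff: float) -> float:
    """Percent of the population with usual intake strictly below ``cutoff``.

    EAR cut-point method on the usual-intake distribution (day-level
    prevalence would overstate inadequacy). The distribution must be on
    the g/kg metric the cutoff is expressed in.
    """
    if dist.label and "per_kg" not in dist.label:
        raise DomainError(
            f"prevalence_below expects a g/kg usual-intake distribution, "
            f"got {dist.label!r}"
        )
    return 100.0 * dist.prob_below(cutoff)


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class StudyReport:
    """The assembled report tables of a full scenario study.

    * ``characteristics``: per scenario x sex — replacement counts,
      plant-protein share (%), kcal p50 (p25, p75);
    * ``daily_intake``: per scenario x sex x metric — usual-intake
      p25/p50/p75 in grams and g/kg;
    * ``occasion_intake``: per scenario x sex x main meal — p25/p50/p75
      of the three protein metrics;
    * ``adequacy``: per scenario x sex — adjusted EAR and prevalence
      below it.
    """

    characteristics: pd.DataFrame
    daily_intake: pd.DataFrame
    occasion_intake: pd.DataFrame
    adequacy: pd.DataFrame
    quality_loss_median: float
    quality_loss_iqr: tuple[float, float]
    adjusted_ear_g_per_kg: float
    adjusted_ear_exact: float

    def validate_complete(self, scenarios, sexes=("male", "female")) -> None:
        gaps = []
        for frame, name in [
            (self.characteristics, "characteristics"),
            (self.daily_intake, "daily_intake"),
            (self.adequacy, "adequacy"),
        ]:
            have = set(zip(frame["scenario"], frame["sex"]))
            for s in scenarios:
                for sex in sexes:
                    if (s, sex) not in have:
                        gaps.append(f"{name}:{s}/{sex}")
        if gaps:
            raise CompletenessError(f"report missing strata: {gaps}")


def build_report(
    *,
    scenario_order,
    replacement_counts: dict[str, dict[str, int]],
    plant_shares: dict[str, dict[str, float]],
    daily_distributions: dict[tuple[str, str, str], UsualIntakeDistribution],
    occasion_distributions: dict[tuple[str, str, str, str], UsualIntakeDistribution],
    adequacy_results: list[AdequacyResult],
    quality_loss_median: float,
    quality_loss_iqr: tuple[float, float],
    adjusted_ear_rounded: float,
    adjusted_ear_exact: float,
    kcal_distributions: dict[tuple[str, str], UsualIntakeDistribution] | None = None,
    sexes=("male", "female"),
) -> StudyReport:
    """Assemble the report tables from per-stratum computed pieces.

    ``daily_distributions`` is keyed by (scenario, sex, metric) and
    ``occasion_distributions`` by (scenario, sex, occasion, metric).
    """
    char_rows = []
    for s in scenario_order:
        for sex in sexes:
            row = {
                "scenario": s,
                "sex": sex,
                "n_replacements": replacement_counts.get(s, {}).get(sex, 0),
                "plant_protein_pct": 100.0 * plant_shares.get(s, {}).get(sex, np.nan),
            }
            if kcal_distributions and (s, sex) in kcal_distributions:
                kd = kcal_distributions[(s, sex)].summary()
                row.update(
                    kcal_p50=kd["p50"], kcal_p25=kd["p25"], kcal_p75=kd["p75"]
                )
            char_rows.append(row)
    characteristics = pd.DataFrame(char_rows)

    daily_rows = []
    for (s, sex, metric), dist in daily_distributions.items():
        daily_rows.append(
            {"scenario": s, "sex": sex, "metric": metric, **dist.summary()}
        )
    daily_intake = pd.DataFrame(daily_rows)

    occ_rows = []
    for (s, sex, occ, metric), dist in occasion_distributions.items():
        occ_rows.append(
            {"scenario": s, "sex": sex, "occasion": occ, "metric": metric,
             **dist.summary()}
        )
    occasion_intake = pd.DataFrame(occ_rows)

    adequacy = pd.DataFrame(
        [
            {
                "scenario": r.scenario,
                "sex": r.sex,
                "ear_reference_g_per_kg": r.ear_reference_g_per_kg,
                "adjusted_ear_g_per_kg": r.adjusted_ear_g_per_kg,
                "prevalence_below_ear_pct": r.prevalence_below_ear,
            }
            for r in adequacy_results
        ]
    )

    report = StudyReport(
        characteristics=characteristics,
        daily_intake=daily_intake,
        occasion_intake=occasion_intake,
        adequacy=adequacy,
        quality_loss_median=quality_loss_median,
        quality_loss_iqr=quality_loss_iqr,
        adjusted_ear_g_per_kg=adjusted_ear_rounded,
        adjusted_ear_exact=adjusted_ear_exact,
    )
    report.validate_complete(scenario_order, sexes)
    return report
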