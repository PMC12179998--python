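"""Habitual (usual) intake from repeated 24-h recalls: a one-part model.

Two recall days per person confound the habitual intake distribution with
day-to-day (within-person) noise: the distribution of single-day intakes
is wider than the distribution of long-run person means. The classic
one-part usual-intake estimator removes that extra width in four steps:

1. **transform** daily values towards normality (identity, log, or
   Box-Cox with maximum-likelihood lambda; log is the default because
   daily protein intake is positive and right-skewed);
2. **decompose** the variance of transformed values into between-person
   (``sigma2_b``) and within-person (``sigma2_w``) components with a
   survey-weighted one-way random-effects fit (persons with >= 2 days
   identify the within component);
3. **shrink** each person's mean toward the weighted stratum mean by the
   square root of the reliability ratio
   ``sqrt(sigma2_b / (sigma2_b + sigma2_w / n_i))`` — the square root
   makes the population of shrunken means have variance ``sigma2_b``, so
   they estimate the usual-intake *distribution* rather than best
   per-person predictions;
4. **back-transform** the shrunken means to the original scale.

Percentiles and tail probabilities are survey-weighted statistics of the
back-transformed usual intakes. No age trend is modelled: the target
population is a single 65-79 stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DomainError, EmptyInputError, ValidationError
from ._stats import weighted_mean_var, weighted_quantile

TRANSFORMS = ("identity", "log", "boxcox")


@dataclass(frozen=True)
class UsualIntakeDistribution:
    """Estimated habitual-intake distribution for one population stratum.

    Holds the weighted population of shrunken person-level usual intakes
    (original scale) together with the transform used and the estimated
    variance components on the transformed scale.
    """

    label: str
    transform: str
    boxcox_lambda: float | None
    between_variance: float
    within_variance: float
    usual_intakes: np.ndarray
    weights: np.ndarray
    pids: tuple[str, ...] = ()

    def percentile(self, q: float) -> float:
        """Weighted quantile of usual intakes; monotone in ``q``."""
        if not 0 < q < 1:
            raise DomainError(f"percentile level must be in (0, 1), got {q}")
        return float(weighted_quantile(self.usual_intakes, self.weights, q))

    def prob_below(self, cutoff: float) -> float:
        """Weighted fraction of usual intakes strictly below ``cutoff``."""
        below = self.usual_intakes < cutoff
        return float(self.weights[below].sum() / self.weights.sum())

    def summary(self) -> dict[str, float]:
        return {
            "p25": self.percentile(0.25),
            "p50": self.percentile(0.50),
            "p75": self.percentile(0.75),
        }


def _forward(x: np.ndarray, transform: str, lam: float | None) -> np.ndarray:
    if transform == "identity":
        return x
    if (x <= 0).any():
        raise ValidationError(
            f"{transform} transform requires strictly positive values"
        )
    if transform == "log":
        return np.log(x)
    return stats.boxcox(x, lmbda=lam)


def _inverse(y: np.ndarray, transform: str, lam: float | None) -> np.ndarray:
    if transform == "identity":
        return y
    if transform == "log":
        return np.exp(y)
    return special.inv_boxcox(y, lam)


def estimate_usual_intake(
    records: pd.DataFrame,
    transform: str = "log",
    label: str = "",
    value_col: str = "value",
    weight_col: str = "weight",
) -> UsualIntakeDistribution:
    """Estimate the usual-intake distribution from person-day records.

    Parameters
    ----------
    records
        DataFrame with columns ``pid``, ``value`` (one row per
        person-day) and ``weight`` (per-person survey weight; must be
        constant within person).
    transform
        ``identity``, ``log`` (default) or ``boxcox``.
    """
    if transform not in TRANSFORMS:
        raise DomainError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")
    df = records.copy()
    for col in ("pid", value_col):
        if col not in df.columns:
            raise ValidationError(f"records missing column {col!r}")
    if weight_col not in df.columns:
        df[weight_col] = 1.0
    if df["pid"].nunique() < 2:
        raise EmptyInputError("usual-intake estimation needs >= 2 persons")

    lam: float | None = None
    if transform == "boxcox":
        vals = df[value_col].to_numpy(dtype=float)
        if (vals <= 0).any():
            raise ValidationError("boxcox transform requires strictly positive values")
        _, lam = stats.boxcox(vals)
    df["_t"] = _forward(df[value_col].to_numpy(dtype=float), transform, lam)

    per = df.groupby("pid").agg(
        mean_t=("_t", "mean"),
        n_days=("_t", "size"),
        ss_within=("_t", lambda s: float(((s - s.mean()) ** 2).sum())),
        weight=(weight_col, "first"),
    )
    if (per["weight"] <= 0).any():
        raise ValidationError("survey weights must be > 0")

    multi = per[per["n_days"] >= 2]
    if multi.empty:
        raise ValidationError(
            "within-person variance inestimable: every person has a single day"
        )
    w_multi = multi["weight"].to_numpy()
    sigma2_w = float(
        (w_multi * multi["ss_within"].to_numpy()).sum()
        / (w_multi * (multi["n_days"].to_numpy() - 1)).sum()
    )

    w = per["weight"].to_numpy(dtype=float)
    ybar = per["mean_t"].to_numpy(dtype=float)
    n_i = per["n_days"].to_numpy(dtype=float)
    mu, var_means = weighted_mean_var(ybar, w)
    mean_inv_n = float((w / n_i).sum() / w.sum())
    sigma2_b = max(var_means - sigma2_w * mean_inv_n, 0.0)

    denom = sigma2_b + sigma2_w / n_i
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, np.sqrt(np.where(denom > 0, sigma2_b / denom, 0.0)), 0.0)
    usual_t = mu + (ybar - mu) * ratio
    usual = _inverse(usual_t, transform, lam)

    return UsualIntakeDistribution(
        label=label,
        transform=transform,
        boxcox_lambda=lam,
        between_variance=sigma2_b,
        within_variance=sigma2_w,
        usual_intakes=np.asarray(usual, dtype=float),
        weights=w,
        pids=tuple(per.index.astype(str)),
    )
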