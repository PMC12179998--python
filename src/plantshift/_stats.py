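"""Survey-weighted quantiles and moments.

The weighted quantile generalises the linear-interpolation (type-7)
sample quantile. Weights are first normalised by their minimum, so each
observation stands for ``w/min(w)`` copies; an observation then occupies
a *pair* of interpolation nodes marking its first and last copy's
plotting position. With unit weights this reduces exactly to
``numpy.quantile`` (linear), and doubling one observation's weight is
exactly equivalent to duplicating the observation. Quantiles are
invariant to rescaling all weights by a constant.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError


def weighted_quantile(values, weights, q) -> np.ndarray | float:
    """Weighted quantile(s) with linear interpolation.

    With min-normalised weights ``w'`` (total ``W'``) the sorted
    observation *i* contributes nodes at positions
    ``c'_i / (W' - 1)`` and ``(c'_i + w'_i - 1) / (W' - 1)`` (``c'_i`` =
    cumulative normalised weight before *i*), both carrying value
    ``v_i``; quantiles interpolate linearly between nodes.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise DomainError("weighted_quantile: empty input")
    if v.shape != w.shape:
        raise DomainError("weighted_quantile: values and weights differ in length")
    if (w <= 0).any():
        raise DomainError("weighted_quantile: weights must be > 0")
    scalar = np.isscalar(q)
    qs = np.atleast_1d(np.asarray(q, dtype=float))
    if ((qs <= 0) | (qs >= 1)).any():
        raise DomainError("quantile levels must be in (0, 1)")

    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    wn = w / w.min()
    total = wn.sum()
    if total - 1 <= 0:  # single (effective) observation
        out = np.full(qs.shape, v[-1])
        return float(out[0]) if scalar else out
    before = np.concatenate(([0.0], np.cumsum(wn)[:-1]))
    start = before / (total - 1)
    end = (before + wn - 1) / (total - 1)
    positions = np.empty(2 * v.size)
    node_values = np.empty(2 * v.size)
    positions[0::2], positions[1::2] = start, end
    node_values[0::2] = node_values[1::2] = v
    out = np.interp(qs, positions, node_values)
    return float(out[0]) if scalar else out


def weighted_median_iqr(values, weights) -> tuple[float, tuple[float, float]]:
    """Weighted median and (p25, p75)."""
    p25, p50, p75 = weighted_quantile(values, weights, [0.25, 0.5, 0.75])
    return float(p50), (float(p25), float(p75))


def weighted_mean_var(values, weights, ddof_correction: bool = True) -> tuple[float, float]:
    """Weighted mean and bias-corrected weighted variance.

    Weights carry frequency semantics (a weight of 2 means the
    observation stands for two population units), so the correction is
    ``var = sum w (x - m)^2 / (W - 1)`` — exactly the ``ddof=1`` variance
    of the weight-expanded sample for integer weights.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    mean = float((w * v).sum() / total)
    dev2 = (w * (v - mean) ** 2).sum()
    if ddof_correction:
        var = float(dev2 / (total - 1)) if total > 1 else 0.0
    else:
        var = float(dev2 / total)
    return mean, max(var, 0.0)
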