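"""Quantile normalization of log-intensity ratios to a scaled t distribution.

Raw log-intensity-ratio (LIR) tracks from different array platforms have
different noise scales and tail behaviour.  To make one set of calling
cutoffs portable across platforms, LIR values are quantile-normalized to a
common target: a Student t distribution with a small number of degrees of
freedom (heavy tails survive normalization of real array data), rescaled so
that its median absolute deviation (MAD) equals a fixed value.  The default
target is t with 5 df scaled to MAD 0.2.

The transform is rank-based and monotone: value with rank r out of n maps to
the target quantile at plotting position (r - 0.5)/n.  Ties receive average
ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["NormalizationSpec", "target_quantile", "quantile_normalize"]


@dataclass(frozen=True)
class NormalizationSpec:
    """Target distribution for quantile normalization.

    Parameters
    ----------
    df : int
        Degrees of freedom of the target t distribution.
    target_mad : float
        Median absolute deviation of the scaled target.  The scale
        multiplier applied to standard-t quantiles is
        ``target_mad / t_{df}^{-1}(0.75)`` because the population MAD of a
        symmetric distribution equals its 75th percentile.
    """

    df: int = 5
    target_mad: float = 0.2
    scale: float = field(init=False)

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError(f"df must be a positive integer, got {self.df}")
        if self.target_mad <= 0:
            raise ValueError(f"target_mad must be positive, got {self.target_mad}")
        object.__setattr__(
            self, "scale", self.target_mad / stats.t.ppf(0.75, self.df)
        )


def target_quantile(p, spec: NormalizationSpec = NormalizationSpec()):
    """Quantile function of the scaled target distribution.

    Accepts a scalar or array of probabilities in the open interval (0, 1)
    and returns ``scale * t_df^{-1}(p)``.  Strictly increasing in ``p`` and
    antisymmetric about p = 0.5.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    q = spec.scale * stats.t.ppf(p, spec.df)
    return float(q) if q.ndim == 0 else q


def quantile_normalize(values, spec: NormalizationSpec = NormalizationSpec()):
    """Quantile-normalize a vector onto the scaled target distribution.

    Each value of rank r (1-based, average ranks for ties) among n maps to
    ``target_quantile((r - 0.5) / n)``.  The map is rank-preserving, and the
    sample MAD of the output converges to ``spec.target_mad`` as n grows.

    Raises
    ------
    ValueError
        If fewer than two values are supplied or any value is non-finite
        (the message names the first offending index).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-D vector of LIR values")
    n = values.size
    if n < 2:
        raise ValueError(f"need at least 2 values to normalize, got {n}")
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValueError(f"non-finite LIR value at index {bad[0]}")
    ranks = stats.rankdata(values, method="average")
    return target_quantile((ranks - 0.5) / n, spec)
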