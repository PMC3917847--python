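"""The univariate CNV score S = mu * m^alpha, its cutoff function, and
estimation of the exponent alpha from validation-labelled calls.

A called CNV is characterized by two numbers: its intensity mu (absolute
median normalized LIR over its probes) and its length m (probe count).
The score S = mu * m^alpha collapses the two into one ranking statistic;
alpha = 0.5 corresponds to statistical information (a t-statistic for the
region mean is proportional to mu * sqrt(m)).  The exponent can instead be
fit empirically: given calls with known experimental validation status, a
logistic regression of validation on ln(mu) and ln(m) has a linear decision
boundary in (ln m, ln mu) space whose slope is -alpha_hat with
alpha_hat = b_lnm / b_lnmu.

During backward elimination (see :mod:`cnvbeast.engine`) a jump of height
beta with gap g is kept when |beta| * g^alpha >= C(g), where the cutoff
function C enforces three rules at once: no call shorter than ``m_min``
probes (infinite wall), a flat user score threshold on intermediate
lengths, and an intensity floor ``mu_min`` for calls longer than ``m_max``
probes (so that very long, very faint drifts are not called).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "CutoffParams",
    "ValidationRecord",
    "ScoreFit",
    "cnv_score",
    "cutoff",
    "fit_score_exponent",
]

#: Default very large constant for the short-gap wall of C(g); must exceed
#: any |LIR| in the data by many orders of magnitude.
BIG_M = 1e16


@dataclass(frozen=True)
class CutoffParams:
    """Knobs of the cutoff function C(g) and the score threshold.

    score_min is the user threshold (no universal default exists; the CLI
    uses 2.5).  Defaults for the structural parameters: m_min=6, m_max=30,
    mu_min=0.25, alpha=0.5.
    """

    score_min: float = 2.5
    m_min: int = 6
    m_max: int = 30
    mu_min: float = 0.25
    alpha: float = 0.5
    big_M: float = BIG_M

    def __post_init__(self) -> None:
        if self.m_min < 1 or self.m_max < self.m_min:
            raise ValueError("require 1 <= m_min <= m_max")
        if self.score_min <= 0 or self.mu_min <= 0:
            raise ValueError("score_min and mu_min must be positive")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if self.big_M < 1e6:
            raise ValueError("big_M must be very large")


def cnv_score(mu: float, m: float, alpha: float = 0.5) -> float:
    """Score S = mu * m**alpha of a call with intensity mu and m probes."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if mu < 0:
        raise ValueError(f"mu must be nonnegative, got {mu}")
    return mu * m**alpha


def cutoff(g: float, params: CutoffParams) -> float:
    """Gap-dependent keep threshold C(g) for a jump with gap g.

    Piecewise: big_M below m_min (nothing short survives); the flat score
    threshold on [m_min, m_max]; max(score_min, mu_min * g^alpha) beyond
    m_max, so a kept long jump has both score >= score_min and
    |beta| >= mu_min.
    """
    if g < 1:
        raise ValueError(f"gap must be >= 1, got {g}")
    if g < params.m_min:
        return params.big_M
    if g <= params.m_max:
        return params.score_min
    return max(params.score_min, params.mu_min * g**params.alpha)


@dataclass(frozen=True)
class ValidationRecord:
    """One called CNV with known experimental validation status."""

    mu: float
    m: int
    validated: int

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.validated not in (0, 1):
            raise ValueError("validated must be 0 or 1")


@dataclass(frozen=True)
class ScoreFit:
    """Fitted logistic model logit P(V=1) = b0 + b_lnmu*ln(mu) + b_lnm*ln(m).

    alpha_hat = b_lnm / b_lnmu with a 95% delta-method CI computed on the
    log scale.  The decision boundary (logit = 0) in (ln m, ln mu) space is
    ln mu = boundary_intercept + boundary_slope * ln m with
    boundary_slope = -alpha_hat and boundary_intercept = -b0 / b_lnmu —
    i.e. a contour of constant score S = mu * m^alpha_hat.
    """

    b0: float
    b_lnmu: float
    b_lnm: float
    alpha_hat: float
    ci_low: float
    ci_high: float
    boundary_intercept: float
    boundary_slope: float
    n_records: int


def fit_score_exponent(
    records: Sequence[ValidationRecord], alpha_fixed: float | None = None
) -> ScoreFit:
    """Estimate the score exponent from validation-labelled calls.

    Fits the logistic model by maximum likelihood, treating records as
    independent (calls from one individual, and overlapping calls across
    individuals, are deliberately not clustered).  Returns the coefficients,
    alpha_hat = b_lnm / b_lnmu, and a 95% CI from the delta method applied
    to ln(alpha_hat): with gradient (d/db_lnmu, d/db_lnm) =
    (-1/b_lnmu, 1/b_lnm), var(ln alpha_hat) = grad' Cov grad, and the CI is
    exp(ln alpha_hat -/+ 1.96 sd).

    With ``alpha_fixed`` the restricted model
    logit P = b0 + b * (ln mu + alpha_fixed * ln m) is fit instead (the
    single-predictor fit used to compare against a postulated exponent);
    alpha_hat is then alpha_fixed and the CI degenerates to it.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 validation records")
    v = np.array([r.validated for r in records], dtype=float)
    if v.min() == v.max():
        raise ValueError("validation outcomes are single-class; cannot fit")
    ln_mu = np.log([r.mu for r in records])
    ln_m = np.log([r.m for r in records])

    if alpha_fixed is not None:
        X = sm.add_constant(ln_mu + alpha_fixed * ln_m)
        res = _fit_logit(v, X)
        b0, b = res.params
        return ScoreFit(
            b0=b0,
            b_lnmu=b,
            b_lnm=alpha_fixed * b,
            alpha_hat=alpha_fixed,
            ci_low=alpha_fixed,
            ci_high=alpha_fixed,
            boundary_intercept=-b0 / b,
            boundary_slope=-alpha_fixed,
            n_records=len(records),
        )

    X = sm.add_constant(np.column_stack([ln_mu, ln_m]))
    res = _fit_logit(v, X)
    b0, b_lnmu, b_lnm = res.params
    cov = np.asarray(res.cov_params())[1:, 1:]
    alpha_hat = b_lnm / b_lnmu
    if alpha_hat <= 0:
        # log-scale delta method undefined; report a degenerate CI
        ci_low = ci_high = math.nan
    else:
        grad = np.array([-1.0 / b_lnmu, 1.0 / b_lnm])
        var_ln = float(grad @ cov @ grad)
        sd_ln = math.sqrt(max(var_ln, 0.0))
        ci_low = alpha_hat * math.exp(-1.959963984540054 * sd_ln)
        ci_high = alpha_hat * math.exp(1.959963984540054 * sd_ln)
    return ScoreFit(
        b0=b0,
        b_lnmu=b_lnmu,
        b_lnm=b_lnm,
        alpha_hat=alpha_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        boundary_intercept=-b0 / b_lnmu,
        boundary_slope=-alpha_hat,
        n_records=len(records),
    )


def _fit_logit(v, X):
    try:
        res = sm.Logit(v, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge (quasi-separation?)")
    return res
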