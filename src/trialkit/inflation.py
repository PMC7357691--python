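"""Exact type-I-error inflation from an unplanned sample-size increase.

A trial runs a two-sided log-rank test at the planned size N1; finding no
significance, it enrolls up to N2 and tests again at the same unadjusted
critical value.  Under the null the two log-rank statistics (Z1, Z2) are
asymptotically bivariate normal with unit variances and correlation

    rho = sqrt(D1 / D2),      D_k = d * N_k,

where d is the expected event proportion (so D_k is the expected number of
events at each analysis).  The overall two-sided type-I error of the naive
two-look procedure is

    alpha_overall = 1 - P(|Z1| <= c, |Z2| <= c),   c = z_{1 - alpha/2},

computed here by deterministic one-dimensional Gaussian quadrature of the
bivariate-normal rectangle probability (absolute tolerance well below 1e-6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import norm

from .errors import ValidationError


@dataclass(frozen=True)
class InflationResult:
    """Overall type-I error of the naive two-stage procedure with its inputs."""

    alpha_overall: float
    correlation: float
    critical_value: float
    n1: int
    n2: int
    d: float
    alpha: float

    def to_dict(self) -> dict:
        return {
            "alpha_overall": self.alpha_overall,
            "correlation": self.correlation,
            "critical_value": self.critical_value,
            "n1": self.n1,
            "n2": self.n2,
            "d": self.d,
            "alpha": self.alpha,
        }


def both_within_rectangle(rho: float, c: float) -> float:
    """P(|Z1| <= c, |Z2| <= c) for standard bivariate normal with correlation rho.

    Conditioning on Z1 = z reduces the rectangle probability to a 1-D
    integral of phi(z) * [Phi((c - rho z)/s) - Phi((-c - rho z)/s)],
    s = sqrt(1 - rho^2), evaluated by adaptive quadrature.
    """
    if not (-1.0 <= rho <= 1.0):
        raise ValidationError("correlation must lie in [-1, 1]")
    if abs(rho) >= 1.0 - 1e-12:
        inner = norm.cdf(c) - norm.cdf(-c)
        return float(inner)

    s = np.sqrt(1.0 - rho * rho)

    def integrand(z):
        return norm.pdf(z) * (norm.cdf((c - rho * z) / s) - norm.cdf((-c - rho * z) / s))

    value, _ = integrate.quad(integrand, -c, c, epsabs=1e-12, epsrel=1e-12, limit=200)
    return float(value)


def overall_type1_error(n1: int, n2: int, d: float, alpha: float = 0.05) -> InflationResult:
    """Overall two-sided type-I error when testing at N1 and again at N2.

    Parameters
    ----------
    n1, n2 : planned and enlarged sample sizes, ``n2 >= n1``
    d : expected proportion of subjects with an event, in (0, 1]
    alpha : nominal two-sided significance level of each look

    Returns a result bounded by ``alpha`` (identical looks, rho = 1) and
    ``1 - (1 - alpha)^2`` (independent looks, rho = 0).
    """
    n1, n2 = int(n1), int(n2)
    if n2 < n1 or n1 <= 0:
        raise ValidationError("require 0 < N1 <= N2")
    if not (0.0 < d <= 1.0):
        raise ValidationError("event proportion d must lie in (0, 1]")
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")

    d1, d2 = d * n1, d * n2
    rho = float(np.sqrt(d1 / d2))
    c = float(norm.ppf(1.0 - alpha / 2.0))
    alpha_overall = 1.0 - both_within_rectangle(rho, c)
    return InflationResult(
        alpha_overall=float(alpha_overall),
        correlation=rho,
        critical_value=c,
        n1=n1,
        n2=n2,
        d=float(d),
        alpha=float(alpha),
    )
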