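"""Closed-form between-cluster heterogeneity measures for two-level logistic regression.

For a random-intercept logistic model

    logit Pr(Y_hi = 1 | u_h) = beta' x_hi + alpha * x_h + u_h,
    u_h ~ Normal(0, sigma2_u),

where ``x_h`` is a covariate constant within cluster ``h``, four scalar
summaries of the cluster structure are in common use:

* **ICC** (intra-class correlation coefficient, also called the variance
  partition coefficient): the share of latent outcome variance attributable
  to clusters, ``sigma2_u / (sigma2_u + pi^2/3)``.  The level-1 variance is
  the variance of the standard logistic distribution, ``pi^2/3``, a property
  of the link function, not a tunable quantity.
* **MOR** (median odds ratio): the median of the odds ratios comparing two
  covariate-identical individuals from two randomly chosen clusters, ordered
  so the ratio is at least 1: ``exp(sqrt(2*sigma2_u) * PhiInv(0.75))``.
* **IOR** (interval odds ratio, conventionally at 80% mass): the central
  interval of the distribution of odds ratios between individuals in clusters
  one unit apart on the cluster-level covariate,
  ``exp(alpha -/+ sqrt(2*sigma2_u) * z)`` with ``z`` the normal quantile at
  ``(1 + mass)/2``.  If the interval contains 1, residual cluster
  heterogeneity dominates the covariate effect.
* **SOI** (sorting-out index): the proportion of those pairwise odds ratios
  exceeding 1, ``Phi(alpha / sqrt(2*sigma2_u))``.  50% means the cluster-level
  covariate is uninformative relative to the residual heterogeneity; values
  near 0% or 100% mean it dominates.

All functions compute at full floating-point precision.  The rounded
constants that circulate in the applied literature (0.6745, 1.2816, and the
collapsed form ``exp(0.95*sqrt(sigma2_u))`` for the MOR) are available as
explicit modes so that numbers printed from those forms can be reproduced
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import norm

__all__ = [
    "LOGISTIC_LEVEL1_VARIANCE",
    "MOR_MODES",
    "HeterogeneityReport",
    "icc",
    "mor",
    "ior",
    "soi",
    "report",
    "true_values_table",
]

#: Variance of the standard logistic distribution; the level-1 latent
#: residual variance implied by the logit link.
LOGISTIC_LEVEL1_VARIANCE: float = math.pi**2 / 3.0

#: Recognised modes for the MOR constant.
MOR_MODES = ("exact", "printed_0p6745", "printed_0p95")

_PHI_INV_075 = float(norm.ppf(0.75))  # 0.6744897501960817


def _check_sigma2(sigma2_u: float) -> float:
    sigma2_u = float(sigma2_u)
    if not math.isfinite(sigma2_u) or sigma2_u < 0.0:
        raise ValueError(f"sigma2_u must be a finite non-negative number, got {sigma2_u!r}")
    return sigma2_u


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not math.isfinite(alpha):
        raise ValueError(f"alpha must be finite, got {alpha!r}")
    return alpha


def icc(sigma2_u: float) -> float:
    """Intra-class correlation on the latent (logit) scale.

    Parameters
    ----------
    sigma2_u
        Between-cluster variance of the random intercept (logit scale).

    Returns
    -------
    float
        ``sigma2_u / (sigma2_u + pi^2/3)``, in ``[0, 1)``.
    """
    sigma2_u = _check_sigma2(sigma2_u)
    return sigma2_u / (sigma2_u + LOGISTIC_LEVEL1_VARIANCE)


def mor(sigma2_u: float, mode: str = "exact") -> float:
    """Median odds ratio for a normal random intercept.

    Parameters
    ----------
    sigma2_u
        Between-cluster variance on the logit scale.
    mode
        ``"exact"`` uses the full-precision quantile Phi^-1(0.75);
        ``"printed_0p6745"`` uses the rounded constant 0.6745;
        ``"printed_0p95"`` uses the collapsed rounded form
        ``exp(0.95 * sqrt(sigma2_u))``.

    Returns
    -------
    float
        An odds ratio >= 1; equals 1 exactly when ``sigma2_u`` is 0.
    """
    sigma2_u = _check_sigma2(sigma2_u)
    if mode == "exact":
        return math.exp(math.sqrt(2.0 * sigma2_u) * _PHI_INV_075)
    if mode == "printed_0p6745":
        return math.exp(math.sqrt(2.0 * sigma2_u) * 0.6745)
    if mode == "printed_0p95":
        return math.exp(0.95 * math.sqrt(sigma2_u))
    raise ValueError(f"unknown MOR mode {mode!r}; expected one of {MOR_MODES}")


def ior(
    alpha: float, sigma2_u: float, interval_mass: float = 0.80
) -> tuple[float, float]:
    """Interval odds ratio for a cluster-level covariate.

    Returns the central ``interval_mass`` interval of the distribution of
    odds ratios between individuals whose clusters differ by one unit of the
    cluster-level covariate, ``exp(alpha -/+ sqrt(2*sigma2_u) * z)`` with
    ``z`` the standard-normal quantile at ``(1 + interval_mass)/2``
    (1.2816 at four decimals for the conventional 80% mass).

    The interval is log-symmetric about ``alpha``:
    ``log(lower) + log(upper) == 2*alpha``.  At ``sigma2_u == 0`` it
    degenerates to the point ``(exp(alpha), exp(alpha))``.
    """
    alpha = _check_alpha(alpha)
    sigma2_u = _check_sigma2(sigma2_u)
    interval_mass = float(interval_mass)
    if not 0.0 < interval_mass < 1.0:
        raise ValueError(f"interval_mass must be in (0, 1), got {interval_mass!r}")
    z = float(norm.ppf(0.5 + interval_mass / 2.0))
    half_width = math.sqrt(2.0 * sigma2_u) * z
    return math.exp(alpha - half_width), math.exp(alpha + half_width)


def soi(alpha: float, sigma2_u: float) -> float:
    """Sorting-out index: proportion of pairwise odds ratios exceeding 1.

    ``Phi(alpha / sqrt(2*sigma2_u))``.  At ``sigma2_u == 0`` the
    distribution of pairwise odds ratios degenerates and the limit is
    returned: 1 for ``alpha > 0``, 0 for ``alpha < 0``, 0.5 for
    ``alpha == 0``.
    """
    alpha = _check_alpha(alpha)
    sigma2_u = _check_sigma2(sigma2_u)
    if sigma2_u == 0.0:
        if alpha > 0.0:
            return 1.0
        if alpha < 0.0:
            return 0.0
        return 0.5
    return float(norm.cdf(alpha / math.sqrt(2.0 * sigma2_u)))


@dataclass(frozen=True)
class HeterogeneityReport:
    """The four heterogeneity measures computed from one (alpha, sigma2_u) pair."""

    alpha: float
    sigma2_u: float
    icc: float
    mor: float
    soi: float
    ior_lower: float
    ior_upper: float
    interval_mass: float = 0.80
    mor_mode: str = "exact"

    def ior_contains_one(self) -> bool:
        """Whether 1 lies inside the interval odds ratio (boundary inclusive)."""
        return self.ior_lower <= 1.0 <= self.ior_upper


def report(
    alpha: float,
    sigma2_u: float,
    interval_mass: float = 0.80,
    mor_mode: str = "exact",
) -> HeterogeneityReport:
    """Compute all four measures consistently from the same inputs."""
    lower, upper = ior(alpha, sigma2_u, interval_mass)
    return HeterogeneityReport(
        alpha=float(alpha),
        sigma2_u=float(sigma2_u),
        icc=icc(sigma2_u),
        mor=mor(sigma2_u, mor_mode),
        soi=soi(alpha, sigma2_u),
        ior_lower=lower,
        ior_upper=upper,
        interval_mass=float(interval_mass),
        mor_mode=mor_mode,
    )


def true_values_table(
    sigma2_list: Iterable[float] | Sequence[float],
    beta0: float = 0.5,
    beta1: float = -1.5,
    beta2: float = 0.3,
    alpha: float = -0.3,
    interval_mass: float = 0.80,
    mor_mode: str = "exact",
) -> pd.DataFrame:
    """Analytic true values of the measures over a list of variances.

    One row per between-cluster variance, with the fixed effects echoed.
    Values are returned at full precision; rounding for display is left to
    the caller (see :func:`clusterhet.study.render_tables`).
    """
    rows = []
    for sigma2_u in sigma2_list:
        rep = report(alpha, sigma2_u, interval_mass=interval_mass, mor_mode=mor_mode)
        rows.append(
            {
                "sigma2_u": float(sigma2_u),
                "beta0": float(beta0),
                "beta1": float(beta1),
                "beta2": float(beta2),
                "alpha": float(alpha),
                "icc": rep.icc,
                "mor": rep.mor,
                "soi": rep.soi,
                "ior_lower": rep.ior_lower,
                "ior_upper": rep.ior_upper,
            }
        )
    return pd.DataFrame(rows)
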