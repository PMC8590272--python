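"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the measures oracle
recovers normal quantiles by root-finding on the normal CDF instead of
calling ``ppf``; the likelihood oracle integrates the per-cluster integrand
on a dense trapezoid grid instead of Gauss-Hermite quadrature.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, minimize
from scipy.special import logsumexp
from scipy.stats import norm


def quantile_by_root_finding(p: float) -> float:
    """Standard-normal quantile found by bisection on the CDF."""
    return brentq(lambda x: norm.cdf(x) - p, -40, 40, xtol=1e-14, rtol=1e-15)


def mor_oracle(sigma2_u: float) -> float:
    """Median odds ratio from first principles.

    The log odds ratio between two random clusters, ordered, is |d| with
    d ~ N(0, 2*sigma2_u); the median m of |d| solves P(|d| <= m) = 1/2.
    """
    if sigma2_u == 0:
        return 1.0
    sd = math.sqrt(2.0 * sigma2_u)
    m = brentq(
        lambda x: (norm.cdf(x / sd) - norm.cdf(-x / sd)) - 0.5,
        0.0, 60.0 * sd, xtol=1e-15, rtol=1e-15,
    )
    return math.exp(m)


def ior_oracle(alpha: float, sigma2_u: float, mass: float) -> tuple[float, float]:
    """Central interval of exp(alpha + d), d ~ N(0, 2*sigma2_u), by CDF inversion."""
    if sigma2_u == 0:
        return math.exp(alpha), math.exp(alpha)
    sd = math.sqrt(2.0 * sigma2_u)
    lo_p, hi_p = (1.0 - mass) / 2.0, (1.0 + mass) / 2.0
    lo = brentq(lambda x: norm.cdf((x - alpha) / sd) - lo_p, alpha - 60 * sd,
                alpha + 60 * sd, xtol=1e-14, rtol=1e-15)
    hi = brentq(lambda x: norm.cdf((x - alpha) / sd) - hi_p, alpha - 60 * sd,
                alpha + 60 * sd, xtol=1e-14, rtol=1e-15)
    return math.exp(lo), math.exp(hi)


def soi_oracle(alpha: float, sigma2_u: float) -> float:
    """P(alpha + d > 0) by numerical integration of the normal density."""
    if sigma2_u == 0:
        return 1.0 if alpha > 0 else (0.0 if alpha < 0 else 0.5)
    sd = math.sqrt(2.0 * sigma2_u)
    val, _ = quad(lambda d: norm.pdf(d, 0.0, sd), -alpha, np.inf, limit=500)
    return val


def dense_marginal_loglik(
    dataset, beta, sigma_u, n_grid: int = 40001, half_width: float = 12.0
) -> float:
    """Marginal log-likelihood by dense trapezoid integration over u.

    Integrates each cluster's integrand on a uniform grid spanning
    ``half_width`` random-effect standard deviations, in log space.
    """
    df = dataset.data
    beta = np.asarray(beta, dtype=float)
    X = np.column_stack([
        np.ones(len(df)),
        df["x1"].to_numpy(float),
        df["x2"].to_numpy(float),
        df["xh"].to_numpy(float),
    ])
    fixed = X @ beta
    y = df["y"].to_numpy(float)
    ids = df["cluster_id"].to_numpy()
    if sigma_u == 0:
        return float(np.sum(y * fixed - np.logaddexp(0.0, fixed)))
    u = np.linspace(-half_width * sigma_u, half_width * sigma_u, n_grid)
    h = u[1] - u[0]
    log_w = np.full(n_grid, math.log(h))
    log_w[0] -= math.log(2.0)
    log_w[-1] -= math.log(2.0)
    total = 0.0
    for cid in np.unique(ids):
        mask = ids == cid
        eta = fixed[mask][:, None] + u[None, :]
        log_f = np.sum(
            y[mask][:, None] * eta - np.logaddexp(0.0, eta), axis=0
        ) + norm.logpdf(u, 0.0, sigma_u)
        total += logsumexp(log_f + log_w)
    return float(total)


def grid_search_argmax(dataset, lattice=None, sigma_lattice=(0.05, 0.4, 1.0, 2.0)):
    """Brute-force ML: coarse lattice over (beta, alpha, sigma) refined locally.

    Evaluates the dense-integration log-likelihood (independent of the AGQ
    path) on a coarse parameter lattice, then polishes the best point with
    Nelder-Mead.  Returns (theta, loglik) with theta = (beta0..beta2, alpha,
    sigma_u).
    """
    lattice = lattice if lattice is not None else (-1.5, 0.0, 1.5)

    def negll(theta):
        sigma = abs(theta[4])
        try:
            return -dense_marginal_loglik(dataset, theta[:4], sigma,
                                          n_grid=4001, half_width=10.0)
        except FloatingPointError:
            return np.inf

    best, best_val = None, np.inf
    for b0 in lattice:
        for b1 in lattice:
            for b2 in lattice:
                for a in lattice:
                    for s in sigma_lattice:
                        theta = np.array([b0, b1, b2, a, s])
                        val = negll(theta)
                        if val < best_val:
                            best, best_val = theta, val
    res = minimize(negll, best, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000})
    theta = res.x.copy()
    theta[4] = abs(theta[4])
    ll = dense_marginal_loglik(dataset, theta[:4], theta[4])
    return theta, float(ll)
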