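"""Maximum-likelihood fitting of the two-level random-intercept logistic model.

The marginal likelihood integrates the cluster intercept out of the
conditional Bernoulli likelihood,

    L_h(beta, alpha, sigma_u) =
        integral  prod_i expit(eta_hi + u)^y_hi (1-expit(eta_hi + u))^(1-y_hi)
                  * phi(u; 0, sigma_u^2)  du,

and is evaluated cluster by cluster with adaptive Gauss-Hermite quadrature:
nodes are centred at each cluster's conditional mode (found by a damped
Newton iteration on the concave log-integrand) and scaled by the curvature
there.  One quadrature node is exactly the Laplace approximation; 15 nodes
(the default) is accurate to well beyond optimizer tolerance for the cluster
sizes this package targets.  At ``sigma_u == 0`` the integral collapses and
the marginal likelihood equals the ordinary logistic likelihood, which is
used directly.

The variance component is optimised on the standard-deviation scale over
``[0, inf)`` rather than ``log sigma``, so a boundary estimate
``sigma_hat = 0`` (no detectable clustering) is attainable and is flagged.
Standard errors come from the observed information (numerical Hessian of the
marginal log-likelihood); at the boundary the information matrix is singular
and standard errors are reported as absent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from . import measures
from .simulate import ClusteredBinaryDataset

__all__ = [
    "FitOptions",
    "FitResult",
    "NumericalError",
    "marginal_loglik",
    "fit",
    "fit_then_report",
]

_SIGMA_BOUNDARY_SCAN = 0.05  # below this sigma, compare against the sigma=0 fit
_SIGMA_UPPER = 15.0  # generous bound on sigma_u for the optimizer
DEFAULT_COVARIATES = ("x1", "x2", "xh")


class NumericalError(RuntimeError):
    """The optimiser or a numerical routine failed irrecoverably."""


@dataclass(frozen=True)
class FitOptions:
    """Knobs of the maximum-likelihood fit.

    ``n_quad_points`` must be a positive odd integer; ``laplace_only`` forces
    a single node (the Laplace approximation).  ``sigma_start`` is the fixed
    deterministic starting value for sigma_u, so fits are reproducible
    without random restarts.
    """

    n_quad_points: int = 15
    max_iter: int = 200
    grad_tol: float = 1e-6
    sigma_start: float = 0.3
    laplace_only: bool = False

    def __post_init__(self) -> None:
        if self.n_quad_points < 1 or self.n_quad_points % 2 == 0:
            raise ValueError(
                f"n_quad_points must be a positive odd integer, got {self.n_quad_points}"
            )
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    @property
    def effective_quad_points(self) -> int:
        return 1 if self.laplace_only else self.n_quad_points


@dataclass
class FitResult:
    """Maximum-likelihood estimates for the random-intercept logistic model.

    ``beta_hat`` holds the coefficients of the intercept and any
    individual-level covariates, in ``param_names`` order; ``alpha_hat`` is
    the cluster-level covariate coefficient (``None`` when the model has no
    cluster covariate).  ``standard_errors`` is aligned with
    ``param_names + ('sigma_u',)`` and is ``None`` at a boundary fit.
    """

    param_names: tuple[str, ...]
    beta_hat: np.ndarray
    alpha_hat: float | None
    sigma2_u_hat: float
    standard_errors: np.ndarray | None
    loglik: float
    converged: bool
    boundary: bool
    n_clusters_used: int
    n_obs_used: int
    n_quad_points: int


def _cluster_codes(df) -> np.ndarray:
    ids = df["cluster_id"].to_numpy()
    _, codes = np.unique(ids, return_inverse=True)
    return codes


class _MarginalLoglik:
    """Callable computing the AGQ marginal log-likelihood for one dataset.

    Caches the last conditional modes to warm-start the Newton iteration on
    subsequent calls (the optimiser evaluates at nearby parameter values).
    """

    def __init__(
        self, y: np.ndarray, X: np.ndarray, codes: np.ndarray, n_quad: int
    ) -> None:
        self.y = y
        self.X = X
        self.codes = codes
        self.n_clusters = int(codes.max()) + 1
        nodes, weights = hermgauss(n_quad)
        self.nodes = nodes
        self.log_weights = np.log(weights) + nodes**2
        self.y_by_cluster = np.bincount(codes, weights=y, minlength=self.n_clusters)
        self._mode_cache = np.zeros(self.n_clusters)

    def _plain_loglik(self, fixed: np.ndarray) -> float:
        return float(np.sum(self.y * fixed - np.logaddexp(0.0, fixed)))

    def _find_modes(
        self, fixed: np.ndarray, sigma2: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Damped Newton for the per-cluster conditional modes (concave)."""
        u = self._mode_cache.copy()
        for _ in range(100):
            eta = fixed + u[self.codes]
            p = expit(eta)
            grad = self.y_by_cluster - np.bincount(
                self.codes, weights=p, minlength=self.n_clusters
            ) - u / sigma2
            curv = -np.bincount(
                self.codes, weights=p * (1.0 - p), minlength=self.n_clusters
            ) - 1.0 / sigma2
            step = grad / curv
            np.clip(step, -4.0, 4.0, out=step)
            u -= step
            if np.max(np.abs(grad)) < 1e-11:
                break
        eta = fixed + u[self.codes]
        p = expit(eta)
        curv = -np.bincount(
            self.codes, weights=p * (1.0 - p), minlength=self.n_clusters
        ) - 1.0 / sigma2
        self._mode_cache = u
        return u, curv

    def __call__(self, beta: np.ndarray, sigma_u: float) -> float:
        if not np.all(np.isfinite(beta)) or not np.isfinite(sigma_u):
            raise ValueError("non-finite parameters")
        if sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        fixed = self.X @ beta
        if sigma_u < 1e-8:
            return self._plain_loglik(fixed)
        sigma2 = sigma_u * sigma_u
        u_hat, curv = self._find_modes(fixed, sigma2)
        tau = 1.0 / np.sqrt(-curv)  # adaptive scale per cluster
        # log integrand at the shifted/scaled nodes, clusters x nodes
        contrib = np.empty((self.n_clusters, len(self.nodes)))
        log_norm_const = -0.5 * math.log(2.0 * math.pi) - math.log(sigma_u)
        for k, x_k in enumerate(self.nodes):
            u_k = u_hat + math.sqrt(2.0) * tau * x_k
            eta = fixed + u_k[self.codes]
            ll_rows = self.y * eta - np.logaddexp(0.0, eta)
            per_cluster = np.bincount(
                self.codes, weights=ll_rows, minlength=self.n_clusters
            )
            contrib[:, k] = (
                per_cluster
                + log_norm_const
                - 0.5 * (u_k / sigma_u) ** 2
                + self.log_weights[k]
            )
        ll = logsumexp(contrib, axis=1) + 0.5 * math.log(2.0) + np.log(tau)
        return float(ll.sum())


def marginal_loglik(
    dataset: ClusteredBinaryDataset,
    beta: Sequence[float],
    sigma_u: float,
    n_quad_points: int = 15,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> float:
    """Marginal log-likelihood at given parameters.

    ``beta`` lists the coefficients of (intercept, *covariates) in order; the
    cluster-covariate coefficient alpha is simply the entry matching ``"xh"``
    when it is included.  Exact (no quadrature error) at ``sigma_u == 0``.
    """
    y, X, codes, _ = _prepare(dataset, covariates)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (X.shape[1],):
        raise ValueError(f"beta must have length {X.shape[1]}, got {beta.shape}")
    return _MarginalLoglik(y, X, codes, n_quad_points)(beta, float(sigma_u))


def _prepare(
    dataset: ClusteredBinaryDataset, covariates: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    df = dataset.data
    for col in ("cluster_id", "y"):
        if col not in df.columns:
            raise ValueError(f"dataset is missing required column {col!r}")
    for col in covariates:
        if col not in df.columns:
            raise ValueError(f"covariate {col!r} not in dataset")
    y = df["y"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covariates]
    )
    codes = _cluster_codes(df)
    return y, X, codes, ("intercept", *covariates)


def _initial_beta(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Ordinary logistic fit for the starting fixed effects."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
        beta = np.asarray(res.params, dtype=float)
        if np.all(np.isfinite(beta)):
            return np.clip(beta, -10.0, 10.0)
    except Exception:
        pass
    return np.zeros(X.shape[1])


def fit(
    dataset: ClusteredBinaryDataset,
    options: FitOptions | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> FitResult:
    """Maximise the marginal likelihood over (beta, alpha, sigma_u >= 0).

    Deterministic: initialisation is the ordinary logistic fit with
    ``sigma_u`` started at ``options.sigma_start``.  A fit whose optimum
    lies at ``sigma_u = 0`` is returned with the ``boundary`` flag set and
    ``sigma2_u_hat == 0`` exactly.  Non-convergence is reported through the
    ``converged`` flag, never silently.
    """
    options = options or FitOptions()
    y, X, codes, names = _prepare(dataset, covariates)
    n_clusters = int(codes.max()) + 1
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters to estimate a cluster variance")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(
            "all outcomes are identical; the intercept is not identifiable"
        )

    nq = options.effective_quad_points
    ll = _MarginalLoglik(y, X, codes, nq)
    n = len(y)
    p = X.shape[1]

    def objective(theta: np.ndarray) -> float:
        try:
            return -ll(theta[:p], theta[p]) / n
        except (FloatingPointError, ValueError):
            return np.inf

    theta0 = np.append(_initial_beta(y, X), options.sigma_start)
    bounds = [(None, None)] * p + [(0.0, _SIGMA_UPPER)]
    with np.errstate(over="ignore"):
        res = minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": options.max_iter,
                "ftol": 1e-12,
                "gtol": options.grad_tol,
            },
        )
    theta = res.x
    sigma_hat = float(theta[p])
    loglik = float(ll(theta[:p], sigma_hat))
    boundary = False
    if sigma_hat <= _SIGMA_BOUNDARY_SCAN:
        # the optimum may sit on the sigma = 0 constraint: re-polish the
        # fixed effects there (plain logistic model) and keep the better fit
        with np.errstate(over="ignore"):
            res0 = minimize(
                lambda b: -ll(b, 0.0) / n,
                theta[:p],
                method="L-BFGS-B",
                options={"maxiter": options.max_iter, "ftol": 1e-12},
            )
        loglik0 = float(-res0.fun * n)
        if loglik0 + 1e-8 >= loglik:
            boundary = True
            theta = np.append(res0.x, 0.0)
            sigma_hat = 0.0
            loglik = loglik0
    converged = bool(res.success and math.isfinite(loglik))

    se = None
    if converged and not boundary:
        se = _standard_errors(ll, theta, p)

    alpha_hat = None
    beta_names = names
    beta_vals = theta[:p]
    if "xh" in names:
        idx = names.index("xh")
        alpha_hat = float(theta[idx])
        beta_names = tuple(nm for i, nm in enumerate(names) if i != idx)
        beta_vals = np.delete(theta[:p], idx)

    return FitResult(
        param_names=beta_names,
        beta_hat=np.asarray(beta_vals, dtype=float),
        alpha_hat=alpha_hat,
        sigma2_u_hat=sigma_hat * sigma_hat,
        standard_errors=se,
        loglik=loglik,
        converged=converged,
        boundary=boundary,
        n_clusters_used=n_clusters,
        n_obs_used=n,
        n_quad_points=nq,
    )


def _standard_errors(
    ll: _MarginalLoglik, theta: np.ndarray, p: int
) -> np.ndarray | None:
    """Observed-information standard errors by central-difference Hessian."""
    dim = p + 1

    def f(t: np.ndarray) -> float:
        sigma = max(t[p], 0.0)
        return ll(t[:p], sigma)

    h = 1e-4 * (1.0 + np.abs(theta))
    hess = np.empty((dim, dim))
    with np.errstate(over="ignore"):
        f0 = f(theta)
        for i in range(dim):
            ei = np.zeros(dim)
            ei[i] = h[i]
            hess[i, i] = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / h[i] ** 2
        for i in range(dim):
            for j in range(i + 1, dim):
                ei = np.zeros(dim)
                ej = np.zeros(dim)
                ei[i] = h[i]
                ej[j] = h[j]
                hess[i, j] = hess[j, i] = (
                    f(theta + ei + ej)
                    - f(theta + ei - ej)
                    - f(theta - ei + ej)
                    + f(theta - ei - ej)
                ) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        return None
    diag = np.diag(cov)
    if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
        return None
    return np.sqrt(diag)


def fit_then_report(
    dataset: ClusteredBinaryDataset,
    options: FitOptions | None = None,
    interval_mass: float = 0.80,
    mor_mode: str = "exact",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> tuple[FitResult, measures.HeterogeneityReport]:
    """Fit the model, then compute the four measures from (alpha_hat, sigma2_hat).

    A boundary fit uses the sigma2 = 0 conventions of :mod:`clusterhet.measures`
    (MOR 1, ICC 0, point IOR interval, sign-limit SOI).
    """
    result = fit(dataset, options=options, covariates=covariates)
    if result.alpha_hat is None:
        raise ValueError(
            "fit_then_report needs the cluster-level covariate 'xh' in the model"
        )
    rep = measures.report(
        result.alpha_hat,
        result.sigma2_u_hat,
        interval_mass=interval_mass,
        mor_mode=mor_mode,
    )
    return result, rep
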