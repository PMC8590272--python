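"""Simulation of two-level clustered binary data from a random-intercept logit model.

The generating model is

    logit(pi_hi) = beta0 + beta1*x1_hi + beta2*x2_hi + alpha*xh_h + u_h,
    u_h ~ Normal(0, sigma2_u),   xh_h ~ Bernoulli(p),   x1, x2 ~ Normal(0, 1),
    y_hi ~ Bernoulli(pi_hi),

with ``xh`` drawn once per cluster (it is a cluster-level covariate) and the
individual covariates drawn fresh for every row.  The true random effects are
retained alongside the data so that parameter-recovery checks can compare a
fit against the exact values used in every linear predictor.

:func:`application_preset` builds a dataset with the structural skeleton of a
community-clustered child-health survey: ~850 communities of 1-15 children
(mean about 5.5), one binary community covariate (an urban/rural analogue),
between-community variance 0.455 and marginal outcome prevalence about 0.63.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "SchemaError",
    "SimulationConfig",
    "ClusteredBinaryDataset",
    "draw_random_effects",
    "linear_predictor_to_prob",
    "simulate_dataset",
    "application_preset",
]

DATASET_COLUMNS = ("cluster_id", "x1", "x2", "xh", "y")


class SchemaError(ValueError):
    """A supplied dataset violates the expected two-level schema."""


@dataclass(frozen=True)
class SimulationConfig:
    """One data-generating condition for the two-level logit simulator.

    Defaults for the fixed effects are the canonical study condition
    (beta0=0.5, beta1=-1.5, beta2=0.3, alpha=-0.3).
    """

    n_clusters: int
    cluster_size: int
    sigma2_u: float
    beta0: float = 0.5
    beta1: float = -1.5
    beta2: float = 0.3
    alpha: float = -0.3
    cluster_covariate_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_clusters) < 1:
            raise ValueError(f"n_clusters must be >= 1, got {self.n_clusters}")
        if int(self.cluster_size) < 1:
            raise ValueError(f"cluster_size must be >= 1, got {self.cluster_size}")
        if not (math.isfinite(self.sigma2_u) and self.sigma2_u >= 0):
            raise ValueError(f"sigma2_u must be finite and >= 0, got {self.sigma2_u}")
        if not 0.0 <= self.cluster_covariate_prob <= 1.0:
            raise ValueError(
                f"cluster_covariate_prob must be in [0, 1], got {self.cluster_covariate_prob}"
            )
        for name in ("beta0", "beta1", "beta2", "alpha"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass
class ClusteredBinaryDataset:
    """Two-level clustered binary data, with the generating truth when simulated.

    ``data`` holds one row per individual with columns
    ``cluster_id, x1, x2, xh, y`` (cluster ids 1..H, contiguous).
    ``random_effects`` (length H) and ``probabilities`` (length n, only when
    requested) record the values actually used to draw the outcomes; both are
    ``None`` for externally supplied data.
    """

    data: pd.DataFrame
    random_effects: np.ndarray | None = None
    probabilities: np.ndarray | None = None
    config: SimulationConfig | None = field(default=None, repr=False)

    @property
    def n_clusters(self) -> int:
        return int(self.data["cluster_id"].nunique())

    @property
    def n_obs(self) -> int:
        return int(len(self.data))

    def cluster_sizes(self) -> pd.Series:
        return self.data["cluster_id"].value_counts().sort_index()

    def validate(self) -> None:
        """Raise :class:`SchemaError` if the schema invariants are violated."""
        missing = [c for c in DATASET_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        y = self.data["y"]
        bad_y = self.data.index[~y.isin([0, 1])]
        if len(bad_y):
            raise SchemaError(f"y must be 0/1; offending rows: {list(bad_y[:10])}")
        xh_n = self.data.groupby("cluster_id")["xh"].nunique()
        bad_clusters = xh_n.index[xh_n > 1].tolist()
        if bad_clusters:
            raise SchemaError(
                f"xh must be constant within cluster; offending cluster_ids: {bad_clusters[:10]}"
            )
        for col in ("x1", "x2", "xh"):
            if not np.all(np.isfinite(self.data[col].to_numpy(dtype=float))):
                raise SchemaError(f"column {col!r} contains non-finite values")

    def to_csv(self, path: Union[str, Path], keep_truth: bool = False) -> None:
        """Write the dataset as UTF-8 CSV (header mandatory, '.' decimal).

        With ``keep_truth`` the per-cluster random effect is repeated on each
        row as a ``u_h`` column (only available for simulated data).
        """
        out = self.data.copy()
        if keep_truth:
            if self.random_effects is None:
                raise ValueError("no retained random effects to write")
            ids = out["cluster_id"].to_numpy(dtype=int)
            out["u_h"] = self.random_effects[ids - 1]
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ClusteredBinaryDataset":
        """Read a dataset CSV, validating the schema.

        A ``u_h`` column, if present, is folded back into the per-cluster
        random-effect vector (it must be constant within clusters).
        """
        try:
            df = pd.read_csv(path)
        except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise SchemaError(f"could not read dataset CSV {path}: {exc}") from exc
        u = None
        if "u_h" in df.columns:
            per_cluster = df.groupby("cluster_id")["u_h"]
            if (per_cluster.nunique() > 1).any():
                raise SchemaError("u_h must be constant within cluster")
            u = per_cluster.first().sort_index().to_numpy()
            df = df.drop(columns=["u_h"])
        ds = cls(data=df, random_effects=u)
        ds.validate()
        return ds


def draw_random_effects(
    n_clusters: int, sigma2_u: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_clusters`` independent Normal(0, sigma2_u) random intercepts."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if not (math.isfinite(sigma2_u) and sigma2_u >= 0):
        raise ValueError(f"sigma2_u must be finite and >= 0, got {sigma2_u}")
    return rng.normal(0.0, math.sqrt(sigma2_u), size=int(n_clusters))


def linear_predictor_to_prob(eta):
    """Inverse-logit map ``eta -> 1/(1+exp(-eta))`` (vectorised)."""
    return expit(eta)


def _simulate_from_sizes(
    sizes: np.ndarray,
    sigma2_u: float,
    beta0: float,
    beta1: float,
    beta2: float,
    alpha: float,
    cluster_covariate_prob: float,
    rng: np.random.Generator,
    config: SimulationConfig | None,
) -> ClusteredBinaryDataset:
    """Core generator shared by the constant-size and preset entry points.

    Draw order (fixed for reproducibility): all random effects, then the
    cluster covariates, then the individual covariates, then the outcomes.
    """
    n_clusters = len(sizes)
    n = int(sizes.sum())
    u = draw_random_effects(n_clusters, sigma2_u, rng)
    xh = rng.binomial(1, cluster_covariate_prob, size=n_clusters)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    cluster_id = np.repeat(np.arange(1, n_clusters + 1), sizes)
    eta = (
        beta0
        + beta1 * x1
        + beta2 * x2
        + alpha * xh[cluster_id - 1]
        + u[cluster_id - 1]
    )
    pi = linear_predictor_to_prob(eta)
    y = (rng.random(n) < pi).astype(np.int64)
    df = pd.DataFrame(
        {
            "cluster_id": cluster_id,
            "x1": x1,
            "x2": x2,
            "xh": xh[cluster_id - 1],
            "y": y,
        }
    )
    return ClusteredBinaryDataset(
        data=df, random_effects=u, probabilities=pi, config=config
    )


def simulate_dataset(config: SimulationConfig) -> ClusteredBinaryDataset:
    """Simulate one dataset under ``config``; bit-reproducible from its seed."""
    rng = np.random.default_rng(config.seed)
    sizes = np.full(config.n_clusters, config.cluster_size, dtype=np.int64)
    return _simulate_from_sizes(
        sizes,
        config.sigma2_u,
        config.beta0,
        config.beta1,
        config.beta2,
        config.alpha,
        config.cluster_covariate_prob,
        rng,
        config,
    )


def _marginal_prevalence(
    beta0: float, alpha: float, covariate_prob: float, sigma2_u: float
) -> float:
    """Population prevalence E[expit(beta0 + alpha*X + u)] by Gauss-Hermite."""
    nodes, weights = hermgauss(40)
    sd = math.sqrt(sigma2_u)
    u = math.sqrt(2.0) * sd * nodes
    w = weights / math.sqrt(math.pi)
    p0 = float(np.sum(w * expit(beta0 + u)))
    p1 = float(np.sum(w * expit(beta0 + alpha + u)))
    return (1.0 - covariate_prob) * p0 + covariate_prob * p1


def application_preset(
    seed: int = 0,
    n_clusters: int = 850,
    mean_cluster_size: float = 5.5,
    size_range: tuple[int, int] = (1, 15),
    sigma2_u: float = 0.455,
    prevalence: float = 0.63,
    alpha: float = math.log(1.21),
    cluster_covariate_prob: float = 0.5,
) -> ClusteredBinaryDataset:
    """Structural emulator of a community-clustered child-health survey.

    Cluster sizes are Poisson(``mean_cluster_size``) truncated to
    ``size_range``; the binary cluster covariate is an urban/rural analogue
    with effect ``alpha`` (default: log of an odds ratio of 1.21); the
    intercept is solved numerically so the marginal outcome prevalence equals
    ``prevalence`` given the between-cluster variance.  Individual-level
    covariates ``x1, x2`` are included in the schema with zero effect: the
    preset emulates the data's nesting structure, not its substantive
    covariates.
    """
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    sizes = np.empty(n_clusters, dtype=np.int64)
    filled = 0
    while filled < n_clusters:  # rejection sampling of the truncated Poisson
        draw = rng.poisson(mean_cluster_size, size=2 * (n_clusters - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: n_clusters - filled]
        sizes[filled : filled + len(keep)] = keep
        filled += len(keep)

    def prevalence_gap(b0: float) -> float:
        return (
            _marginal_prevalence(b0, alpha, cluster_covariate_prob, sigma2_u)
            - prevalence
        )

    beta0 = brentq(prevalence_gap, -8.0, 8.0, xtol=1e-12)
    return _simulate_from_sizes(
        sizes,
        sigma2_u,
        beta0,
        0.0,
        0.0,
        alpha,
        cluster_covariate_prob,
        rng,
        config=None,
    )
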