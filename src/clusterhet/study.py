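"""Monte Carlo evaluation of the heterogeneity measures over a factorial grid.

For every combination of number of clusters H, cluster size N_h and
between-cluster variance sigma2_u, ``R`` datasets are simulated, the
random-intercept logistic model is fitted to each by maximum likelihood, and
the four measures are computed from every fit.  Per condition the runner
records the mean of each estimated quantity over converged replicates and
its root-mean-square error against the analytic true value,

    RMSE = sqrt( (1/R_conv) * sum_r (estimate_r - true)^2 ).

Seeds are derived from a base seed and the condition/replicate indices via
``numpy.random.SeedSequence`` spawn keys, so any single replicate is
reproducible in isolation and results are identical whether conditions run
serially or in parallel.
"""

from __future__ import annotations

import itertools
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import measures
from .glmm import FitOptions, fit_then_report
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "QUANTITIES",
    "GridSpec",
    "ConditionSummary",
    "rmse",
    "replicate_seed",
    "run_condition",
    "run_grid",
    "render_tables",
    "write_tables",
]

#: Quantities aggregated per condition, in paper-table column order.
QUANTITIES = (
    "beta0",
    "beta1",
    "beta2",
    "alpha",
    "icc",
    "mor",
    "soi",
    "ior_lower",
    "ior_upper",
)

# Canonical full-study grid (the package supports it; routine runs use less).
PAPER_CLUSTER_COUNTS = (10, 50, 100, 300, 500)
PAPER_CLUSTER_SIZES = (5, 20, 50, 100, 250)
PAPER_VARIANCES = (0.2, 0.5, 1.0, 1.5)
PAPER_FIXED_EFFECTS = {"beta0": 0.5, "beta1": -1.5, "beta2": 0.3, "alpha": -0.3}

# Display precision per column, following the published table style.
_TRUE_DECIMALS = {
    "beta0": 4, "beta1": 4, "beta2": 4, "alpha": 4,
    "icc": 4, "mor": 3, "soi": 4, "ior_lower": 4, "ior_upper": 3,
}
_EST_DECIMALS = {q: 3 for q in QUANTITIES} | {"icc": 4, "soi": 4, "ior_lower": 4}
_RMSE_DECIMALS = {q: 3 for q in QUANTITIES}


def rmse(estimates: Sequence[float], true_value: float) -> float:
    """Root-mean-square error of ``estimates`` around ``true_value``."""
    arr = np.asarray(estimates, dtype=float)
    if arr.size == 0:
        raise ValueError("rmse needs at least one estimate")
    return float(np.sqrt(np.mean((arr - float(true_value)) ** 2)))


def replicate_seed(
    base_seed: int, n_clusters: int, cluster_size: int, sigma2_u: float, replicate: int
) -> int:
    """Deterministic per-replicate seed (< 2^31), independent of run order."""
    ss = np.random.SeedSequence(
        entropy=int(base_seed),
        spawn_key=(
            int(n_clusters),
            int(cluster_size),
            int(round(float(sigma2_u) * 1_000_000)),
            int(replicate),
        ),
    )
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


@dataclass
class ConditionSummary:
    """Aggregated results for one (H, N_h, sigma2_u) grid cell."""

    n_clusters: int
    cluster_size: int
    sigma2_u: float
    n_replicates: int
    n_converged: int
    n_failed: int
    true_values: dict[str, float]
    means: dict[str, float]
    rmses: dict[str, float]
    usable: bool
    replicate_log: list[dict] = field(default_factory=list, repr=False)


def _true_values(sigma2_u: float, effects: dict[str, float]) -> dict[str, float]:
    rep = measures.report(effects["alpha"], sigma2_u)
    return {
        "beta0": effects["beta0"],
        "beta1": effects["beta1"],
        "beta2": effects["beta2"],
        "alpha": effects["alpha"],
        "icc": rep.icc,
        "mor": rep.mor,
        "soi": rep.soi,
        "ior_lower": rep.ior_lower,
        "ior_upper": rep.ior_upper,
    }


def run_condition(
    n_clusters: int,
    cluster_size: int,
    sigma2_u: float,
    n_replicates: int,
    base_seed: int,
    fit_options: FitOptions | None = None,
    fixed_effects: dict[str, float] | None = None,
) -> ConditionSummary:
    """Simulate, fit and aggregate ``n_replicates`` datasets for one condition.

    Non-converged fits (and fits that error) are excluded from the means and
    RMSEs but counted; a condition where nothing converged is returned with
    ``usable=False`` and NaN aggregates rather than aborting a grid run.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    effects = dict(fixed_effects or PAPER_FIXED_EFFECTS)
    fit_options = fit_options or FitOptions()
    truth = _true_values(sigma2_u, effects)

    estimates: dict[str, list[float]] = {q: [] for q in QUANTITIES}
    sigma2_estimates: list[float] = []
    log: list[dict] = []
    n_converged = 0
    for r in range(n_replicates):
        seed = replicate_seed(base_seed, n_clusters, cluster_size, sigma2_u, r)
        cfg = SimulationConfig(
            n_clusters=n_clusters,
            cluster_size=cluster_size,
            sigma2_u=sigma2_u,
            beta0=effects["beta0"],
            beta1=effects["beta1"],
            beta2=effects["beta2"],
            alpha=effects["alpha"],
            seed=seed,
        )
        t0 = time.perf_counter()
        entry = {"replicate": r, "seed": seed, "converged": False, "error": None}
        try:
            dataset = simulate_dataset(cfg)
            result, rep = fit_then_report(dataset, options=fit_options)
        except (ValueError, FloatingPointError) as exc:
            entry["error"] = str(exc)
            log.append(entry)
            continue
        entry["seconds"] = round(time.perf_counter() - t0, 4)
        entry["converged"] = bool(result.converged)
        entry["boundary"] = bool(result.boundary)
        log.append(entry)
        if not result.converged:
            continue
        n_converged += 1
        values = {
            "beta0": float(result.beta_hat[0]),
            "beta1": float(result.beta_hat[1]),
            "beta2": float(result.beta_hat[2]),
            "alpha": float(result.alpha_hat),
            "icc": rep.icc,
            "mor": rep.mor,
            "soi": rep.soi,
            "ior_lower": rep.ior_lower,
            "ior_upper": rep.ior_upper,
        }
        for q in QUANTITIES:
            estimates[q].append(values[q])
        sigma2_estimates.append(result.sigma2_u_hat)

    usable = n_converged > 0
    if usable:
        means = {q: float(np.mean(estimates[q])) for q in QUANTITIES}
        means["sigma2_u"] = float(np.mean(sigma2_estimates))
        rmses = {q: rmse(estimates[q], truth[q]) for q in QUANTITIES}
    else:
        means = {q: math.nan for q in (*QUANTITIES, "sigma2_u")}
        rmses = {q: math.nan for q in QUANTITIES}
    return ConditionSummary(
        n_clusters=n_clusters,
        cluster_size=cluster_size,
        sigma2_u=sigma2_u,
        n_replicates=n_replicates,
        n_converged=n_converged,
        n_failed=n_replicates - n_converged,
        true_values=truth,
        means=means,
        rmses=rmses,
        usable=usable,
        replicate_log=log,
    )


@dataclass(frozen=True)
class GridSpec:
    """Full factorial experiment specification."""

    cluster_counts: tuple[int, ...] = PAPER_CLUSTER_COUNTS
    cluster_sizes: tuple[int, ...] = PAPER_CLUSTER_SIZES
    variances: tuple[float, ...] = PAPER_VARIANCES
    replicates: int = 1000
    base_seed: int = 0
    fit_options: FitOptions = field(default_factory=FitOptions)
    fixed_effects: tuple[tuple[str, float], ...] = tuple(PAPER_FIXED_EFFECTS.items())
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if not (self.cluster_counts and self.cluster_sizes and self.variances):
            raise ValueError("cluster_counts, cluster_sizes and variances must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def effects(self) -> dict[str, float]:
        return dict(self.fixed_effects)

    def conditions(self) -> list[tuple[int, int, float]]:
        return list(
            itertools.product(self.cluster_counts, self.cluster_sizes, self.variances)
        )


def run_grid(spec: GridSpec) -> list[ConditionSummary]:
    """Run every condition of the grid; optionally parallel across conditions.

    Results are identical serial vs parallel: every replicate seed is a pure
    function of (base_seed, condition, replicate index).
    """
    conditions = spec.conditions()
    tasks = (
        delayed(run_condition)(
            H,
            N_h,
            s2,
            spec.replicates,
            spec.base_seed,
            spec.fit_options,
            spec.effects,
        )
        for (H, N_h, s2) in conditions
    )
    return list(Parallel(n_jobs=spec.n_jobs)(tasks))


def _round_df(df: pd.DataFrame, decimals: dict[str, int]) -> pd.DataFrame:
    out = df.copy()
    for col, d in decimals.items():
        if col in out.columns:
            out[col] = out[col].round(d)
    return out


def render_tables(
    summaries: Sequence[ConditionSummary],
    style: str,
    quantities: Sequence[str] = QUANTITIES,
) -> dict[float, pd.DataFrame] | pd.DataFrame:
    """Render paper-style tables from condition summaries.

    ``style="true"`` returns a single analytic true-value table over the
    grid's variances.  ``style="estimates"`` and ``style="rmse"`` return one
    table per variance (condition rows x quantity columns).  In the
    estimates table the four measure columns are recomputed from the mean
    alpha and mean sigma2 estimates, so the table is internally consistent
    (its own measure entries equal the closed forms applied to its own
    parameter entries).
    """
    if style not in ("true", "estimates", "rmse"):
        raise ValueError(f"unknown style {style!r}")
    if not summaries:
        raise ValueError("no summaries to render")
    variances = sorted({s.sigma2_u for s in summaries})
    if style == "true":
        effects = summaries[0].true_values
        table = measures.true_values_table(
            variances,
            beta0=effects["beta0"],
            beta1=effects["beta1"],
            beta2=effects["beta2"],
            alpha=effects["alpha"],
        )
        keep = ["sigma2_u"] + [c for c in table.columns if c in quantities or c.startswith("beta") or c == "alpha"]
        return _round_df(table[[c for c in table.columns if c in keep]], _TRUE_DECIMALS)

    out: dict[float, pd.DataFrame] = {}
    for s2 in variances:
        rows = []
        cell = sorted(
            (s for s in summaries if s.sigma2_u == s2),
            key=lambda s: (s.n_clusters, s.cluster_size),
        )
        for s in cell:
            row = {"clusters": s.n_clusters, "cluster_size": s.cluster_size}
            if style == "rmse":
                for q in quantities:
                    row[q] = s.rmses[q]
            else:
                derived = measures.report(s.means["alpha"], s.means["sigma2_u"])
                values = {
                    "beta0": s.means["beta0"],
                    "beta1": s.means["beta1"],
                    "beta2": s.means["beta2"],
                    "alpha": s.means["alpha"],
                    "icc": derived.icc,
                    "mor": derived.mor,
                    "soi": derived.soi,
                    "ior_lower": derived.ior_lower,
                    "ior_upper": derived.ior_upper,
                }
                for q in quantities:
                    row[q] = values[q]
            row["n_converged"] = s.n_converged
            row["n_failed"] = s.n_failed
            rows.append(row)
        df = pd.DataFrame(
            rows, columns=["clusters", "cluster_size", *quantities, "n_converged", "n_failed"]
        )
        out[s2] = _round_df(df, _EST_DECIMALS if style == "estimates" else _RMSE_DECIMALS)
    return out


def write_tables(
    summaries: Sequence[ConditionSummary],
    out_dir: str | Path,
    quantities: Sequence[str] = QUANTITIES,
) -> list[Path]:
    """Write true_values.csv, estimates_<s2>.csv, rmse_<s2>.csv and a run log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    true_df = render_tables(summaries, "true", quantities)
    path = out_dir / "true_values.csv"
    true_df.to_csv(path, index=False)
    written.append(path)

    for style in ("estimates", "rmse"):
        tables = render_tables(summaries, style, quantities)
        for s2, df in tables.items():
            path = out_dir / f"{style}_{s2:g}.csv"
            df.to_csv(path, index=False)
            written.append(path)

    log_path = out_dir / "run_log.txt"
    with open(log_path, "w", encoding="utf-8") as fh:
        for s in summaries:
            head = (
                f"condition H={s.n_clusters} N_h={s.cluster_size} "
                f"sigma2={s.sigma2_u:g} R={s.n_replicates} "
                f"converged={s.n_converged} failed={s.n_failed}"
            )
            fh.write(head + "\n")
            for entry in s.replicate_log:
                fh.write(
                    f"  replicate={entry['replicate']} seed={entry['seed']} "
                    f"converged={entry['converged']} "
                    f"boundary={entry.get('boundary', '')} "
                    f"error={entry.get('error')}\n"
                )
    written.append(log_path)
    return written
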