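"""Fitter tests: quadrature accuracy, oracle equivalence, invariances, recovery."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import clusterhet as ch
from clusterhet.glmm import FitOptions

from conftest import tiny_datasets
from _oracles import dense_marginal_loglik

TRUTH = np.array([0.5, -1.5, 0.3, -0.3])


class TestMarginalLoglik:
    def test_collapses_to_plain_logistic_at_zero_variance(self, moderate_dataset):
        df = moderate_dataset.data
        X = sm.add_constant(df[["x1", "x2", "xh"]].to_numpy())
        beta = np.array([0.4, -1.2, 0.2, -0.1])
        plain = float(sm.Logit(df["y"].to_numpy(), X).loglike(beta))
        ours = ch.marginal_loglik(moderate_dataset, beta, 0.0)
        assert ours == pytest.approx(plain, rel=1e-12)

    @pytest.mark.parametrize("i", range(5))
    def test_matches_dense_integration_on_tiny_data(self, i):
        ds = tiny_datasets()[i]
        beta = np.array([0.3, -0.8, 0.2, -0.3])
        sigma = math.sqrt(max(ds.config.sigma2_u, 0.1))
        agq = ch.marginal_loglik(ds, beta, sigma)
        dense = dense_marginal_loglik(ds, beta, sigma)
        assert agq == pytest.approx(dense, abs=1e-8)

    def test_quadrature_order_convergence(self, moderate_dataset):
        beta = np.array([0.5, -1.5, 0.3, -0.3])
        ll15 = ch.marginal_loglik(moderate_dataset, beta, 0.7, n_quad_points=15)
        ll25 = ch.marginal_loglik(moderate_dataset, beta, 0.7, n_quad_points=25)
        assert ll15 == pytest.approx(ll25, rel=1e-6)

    def test_laplace_error_shrinks_with_cluster_size(self):
        # |loglik(1 node) - loglik(25 nodes)| per cluster decreases as
        # clusters carry more observations (the integrand concentrates and
        # the Laplace approximation becomes exact; non-monotone noise below
        # ~10 observations per cluster keeps the grid at 10/40/160)
        gaps = []
        for size in (10, 40, 160):
            ds = ch.simulate_dataset(ch.SimulationConfig(40, size, 1.0, seed=13))
            beta = TRUTH
            g = abs(
                ch.marginal_loglik(ds, beta, 1.0, n_quad_points=1)
                - ch.marginal_loglik(ds, beta, 1.0, n_quad_points=25)
            )
            gaps.append(g / 40)
        assert gaps[0] > gaps[1] > gaps[2]

    def test_nonfinite_params_rejected(self, moderate_dataset):
        with pytest.raises(ValueError):
            ch.marginal_loglik(moderate_dataset, [np.nan, 0, 0, 0], 0.5)
        with pytest.raises(ValueError):
            ch.marginal_loglik(moderate_dataset, [0, 0, 0, 0], -0.5)


class TestFit:
    def test_zero_variance_data_hits_boundary(self):
        ds = ch.simulate_dataset(ch.SimulationConfig(80, 40, 0.0, seed=22))
        res = ch.fit(ds)
        assert res.boundary
        assert res.sigma2_u_hat == 0.0
        assert res.standard_errors is None
        # fixed effects agree with a plain logistic fit
        X = sm.add_constant(ds.data[["x1", "x2", "xh"]].to_numpy())
        plain = sm.Logit(ds.data["y"].to_numpy(), X).fit(disp=0)
        fitted = np.array([res.beta_hat[0], res.beta_hat[1], res.beta_hat[2],
                           res.alpha_hat])
        assert np.allclose(fitted, plain.params, atol=2e-3)

    def test_permutation_invariance(self, moderate_dataset, moderate_fit):
        shuffled = moderate_dataset.data.sample(frac=1.0, random_state=5)
        ds2 = ch.ClusteredBinaryDataset(data=shuffled.reset_index(drop=True))
        res2 = ch.fit(ds2)
        assert res2.loglik == pytest.approx(moderate_fit.loglik, abs=1e-6)
        assert np.allclose(res2.beta_hat, moderate_fit.beta_hat, atol=1e-5)
        assert res2.sigma2_u_hat == pytest.approx(
            moderate_fit.sigma2_u_hat, abs=1e-5
        )

    def test_deterministic(self, moderate_dataset, moderate_fit):
        again = ch.fit(moderate_dataset)
        assert again.loglik == moderate_fit.loglik
        assert np.array_equal(again.beta_hat, moderate_fit.beta_hat)

    def test_identical_outcomes_rejected(self):
        df = pd.DataFrame({
            "cluster_id": [1, 1, 2, 2], "x1": [0.1, -0.2, 0.3, 0.0],
            "x2": [0.0, 0.1, -0.1, 0.2], "xh": [0, 0, 1, 1], "y": [1, 1, 1, 1],
        })
        with pytest.raises(ValueError, match="identifiable"):
            ch.fit(ch.ClusteredBinaryDataset(data=df))

    def test_single_cluster_rejected(self):
        df = pd.DataFrame({"cluster_id": [1] * 4, "x1": [0.0, 1, 0, 1],
                           "x2": [0.0, 0, 1, 1], "xh": [0] * 4, "y": [0, 1, 0, 1]})
        with pytest.raises(ValueError, match="clusters"):
            ch.fit(ch.ClusteredBinaryDataset(data=df))

    def test_bad_quad_options_rejected(self):
        with pytest.raises(ValueError):
            FitOptions(n_quad_points=0)
        with pytest.raises(ValueError):
            FitOptions(n_quad_points=10)

    def test_small_scale_parameter_recovery(self):
        # quick recovery check; the full-scale one lives in the acceptance suite
        sig, b1 = [], []
        for seed in range(5):
            ds = ch.simulate_dataset(
                ch.SimulationConfig(200, 30, 0.5, seed=1000 + seed)
            )
            res = ch.fit(ds)
            assert res.converged
            sig.append(res.sigma2_u_hat)
            b1.append(res.beta_hat[1])
        assert abs(np.mean(sig) - 0.5) < 0.08
        assert abs(np.mean(b1) - (-1.5)) < 0.08


class TestFitThenReport:
    def test_boundary_fit_reports_absence(self):
        ds = ch.simulate_dataset(ch.SimulationConfig(80, 40, 0.0, seed=22))
        res, rep = ch.fit_then_report(ds)
        assert res.boundary
        assert rep.mor == 1.0 and rep.icc == 0.0

    def test_report_consistent_with_fit(self, moderate_dataset):
        res, rep = ch.fit_then_report(moderate_dataset)
        assert rep.sigma2_u == res.sigma2_u_hat
        assert rep.alpha == res.alpha_hat
        assert rep.icc == pytest.approx(ch.icc(res.sigma2_u_hat))
        # duality holds on any fitted report
        inside = rep.ior_lower < 1.0 < rep.ior_upper
        assert inside == (0.10 < rep.soi < 0.90)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestLme4CrossCheck:
    def test_agrees_with_glmer_agq(self, tmp_path, moderate_dataset, moderate_fit):
        """Independent mixed-model implementation reproduces the same optimum."""
        csv = tmp_path / "ds.csv"
        moderate_dataset.to_csv(csv)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ x1 + x2 + xh + (1|cluster_id), data=d,
                       family=binomial, nAGQ=15)
            cat(fixef(m), as.numeric(VarCorr(m)$cluster_id),
                as.numeric(logLik(m)), sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.strip().splitlines()]
        b0, b1, b2, a, s2, ll = vals
        assert moderate_fit.beta_hat[0] == pytest.approx(b0, abs=1e-3)
        assert moderate_fit.beta_hat[1] == pytest.approx(b1, abs=1e-3)
        assert moderate_fit.beta_hat[2] == pytest.approx(b2, abs=1e-3)
        assert moderate_fit.alpha_hat == pytest.approx(a, abs=1e-3)
        assert moderate_fit.sigma2_u_hat == pytest.approx(s2, abs=5e-3)
        assert moderate_fit.loglik == pytest.approx(ll, abs=1e-3)
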