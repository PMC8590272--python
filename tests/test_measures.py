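"""Closed-form measure tests: frozen examples, identities, brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import clusterhet as ch
from clusterhet.measures import LOGISTIC_LEVEL1_VARIANCE

from _oracles import ior_oracle, mor_oracle, quantile_by_root_finding, soi_oracle

ALPHAS = st.floats(-3.0, 3.0)
SIGMA2 = st.floats(0.0, 5.0)
SIGMA2_POS = st.floats(1e-6, 5.0)
MASSES = st.floats(0.05, 0.99)


class TestExamples:
    @pytest.mark.parametrize(
        "sigma2, expected",
        [(0.5, 0.1319), (1.0, 0.2331), (0.0, 0.0), (LOGISTIC_LEVEL1_VARIANCE, 0.5)],
    )
    def test_icc(self, sigma2, expected):
        assert ch.icc(sigma2) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize(
        "sigma2, mode, expected",
        [
            (0.5, "exact", 1.963),
            (1.5, "exact", 3.216),
            (0.0, "exact", 1.0),
            (0.0, "printed_0p95", 1.0),
            (0.455, "printed_0p95", 1.898),
            (0.497, "printed_0p95", 1.954),
        ],
    )
    def test_mor(self, sigma2, mode, expected):
        assert ch.mor(sigma2, mode) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize(
        "alpha, sigma2, expected",
        [
            (-0.3, 0.5, (0.2057, 2.669)),
            (-0.3, 1.0, (0.1209, 4.538)),
            (-0.3, 0.0, (math.exp(-0.3), math.exp(-0.3))),
        ],
    )
    def test_ior(self, alpha, sigma2, expected):
        lo, hi = ch.ior(alpha, sigma2)
        assert lo == pytest.approx(expected[0], abs=5e-4)
        assert hi == pytest.approx(expected[1], abs=5e-4)

    @pytest.mark.parametrize(
        "alpha, sigma2, expected",
        [(-0.3, 0.5, 0.3821), (-0.3, 1.5, 0.4312), (0.0, 2.0, 0.5)],
    )
    def test_soi(self, alpha, sigma2, expected):
        assert ch.soi(alpha, sigma2) == pytest.approx(expected, abs=5e-5)

    def test_soi_zero_variance_limits(self):
        assert ch.soi(0.7, 0.0) == 1.0
        assert ch.soi(-0.7, 0.0) == 0.0
        assert ch.soi(0.0, 0.0) == 0.5

    def test_report_bundles_components(self):
        rep = ch.report(-0.3, 1.5)
        assert rep.icc == pytest.approx(0.3131, abs=1e-4)
        assert rep.mor == pytest.approx(3.216, abs=5e-4)
        assert (rep.ior_lower, rep.ior_upper) == pytest.approx(
            (0.0805, 6.819), abs=5e-4
        )
        assert rep.soi == pytest.approx(0.4312, abs=5e-5)

    def test_report_degenerate(self):
        rep = ch.report(0.0, 0.0)
        assert (rep.icc, rep.mor, rep.soi) == (0.0, 1.0, 0.5)
        assert rep.ior_lower == rep.ior_upper == 1.0

    def test_report_matches_direct_recomputation(self):
        # independent spreadsheet-style re-evaluation of each formula
        alpha, s2 = 0.2, 0.3
        rep = ch.report(alpha, s2)
        assert rep.icc == pytest.approx(s2 / (s2 + math.pi**2 / 3), rel=1e-12)
        z75 = quantile_by_root_finding(0.75)
        assert rep.mor == pytest.approx(math.exp(math.sqrt(2 * s2) * z75), rel=1e-10)
        z90 = quantile_by_root_finding(0.90)
        assert rep.ior_lower == pytest.approx(
            math.exp(alpha - math.sqrt(2 * s2) * z90), rel=1e-10
        )
        assert rep.soi == pytest.approx(soi_oracle(alpha, s2), abs=1e-11)

    @pytest.mark.parametrize("bad", [-0.1, float("nan"), float("inf")])
    def test_negative_or_nonfinite_variance_rejected(self, bad):
        with pytest.raises(ValueError):
            ch.icc(bad)
        with pytest.raises(ValueError):
            ch.mor(bad)
        with pytest.raises(ValueError):
            ch.soi(0.0, bad)

    def test_bad_interval_mass_rejected(self):
        for mass in (0.0, 1.0, -0.2, 1.7):
            with pytest.raises(ValueError):
                ch.ior(0.0, 0.5, mass)

    def test_unknown_mor_mode_rejected(self):
        with pytest.raises(ValueError):
            ch.mor(0.5, "nope")


class TestTrueValuesTable:
    def test_reproduces_published_style_rows(self):
        table = ch.true_values_table([0.2, 0.5, 1.0, 1.5])
        expected_mor = [1.532, 1.963, 2.596, 3.216]
        expected_soi = [0.3176, 0.3821, 0.4160, 0.4312]
        assert np.allclose(table["mor"], expected_mor, atol=1e-3)
        assert np.allclose(table["soi"], expected_soi, atol=1e-4)
        assert list(table["beta1"].unique()) == [-1.5]

    def test_zero_variance_row(self):
        table = ch.true_values_table([0.0], alpha=-0.3)
        assert table.loc[0, "mor"] == 1.0
        assert table.loc[0, "ior_lower"] == pytest.approx(math.exp(-0.3))
        assert table.loc[0, "ior_upper"] == pytest.approx(math.exp(-0.3))

    def test_monotone_in_variance(self):
        grid = np.linspace(0.0, 4.0, 80)
        table = ch.true_values_table(grid)
        assert np.all(np.diff(table["icc"]) > 0)
        assert np.all(np.diff(table["mor"]) > 0)
        width = np.log(table["ior_upper"]) - np.log(table["ior_lower"])
        assert np.all(np.diff(width) > 0)


class TestIdentities:
    @given(alpha=ALPHAS, s2=SIGMA2, mass=MASSES)
    def test_ior_log_symmetry(self, alpha, s2, mass):
        lo, hi = ch.ior(alpha, s2, mass)
        assert math.log(lo) + math.log(hi) == pytest.approx(2 * alpha, abs=1e-9)

    @given(alpha=ALPHAS, s2=SIGMA2)
    def test_soi_reflection(self, alpha, s2):
        assert ch.soi(alpha, s2) + ch.soi(-alpha, s2) == pytest.approx(1.0, abs=1e-12)

    @given(alpha=ALPHAS, s2=SIGMA2_POS, mass=MASSES)
    def test_ior_soi_duality(self, alpha, s2, mass):
        # 1 inside the interval  <=>  (1-mass)/2 < SOI < (1+mass)/2
        lo, hi = ch.ior(alpha, s2, mass)
        s = ch.soi(alpha, s2)
        inside = lo < 1.0 < hi
        assert inside == ((1 - mass) / 2 < s < (1 + mass) / 2)

    @given(s2=SIGMA2, alpha=ALPHAS)
    def test_mor_at_least_one_and_alpha_invariant(self, s2, alpha):
        m = ch.mor(s2)
        assert m >= 1.0
        if s2 == 0.0:
            assert m == 1.0
        elif s2 > 1e-10:  # exp underflows to 1.0 for subnormal variances
            assert m > 1.0
        rep = ch.report(alpha, s2)
        assert rep.mor == m

    @given(s2=st.floats(0.0, 10.0))
    def test_icc_range(self, s2):
        v = ch.icc(s2)
        assert 0.0 <= v < 1.0


class TestBruteForceOracles:
    """Quantile/CDF expressions recovered by root-finding, >= 10 significant digits."""

    @pytest.mark.parametrize("s2", [0.05, 0.2, 0.5, 1.0, 1.5, 3.7])
    def test_mor_oracle(self, s2):
        assert ch.mor(s2) == pytest.approx(mor_oracle(s2), rel=1e-11)

    @pytest.mark.parametrize("alpha,s2,mass", [
        (-0.3, 0.5, 0.80), (0.9, 1.2, 0.80), (0.0, 0.3, 0.50), (-1.1, 2.0, 0.95),
    ])
    def test_ior_oracle(self, alpha, s2, mass):
        lo, hi = ch.ior(alpha, s2, mass)
        olo, ohi = ior_oracle(alpha, s2, mass)
        assert lo == pytest.approx(olo, rel=1e-10)
        assert hi == pytest.approx(ohi, rel=1e-10)

    @pytest.mark.parametrize("alpha,s2", [(-0.3, 0.5), (0.7, 1.5), (-2.0, 0.1)])
    def test_soi_oracle(self, alpha, s2):
        assert ch.soi(alpha, s2) == pytest.approx(soi_oracle(alpha, s2), abs=1e-11)
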