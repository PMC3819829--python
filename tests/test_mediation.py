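"""Mediation core: regressions, Sobel statistic, permutation test, trio scan."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from mediqtl import (
    RunConfig,
    permutation_null,
    permutation_pvalue,
    scan_trios,
    simple_regression,
    sobel_statistic,
    two_predictor_regression,
)
from mediqtl.mediation import slope_pvalue


def ols_oracle(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normal-equation OLS oracle: coefficients and standard errors."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se


class TestSimpleRegression:
    def test_perfect_line(self):
        fit = simple_regression([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.slope_se == pytest.approx(0.0)

    def test_constant_response(self, rng):
        fit = simple_regression(rng.normal(size=20), np.full(20, 3.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            simple_regression(np.ones(10), np.arange(10.0))

    def test_matches_normal_equation_oracle(self, rng):
        x = rng.normal(size=50)
        y = 0.7 * x + rng.normal(size=50)
        fit = simple_regression(x, y)
        beta, se = ols_oracle(np.column_stack([np.ones(50), x]), y)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-10)
        assert fit.slope == pytest.approx(beta[1], rel=1e-10)
        assert fit.slope_se == pytest.approx(se[1], rel=1e-10)

    def test_pairwise_missing_removal(self, rng):
        x = rng.normal(size=30)
        y = 2.0 * x + rng.normal(size=30) * 0.1
        x_nan, y_nan = x.copy(), y.copy()
        x_nan[3] = np.nan
        y_nan[7] = np.nan
        fit = simple_regression(x_nan, y_nan)
        keep = ~(np.isnan(x_nan) | np.isnan(y_nan))
        ref = simple_regression(x[keep], y[keep])
        assert fit.slope == pytest.approx(ref.slope)
        assert fit.n_used == 28


class TestTwoPredictorRegression:
    def test_full_mediation_limit(self, rng):
        m = rng.normal(size=60)
        x = rng.normal(size=60)
        fit = two_predictor_regression(x, m, y=m.copy())
        assert fit.slope_m == pytest.approx(1.0, abs=1e-10)
        assert fit.slope_x == pytest.approx(0.0, abs=1e-10)

    def test_no_mediation_limit(self, rng):
        m = rng.normal(size=60)
        x = rng.normal(size=60)
        fit = two_predictor_regression(x, m, y=x.copy())
        assert fit.slope_x == pytest.approx(1.0, abs=1e-10)
        assert fit.slope_m == pytest.approx(0.0, abs=1e-10)

    def test_collinear_errors(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(ValueError, match="rank deficient"):
            two_predictor_regression(x, 2.0 * x, rng.normal(size=20))

    def test_matches_normal_equation_oracle(self, rng):
        x = rng.normal(size=50)
        m = 0.5 * x + rng.normal(size=50)
        y = 0.3 * m + 0.2 * x + rng.normal(size=50)
        fit = two_predictor_regression(x, m, y)
        beta, se = ols_oracle(np.column_stack([np.ones(50), m, x]), y)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-10)
        assert fit.slope_m == pytest.approx(beta[1], rel=1e-10)
        assert fit.slope_x == pytest.approx(beta[2], rel=1e-10)
        assert fit.slope_m_se == pytest.approx(se[1], rel=1e-10)
        assert fit.slope_x_se == pytest.approx(se[2], rel=1e-10)


class TestSobel:
    def test_null_indirect(self):
        s = sobel_statistic(0.0, 0.2, 1.5, 0.3)
        assert s.indirect == 0.0
        assert s.z == 0.0
        assert s.p_analytic == 1.0

    def test_arithmetic_symmetric(self):
        s = sobel_statistic(1.0, 0.1, 1.0, 0.1)
        assert s.se == pytest.approx(math.sqrt(0.02))
        assert s.z == pytest.approx(7.0711, abs=1e-4)

    def test_arithmetic_asymmetric(self):
        s = sobel_statistic(2.0, 0.5, 3.0, 1.0)
        assert s.se == pytest.approx(2.5)
        assert s.z == pytest.approx(2.4)

    def test_zero_se_edge_cases(self):
        degenerate = sobel_statistic(1.0, 0.0, 2.0, 0.0)
        assert degenerate.z == math.inf and degenerate.p_analytic == 0.0
        null = sobel_statistic(0.0, 0.0, 0.0, 0.0)
        assert null.z == 0.0 and null.p_analytic == 1.0

    @given(
        st.floats(-3, 3), st.floats(0.01, 1), st.floats(-3, 3), st.floats(0.01, 1),
        st.floats(0.1, 10).filter(lambda c: abs(c) > 0.1),
    )
    @settings(deadline=None, max_examples=80)
    def test_scale_invariance(self, b2, se2, b4, se4, c):
        # rescaling the mediator by c maps (b2, se2, b4, se4) ->
        # (c*b2, c*se2, b4/c, se4/c) and must leave z and p unchanged
        base = sobel_statistic(b2, se2, b4, se4)
        scaled = sobel_statistic(c * b2, c * se2, b4 / c, se4 / c)
        assert scaled.z == pytest.approx(base.z, rel=1e-9, abs=1e-12)
        assert scaled.p_analytic == pytest.approx(base.p_analytic, rel=1e-9, abs=1e-12)

    def test_scale_invariance_on_data(self, rng):
        x = rng.binomial(2, 0.3, 100).astype(float)
        m = 0.5 * x + rng.normal(size=100)
        y = 0.5 * m + rng.normal(size=100)
        def z_of(mv):
            f2 = simple_regression(x, mv)
            f4 = two_predictor_regression(x, mv, y)
            return sobel_statistic(f2.slope, f2.slope_se, f4.slope_m, f4.slope_m_se).z
        assert z_of(m * 37.5) == pytest.approx(z_of(m), rel=1e-9)


class TestPermutation:
    def test_deterministic_for_fixed_seed(self, rng):
        x = rng.normal(size=40)
        m = rng.normal(size=40)
        y = rng.normal(size=40)
        a = permutation_null(x, m, y, B=200, seed=42)
        b = permutation_null(x, m, y, B=200, seed=42)
        np.testing.assert_array_equal(a.products, b.products)
        c = permutation_null(x, m, y, B=200, seed=43)
        assert not np.array_equal(a.products, c.products)

    def test_matches_explicit_refit(self, rng):
        # each permuted beta4+ must equal an actual step-4 refit on permuted y,
        # and each beta2+ an actual step-2 refit on permuted m
        n = 30
        x = rng.binomial(2, 0.4, n).astype(float)
        m = rng.normal(size=n)
        y = rng.normal(size=n)
        null = permutation_null(x, m, y, B=5, seed=7)
        rng_replay = np.random.default_rng(7)
        perm_y = np.argsort(rng_replay.random((5, n)), axis=1)
        perm_m = np.argsort(rng_replay.random((5, n)), axis=1)
        for i in range(5):
            b4 = two_predictor_regression(x, m, y[perm_y[i]]).slope_m
            b2 = simple_regression(x, m[perm_m[i]]).slope
            assert null.products[i] == pytest.approx(b2 * b4, rel=1e-10)

    def test_pvalue_add_one_rule(self):
        from mediqtl import PermutationNull

        null = PermutationNull(products=np.linspace(-1, 1, 999), B=999, seed=0)
        assert permutation_pvalue(2.0, null) == pytest.approx(1 / 1000)
        assert permutation_pvalue(0.0, null) == 1.0

    @given(st.floats(-5, 5), st.integers(1, 200))
    @settings(deadline=None, max_examples=40)
    def test_pvalue_lower_bound(self, observed, B):
        from mediqtl import PermutationNull

        rng = np.random.default_rng(B)
        null = PermutationNull(products=rng.normal(size=B), B=B, seed=B)
        p = permutation_pvalue(observed, null)
        assert 1 / (B + 1) <= p <= 1.0

    def test_calibration_under_complete_null(self):
        # permutation p of the observed product is ~uniform when x, m, y are
        # mutually independent: empirical rejection at 0.05 stays near 0.05
        n, B, reps = 100, 2000, 1000
        rng = np.random.default_rng(2718)
        hits = 0
        for i in range(reps):
            x = rng.normal(size=n)
            m = rng.normal(size=n)
            y = rng.normal(size=n)
            f2 = simple_regression(x, m)
            f4 = two_predictor_regression(x, m, y)
            null = permutation_null(x, m, y, B=B, seed=rng.integers(2**31))
            if permutation_pvalue(f2.slope * f4.slope_m, null) <= 0.05:
                hits += 1
        assert hits / reps == pytest.approx(0.05, abs=0.015)

    def test_strong_mediation_attains_minimal_p(self, rng):
        n, B = 200, 2000
        x = rng.binomial(2, 0.3, n).astype(float)
        m = x + rng.normal(size=n) * 0.5
        y = m + rng.normal(size=n) * 0.5
        f2 = simple_regression(x, m)
        f4 = two_predictor_regression(x, m, y)
        null = permutation_null(x, m, y, B=B, seed=1)
        p = permutation_pvalue(f2.slope * f4.slope_m, null)
        assert p <= 2 / (B + 1)


class TestScanTrios:
    def test_single_pair_reduces_to_manual_fits(self, rng):
        from mediqtl import ExpressionMatrix, GenotypeMatrix

        n = 80
        x = rng.binomial(2, 0.4, n).astype(float)
        m = 0.6 * x + rng.normal(size=n)
        y = 0.6 * m + rng.normal(size=n)
        g = GenotypeMatrix([f"S{i}" for i in range(n)], ["rs1"], x[:, None])
        e = ExpressionMatrix([f"S{i}" for i in range(n)], ["pr1"], m[:, None])
        res = list(scan_trios(g, e, y, RunConfig(emit_all=True)))
        assert len(res) == 1
        f2 = simple_regression(x, m)
        f4 = two_predictor_regression(x, m, y)
        expected = sobel_statistic(f2.slope, f2.slope_se, f4.slope_m, f4.slope_m_se)
        r = res[0]
        assert r.beta2 == pytest.approx(f2.slope, rel=1e-10)
        assert r.beta4 == pytest.approx(f4.slope_m, rel=1e-10)
        assert r.beta5 == pytest.approx(f4.slope_x, rel=1e-10)
        assert r.sobel.z == pytest.approx(expected.z, rel=1e-10)
        assert r.sobel.p_analytic == pytest.approx(expected.p_analytic, rel=1e-10)

    def test_planted_trio_is_top_hit(self, planted_dataset):
        from mediqtl import preprocess_expression, preprocess_phenotype

        g, e, p, truth = planted_dataset
        e_norm = preprocess_expression(e, p)
        y = preprocess_phenotype(p)
        res = list(scan_trios(g, e_norm, y, RunConfig(emit_all=True)))
        best = min(res, key=lambda r: (np.nan_to_num(r.sobel.p_analytic, nan=1.0)))
        assert (best.snp_id, best.probe_id) in truth.true_trio_ids()

    def test_null_scan_calibrates(self, null_dataset):
        g, e, p, _ = null_dataset
        cutoff = 1e-3
        res = list(scan_trios(g, e, p.trait, RunConfig(trio_p_cutoff=cutoff)))
        n_tests = g.n_snps * e.n_probes
        lo, hi = binom.ppf([0.005, 0.995], n_tests, cutoff)
        assert lo <= len(res) <= hi

    def test_dimension_mismatch_errors(self, rng):
        from mediqtl import ExpressionMatrix, GenotypeMatrix

        g = GenotypeMatrix(["A", "B", "C"], ["rs1"], np.zeros((3, 1)))
        e = ExpressionMatrix(["A", "B"], ["pr1"], np.zeros((2, 1)))
        with pytest.raises(ValueError, match="aligned"):
            next(iter(scan_trios(g, e, np.zeros(3), RunConfig())))

    def test_screen_then_permute_adds_p_only_below_cutoff(self, planted_dataset):
        g, e, p, truth = planted_dataset
        cfg = RunConfig(trio_p_cutoff=1e-5, permutations=199, emit_all=True, seed=5)
        res = list(scan_trios(g, e, p.trait, cfg))
        with_perm = [r for r in res if r.p_permutation is not None]
        assert with_perm, "the planted trio should pass the screening cutoff"
        for r in with_perm:
            assert r.sobel.p_analytic < 1e-5
            assert 1 / 200 <= r.p_permutation <= 1.0
        for r in res:
            if r.p_permutation is None and np.isfinite(r.sobel.p_analytic):
                assert r.sobel.p_analytic >= 1e-5

    def test_slope_pvalue_helper(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        fit = simple_regression(x, y)
        import scipy.stats as ss

        expected = 2 * ss.t.sf(abs(fit.slope / fit.slope_se), df=38)
        assert slope_pvalue(fit) == pytest.approx(expected)
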