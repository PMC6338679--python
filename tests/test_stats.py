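"""Trajectory statistics: OLS oracle checks, two-lines behavior, Bayes factors."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lccr.stats import (
    association,
    cohens_d_from_t,
    compare_aic,
    fit_polynomial,
    jzs_bayes_factor,
    paired_t,
    student_t,
    two_lines_test,
    variance_ratio_test,
    vif,
    welch_t,
)


def normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direct (X'X)^-1 X'y solution — the independent OLS oracle."""
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFitPolynomial:
    def test_coefficients_match_normal_equations_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12])
        y = np.array([2.1, 3.9, 9.2, 15.8, 26.1, 37.5, 52.0, 68.2,
                      87.1, 108.0, 131.5, 157.3])
        fit = fit_polynomial(x, y, degree=2)
        X = np.column_stack([np.ones_like(x), x, x ** 2])
        expected = normal_equations(X, y)
        np.testing.assert_allclose(
            fit.params[["const", "x", "x2"]].to_numpy(), expected, atol=1e-10)

    def test_exact_linear_fit_flagged_degenerate(self):
        x = np.arange(10.0)
        fit = fit_polynomial(x, 3 * x + 1, degree=1)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.degenerate

    def test_duplicated_column_raises_naming_culprit(self):
        x = np.arange(20.0)
        rng = np.random.default_rng(0)
        y = x + rng.normal(size=20)
        covs = pd.DataFrame({"copy_of_x": x})
        with pytest.raises(ValueError, match="copy_of_x"):
            fit_polynomial(x, y, degree=1, covariates=covs)

    def test_adjusted_r2_never_exceeds_r2(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 50)
        y = x + rng.normal(0, 2, 50)
        fit = fit_polynomial(x, y, degree=2)
        assert fit.adj_r2 <= fit.r2

    def test_nested_loglik_identity(self):
        # -2 (llf_small - llf_large) = n log(RSS_small / RSS_large)
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 80)
        y = 1 + 0.5 * x + 0.2 * x ** 2 + rng.normal(0, 1, 80)
        lin = fit_polynomial(x, y, degree=1)
        quad = fit_polynomial(x, y, degree=2)
        lhs = -2 * (lin.log_likelihood - quad.log_likelihood)
        rhs = 80 * math.log((lin.resid_var) / (quad.resid_var))
        assert lhs == pytest.approx(rhs, rel=1e-10)


class TestCompareAIC:
    def test_identical_fits_tie(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 30)
        y = x + rng.normal(0, 1, 30)
        fit = fit_polynomial(x, y, degree=1)
        winner, diff = compare_aic(fit, fit)
        assert winner == "tie" and diff == 0.0

    def test_strong_quadratic_signal_prefers_quadratic(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, 200)
        y = 1 + x - 0.5 * x ** 2 + rng.normal(0, 0.5, 200)
        quad = fit_polynomial(x, y, degree=2)
        lin = fit_polynomial(x, y, degree=1)
        winner, diff = compare_aic(quad, lin)
        assert winner == "a" and diff > 10

    def test_pure_noise_prefers_smaller_model_on_average(self):
        wins_small = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 10, 100)
            y = rng.normal(0, 1, 100)
            quad = fit_polynomial(x, y, degree=2)
            lin = fit_polynomial(x, y, degree=1)
            winner, _ = compare_aic(quad, lin)
            wins_small += winner == "b"
        assert wins_small > 20

    def test_different_responses_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 30)
        fit1 = fit_polynomial(x, x + rng.normal(0, 1, 30), degree=1)
        fit2 = fit_polynomial(x, 2 * x + rng.normal(0, 1, 30), degree=1)
        with pytest.raises(ValueError):
            compare_aic(fit1, fit2)


class TestTwoLines:
    def test_increasing_line_is_monotonic(self):
        rng = np.random.default_rng(6)
        x = np.linspace(20, 80, 120)
        y = 0.01 * x + rng.normal(0, 0.05, 120)
        res = two_lines_test(x, y)
        assert res.verdict == "monotonic"
        assert res.slope_low > 0

    def test_noise_free_parabola_confirms_u_at_its_peak(self):
        x = np.linspace(20, 80, 121)
        y = -(x - 50.0) ** 2
        res = two_lines_test(x, y)
        assert res.breakpoint_x == pytest.approx(50.0, abs=0.51)
        assert res.verdict == "u_shape_confirmed"
        assert res.slope_low > 0 and res.slope_high < 0
        assert res.p_low < 0.05 and res.p_high < 0.05

    def test_weak_decline_after_rise_is_inconclusive(self):
        # a whole-LC-like mixture: quadratic rise to a peak, then a decline
        # too shallow for its own significance -> upward slope significant,
        # downward not, verdict inconclusive rather than u_shape_confirmed
        rng = np.random.default_rng(31)
        n = 605
        x = rng.uniform(18, 88, n)
        y = np.where(x <= 60, 0.094 - 2e-5 * (x - 60) ** 2,
                     0.094 - 2e-4 * (x - 60)) + rng.normal(0, 0.022, n)
        res = two_lines_test(x, y)
        assert res.verdict == "inconclusive"
        assert res.p_low < 0.001 and res.p_high > 0.05
        assert res.slope_low > 0 > res.slope_high

    def test_fixed_breakpoint_is_honored(self):
        rng = np.random.default_rng(7)
        x = np.linspace(20, 80, 200)
        y = -(x - 50.0) ** 2 / 100 + rng.normal(0, 0.5, 200)
        res = two_lines_test(x, y, breakpoint=57.0)
        assert res.breakpoint_x == 57.0
        assert res.n_low == int((x <= 57).sum())
        assert res.n_low + res.n_high == len(x)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            two_lines_test(np.arange(5.0), np.arange(5.0))

    def test_breakpoint_starving_one_side_rejected(self):
        x = np.linspace(0, 10, 20)
        with pytest.raises(ValueError):
            two_lines_test(x, x ** 2, breakpoint=0.1)


class TestJZSBayesFactor:
    def test_null_favored_printed_value(self):
        # the desk-reproducible published comparison: t(603)=1.46, 295 vs 310
        res = jzs_bayes_factor(1.46, 295, 310)
        assert round(res.bf01, 1) == 3.9

    def test_matches_brute_force_midpoint_oracle(self):
        t, n1, n2, r = 2.5, 30, 30, math.sqrt(2) / 2
        N = n1 * n2 / (n1 + n2)
        nu = n1 + n2 - 2
        u = (np.arange(1_000_000) + 0.5) / 1_000_000
        g = u / (1 - u)
        integrand = (
            (1 + N * g * r ** 2) ** -0.5
            * (1 + t ** 2 / (nu * (1 + N * g * r ** 2))) ** (-(nu + 1) / 2)
            * (2 * np.pi) ** -0.5 * g ** -1.5 * np.exp(-1 / (2 * g))
            / (1 - u) ** 2
        )
        oracle_bf10 = np.mean(integrand) / (1 + t ** 2 / nu) ** (-(nu + 1) / 2)
        res = jzs_bayes_factor(t, n1, n2, r)
        assert res.bf10 == pytest.approx(oracle_bf10, rel=5e-4)

    def test_matches_independent_pingouin_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        for t, n1, n2 in [(1.46, 295, 310), (0.5, 20, 25), (3.2, 50, 40)]:
            expected = float(pingouin.bayesfactor_ttest(
                t, n1, n2, paired=False, r=math.sqrt(2) / 2))
            assert jzs_bayes_factor(t, n1, n2).bf10 == pytest.approx(
                expected, rel=1e-6)

    def test_null_maximally_favored_at_t_zero(self):
        bf01_zero = jzs_bayes_factor(0.0, 30, 30).bf01
        assert bf01_zero > 1
        for t in (0.5, 1.0, 2.0):
            assert bf01_zero > jzs_bayes_factor(t, 30, 30).bf01

    def test_bf10_strictly_increasing_in_abs_t(self):
        ts = np.linspace(0, 4, 17)
        bfs = [jzs_bayes_factor(t, 40, 35).bf10 for t in ts]
        assert np.all(np.diff(bfs) > 0)

    def test_reciprocal_consistency(self):
        res = jzs_bayes_factor(1.7, 25, 30)
        assert res.bf01 * res.bf10 == pytest.approx(1.0, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            jzs_bayes_factor(1.0, 1, 30)
        with pytest.raises(ValueError):
            jzs_bayes_factor(float("nan"), 30, 30)


class TestCohensD:
    def test_printed_effect_size_and_ci(self):
        d, ci = cohens_d_from_t(1.46, 295, 310)
        assert round(d, 2) == 0.12
        assert round(ci[0], 2) == -0.04 and round(ci[1], 2) == 0.28

    def test_zero_t_gives_symmetric_ci_about_zero(self):
        d, ci = cohens_d_from_t(0.0, 40, 40)
        assert d == 0.0
        assert ci[0] == pytest.approx(-ci[1])

    def test_formula_oracle(self):
        d, ci = cohens_d_from_t(2.0, 50, 50)
        assert d == pytest.approx(2.0 * math.sqrt(2 / 50))
        se = math.sqrt(100 / 2500 + d ** 2 / 200)
        assert ci[0] == pytest.approx(d - 1.96 * se)


class TestGroupTests:
    def test_identical_groups_give_t0_p1(self):
        a = [1.0, 2, 3, 4]
        t, df, p = student_t(a, a)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_student_hand_computation(self):
        # means 3 vs 4, each sample variance 2.5 -> t = -1 / sqrt(2.5 * 2/5) = -1
        t, df, p = student_t([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert t == pytest.approx(-1.0, abs=1e-12)
        assert df == 8

    def test_welch_df_below_student_df_for_unequal_variances(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 5, 30)
        b = rng.normal(0, 1, 30)
        _, df_w, _ = welch_t(a, b)
        _, df_s, _ = student_t(a, b)
        assert df_w < df_s

    def test_zero_variance_both_groups_rejected(self):
        with pytest.raises(ValueError):
            student_t([1.0, 1.0], [2.0, 2.0])

    def test_paired_hand_computation(self):
        # pairs (3,1),(4,2),(5,2): diffs {2,2,3}, mean 7/3, se 1/3 -> t = 7
        t, df, p = paired_t([3, 4, 5], [1, 2, 2])
        assert t == pytest.approx(7.0, abs=1e-12)
        assert df == 2

    def test_paired_identical_sides_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0, 2.0])


class TestVarianceRatio:
    def test_shifted_copy_gives_f1(self):
        a = np.array([1.0, 2, 3, 4, 5])
        F, p = variance_ratio_test(a + 10, a)
        assert F == pytest.approx(1.0)

    def test_swap_inverts_f(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 2, 40)
        b = rng.normal(0, 1, 30)
        F1, _ = variance_ratio_test(a, b)
        F2, _ = variance_ratio_test(b, a)
        assert F2 == pytest.approx(1 / F1)

    def test_detects_inflated_variance_at_n300(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            older = rng.normal(0, 1.5, 300)
            younger = rng.normal(0, 1.0, 300)
            F, p = variance_ratio_test(older, younger)
            rejections += p < 0.05
        assert rejections >= 19  # F ~ 2.25 at n=300: essentially always


class TestVIF:
    def test_orthogonal_columns_have_unit_vif(self):
        rng = np.random.default_rng(13)
        u = rng.normal(size=(64, 3))
        u -= u.mean(axis=0)
        q, _ = np.linalg.qr(u)  # exactly orthogonal, centered columns
        design = pd.DataFrame(q, columns=["a", "b", "c"])
        assert np.allclose(vif(design).to_numpy(), 1.0, atol=1e-8)

    def test_duplicated_column_flagged_infinite(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        design = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        v = vif(design)
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_known_correlation_0p8_gives_vif_2p78(self):
        # construct columns with *exact* sample correlation 0.8
        rng = np.random.default_rng(11)
        u = rng.normal(size=(300, 3))
        u -= u.mean(axis=0)
        q, _ = np.linalg.qr(u)
        x1, x2_orth, x3 = q[:, 0], q[:, 1], q[:, 2]
        x2 = 0.8 * x1 + 0.6 * x2_orth
        design = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        v = vif(design)
        assert v["x1"] == pytest.approx(1 / (1 - 0.64), rel=1e-6)
        assert v["x3"] == pytest.approx(1.0, rel=1e-6)


class TestAssociation:
    def test_exact_proportionality(self):
        x = np.arange(1.0, 11)
        res = association(x, 2 * x)
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)

    def test_permutation_pvalues_are_uniform(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 10, 60)
        y = rng.normal(0, 1, 60)
        pvals = []
        for _ in range(200):
            pvals.append(association(x, rng.permutation(y))["p"])
        from scipy import stats as st_
        ks_p = st_.kstest(pvals, "uniform").pvalue
        assert ks_p > 0.01

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            association(np.ones(10), np.arange(10.0))
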