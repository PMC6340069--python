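"""Unit and oracle tests for the statistical kernel."""

import math
from fractions import Fraction

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gxescore.stats_core import (
    bh_adjust,
    cochran_armitage,
    descriptive_tests,
    fit_logistic,
    hwe_exact,
    odds_ratio_ci,
)

from conftest import two_by_two_design


# ---------------------------------------------------------------------------
# logistic regression


class TestFitLogistic:
    def test_crude_or_matches_printed_agrichem_value(self):
        """Cases 46/123 vs controls 26/395 exposed give OR 5.68 with a Wald
        interval close to the published 3.4-9.69."""
        X, y = two_by_two_design(46, 123, 26, 395)
        fit = fit_logistic(X, y, ["intercept", "agrichem"])
        or_, lo, hi = odds_ratio_ci(fit, "agrichem")
        assert round(or_, 2) == 5.68
        assert 3.3 <= lo <= 3.5
        assert 9.4 <= hi <= 9.8

    def test_symmetric_table_gives_null_or(self):
        X, y = two_by_two_design(30, 70, 30, 70)
        fit = fit_logistic(X, y)
        assert abs(fit.coef[1]) < 1e-8
        assert round(odds_ratio_ci(fit, "x1")[0], 10) == 1.0

    def test_two_by_two_or_equals_cross_product_ratio(self, rng):
        """Saturated-model identity: exp(beta) == ad/bc, 1000 random tables."""
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 60, size=4)
            X, y = two_by_two_design(a, b, c, d)
            fit = fit_logistic(X, y)
            assert math.exp(fit.coef[1]) == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_zero_exposed_controls_separates(self):
        """The benzene pattern (0/421 controls vs 11/158 cases exposed)."""
        X, y = two_by_two_design(11, 158, 0, 421)
        fit = fit_logistic(X, y, ["intercept", "benzene"])
        assert fit.separation and "benzene" in fit.separated_terms
        or_, lo, hi = odds_ratio_ci(fit, "benzene")
        assert math.isnan(or_) and lo == 0.0 and hi == math.inf

    def test_loglik_monotone_and_gradient_small_on_converged_fits(self, rng):
        for _ in range(20):
            n, p = 120, 4
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            beta = rng.normal(scale=0.8, size=p)
            y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(float)
            if y.min() == y.max():
                continue
            fit = fit_logistic(X, y)
            trace = np.array(fit.loglik_trace)
            assert (np.diff(trace) >= -1e-9).all()
            if fit.converged:
                mu = 1 / (1 + np.exp(-(X @ fit.coef)))
                assert np.linalg.norm(X.T @ (y - mu)) < 1e-8

    def test_matches_statsmodels_mle(self, rng):
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + X[:, 1] - 0.5 * X[:, 2])))).astype(float)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=False)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-5)

    def test_complete_case_drops_rows_with_missing(self):
        X, y = two_by_two_design(20, 30, 10, 40)
        X[0, 1] = np.nan
        fit = fit_logistic(X, y)
        assert fit.n_used == len(y) - 1

    def test_constant_outcome_raises(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(X, np.ones(10))

    def test_collinear_design_names_columns(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, 2 * x])
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_logistic(X, y, ["intercept", "x", "x2"])


class TestOddsRatioCI:
    def test_closed_form(self):
        X, y = two_by_two_design(25, 25, 25, 25)
        fit = fit_logistic(X, y)
        fit.coef[1], fit.se[1] = 0.0, 0.5
        fit.separated_terms = []
        or_, lo, hi = odds_ratio_ci(fit, "x1")
        z = sps.norm.ppf(0.975)
        assert or_ == pytest.approx(1.0)
        assert lo == pytest.approx(math.exp(-z * 0.5))
        assert hi == pytest.approx(math.exp(z * 0.5))

    def test_higher_level_widens_interval(self):
        X, y = two_by_two_design(30, 20, 15, 35)
        fit = fit_logistic(X, y)
        _, lo95, hi95 = odds_ratio_ci(fit, "x1", 0.95)
        _, lo99, hi99 = odds_ratio_ci(fit, "x1", 0.99)
        assert lo99 < lo95 and hi99 > hi95


# ---------------------------------------------------------------------------
# exact HWE test


def hwe_enumeration_oracle(n_hom_rare: int, n_het: int, n_hom_common: int) -> float:
    """Independent brute force in exact rational arithmetic."""
    n = n_hom_rare + n_het + n_hom_common
    rare = 2 * min(n_hom_rare, n_hom_common) + n_het
    if rare == 0:
        return 1.0
    denom = math.comb(2 * n, rare)
    probs = {}
    for het in range(rare % 2, rare + 1, 2):
        hr = (rare - het) // 2
        hc = n - het - hr
        if hc < 0:
            continue
        num = math.comb(n, hr) * math.comb(n - hr, het) * 2**het
        probs[het] = Fraction(num, denom)
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHweExact:
    def test_monomorphic_marker(self):
        assert hwe_exact(0, 0, 379) == 1.0

    def test_printed_sparse_table_matches_enumeration(self):
        """Control counts 0/18/379 of the sparsest published marker."""
        p = hwe_exact(0, 18, 379)
        assert p == pytest.approx(hwe_enumeration_oracle(0, 18, 379), rel=1e-10)

    def test_label_symmetry(self):
        assert hwe_exact(5, 20, 30) == pytest.approx(hwe_exact(30, 20, 5), rel=1e-12)

    def test_exhaustive_agreement_up_to_n_50(self):
        """Every genotype table with n <= 50 matches the rational-arithmetic
        enumeration oracle."""
        for n in range(1, 51):
            for hr in range(n + 1):
                for het in range(n - hr + 1):
                    hc = n - hr - het
                    p = hwe_exact(hr, het, hc)
                    assert p == pytest.approx(
                        hwe_enumeration_oracle(hr, het, hc), rel=1e-9
                    ), (hr, het, hc)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact(-1, 2, 3)


# ---------------------------------------------------------------------------
# Cochran-Armitage trend test


class TestCochranArmitage:
    def test_published_counts_give_extreme_p(self):
        stat, p = cochran_armitage((116, 46, 0), (379, 18, 0))
        assert p < 1e-10

    def test_null_table(self):
        stat, p = cochran_armitage((10, 20, 5), (20, 40, 10))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_statistic_equals_squared_trend_correlation(self, rng):
        """Closed-form identity: with hypergeometric variance the statistic
        is (N-1) * corr(dose, status)^2."""
        for _ in range(200):
            cases = tuple(rng.integers(0, 20, size=3))
            controls = tuple(rng.integers(0, 20, size=3))
            if sum(cases) == 0 or sum(controls) == 0:
                continue
            doses = np.repeat([0, 1, 2, 0, 1, 2], list(cases) + list(controls)).astype(float)
            y = np.r_[np.ones(sum(cases)), np.zeros(sum(controls))]
            if np.std(doses) == 0:
                continue
            stat, _ = cochran_armitage(cases, controls)
            r = np.corrcoef(doses, y)[0, 1]
            assert stat == pytest.approx((len(y) - 1) * r * r, rel=1e-9)

    def test_p_within_permutation_null_bracket(self, rng):
        """The chi2(1) p lies inside the [P(T > t), P(T >= t)] bracket of a
        1e5 label-permutation null (discrete), up to Monte-Carlo error."""
        cases, controls = (3, 9, 4), (10, 11, 3)
        doses = np.repeat([0, 1, 2, 0, 1, 2], [3, 9, 4, 10, 11, 3]).astype(float)
        y = np.r_[np.ones(16), np.zeros(24)]
        stat_obs, p_chi2 = cochran_armitage(cases, controls)

        n_perm = 100_000
        perm = np.argsort(rng.random((n_perm, y.size)), axis=1)
        yp = y[perm]
        geq = gt = 0
        for block in np.array_split(np.arange(n_perm), 20):
            stats_blk = np.array([
                cochran_armitage(
                    tuple(int(((doses == k) & (yb == 1)).sum()) for k in (0, 1, 2)),
                    tuple(int(((doses == k) & (yb == 0)).sum()) for k in (0, 1, 2)),
                )[0]
                for yb in yp[block]
            ])
            geq += int((stats_blk >= stat_obs - 1e-9).sum())
            gt += int((stats_blk > stat_obs + 1e-9).sum())
        p_geq, p_gt = geq / n_perm, gt / n_perm
        se = math.sqrt(max(p_geq * (1 - p_geq), p_gt * (1 - p_gt)) / n_perm)
        assert p_gt - 4 * se <= p_chi2 <= p_geq + 4 * se

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cochran_armitage((0, 0, 0), (10, 5, 2))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.05]).tolist() == [0.05]

    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_reference_step_up(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ref = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(pvals), ref, atol=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30), st.randoms(use_true_random=False))
    def test_permutation_equivariance_and_ordering(self, pvals, rand):
        p = np.array(pvals)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()
        perm = list(range(len(p)))
        rand.shuffle(perm)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-15)


# ---------------------------------------------------------------------------
# descriptive tests


class TestDescriptiveTests:
    def test_gender_counts_not_significant(self):
        """258/163 vs 103/66 female/male: balanced by design, p > 0.05."""
        v = np.r_[np.zeros(258), np.ones(163), np.zeros(103), np.ones(66)]
        y = np.r_[np.zeros(421), np.ones(169)]
        res = descriptive_tests(v, y, "gender", kind="categorical")
        assert res.p > 0.05 and not res.significant

    def test_perfectly_balanced_table(self):
        v = np.r_[np.zeros(50), np.ones(50), np.zeros(50), np.ones(50)]
        y = np.r_[np.zeros(100), np.ones(100)]
        assert descriptive_tests(v, y, kind="categorical").p == pytest.approx(1.0)

    def test_chi_square_matches_direct_formula(self, rng):
        for _ in range(50):
            tab = rng.integers(5, 50, size=(2, 2)).astype(float)
            v = np.repeat([0, 1, 0, 1], tab.ravel().astype(int)).astype(float)
            y = np.repeat([0, 0, 1, 1], tab.ravel().astype(int)).astype(float)
            exp = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
            stat = ((tab - exp) ** 2 / exp).sum()
            p_oracle = sps.chi2.sf(stat, df=1)
            assert descriptive_tests(v, y, kind="categorical").p == pytest.approx(
                p_oracle, rel=1e-9
            )

    def test_continuous_reports_both_tests(self, rng):
        v = np.r_[rng.normal(0, 1, 60), rng.normal(0.8, 1, 60)]
        y = np.r_[np.zeros(60), np.ones(60)]
        res = descriptive_tests(v, y, "age", kind="continuous")
        assert res.p < 0.05 and res.p_wilcoxon is not None and res.p_wilcoxon < 0.05

    def test_constant_variable_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            res = descriptive_tests(np.ones(20), np.r_[np.zeros(10), np.ones(10)])
        assert res.p == 1.0
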