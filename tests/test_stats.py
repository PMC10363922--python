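"""Correlation and two-sample statistics against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import speccurve as sc


def brute_force_rho(x, y):
    """1 − 6 Σd² / (n(n²−1)) on untied ranks."""
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = ((rx - ry) ** 2).sum()
    return 1 - 6 * d2 / (n * (n * n - 1))


def exact_rank_sum_p(a, b):
    """Exhaustive two-sided rank-sum p over all rank assignments."""
    pooled = np.concatenate([a, b])
    assert len(np.unique(pooled)) == len(pooled), "oracle assumes no ties"
    n_a = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1
    obs_u = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    mu = n_a * len(b) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n_a):
        r = np.sort(ranks)[list(combo)]
        us.append(r.sum() - n_a * (n_a + 1) / 2)
    us = np.array(us)
    return float(np.mean(np.abs(us - mu) >= abs(obs_u - mu)))


class TestSpearman:
    def test_perfect_monotone(self):
        assert sc.spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == 1.0
        assert sc.spearman([1, 2, 3, 4], [40, 30, 20, 10]).rho == -1.0

    def test_small_example_matches_brute_force(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        res = sc.spearman(x, y)
        assert res.rho == pytest.approx(brute_force_rho(x, y), abs=1e-12)
        assert res.rho == pytest.approx(0.8)
        assert res.n == 5

    def test_pairwise_deletion_and_min_n(self):
        x = [1, 2, np.nan, 4, 5, 6]
        y = [2, 4, 5, np.nan, 9, 12]
        res = sc.spearman(x, y)
        assert res.n == 4
        too_few = sc.spearman([1, 2, 3], [3, 1, 2])
        assert too_few.missing and too_few.n == 3

    def test_ci_brackets_rho(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        res = sc.spearman(x, y)
        assert res.ci_low <= res.rho <= res.ci_high
        assert -1 <= res.ci_low and res.ci_high <= 1

    def test_bonett_wright_ci_is_wider_near_zero(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        f = sc.spearman(x, y, ci_method="fisher")
        b = sc.spearman(x, y, ci_method="bonett-wright")
        assert (b.ci_high - b.ci_low) > (f.ci_high - f.ci_low)
        assert b.rho == f.rho

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.permutations(list(range(7))))
    def test_matches_brute_force_on_untied_vectors(self, perm):
        x = np.arange(7.0)
        y = np.asarray(perm, dtype=float)
        assert sc.spearman(x, y).rho == pytest.approx(
            brute_force_rho(x, y), abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.integers(-10 ** 6, 10 ** 6), min_size=5, max_size=30,
                    unique=True),
           st.integers(0, 2 ** 31))
    def test_symmetry_and_monotone_invariance(self, xs, seed):
        rng = np.random.default_rng(seed)
        x = np.asarray(xs, dtype=float)
        y = rng.normal(size=len(x))
        a = sc.spearman(x, y)
        assert a.rho == pytest.approx(sc.spearman(y, x).rho, abs=1e-12)
        # strictly increasing transform of x leaves rho unchanged
        b = sc.spearman(np.arctan(x / 1000.0), y)
        assert a.rho == pytest.approx(b.rho, abs=1e-12)

    def test_null_p_values_reject_at_nominal_rate(self):
        """Under independence the t-approximation p is ~uniform."""
        rng = np.random.default_rng(1234)
        n, reps = 50, 5000
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        rejections = sum(sc.spearman(x[i], y[i]).p_value < 0.05
                         for i in range(reps))
        assert 0.04 <= rejections / reps <= 0.06


class TestPartialSpearman:
    def test_empty_covariates_reduce_to_plain(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        assert sc.partial_spearman(x, y, []) == sc.spearman(x, y)

    def test_independent_covariate_changes_little(self):
        rng = np.random.default_rng(7)
        n = 10_000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        plain = sc.spearman(x, y).rho
        part = sc.partial_spearman(x, y, [z]).rho
        assert part == pytest.approx(plain, abs=0.02)

    def test_y_linear_in_covariate_residualizes_to_zero(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=1000)
        x = 0.4 * z + rng.normal(size=1000)
        # exactly collinear: no rank variance left once z is removed
        exact = sc.partial_spearman(x, 2.0 + 3.0 * z, [z])
        assert exact.rho == 0.0 and exact.p_value == 1.0
        # near-collinear: residual association is sampling noise around 0
        y = 2.0 + 3.0 * z + 0.01 * rng.normal(size=1000)
        assert abs(sc.partial_spearman(x, y, [z]).rho) < 0.05

    def test_constant_covariate_dropped_with_warning(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        with pytest.warns(UserWarning, match="constant"):
            res = sc.partial_spearman(x, y, [np.ones(25)])
        assert res.rho == pytest.approx(sc.spearman(x, y).rho)

    def test_matches_pingouin_partial_correlation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        n = 80
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        x = 0.5 * z1 - 0.3 * z2 + rng.normal(size=n)
        y = -0.4 * z1 + 0.2 * z2 + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "z1": z1, "z2": z2})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"],
                                    method="spearman")
        res = sc.partial_spearman(x, y, [z1, z2])
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]),
                                            rel=1e-6)

    def test_listwise_deletion_counts_covariate_missingness(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        z = rng.normal(size=20)
        z[:5] = np.nan
        assert sc.partial_spearman(x, y, [z]).n == 15


class TestWilcoxonRankSum:
    def test_identical_samples_give_p_one(self):
        res = sc.wilcoxon_rank_sum_cc([1, 2, 3], [1, 2, 3],
                                      bootstrap_reps=200, rng=0)
        assert res.p_value == 1.0
        assert res.effect_r == 0.0
        assert res.effect_r_ci_low <= 0.0 + 1e-12

    def test_complete_separation_close_to_exact_enumeration(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [10.0, 11.0, 12.0, 13.0]
        exact = exact_rank_sum_p(np.array(a), np.array(b))
        assert exact == pytest.approx(2 / 70)  # 2 of C(8,4) assignments
        res = sc.wilcoxon_rank_sum_cc(a, b, bootstrap_reps=0)
        # continuity-corrected normal approximation of the exact tail
        assert res.p_value == pytest.approx(exact, abs=0.005)
        assert res.statistic == 0.0  # U of the first (lower) sample

    def test_statistic_is_u_of_first_sample(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(size=12)
        res = sc.wilcoxon_rank_sum_cc(a, b, bootstrap_reps=0)
        from scipy.stats import mannwhitneyu
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.statistic == pytest.approx(float(ref.statistic))
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_effect_r_ci_brackets_point_estimate(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(loc=1.0, size=30)
        res = sc.wilcoxon_rank_sum_cc(a, b, bootstrap_reps=400, rng=1)
        assert res.effect_r_ci_low <= res.effect_r <= res.effect_r_ci_high
        assert 0 <= res.effect_r <= 1

    def test_all_missing_input_is_an_error(self):
        with pytest.raises(ValueError):
            sc.wilcoxon_rank_sum_cc([np.nan, np.nan], [1.0, 2.0])


class TestWelchT:
    def test_identical_samples(self):
        res = sc.welch_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_hand_computed_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 2.0, 3.0, 40.0])
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / 4 + vb / 4
        t = (a.mean() - b.mean()) / math.sqrt(se2)
        df = se2 ** 2 / ((va / 4) ** 2 / 3 + (vb / 4) ** 2 / 3)
        from scipy.stats import t as tdist
        p = 2 * tdist.sf(abs(t), df)
        res = sc.welch_t(a, b)
        assert res.statistic == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_shift_moves_t_monotonically(self, rng):
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        ts = [sc.welch_t(a, b + shift).statistic
              for shift in (-1.0, 0.0, 1.0, 2.0)]
        assert ts == sorted(ts, reverse=True)

    def test_too_small_sample_is_an_error(self):
        with pytest.raises(ValueError):
            sc.welch_t([1.0], [1.0, 2.0])
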