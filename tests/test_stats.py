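"""Inferential routines against closed forms, oracles, and calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

import sfcoupling as sf
from sfcoupling.stats import anova_oneway, tamhane_t2


def orthonormal_pair(n, rng):
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    a = (a - a.mean()) / a.std()
    b = b - b.mean() - (b @ a) / (a @ a) * a
    b = b / b.std()
    return a, b


# ---------------------------------------------------------------------------
# spin test
# ---------------------------------------------------------------------------


class TestSpinTest:
    def test_identical_maps_give_unit_correlation(self, region_set_small):
        g = region_set_small.gradient
        res = sf.spin_test(g, g, region_set_small, n_rotations=100, seed=0)
        assert res.r_emp == pytest.approx(1.0)
        assert res.p_spin >= 1 / 101

    def test_zero_rotations_rejected(self, region_set_small):
        g = region_set_small.gradient
        with pytest.raises(ValueError):
            sf.spin_test(g, g, region_set_small, n_rotations=0, seed=0)

    def test_reproducible_null_distribution(self, region_set_small):
        g, m = region_set_small.gradient, region_set_small.myelin
        a = sf.spin_test(g, m, region_set_small, n_rotations=50, seed=4)
        b = sf.spin_test(g, m, region_set_small, n_rotations=50, seed=4)
        np.testing.assert_array_equal(a.null_r, b.null_r)
        assert a.p_spin == b.p_spin

    def test_null_correlations_bounded(self, region_set_small):
        g, m = region_set_small.gradient, region_set_small.myelin
        res = sf.spin_test(g, m, region_set_small, n_rotations=200, seed=1)
        assert np.all(np.abs(res.null_r) <= 1 + 1e-12)
        assert 1 / 201 <= res.p_spin <= 1.0

    def test_missing_values_are_ignored(self, region_set_small):
        g = region_set_small.gradient.copy()
        m = region_set_small.myelin
        g[:5] = np.nan
        res = sf.spin_test(g, m, region_set_small, n_rotations=50, seed=0)
        ok = np.isfinite(g)
        want = sps.spearmanr(g[ok], m[ok]).statistic
        assert res.r_emp == pytest.approx(want, abs=1e-12)


# ---------------------------------------------------------------------------
# Fisher combination, FDR
# ---------------------------------------------------------------------------


class TestFisher:
    def test_all_ones(self):
        res = sf.fisher_combine([1.0, 1.0, 1.0])
        assert res.T == 0.0
        assert res.p_fisher == pytest.approx(1.0)
        assert res.df == 6

    @pytest.mark.parametrize("q", [0.3, 0.05, 0.9])
    def test_single_p_identity(self, q):
        # with df=2 the chi-square survival is exp(-T/2) = q exactly
        assert sf.fisher_combine([q]).p_fisher == pytest.approx(q, abs=1e-12)

    def test_two_p_chi_square_oracle(self):
        res = sf.fisher_combine([0.05, 0.05])
        t = -4 * np.log(0.05)
        assert res.T == pytest.approx(t, abs=1e-12)
        assert res.df == 4
        assert res.p_fisher == pytest.approx(sps.chi2.sf(t, 4), abs=1e-15)

    def test_nine_subjects_use_18_df(self):
        assert sf.fisher_combine(np.full(9, 0.2)).df == 18

    @pytest.mark.parametrize("bad", [[0.0], [1.2], [-0.1]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            sf.fisher_combine(bad)

    @settings(deadline=None, max_examples=50)
    @given(
        p=hst.lists(hst.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=8),
        idx=hst.integers(min_value=0, max_value=7),
        shrink=hst.floats(min_value=0.1, max_value=0.99),
    )
    def test_monotone_in_each_p(self, p, idx, shrink):
        idx = idx % len(p)
        smaller = list(p)
        smaller[idx] = p[idx] * shrink
        assert sf.fisher_combine(smaller).p_fisher <= sf.fisher_combine(p).p_fisher + 1e-15


class TestBhFdr:
    def test_hand_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        # step-up: p_(i) * m / i with monotonicity from the largest down
        want = np.array([0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(sf.bh_fdr(p), want, atol=1e-12)

    def test_distinct_spacing(self):
        p = np.array([0.005, 0.04, 0.2, 0.9])
        raw = p * 4 / np.arange(1, 5)
        want = np.minimum.accumulate(raw[::-1])[::-1]
        np.testing.assert_allclose(sf.bh_fdr(p), want, atol=1e-12)

    def test_all_equal_and_single(self):
        np.testing.assert_allclose(sf.bh_fdr([0.3, 0.3, 0.3]), 0.3)
        np.testing.assert_allclose(sf.bh_fdr([0.07]), [0.07])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sf.bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(
        p=hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12)
    )
    def test_adjusted_at_least_raw_and_order_preserving(self, p):
        adj = sf.bh_fdr(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# ANOVA + Tamhane
# ---------------------------------------------------------------------------


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = np.array(list("aaabbb"))
        f, p = anova_oneway(vals, labels)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_three_group_sums_of_squares_oracle(self):
        vals = np.array([2.0, 3.0, 4.0, 6.0, 7.0, 8.0, 10.0, 12.0, 14.0])
        labels = np.repeat(["a", "b", "c"], 3)
        f, p = anova_oneway(vals, labels)
        grand = vals.mean()
        groups = [vals[labels == k] for k in "abc"]
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        want_f = (ssb / 2) / (ssw / 6)
        assert f == pytest.approx(want_f, abs=1e-10)
        assert p == pytest.approx(sps.f.sf(want_f, 2, 6), abs=1e-12)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_tamhane_table_shape_and_bounds(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate(
            [rng.normal(0, 1, 20), rng.normal(1, 3, 20), rng.normal(2, 0.5, 20)]
        )
        labels = np.repeat(["a", "b", "c"], 20)
        tab = tamhane_t2(vals, labels)
        assert len(tab) == 3
        assert np.all((tab["p_adj"] >= 0) & (tab["p_adj"] <= 1))
        assert np.all(tab["p_adj"] >= tab["p_raw"] - 1e-15)

    def test_tamhane_welch_statistic_oracle(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([10.0, 12.0, 8.0, 9.0, 11.0])
        tab = tamhane_t2(np.concatenate([a, b]), ["a"] * 4 + ["b"] * 5)
        t_want = sps.ttest_ind(a, b, equal_var=False).statistic
        assert tab["t"].iloc[0] == pytest.approx(t_want, abs=1e-10)


# ---------------------------------------------------------------------------
# Breusch-Pagan
# ---------------------------------------------------------------------------


class TestBreuschPagan:
    def test_detects_variance_growing_with_x_squared(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            x = rng.uniform(1, 3, 500)
            y = 1.0 + 2.0 * x + rng.standard_normal(500) * x**2
            _, p = sf.breusch_pagan(y, x)
            hits += p < 0.05
        assert hits >= 95

    def test_calibrated_under_homoscedasticity(self):
        ps = []
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            x = rng.uniform(-1, 1, 500)
            y = 0.5 * x + rng.standard_normal(500)
            ps.append(sf.breusch_pagan(y, x)[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_perfect_fit_rejected(self):
        x = np.linspace(0, 1, 50)
        with pytest.raises(ValueError):
            sf.breusch_pagan(3.0 * x + 1.0, x)


# ---------------------------------------------------------------------------
# centering, design, VIF
# ---------------------------------------------------------------------------


class TestCenterAndDesign:
    def test_center_forced_arithmetic(self):
        np.testing.assert_allclose(sf.center([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])
        assert abs(sf.center(np.random.default_rng(0).normal(5, 2, 100)).mean()) < 1e-12
        np.testing.assert_allclose(sf.center([4.0, 4.0]), [0.0, 0.0])

    def test_self_interaction_equals_centered_square(self):
        rng = np.random.default_rng(1)
        x = rng.normal(2, 1, 50)
        d = sf.build_design({"a": x, "b": x.copy() + 0.0}, interaction=("a", "b"))
        np.testing.assert_allclose(
            d["a_x_b"].to_numpy(), sf.center(x) ** 2, atol=1e-12
        )

    def test_interaction_mean_equals_covariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        d = sf.build_design({"x": x, "y": y}, interaction=("x", "y"))
        cov = np.mean(sf.center(x) * sf.center(y))
        assert d["x_x_y"].mean() == pytest.approx(cov, abs=1e-12)

    def test_no_options_gives_predictors_with_intercept(self):
        d = sf.build_design({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        assert list(d.columns) == ["const", "a", "b"]
        np.testing.assert_allclose(d["const"], 1.0)

    def test_name_collision_rejected(self):
        with pytest.raises(ValueError):
            sf.build_design(
                {"a": [1.0, 2.0, 3.0]}, covariates={"a": [1.0, 2.0, 3.0]}
            )


class TestVif:
    def test_orthogonal_columns_give_unit_vif(self):
        a, b = orthonormal_pair(100, np.random.default_rng(3))
        v = sf.vif(pd.DataFrame({"a": a, "b": b}))
        np.testing.assert_allclose(v.to_numpy(), 1.0, atol=1e-9)

    def test_correlation_09_closed_form(self):
        a, b = orthonormal_pair(200, np.random.default_rng(4))
        x2 = 0.9 * a + np.sqrt(1 - 0.81) * b
        v = sf.vif(pd.DataFrame({"a": a, "x2": x2}))
        np.testing.assert_allclose(v.to_numpy(), 1 / (1 - 0.81), atol=1e-9)

    def test_perfect_collinearity_is_infinite(self):
        a, _ = orthonormal_pair(50, np.random.default_rng(5))
        v = sf.vif(pd.DataFrame({"a": a, "b": 2.0 * a}))
        assert np.isinf(v).all()


# ---------------------------------------------------------------------------
# bootstrap OLS
# ---------------------------------------------------------------------------


class TestBootstrapOls:
    def test_noise_free_fit_has_unit_beta_and_tight_interval(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=100)
        res = sf.bootstrap_ols(2.0 * x, sf.build_design({"x": x}), n_boot=200, seed=0)
        assert res.beta_stand[0] == pytest.approx(1.0, abs=1e-10)
        assert res.bci[0, 1] - res.bci[0, 0] < 1e-8

    def test_single_predictor_beta_equals_pearson_r(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=150)
        y = 0.4 * x + rng.normal(size=150)
        res = sf.bootstrap_ols(y, sf.build_design({"x": x}), n_boot=50, seed=0)
        assert res.beta_stand[0] == pytest.approx(
            sps.pearsonr(x, y).statistic, abs=1e-10
        )

    def test_duplicated_predictor_rejected(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        d = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="collinear"):
            sf.bootstrap_ols(rng.normal(size=50), d, n_boot=10, seed=0)

    def test_reproducible(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=80)
        y = 0.5 * x + rng.normal(size=80)
        d = sf.build_design({"x": x})
        a = sf.bootstrap_ols(y, d, n_boot=100, seed=3)
        b = sf.bootstrap_ols(y, d, n_boot=100, seed=3)
        np.testing.assert_array_equal(a.bci, b.bci)
        np.testing.assert_array_equal(a.p_boot, b.p_boot)


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


class TestMediate:
    def test_ols_identity_on_arbitrary_data(self):
        rng = np.random.default_rng(10)
        x, m, y = rng.normal(size=(3, 60))
        res = sf.mediate(x, m, y, n_boot=50, seed=0)
        assert res.total - (res.direct + res.indirect) == pytest.approx(0.0, abs=1e-10)

    def test_generative_recovery(self):
        rng = np.random.default_rng(11)
        n = 2000
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.4 * m + 0.1 * x + rng.normal(size=n)
        res = sf.mediate(x, m, y, n_boot=500, seed=1)
        assert res.indirect == pytest.approx(0.20, abs=0.05)
        assert res.indirect_bci[0] > 0

    def test_null_mediator_interval_covers_zero(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(2000 + s)
            x = rng.normal(size=500)
            m = rng.normal(size=500)  # independent of x and y
            y = 0.3 * x + rng.normal(size=500)
            res = sf.mediate(x, m, y, n_boot=200, seed=s)
            hits += res.indirect_bci[0] <= 0 <= res.indirect_bci[1]
        assert hits >= 90

    def test_zero_variance_input_rejected(self):
        with pytest.raises(ValueError):
            sf.mediate(np.ones(50), np.arange(50.0), np.arange(50.0), n_boot=10, seed=0)
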