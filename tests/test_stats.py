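"""Statistical operators checked against enumeration oracles, closed forms
and independent library implementations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst
from scipy import stats as sps

from tmaquant import stats as st

# ---------------------------------------------------------------------------
# paired comparisons


class TestWilcoxon:
    def test_all_positive_differences_exact_enumeration(self):
        """d = {1..5}: only 1 of the 2^5 sign patterns reaches W+ = 15, so the
        two-sided exact p is 2/32."""
        res = st.wilcoxon_signed_rank(np.array([1.0, 2, 3, 4, 5]), np.zeros(5))
        assert res.statistic == 15.0
        assert res.p_value == pytest.approx(2 / 32)

    def test_identical_pairs_degenerate(self):
        res = st.paired_compare([1.0, 2, 3], [1.0, 2, 3])
        assert res.degenerate
        assert res.p_value == 1.0

    def test_exact_p_matches_full_sign_enumeration(self, rng):
        """Brute-force oracle: enumerate all 2^n sign assignments."""
        for _ in range(5):
            d = rng.normal(size=9)
            d = d[d != 0]
            ranks = sps.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            ws = [
                ranks[np.array(signs, dtype=bool)].sum()
                for signs in itertools.product([0, 1], repeat=d.size)
            ]
            ws = np.array(ws)
            p_oracle = min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))
            res = st.wilcoxon_signed_rank(d)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_normal_approximation_matches_scipy(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        mine = st.wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, correction=False, mode="approx")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_auto_selects_wilcoxon_for_skewed_differences(self, rng):
        normal = rng.normal(size=60)
        tumor = normal + rng.exponential(2.0, size=60) ** 3
        res = st.paired_compare(tumor, normal, method="auto")
        assert res.method.startswith("wilcoxon")

    def test_auto_selects_t_for_normal_differences(self, rng):
        normal = rng.normal(size=60)
        tumor = normal + rng.normal(1.0, 1.0, size=60)
        res = st.paired_compare(tumor, normal, method="auto")
        assert res.method == "paired_t"


class TestMannWhitney:
    def test_separated_groups_exact(self):
        """{1,2,3} vs {10,20,30}: U = 0, two-sided exact p = 2/20."""
        res = st.mann_whitney_u([1.0, 2, 3], [10.0, 20, 30])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_p_near_one(self):
        res = st.mann_whitney_u([5.0, 5, 5, 5], [5.0, 5, 5, 5])
        assert res.p_value > 0.99

    def test_exact_matches_permutation_enumeration(self, rng):
        """Oracle: U distribution over all C(n1+n2, n1) rank assignments."""
        for _ in range(4):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            combined = np.concatenate([x, y])
            ranks = sps.rankdata(combined)
            u_obs = ranks[:5].sum() - 5 * 6 / 2
            us = [
                ranks[list(pick)].sum() - 5 * 6 / 2
                for pick in itertools.combinations(range(11), 5)
            ]
            us = np.array(us)
            p_oracle = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
            res = st.mann_whitney_u(x, y)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_tied_data_matches_scipy_asymptotic(self, rng):
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(1, 6, 25).astype(float)
        mine = st.mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic", use_continuity=False)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestKruskalWallis:
    def test_rank_formula_hand_computation(self):
        """{1,2},{3,4},{5,6}: H = 12/(6*7) * (3^2/2 + 7^2/2 + 11^2/2) - 21."""
        res = st.kruskal_wallis([[1.0, 2], [3.0, 4], [5.0, 6]])
        assert res.statistic == pytest.approx(12 / 42 * (9 / 2 + 49 / 2 + 121 / 2) - 21)
        assert res.statistic == pytest.approx(
            sps.kruskal([1, 2], [3, 4], [5, 6]).statistic
        )

    def test_group_assoc_dispatch(self, rng):
        values = rng.normal(size=30)
        labels = np.repeat(["a", "b", "c"], 10)
        res = st.group_assoc(values, labels)
        assert res.method == "kruskal_wallis"
        res2 = st.group_assoc(values, np.repeat(["a", "b"], 15), parametric=True)
        assert res2.method == "t_test"

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            st.group_assoc([1.0, 2.0], ["a", "a"])


# ---------------------------------------------------------------------------
# contingency tables


class TestCategorical:
    def test_independent_table_chi2_zero(self):
        res = st.chi_square_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_chi2_matches_scipy_no_correction(self, rng):
        t = rng.integers(1, 30, (3, 4))
        mine = st.chi_square_test(t)
        ref = sps.chi2_contingency(t, correction=False)
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue)

    def test_fisher_matches_hypergeometric_enumeration(self):
        """[[1,9],[11,3]]: sum P(tables) with P <= P(observed), margins fixed."""
        t = np.array([[1, 9], [11, 3]])
        res = st.fisher_exact_2x2(t)
        p_obs = sps.hypergeom.pmf(1, 24, 10, 12)
        total = sum(
            p
            for a in range(max(0, 12 - 14), min(12, 10) + 1)
            if (p := sps.hypergeom.pmf(a, 24, 10, 12)) <= p_obs * (1 + 1e-9)
        )
        assert res.p_value == pytest.approx(total)
        assert res.p_value == pytest.approx(sps.fisher_exact(t)[1])

    def test_auto_switch_to_fisher_for_small_expected(self):
        res = st.categorical_assoc([[1, 9], [5, 3]])  # min expected 8*6/18 < 5
        assert res.method == "fisher_exact"
        res2 = st.categorical_assoc([[20, 20], [20, 25]])
        assert res2.method == "chi_square"

    def test_zero_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            res = st.chi_square_test([[5, 0, 5], [3, 0, 7]])
        assert res.n == 20


# ---------------------------------------------------------------------------
# cutpoints


class TestCutoffs:
    def test_perfect_separation_auc_one(self):
        values = np.array([1.0, 5, 8, 25, 30, 40])
        deaths = np.array([True, True, True, False, False, False])
        model = st.roc_cutoff(values, deaths)
        assert model.auc == 1.0
        assert 8 < model.cutoff < 25
        assert model.sensitivity == 1.0 and model.specificity == 1.0

    def test_exhaustive_sweep_example(self):
        model = st.roc_cutoff(np.array([1.0, 2, 3, 4]),
                              np.array([True, True, False, False]))
        assert model.auc == 1.0
        assert model.cutoff == 2.5

    def test_null_auc_near_half(self, rng):
        values = rng.normal(size=1000)
        deaths = rng.random(1000) < 0.4
        model = st.roc_cutoff(values, deaths)
        assert abs(model.auc - 0.5) < 0.05

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        values = rng.normal(size=200)
        values[rng.random(200) < 0.3] = np.round(values[rng.random(200) < 0.3][:1], 1)
        deaths = rng.random(200) < 0.35
        model = st.roc_cutoff(values, deaths)
        assert model.auc == pytest.approx(roc_auc_score(deaths, -values))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            st.roc_cutoff([1.0, 2.0], [True, True])

    def test_stratification_consistency(self, rng):
        """Applying the fitted rule to its training data reproduces the
        sensitivity/specificity implied by the threshold exactly."""
        values = rng.normal(size=80)
        deaths = rng.random(80) < 0.4
        model = st.roc_cutoff(values, deaths)
        groups = model.stratify(values)
        sens = (groups[deaths] == "low").mean()
        spec = (groups[~deaths] == "high").mean()
        assert sens == pytest.approx(model.sensitivity)
        assert spec == pytest.approx(model.specificity)

    def test_median_cutoff_odd_even(self):
        odd = st.median_cutoff([1.0, 2, 3])
        assert odd.cutoff == 2.0
        np.testing.assert_array_equal(odd.stratify([1, 2, 3]),
                                      ["low", "low", "high"])
        even = st.median_cutoff([1.0, 2, 3, 4])
        assert even.cutoff == 2.5

    def test_median_cutoff_degenerate_all_equal(self):
        model = st.median_cutoff([7.0, 7, 7, 7])
        assert model.degenerate
        assert set(model.stratify([7.0, 7, 7, 7])) == {"low"}


# ---------------------------------------------------------------------------
# survival


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        km = st.km_estimate([3.0, 5, 9], [False, False, False])
        assert km.survival_at(100.0) == 1.0

    def test_hand_product_limit(self):
        """times {1,2,3}, events {1,1,0}: S(3) = (2/3)(1/2) = 1/3."""
        km = st.km_estimate([1.0, 2, 3], [True, True, False])
        assert km.survival_at(3.0) == pytest.approx(1 / 3)
        assert km.survival_at(0.5) == 1.0

    def test_matches_exponential_closed_form(self, rng):
        h = 0.02
        t = rng.exponential(1 / h, size=2000)
        km = st.km_estimate(t, np.ones(2000, dtype=bool))
        for q in (20.0, 50.0, 80.0):
            expected = np.exp(-h * q)
            se = np.sqrt(expected * (1 - expected) / 2000)
            assert abs(km.survival_at(q) - expected) < 4 * se

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(40, 300)
        e = rng.random(300) < 0.6
        km = st.km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        grid = [10.0, 30.0, 60.0, 90.0]
        ref = kmf.survival_function_at_times(grid).to_numpy()
        mine = [km.survival_at(g) for g in grid]
        np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            st.km_estimate([], [])

    @given(
        hst.lists(
            hst.tuples(hst.floats(0.1, 100.0), hst.booleans()),
            min_size=1,
            max_size=40,
        )
    )
    def test_curve_is_monotone_in_unit_interval(self, data):
        times = [t for t, _ in data]
        events = [e for _, e in data]
        km = st.km_estimate(times, events)
        assert np.all(km.survival >= 0) and np.all(km.survival <= 1)
        assert np.all(np.diff(km.survival) <= 1e-12)


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        t = np.array([1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5])
        e = np.array([1, 1, 0, 1, 0, 1, 1, 0, 1, 0], dtype=bool)
        g = np.repeat(["a", "b"], 5)
        res = st.logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_enumerated_risk_tables(self):
        """Group A {1,2} both events, group B {3,4} both events: follow the
        hypergeometric O-E ledger table by table."""
        t = np.array([1.0, 2, 3, 4])
        e = np.ones(4, dtype=bool)
        g = np.array(["A", "A", "B", "B"])
        # t=1: n=4, n_A=2, E=0.5, V=0.25;  t=2: n=3, n_A=1, E=1/3, V=2/9
        # t=3: n=2, n_A=0, E=0, V=0;      t=4: n=1, E=0, V=0
        u = (1 - 0.5) + (1 - 1 / 3) + 0 + 0
        v = 0.25 + 2 / 9
        res = st.logrank_test(t, e, g)
        assert res.statistic == pytest.approx(u * u / v)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        t = rng.exponential(30, 150)
        e = rng.random(150) < 0.7
        g = rng.random(150) < 0.5
        mine = st.logrank_test(t, e, np.where(g, "x", "y"))
        ref = ll_logrank(t[g], t[~g], e[g], e[~g])
        assert mine.statistic == pytest.approx(ref.test_statistic, abs=1e-9)
        assert mine.p_value == pytest.approx(ref.p_value, abs=1e-9)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            st.logrank_test([1.0, 2], [True, True], ["a", "a"])


class TestCox:
    def test_null_covariate_ci_covers_one(self, rng):
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(100, n)
        e = rng.random(n) < 0.5
        fit = st.cox_fit(t, e, x)
        lo, hi = fit.ci95
        assert lo <= 1.0 <= hi

    def test_two_subject_separation_matches_grid_boundary(self):
        """With the high-covariate subject dying first, the partial likelihood
        beta - log(e^beta + 1) is strictly increasing: a bounded grid argmax
        sits at the boundary and the fit flags divergence."""
        grid = np.linspace(-10, 10, 2001)
        ll = grid - np.log(np.exp(grid) + 1)
        assert grid[np.argmax(ll)] == grid[-1]
        fit = st.cox_fit([1.0, 2.0], [True, True], np.array([1.0, 0.0]))
        assert not fit.converged
        assert any("divergent" in w for w in fit.warnings)
        assert fit.coefficients["x0"]["beta"] > 5.0

    def test_three_subject_fit_matches_grid_search(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.ones(3, dtype=bool)
        x = np.array([2.0, 0.0, 1.0])
        grid = np.linspace(-5, 5, 200001)
        # partial likelihood for distinct times, risk sets {1,2,3},{2,3},{3}
        ll = (
            2 * grid
            - np.log(np.exp(2 * grid) + np.exp(0.0) + np.exp(grid))
            + 0.0
            - np.log(np.exp(0.0) + np.exp(grid))
        )
        beta_grid = grid[np.argmax(ll)]
        fit = st.cox_fit(t, e, x)
        assert fit.coefficients["x0"]["beta"] == pytest.approx(beta_grid, abs=1e-3)

    def test_efron_ties_match_lifelines(self, rng):
        from lifelines import CoxPHFitter

        n = 60
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.4).astype(float)
        t = np.round(rng.exponential(1 / (0.05 * np.exp(0.4 * x1))), 0) + 1.0
        e = rng.random(n) < 0.8
        df = pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2})
        ref = CoxPHFitter().fit(df, "t", "e")
        fit = st.cox_fit(t, e, pd.DataFrame({"x1": x1, "x2": x2}))
        for name in ("x1", "x2"):
            assert fit.coefficients[name]["beta"] == pytest.approx(
                ref.params_[name], abs=1e-4
            )
            assert fit.coefficients[name]["se"] == pytest.approx(
                ref.standard_errors_[name], abs=1e-4
            )

    def test_constant_covariate_raises(self):
        with pytest.raises(ValueError):
            st.cox_fit([1.0, 2, 3], [True, True, False], np.ones(3))


# ---------------------------------------------------------------------------
# profiles, tertiles, percentages


class TestProfileAndSummaries:
    @pytest.mark.parametrize(
        ("a", "b", "expected"),
        [
            ("low", "low", "low/low"),
            ("high", "high", "high/high"),
            ("high", "low", "mixed"),
            ("low", "high", "mixed"),
            ("low", None, None),
        ],
    )
    def test_combine_profile(self, a, b, expected):
        assert st.combine_profile(a, b) == expected

    def test_tertiles_of_one_to_nine(self):
        labels, degenerate = st.tertile_split(np.arange(1.0, 10.0))
        np.testing.assert_array_equal(labels, [0, 0, 0, 1, 1, 1, 2, 2, 2])
        assert not degenerate

    def test_tertiles_all_equal_degenerate(self):
        labels, degenerate = st.tertile_split(np.full(10, 3.0))
        assert degenerate
        assert set(labels) == {0}

    def test_tertile_sizes_balanced_at_n_104(self, rng):
        labels, _ = st.tertile_split(rng.uniform(30, 90, size=104))
        sizes = np.bincount(labels, minlength=3)
        assert set(sizes.tolist()) <= {34, 35}

    @pytest.mark.parametrize(
        ("count", "total", "expected"),
        [(60, 104, 57.7), (44, 104, 42.3), (16, 104, 15.4), (0, 104, 0.0),
         (1, 16, 6.3)],  # 6.25 rounds half-up to 6.3
    )
    def test_percent_summary_half_up(self, count, total, expected):
        assert st.percent_summary(count, total) == expected

    def test_percent_summary_validates(self):
        with pytest.raises(ValueError):
            st.percent_summary(5, 0)
        with pytest.raises(ValueError):
            st.percent_summary(11, 10)

    def test_benjamini_hochberg_monotone(self, rng):
        p = rng.random(20)
        adj = st.benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all((adj >= 0) & (adj <= 1))

    @given(hst.lists(hst.floats(0.0, 1e6), min_size=2, max_size=30))
    def test_median_cutoff_splits_at_most_half_high(self, values):
        model = st.median_cutoff(values)
        groups = model.stratify(values)
        assert (groups == "high").sum() <= len(values) / 2
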