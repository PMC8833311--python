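"""Group statistics: permutation tests, FDR, ANOVA, proportions, correlations."""

import numpy as np
import pytest
from scipy import stats as sps

from dynstates.stats import (
    cohens_d,
    fdr_bh,
    kruskal_wallis,
    perm_ttest,
    rank_sum,
    severity_correlation,
    statewise_fc_test,
    tukey_hsd,
    twoway_anova,
    ztest_proportions,
)


class TestPermTtest:
    def test_identical_samples_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = perm_ttest(x, x.copy(), n_perm=500, seed=0)
        assert t == 0.0
        assert p == 1.0

    def test_strong_shift_detected(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30) + 2.0
        _t, p = perm_ttest(x, y, n_perm=10000, seed=1)
        assert p < 0.001

    def test_type_one_error_calibrated(self, rng):
        """Rejection rate on null normal data stays near nominal alpha."""
        x = rng.standard_normal((20, 1000))
        y = rng.standard_normal((20, 1000))
        _t, p = perm_ttest(x, y, n_perm=1000, seed=2)
        rate = np.mean(p <= 0.05)
        assert 0.03 <= rate <= 0.07

    def test_matrix_and_scalar_paths_agree(self, rng):
        x = rng.standard_normal((12, 3))
        y = rng.standard_normal((15, 3))
        t_mat, p_mat = perm_ttest(x, y, n_perm=2000, seed=3)
        t0, p0 = perm_ttest(x[:, 0], y[:, 0], n_perm=2000, seed=3)
        assert t0 == pytest.approx(t_mat[0])
        assert p0 == pytest.approx(p_mat[0])

    def test_observed_t_is_welch(self, rng):
        x = rng.standard_normal(10)
        y = rng.standard_normal(14) * 3 + 1
        t, _p = perm_ttest(x, y, n_perm=100, seed=4)
        t_ref = sps.ttest_ind(x, y, equal_var=False).statistic
        assert t == pytest.approx(t_ref, abs=1e-10)

    def test_reproducible_from_seed(self, rng):
        x, y = rng.standard_normal(8), rng.standard_normal(8)
        assert perm_ttest(x, y, seed=7, n_perm=500) == perm_ttest(x, y, seed=7, n_perm=500)


class TestFdr:
    def test_all_tiny_p_significant(self):
        p_adj, reject = fdr_bh(np.full(10, 0.001))
        assert reject.all()
        assert (p_adj >= 0.001).all()

    def test_single_p_unchanged(self):
        p_adj, _ = fdr_bh(np.array([0.03]))
        assert p_adj[0] == pytest.approx(0.03)

    def test_step_up_oracle(self):
        """Hand-computed BH on [.01,.02,.03,.5] at q=.05: first three pass."""
        p = np.array([0.01, 0.02, 0.03, 0.5])
        # oracle: p_(i) <= q*i/m  ->  .0125, .025, .0375, .05
        _p_adj, reject = fdr_bh(p, q=0.05)
        assert reject.tolist() == [True, True, True, False]

    def test_order_invariance(self, rng):
        p = rng.uniform(0.001, 1.0, 50)
        perm = rng.permutation(50)
        adj1, rej1 = fdr_bh(p)
        adj2, rej2 = fdr_bh(p[perm])
        assert np.allclose(adj1[perm], adj2)
        assert np.array_equal(rej1[perm], rej2)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.0, 0.5]))


class TestEffectSizes:
    def test_cohens_d_cases(self):
        x = np.array([1.0, 2, 3])
        assert cohens_d(x, x) == 0.0
        assert cohens_d(np.array([1.0, 2, 3]), np.array([2.0, 3, 4])) == pytest.approx(-1.0)

    def test_unit_difference_unit_sd(self, rng):
        x = rng.standard_normal(5000) + 1
        y = rng.standard_normal(5000)
        assert cohens_d(x, y) == pytest.approx(1.0, abs=0.08)


class TestAnova:
    def make_factors(self, n_per_cell=20, k=4):
        group = np.repeat(["A", "B"], k * n_per_cell)
        state = np.tile(np.repeat(np.arange(1, k + 1), n_per_cell), 2)
        return group, state

    def test_constant_data_gives_no_effects(self):
        group, state = self.make_factors(5)
        res = twoway_anova(np.ones(group.size), group, state)
        assert all(a.F == 0.0 and a.p == 1.0 for a in res)

    def test_group_offset_detected(self, rng):
        group, state = self.make_factors(20)
        values = rng.standard_normal(group.size) + 2.0 * (group == "B")
        res = twoway_anova(values, group, state)
        p_group = next(a.p for a in res if a.factor == "group")
        assert p_group < 0.01

    def test_matches_direct_ss_oracle_on_balanced_design(self, rng):
        """Balanced two-way: type-II F equals the classical hand computation."""
        group, state = self.make_factors(10, k=2)
        y = rng.standard_normal(group.size)
        res = {a.factor: a for a in twoway_anova(y, group, state)}
        # direct SS on balanced data
        grand = y.mean()
        ss_group = sum((y[group == g].mean() - grand) ** 2 * (group == g).sum()
                       for g in "AB")
        cell_means = {(g, s): y[(group == g) & (state == s)].mean()
                      for g in "AB" for s in (1, 2)}
        ss_state = sum((y[state == s].mean() - grand) ** 2 * (state == s).sum()
                       for s in (1, 2))
        ss_inter = sum(
            ((cell_means[(g, s)] - y[group == g].mean()
              - y[state == s].mean() + grand) ** 2) * 10
            for g in "AB" for s in (1, 2))
        ss_resid = sum(
            ((y[(group == g) & (state == s)] - cell_means[(g, s)]) ** 2).sum()
            for g in "AB" for s in (1, 2))
        ms_resid = ss_resid / (40 - 4)
        assert res["group"].F == pytest.approx(ss_group / 1 / ms_resid, rel=1e-6)
        assert res["state"].F == pytest.approx(ss_state / 1 / ms_resid, rel=1e-6)
        assert res["interaction"].F == pytest.approx(ss_inter / 1 / ms_resid, rel=1e-6)

    def test_missing_level_rejected(self):
        with pytest.raises(ValueError):
            twoway_anova(np.ones(4), ["A"] * 4, [1, 1, 2, 2])


class TestNonparametrics:
    def test_kruskal_identical_groups(self):
        g = np.array([1.0, 2, 3, 4])
        H, p = kruskal_wallis([g, g.copy(), g.copy()])
        assert H == 0.0
        assert p == 1.0

    def test_shifted_group_flagged_by_tukey(self, rng):
        g1 = rng.standard_normal(30)
        g2 = rng.standard_normal(30)
        g3 = rng.standard_normal(30) + 3.0
        pmat = tukey_hsd([g1, g2, g3])
        assert pmat[0, 2] < 0.01 and pmat[1, 2] < 0.01
        assert pmat[0, 1] > 0.05

    def test_kruskal_two_groups_orders_like_ranksum(self, rng):
        """On two groups, KW p ordering matches the rank-sum oracle."""
        kw_ps, rs_ps = [], []
        for shift in (0.0, 0.5, 1.0, 2.0):
            x = rng.standard_normal(25)
            y = rng.standard_normal(25) + shift
            _h, p_kw = kruskal_wallis([x, y])
            _z, p_rs = rank_sum(x, y)
            kw_ps.append(p_kw)
            rs_ps.append(p_rs)
        assert np.argsort(kw_ps).tolist() == np.argsort(rs_ps).tolist()


class TestProportions:
    def test_equal_rates_degenerate(self):
        z, p = ztest_proportions(5, 10, 10, 20)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_pooled_formula(self):
        k1, n1, k2, n2 = 55, 57, 40, 61
        z, _p = ztest_proportions(k1, n1, k2, n2)
        pool = (k1 + k2) / (n1 + n2)
        z_hand = (k1 / n1 - k2 / n2) / np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        assert z == pytest.approx(z_hand, abs=1e-6)

    def test_antisymmetry(self):
        z1, p1 = ztest_proportions(30, 40, 10, 35)
        z2, p2 = ztest_proportions(10, 35, 30, 40)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_all_or_none_degenerate(self):
        z, p = ztest_proportions(10, 10, 20, 20)
        assert p == 1.0


class TestSeverityCorrelation:
    def test_perfect_correlation(self):
        v = np.arange(10.0)
        r, p = severity_correlation(v, v)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_null_r_stays_small(self, rng):
        small = 0
        for _ in range(200):
            r, _p = severity_correlation(rng.standard_normal(50),
                                         rng.standard_normal(50))
            small += abs(r) < 0.28  # ~2 sigma of the null at n=50
        # nominal coverage ~95%; allow binomial noise around it
        assert small >= 185

    def test_zero_variance_marker(self):
        r, p = severity_correlation(np.ones(10), np.arange(10.0))
        assert np.isnan(r) and np.isnan(p)


class TestStatewiseTest:
    def test_matches_manual_composition(self, rng):
        """The state-wise pipeline equals perm-test + BH applied by hand."""
        fc = {f"s{i}": rng.standard_normal(15) for i in range(20)}
        groups = {f"s{i}": ("A" if i < 10 else "B") for i in range(20)}
        res = statewise_fc_test(fc, groups, n_perm=500, seed=9)
        X = np.vstack([fc[f"s{i}"] for i in range(20)])
        t_ref, p_ref = perm_ttest(X[:10], X[10:], n_perm=500, seed=9)
        for j, r in enumerate(res):
            assert r.t_stat == pytest.approx(t_ref[j], abs=1e-10)
            assert r.p_uncorr == pytest.approx(p_ref[j])
        p_adj, reject = fdr_bh(np.array([r.p_uncorr for r in res]))
        assert np.allclose(p_adj, [r.p_fdr for r in res])

    def test_too_few_visitors_returns_skip(self, rng):
        fc = {"a": rng.standard_normal(5), "b": rng.standard_normal(5),
              "c": rng.standard_normal(5)}
        groups = {"a": "A", "b": "A", "c": "B"}
        assert statewise_fc_test(fc, groups, n_perm=100) is None

    def test_null_cohort_rarely_flags(self, rng):
        flagged = 0
        for rep in range(5):
            fc = {f"s{i}": rng.standard_normal(100) for i in range(30)}
            groups = {f"s{i}": ("A" if i < 15 else "B") for i in range(30)}
            res = statewise_fc_test(fc, groups, n_perm=2000, seed=rep)
            flagged += sum(r.significant for r in res)
        assert flagged <= 1
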