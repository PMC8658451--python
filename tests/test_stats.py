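"""Mixed ANOVA, Greenhouse-Geisser, FDR, regressions and stepwise selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eegmst.stats import (
    bh_fdr,
    mixed_anova_2x2,
    per_condition_group_test,
    regress_pli_on_power,
    rm_anova_gg,
    stepwise_regression,
)


def long_table(values, groups, conditions=("baseline", "task")):
    """values: subjects x k array; groups: per-subject labels."""
    values = np.asarray(values, dtype=float)
    rows = []
    for s in range(values.shape[0]):
        for c, cond in enumerate(conditions):
            rows.append(
                dict(subject=f"s{s:02d}", group=groups[s], condition=cond, value=values[s, c])
            )
    return pd.DataFrame(rows)


def oracle_mixed_2x2(values, groups):
    """Textbook sums-of-squares mixed ANOVA, written with explicit loops.

    Independent of the vectorized implementation: every sum is accumulated
    cell by cell from definitions.
    """
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    labels = sorted(set(groups))
    idx = {g: [i for i, gi in enumerate(groups) if gi == g] for g in labels}
    grand = values.mean()
    subj_mean = values.mean(axis=1)
    ss_between_sub = sum(k * (subj_mean[s] - grand) ** 2 for s in range(n))
    ss_group = sum(
        k * len(ix) * (subj_mean[ix].mean() - grand) ** 2 for ix in idx.values()
    )
    ss_err_between = ss_between_sub - ss_group
    ss_total = ((values - grand) ** 2).sum()
    cond_mean = values.mean(axis=0)
    ss_cond = sum(n * (cond_mean[c] - grand) ** 2 for c in range(k))
    ss_cells = sum(
        len(ix) * (values[ix][:, c].mean() - grand) ** 2
        for ix in idx.values()
        for c in range(k)
    )
    ss_inter = ss_cells - ss_group - ss_cond
    ss_err_within = ss_total - ss_between_sub - ss_cond - ss_inter
    g = len(labels)
    out = {}
    out["group"] = (ss_group / (g - 1)) / (ss_err_between / (n - g))
    out["condition"] = (ss_cond / (k - 1)) / (ss_err_within / ((n - g) * (k - 1)))
    out["interaction"] = (ss_inter / ((g - 1) * (k - 1))) / (
        ss_err_within / ((n - g) * (k - 1))
    )
    out["peta_group"] = ss_group / (ss_group + ss_err_between)
    out["peta_condition"] = ss_cond / (ss_cond + ss_err_within)
    return out


class TestMixedAnova:
    def test_zero_variance_gives_zero_f(self):
        df = long_table(np.ones((6, 2)), ["typical"] * 3 + ["dyslexic"] * 3)
        for r in mixed_anova_2x2(df):
            assert r.F == 0.0

    def test_hand_table_matches_ss_oracle(self):
        values = np.array(
            [[3.1, 4.0], [2.9, 3.5], [3.3, 4.4], [2.0, 2.1], [2.4, 2.2], [1.9, 2.6]]
        )
        groups = ["typical"] * 3 + ["dyslexic"] * 3
        res = {r.effect: r for r in mixed_anova_2x2(long_table(values, groups))}
        oracle = oracle_mixed_2x2(values, groups)
        assert res["group"].F == pytest.approx(oracle["group"], abs=1e-8)
        assert res["condition"].F == pytest.approx(oracle["condition"], abs=1e-8)
        assert res["condition x group"].F == pytest.approx(oracle["interaction"], abs=1e-8)
        assert res["group"].partial_eta_sq == pytest.approx(oracle["peta_group"], abs=1e-8)
        assert res["condition"].partial_eta_sq == pytest.approx(
            oracle["peta_condition"], abs=1e-8
        )

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        values = rng.normal(size=(14, 2)) + rng.normal(size=(14, 1))
        groups = ["typical"] * 8 + ["dyslexic"] * 6
        df = long_table(values, groups)
        ours = {r.effect: r for r in mixed_anova_2x2(df)}
        theirs = pg.mixed_anova(
            df, dv="value", within="condition", between="group", subject="subject"
        ).set_index("Source")
        assert ours["group"].F == pytest.approx(theirs.loc["group", "F"])
        assert ours["condition"].F == pytest.approx(theirs.loc["condition", "F"])
        assert ours["condition x group"].F == pytest.approx(theirs.loc["Interaction", "F"])
        assert ours["condition"].p == pytest.approx(theirs.loc["condition", "p_unc"])
        assert ours["condition"].partial_eta_sq == pytest.approx(
            theirs.loc["condition", "np2"]
        )

    def test_group_shift_moves_group_f_not_interaction(self, rng):
        """Adding +delta to one group in both conditions drives the group
        effect while the interaction stays at null levels."""
        n_sim, deltas = 300, (0.0, 2.0)
        med_group, med_inter = {}, {}
        for delta in deltas:
            fg, fi = [], []
            for s in range(n_sim):
                r = np.random.default_rng(1000 + s)
                base = r.normal(size=(12, 1))
                values = base + r.normal(scale=0.5, size=(12, 2))
                values[6:] += delta
                res = {
                    x.effect: x
                    for x in mixed_anova_2x2(
                        long_table(values, ["typical"] * 6 + ["dyslexic"] * 6)
                    )
                }
                fg.append(res["group"].F)
                fi.append(res["condition x group"].F)
            med_group[delta], med_inter[delta] = np.median(fg), np.median(fi)
        assert med_group[2.0] > 10 * med_group[0.0]
        # interaction F stays near its null median (~0.45 for F(1,10))
        assert med_inter[2.0] < 3 * max(med_inter[0.0], 0.45)

    def test_incomplete_subject_dropped_with_warning(self):
        df = long_table(np.ones((6, 2)), ["typical"] * 3 + ["dyslexic"] * 3)
        df = df.drop(df[(df.subject == "s00") & (df.condition == "task")].index)
        with pytest.warns(UserWarning, match="incomplete"):
            mixed_anova_2x2(df)

    def test_single_group_is_design_error(self):
        df = long_table(np.random.default_rng(0).normal(size=(4, 2)), ["typical"] * 4)
        with pytest.raises(ValueError, match="group"):
            mixed_anova_2x2(df)

    def test_partial_eta_sq_affine_invariant(self, rng):
        values = rng.normal(size=(10, 2))
        groups = ["typical"] * 5 + ["dyslexic"] * 5
        a = mixed_anova_2x2(long_table(values, groups))
        b = mixed_anova_2x2(long_table(values * 7.0 - 3.0, groups))
        for ra, rb in zip(a, b):
            assert ra.partial_eta_sq == pytest.approx(rb.partial_eta_sq, abs=1e-10)
            assert ra.F == pytest.approx(rb.F, abs=1e-8)


class TestRmAnovaGG:
    def test_two_levels_equal_paired_t(self, rng):
        arr = rng.normal(size=(12, 2))
        res = rm_anova_gg(arr)[0]
        t, p = sps.ttest_rel(arr[:, 0], arr[:, 1])
        assert res.gg_epsilon == 1.0
        assert res.F == pytest.approx(t**2)
        assert res.p == pytest.approx(p)

    def test_compound_symmetry_gives_epsilon_near_one(self, rng):
        """Exchangeable covariance satisfies sphericity, so eps ~ 1."""
        n, k = 200, 4
        subj = rng.normal(size=(n, 1))
        arr = subj + rng.normal(size=(n, k))
        assert rm_anova_gg(arr)[0].gg_epsilon > 0.95

    def test_rank_one_within_covariance_hits_lower_bound(self, rng):
        """All within-subject variation on one contrast -> eps -> 1/(k-1)."""
        n, k = 60, 4
        slope = rng.normal(size=(n, 1))
        arr = slope * np.arange(k)[None, :] + 1e-6 * rng.normal(size=(n, k))
        eps = rm_anova_gg(arr)[0].gg_epsilon
        assert eps == pytest.approx(1 / (k - 1), abs=0.01)

    def test_matches_pingouin_rm_anova(self, rng):
        pg = pytest.importorskip("pingouin")
        arr = rng.normal(size=(15, 4)) * np.array([1, 2, 1, 3])
        res = rm_anova_gg(arr)[0]
        theirs = pg.rm_anova(pd.DataFrame(arr), correction=True)
        assert res.F == pytest.approx(theirs["F"][0])
        assert res.gg_epsilon == pytest.approx(theirs["eps"][0], abs=1e-6)
        assert res.p == pytest.approx(theirs["p_GG_corr"][0], abs=1e-6)

    def test_missing_cells_listwise_deleted(self, rng):
        arr = rng.normal(size=(10, 3))
        arr[2, 1] = np.nan
        with pytest.warns(UserWarning, match="listwise"):
            res = rm_anova_gg(arr)[0]
        assert res.df == (2, 16)  # 9 subjects remain


class TestBhFdr:
    def brute_force(self, pvals, q):
        """max i with p_(i) <= i*q/m, reject the i smallest."""
        p = np.sort(np.asarray(pvals))
        m = len(p)
        ks = [i + 1 for i in range(m) if p[i] <= (i + 1) * q / m]
        thresh = p[max(ks) - 1] if ks else -1.0
        return np.asarray(pvals) <= thresh

    def test_step_up_example(self):
        rej = bh_fdr([0.001, 0.02, 0.03, 0.5], q=0.10)
        assert rej.tolist() == [True, True, True, False]

    def test_all_ones_reject_none(self):
        assert not bh_fdr([1.0] * 6, q=0.10).any()

    def test_empty_input(self):
        assert bh_fdr([], q=0.10).size == 0

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 30))
            for q in (0.05, 0.10, 0.3):
                np.testing.assert_array_equal(bh_fdr(p, q), self.brute_force(p, q))

    def test_rejections_monotone_in_q(self, rng):
        for _ in range(20):
            p = rng.uniform(size=15)
            r05, r10 = bh_fdr(p, 0.05), bh_fdr(p, 0.10)
            assert np.all(r10 | ~r05)  # q=0.05 rejections subset of q=0.10


class TestPerConditionGroupTest:
    def test_f_equals_t_squared(self, rng):
        values = rng.normal(size=12)
        groups = np.array(["typical"] * 7 + ["dyslexic"] * 5)
        res = per_condition_group_test(values, groups)
        t, p = sps.ttest_ind(values[groups == "dyslexic"], values[groups == "typical"])
        assert res.F == pytest.approx(t**2, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_equal_means_near_zero_f(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = ["typical"] * 3 + ["dyslexic"] * 3
        assert per_condition_group_test(values, groups).F == pytest.approx(0.0)

    def test_f_grows_with_shift(self, rng):
        base = rng.normal(size=10)
        groups = ["typical"] * 5 + ["dyslexic"] * 5
        fs = []
        for shift in (0.0, 1.0, 2.0):
            v = base.copy()
            v[5:] += shift
            fs.append(per_condition_group_test(v, groups).F)
        assert fs[0] < fs[1] < fs[2]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            per_condition_group_test(np.ones(4), ["typical"] * 4)


class TestRegression:
    def test_exact_linear_relation(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        r, r2, p = regress_pli_on_power(2 * x, x)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_hand_dataset_matches_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 1.9, 3.4, 2.8, 4.0])
        r, r2, p = regress_pli_on_power(y, x)
        # closed-form Pearson r
        rx = (x - x.mean()) / x.std()
        ry = (y - y.mean()) / y.std()
        r_hand = (rx * ry).mean()
        assert r == pytest.approx(r_hand, abs=1e-12)
        assert r2 == pytest.approx(r_hand**2, abs=1e-12)

    def test_null_p_values_uniform(self):
        """Under independence, slope-test p-values are U(0,1) (KS check)."""
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(1000):
            x = rng.normal(size=100)
            y = rng.normal(size=100)
            pvals.append(regress_pli_on_power(y, x)[2])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            regress_pli_on_power(np.arange(5.0), np.ones(5))


class TestStepwise:
    def test_exact_predictor_selected_alone(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = X["c"].to_numpy()
        model = stepwise_regression(y, X)
        assert model.predictors == ["c"]
        assert model.adj_r2 == pytest.approx(1.0)
        assert model.se_estimate == pytest.approx(0.0, abs=1e-10)

    def test_pure_noise_mostly_empty(self):
        """Null candidates rarely enter: with 2 candidates at p_in = 0.05
        the model stays empty in ~0.95^2 = 90% of runs."""
        empty = 0
        n_sim = 500
        for s in range(n_sim):
            r = np.random.default_rng(s)
            X = pd.DataFrame({"x0": r.normal(size=30), "x1": r.normal(size=30)})
            y = r.normal(size=30)
            if not stepwise_regression(y, X).predictors:
                empty += 1
        assert empty / n_sim >= 0.85

    def test_two_true_predictors_entered_stepwise(self, rng):
        n = 80
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = x1 + x2 + 0.05 * rng.normal(size=n)
        X = pd.DataFrame({"x1": x1, "x2": x2, "junk": rng.normal(size=n)})
        model = stepwise_regression(y, X)
        assert set(model.predictors) == {"x1", "x2"}
        adds = [s for s in model.steps if s.action == "add"]
        assert len(adds) >= 2
        assert all(s.delta_r2 > 0 for s in adds[:2])
        assert all(s.p_change < 0.05 for s in adds)

    def test_retained_predictors_below_exit_threshold(self, rng):
        n = 50
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        y = X["a"].to_numpy() + 0.5 * rng.normal(size=n)
        model = stepwise_regression(y, X)
        if model.predictors:
            import statsmodels.api as sm

            fit = sm.OLS(y, sm.add_constant(X[model.predictors])).fit()
            assert (fit.pvalues[1:] <= 0.10 + 1e-12).all()

    def test_empty_model_is_valid_result(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=20)})
        y = rng.normal(size=20)
        model = stepwise_regression(y, X, p_in=1e-9)
        assert model.predictors == []
        assert model.adj_r2 == 0.0
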