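"""Statistics battery vs independent oracles: correlation, ROC, ANOVA,
stratified comparisons and observer agreement."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from aolvratio.cohort import (
    DEFAULT_GROUP_PARAMS,
    CohortConfig,
    SeverityClass,
    generate_cohort,
)
from aolvratio.diagnostics import (
    DiagnosticsError,
    _icc_2_1,
    agreement_stats,
    group_comparison,
    pearson_correlation,
    roc_analysis,
    sens_spec_at_cutoff,
    stratified_comparison,
)


def brute_force_auc(scores, labels):
    """Pairwise concordance count / (n1 n0), lower score = positive, ties half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p < q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = 0.4 * x + rng.normal(size=20)
        res = pearson_correlation(x, y)
        # explicit product-moment formula
        xc, yc = x - x.mean(), y - y.mean()
        r_oracle = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert abs(res.r - r_oracle) < 1e-12
        # two-sided p from the t-transform with n-2 df
        t = r_oracle * np.sqrt((20 - 2) / (1 - r_oracle**2))
        p_oracle = 2 * stats.t.sf(abs(t), 20 - 2)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
        assert res.n == 20

    def test_constant_input_raises_naming_variable(self):
        with pytest.raises(DiagnosticsError, match="y"):
            pearson_correlation([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        with pytest.raises(DiagnosticsError):
            pearson_correlation([1.0, 2.0], [1.0, 2.0])  # too short


class TestRoc:
    def test_perfect_separation(self):
        scores = np.r_[np.full(10, 0.4), np.full(10, 1.0)]
        labels = np.r_[np.ones(10), np.zeros(10)]
        res = roc_analysis(scores, labels, ci_bootstrap_n=0)
        assert res.auc == 1.0

    def test_null_case_auc_near_half(self):
        rng = np.random.default_rng(2)
        n = 2000
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, size=n)
        res = roc_analysis(scores, labels, ci_bootstrap_n=0)
        assert abs(res.auc - 0.5) < 3 / np.sqrt(n)

    def test_auc_equals_brute_force_concordance(self):
        rng = np.random.default_rng(7)
        scores = np.round(rng.normal(size=30), 1)  # rounding forces ties
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]  # ensure both classes
        res = roc_analysis(scores, labels, ci_bootstrap_n=0)
        assert abs(res.auc - brute_force_auc(scores, labels)) < 1e-12

    def test_auc_equals_trapezoidal_integral(self):
        rng = np.random.default_rng(8)
        scores = np.round(rng.normal(size=60), 1)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        res = roc_analysis(scores, labels, ci_bootstrap_n=0)
        fpr = 1.0 - res.specificity
        order = np.argsort(fpr, kind="stable")
        trapz = np.trapezoid(res.sensitivity[order], fpr[order])
        assert abs(res.auc - trapz) < 1e-12

    def test_sweep_monotonicity(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        res = roc_analysis(scores, labels, ci_bootstrap_n=0)
        assert np.all(np.diff(res.sensitivity) >= 0)
        assert np.all(np.diff(res.specificity) <= 0)

    def test_bootstrap_ci_brackets_auc(self):
        rng = np.random.default_rng(10)
        scores = np.r_[rng.normal(0.5, 0.15, 40), rng.normal(1.0, 0.2, 40)]
        labels = np.r_[np.ones(40), np.zeros(40)]
        res = roc_analysis(scores, labels, ci_bootstrap_n=500, seed=3)
        assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]
        assert 0.0 <= res.auc <= 1.0

    def test_youden_tie_prefers_higher_specificity(self):
        # thresholds 0.5 and 0.9 both attain J = 0.5; the lower one is the
        # more specific rule and must win
        scores = np.array([0.3, 0.5, 0.5, 0.9])
        labels = np.array([1, 1, 0, 0])
        res = roc_analysis(scores, labels, ci_bootstrap_n=0)
        assert res.youden_cutoff == pytest.approx(0.5)
        idx = np.flatnonzero(res.thresholds == res.youden_cutoff)[0]
        assert res.specificity[idx] == 1.0

    def test_single_class_raises(self):
        with pytest.raises(DiagnosticsError):
            roc_analysis([0.1, 0.2, 0.3], [1, 1, 1], ci_bootstrap_n=0)


class TestSensSpec:
    def test_extreme_cutoffs(self):
        scores = np.array([0.4, 0.6, 0.9, 1.1])
        labels = np.array([1, 1, 0, 0])
        assert sens_spec_at_cutoff(scores, labels, 0.0) == (0.0, 1.0)
        assert sens_spec_at_cutoff(scores, labels, 99.0) == (1.0, 0.0)

    def test_reconstructed_2x2_table(self):
        # TP=10, FN=2, TN=9, FP=3 at cutoff 0.5
        scores = np.r_[np.full(10, 0.3), np.full(2, 0.9),
                       np.full(9, 0.9), np.full(3, 0.3)]
        labels = np.r_[np.ones(12), np.zeros(12)]
        sens, spec = sens_spec_at_cutoff(scores, labels, 0.5)
        assert sens == pytest.approx(10 / 12)
        assert spec == pytest.approx(9 / 12)


class TestGroupComparison:
    def test_identical_groups_f_zero(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        res = group_comparison(g)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert all(p == pytest.approx(1.0) for p in res.pairwise_p.values())

    def test_two_group_tukey_equals_pooled_t(self):
        """With two groups the studentized range collapses to q = sqrt(2)|t|."""
        rng = np.random.default_rng(4)
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(0.6, 1.0, 15)
        res = group_comparison({"a": a, "b": b})
        t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert abs(res.pairwise_p[("a", "b")] - t_p) < 1e-10

    def test_f_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(6)
        groups = {k: rng.normal(mu, 1.0, n) for k, mu, n in
                  [("a", 0.0, 8), ("b", 0.5, 11), ("c", 1.2, 9)]}
        res = group_comparison(groups)
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups.values())
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
        k, n = len(groups), len(allv)
        f_oracle = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert abs(res.f_statistic - f_oracle) < 1e-10

    def test_tukey_p_at_least_unadjusted_pairwise_p(self):
        rng = np.random.default_rng(14)
        groups = {k: rng.normal(mu, 1.0, 10) for k, mu in
                  [("a", 0.0), ("b", 0.4), ("c", 1.0)]}
        res = group_comparison(groups)
        pooled_sd = np.sqrt(
            sum(((g - g.mean()) ** 2).sum() for g in groups.values()) / (30 - 3)
        )
        for (k1, k2), p_adj in res.pairwise_p.items():
            g1, g2 = groups[k1], groups[k2]
            t = (g1.mean() - g2.mean()) / (pooled_sd * np.sqrt(1 / 10 + 1 / 10))
            p_raw = 2 * stats.t.sf(abs(t), 30 - 3)
            assert p_adj >= p_raw - 1e-12
            assert 0.0 <= p_adj <= 1.0

    def test_severity_separation_on_default_cohort(self, default_cohort):
        groups = {
            s: default_cohort.loc[default_cohort["severity"] == s, "ao_lv_ratio"]
            for s in ("control", "mild", "moderate", "severe")
        }
        res = group_comparison(groups)
        assert res.p_value < 1e-6
        for pair, p in res.pairwise_p.items():
            assert p < 0.001, pair

    def test_degenerate_groups_raise(self):
        with pytest.raises(DiagnosticsError):
            group_comparison({"a": [1.0, 2.0]})
        with pytest.raises(DiagnosticsError):
            group_comparison({"a": [1.0], "b": [1.0, 2.0]})


class TestStratified:
    def test_cell_means_match_groupby_oracle(self, default_cohort):
        res = stratified_comparison(default_cohort, "morphology")
        oracle = default_cohort.groupby(["severity", "bicuspid"])["ao_lv_ratio"].mean()
        for sev in ("control", "mild", "moderate", "severe"):
            for flag, row in ((False, "tricuspid"), (True, "bicuspid")):
                if (sev, flag) in oracle.index:
                    assert res.cell_means.loc[row, sev] == pytest.approx(
                        oracle.loc[(sev, flag)]
                    )

    def test_empty_cell_flagged_absent_not_error(self, default_cohort):
        df = default_cohort.copy()
        df.loc[df["severity"] == "control", "bicuspid"] = False
        res = stratified_comparison(df, "morphology")
        assert np.isnan(res.cell_means.loc["bicuspid", "control"])
        assert np.isnan(res.p_values["control"])
        assert res.cell_ns.loc["bicuspid", "control"] == 0

    def test_null_generator_false_positive_rate_nominal(self):
        """With no morphology effect, stratum tests reject at ~alpha."""
        n_seeds, alpha = 100, 0.05
        rejections, total = 0, 0
        groups = {
            sev: replace(gp, n=40, bicuspid_fraction=0.5)
            for sev, gp in DEFAULT_GROUP_PARAMS.items()
        }
        for seed in range(n_seeds):
            cohort = generate_cohort(CohortConfig(groups=groups, seed=seed))
            res = stratified_comparison(cohort, "morphology")
            for p in res.p_values.values():
                if np.isfinite(p):
                    total += 1
                    rejections += p < alpha
        rate = rejections / total
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / total)

    def test_morphology_offset_means_recovered(self):
        """Configured tricuspid/bicuspid control means are recovered per cell."""
        groups = {SeverityClass.CONTROL: replace(
            DEFAULT_GROUP_PARAMS[SeverityClass.CONTROL], n=4000,
            bicuspid_fraction=0.5)}
        cfg = CohortConfig(
            groups=groups, seed=17,
            morphology_ratio_means={SeverityClass.CONTROL: (1.06, 0.87)},
        )
        res = stratified_comparison(generate_cohort(cfg), "morphology")
        se = 0.19 / np.sqrt(2000)
        assert abs(res.cell_means.loc["tricuspid", "control"] - 1.06) < 3 * se
        assert abs(res.cell_means.loc["bicuspid", "control"] - 0.87) < 3 * se

    def test_unknown_stratifier_raises(self, default_cohort):
        with pytest.raises(DiagnosticsError):
            stratified_comparison(default_cohort, "vendor")


class TestAgreement:
    def test_perfect_copy(self):
        x = np.array([0.4, 0.6, 0.8, 1.0, 1.2, 0.9])
        res = agreement_stats(x, x.copy())
        assert res.icc == pytest.approx(1.0)
        assert res.bland_altman_bias == 0.0
        assert (res.loa_low, res.loa_high) == (0.0, 0.0)
        assert res.pearson_inter == pytest.approx(1.0)

    def test_constant_offset_degrades_icc_not_pearson(self):
        x = np.array([0.4, 0.6, 0.8, 1.0, 1.2, 0.9])
        delta = 0.15
        res = agreement_stats(x, x + delta)
        assert res.pearson_inter == pytest.approx(1.0)
        assert res.icc < 1.0
        assert res.bland_altman_bias == pytest.approx(-delta)

    def test_icc_recovers_variance_components(self):
        """ICC(2,1) estimates sigma_t^2 / (sigma_t^2 + sigma_e^2)."""
        rng = np.random.default_rng(21)
        n, sigma_t, sigma_e = 2000, 0.25, 0.08
        truth = 0.7 + rng.normal(0.0, sigma_t, n)
        r1 = truth + rng.normal(0.0, sigma_e, n)
        r2 = truth + rng.normal(0.0, sigma_e, n)
        res = agreement_stats(r1, r2)
        rho = sigma_t**2 / (sigma_t**2 + sigma_e**2)
        se = (1 - rho**2) / np.sqrt(n)
        assert abs(res.icc - rho) < 3 * se

    def test_mean_squares_match_brute_force_two_way_layout(self):
        rng = np.random.default_rng(22)
        ratings = rng.normal(0.8, 0.2, size=(12, 2))
        icc = _icc_2_1(ratings)
        # brute-force two-way decomposition with explicit loops
        n, k = ratings.shape
        grand = sum(ratings[i, j] for i in range(n) for j in range(k)) / (n * k)
        row = [sum(ratings[i, j] for j in range(k)) / k for i in range(n)]
        col = [sum(ratings[i, j] for i in range(n)) / n for j in range(k)]
        msr = k * sum((r - grand) ** 2 for r in row) / (n - 1)
        msc = n * sum((c - grand) ** 2 for c in col) / (k - 1)
        sse = sum(
            (ratings[i, j] - row[i] - col[j] + grand) ** 2
            for i in range(n)
            for j in range(k)
        )
        mse = sse / ((n - 1) * (k - 1))
        oracle = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert abs(icc - oracle) < 1e-12

    def test_icc_cross_checked_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(23)
        truth = rng.normal(0.8, 0.2, size=15)
        ratings = truth[:, None] + rng.normal(0.0, 0.07, size=(15, 2))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 2),
                "rater": np.tile(["r1", "r2"], 15),
                "score": ratings.ravel(),
            }
        )
        table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="score")
        mask = table["Type"].isin(["ICC2", "ICC(A,1)"])
        ref = float(table.loc[mask, "ICC"].iloc[0])
        assert _icc_2_1(ratings) == pytest.approx(ref, abs=1e-10)

    def test_length_mismatch_raises(self):
        with pytest.raises(DiagnosticsError):
            agreement_stats([1, 2, 3, 4, 5], [1, 2, 3, 4])
        with pytest.raises(DiagnosticsError):
            agreement_stats([1, 2], [1, 2])
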