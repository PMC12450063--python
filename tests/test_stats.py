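import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from gastromill import stats as st
from gastromill.synth import contingency_fixture


class TestOdds:
    def test_printed_counts_give_3_3_fold_increase(self):
        res = st.odds_and_or((38, 6), (42, 22))
        assert res.odds_ratio == pytest.approx((38 / 6) / (42 / 22))
        assert round(res.odds_ratio, 1) == 3.3
        assert res.effect.band == "large"

    def test_recomputed_uh_vs_saline_odds_ratio(self):
        # printed counts give 10.68 (the published text rounds differently)
        res = st.odds_and_or((21, 19), (9, 87))
        assert res.odds_ratio == pytest.approx(10.684, abs=0.001)

    def test_identity_and_reciprocal(self):
        assert st.odds_and_or((5, 7), (5, 7)).odds_ratio == 1.0
        ab = st.odds_and_or((38, 6), (42, 22)).odds_ratio
        ba = st.odds_and_or((42, 22), (38, 6)).odds_ratio
        assert ab * ba == pytest.approx(1.0)

    def test_ci_is_ordered_and_brackets_estimate(self):
        res = st.odds_and_or((38, 6), (42, 22))
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_zero_cell_requires_continuity(self):
        with pytest.raises(ZeroDivisionError):
            st.odds_and_or((38, 0), (42, 22))
        res = st.odds_and_or((38, 0), (42, 22), continuity=True)
        assert res.odds_ratio > 0

    def test_pairwise_table_covers_all_pairs(self):
        table = st.odds_ratio_table(contingency_fixture())
        assert len(table) == 12
        row = table[(table.condition_a == "1uM-FH")
                    & (table.condition_b == "10uM-S")].iloc[0]
        assert round(row.odds_ratio, 1) == 3.3


class TestBootstrap:
    def test_constant_equal_samples_not_significant(self):
        cis = st.bootstrap_mean_diff_ci([2.0] * 5, [2.0] * 5, rng=0)
        assert len(cis) == 1
        assert cis[0].level == 0.95
        assert (cis[0].low, cis[0].high) == (0.0, 0.0)
        assert not cis[0].excludes_zero

    def test_separated_samples_escalate_levels(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(1, 0.1, 30), rng.normal(0, 0.1, 30)
        cis = st.bootstrap_mean_diff_ci(a, b, rng=1)
        assert cis[0].excludes_zero
        assert [c.level for c in cis] == [0.95, 0.99, 0.999, 0.9999, 0.99999]

    def test_cascade_stops_when_interval_crosses_zero(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0.4, 1.0, 15), rng.normal(0.0, 1.0, 15)
        cis = st.bootstrap_mean_diff_ci(a, b, rng=2)
        for first, second in zip(cis, cis[1:]):
            assert first.excludes_zero
        if len(cis) < 5:
            assert not cis[-1].excludes_zero

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            st.bootstrap_mean_diff_ci([], [1.0], rng=0)


class TestCohensD:
    def test_identical_samples(self):
        assert st.cohens_d_unbiased([1, 2, 3], [1, 2, 3]).value == 0.0

    def test_hand_computed_correction(self):
        # d = -1, J = 1 - 3/15 = 0.8 -> -0.8, band large
        eff = st.cohens_d_unbiased([1, 2, 3], [2, 3, 4])
        assert eff.value == pytest.approx(-0.8)
        assert eff.band == "large"

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 12)
        assert st.cohens_d_unbiased(a, b).value == pytest.approx(
            -st.cohens_d_unbiased(b, a).value)

    def test_zero_pooled_sd_with_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            st.cohens_d_unbiased([1.0, 1.0], [2.0, 2.0])


class TestRankBiserial:
    @pytest.mark.parametrize("diffs,expected", [
        ([1, 2, 3], 1.0), ([-1, -2], -1.0), ([1, -1], 0.0),
    ])
    def test_directional_extremes(self, diffs, expected):
        assert st.rank_biserial_wilcoxon(diffs).value == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            st.rank_biserial_wilcoxon([0.0, 0.0])


def brute_force_w(X):
    """Kendall's W from the variance-of-rank-sums definition, with ties."""
    n, k = X.shape
    ranks = np.vstack([sps.rankdata(row) for row in X])
    R = ranks.sum(axis=0)
    s = np.sum((R - R.mean()) ** 2)
    t = sum(float((c ** 3 - c).sum())
            for row in X
            for c in [np.unique(row, return_counts=True)[1]])
    return 12 * s / (n ** 2 * (k ** 3 - k) - n * t)


class TestKendallsW:
    def test_identical_rankings_give_one(self):
        X = np.array([[1, 2, 3], [10, 20, 30], [0.1, 0.5, 0.9]])
        assert st.kendalls_w(X).value == pytest.approx(1.0)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            X = rng.integers(0, 4, size=(5, 3)).astype(float)
            if np.all([len(np.unique(r)) == 1 for r in X]):
                continue
            assert st.kendalls_w(X).value == pytest.approx(brute_force_w(X))

    def test_two_condition_concordance(self):
        # paired design: every subject increases -> full concordance
        X = np.array([[18.5, 45.9], [10.0, 30.0], [5.0, 70.0], [19.1, 71.9]])
        assert st.kendalls_w(X).value == pytest.approx(1.0)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            st.kendalls_w(np.ones((4, 1)))


class TestFriedman:
    def test_matches_scipy_at_three_conditions(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 4))
        ours = st.friedman_with_w(X)
        ref = sps.friedmanchisquare(*X.T)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_w_is_chi2_over_n_k_minus_1(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(7, 3))
        res = st.friedman_with_w(X)
        assert res.effect.value == pytest.approx(res.statistic / (7 * 2))

    def test_two_condition_design_supported(self):
        X = np.array([[1.0, 2.0], [3.0, 5.0], [0.0, 4.0]])
        res = st.friedman_with_w(X)
        assert res.effect.value == pytest.approx(1.0)
        assert res.statistic == pytest.approx(3.0)

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError):
            st.friedman_with_w(np.array([[1.0, np.nan], [2.0, 3.0]]))


def brute_force_chi2(obs):
    obs = np.asarray(obs, float)
    total = obs.sum()
    chi2 = 0.0
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = obs[i].sum() * obs[:, j].sum() / total
            chi2 += (obs[i, j] - e) ** 2 / e
    return chi2


class TestCramersV:
    def test_independence_and_dependence_extremes(self):
        assert st.cramers_v([[5, 5], [10, 10]]).value == pytest.approx(0.0)
        assert st.cramers_v([[10, 0], [0, 10]]).value == pytest.approx(1.0)

    def test_matches_brute_force_composition(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            obs = rng.integers(1, 30, size=(3, 3))
            expected = math.sqrt(brute_force_chi2(obs) / (obs.sum() * 2))
            assert st.cramers_v(obs).value == pytest.approx(expected)

    def test_band_boundaries(self):
        assert st.band_cramers_v(0.07) == "small"
        assert st.band_cramers_v(0.21) == "medium"
        assert st.band_cramers_v(0.35) == "large"


class TestChiSquare:
    def test_identical_distributions(self):
        res = st.chi_square_distribution_test([[10, 10], [20, 20]])
        assert res.p_value == pytest.approx(1.0)
        assert res.effect.value == pytest.approx(0.0)

    def test_disjoint_distributions_fully_dependent(self):
        res = st.chi_square_distribution_test([[15, 0], [0, 25]])
        assert res.effect.value == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        obs = [[10, 20], [30, 40]]
        res = st.chi_square_distribution_test(obs)
        assert res.statistic == pytest.approx(brute_force_chi2(obs))

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            st.chi_square_distribution_test([[0, 0], [5, 5]])


class TestRmCorr:
    def test_parallel_lines_give_unit_correlation(self):
        df = pd.DataFrame({"subject": [1] * 4 + [2] * 4,
                           "x": list(range(4)) * 2,
                           "y": [0, 1, 2, 3, 10, 11, 12, 13]})
        res = st.repeated_measures_correlation(df)
        assert res.r_rm == pytest.approx(1.0)
        assert res.r2_rm == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_no_within_subject_association(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 30),
            "x": rng.normal(size=240),
            "y": rng.normal(size=240)})
        res = st.repeated_measures_correlation(df)
        assert abs(res.r_rm) < 0.15

    def test_matches_pingouin_at_three_plus_subjects(self):
        import pingouin as pg
        rng = np.random.default_rng(2)
        rows = []
        for s in range(5):
            x = rng.normal(size=8)
            rows.append(pd.DataFrame({
                "subject": s, "x": x,
                "y": 0.6 * x + rng.normal(0, 1, 8) + 3 * s}))
        df = pd.concat(rows)
        ours = st.repeated_measures_correlation(df)
        ref = pg.rm_corr(data=df, x="x", y="y", subject="subject")
        assert ours.r_rm == pytest.approx(float(ref.r.iloc[0]))
        assert ours.p_value == pytest.approx(float(ref.pval.iloc[0]))
        assert ours.dof == int(ref.dof.iloc[0])

    def test_small_subjects_dropped_then_error(self):
        df = pd.DataFrame({"subject": [1, 1, 2], "x": [0, 1, 0],
                           "y": [0, 1, 5]})
        with pytest.raises(ValueError):
            st.repeated_measures_correlation(df)


class TestAncova:
    def _data(self, delta=0.5, slope_b=1.0, n=30, seed=0):
        rng = np.random.default_rng(seed)
        xa, xb = rng.normal(1, 0.3, n), rng.normal(1, 0.3, n)
        ya = xa + rng.normal(0, 0.05, n)
        yb = slope_b * xb + delta + rng.normal(0, 0.05, n)
        return pd.DataFrame({"group": ["A"] * n + ["B"] * n,
                             "x": np.r_[xa, xb], "y": np.r_[ya, yb]})

    def test_recovers_planted_group_offset(self):
        res = st.ancova_equal_slopes(self._data(delta=0.5))
        assert res.slopes_homogeneous
        diff = res.adjusted_means["B"] - res.adjusted_means["A"]
        assert diff == pytest.approx(0.5, abs=0.05)
        assert res.pairwise.p_holm_sidak.iloc[0] < 0.001

    def test_distinct_slopes_withhold_adjusted_means(self):
        res = st.ancova_equal_slopes(self._data(slope_b=3.0))
        assert not res.slopes_homogeneous
        assert res.adjusted_means is None and res.pairwise is None

    def test_group_on_identity_line_passes_null_test(self):
        res = st.ancova_equal_slopes(self._data(delta=0.0, seed=3))
        assert res.identity_line_tests["A"] > 0.05

    def test_minimum_group_sizes_enforced(self):
        df = pd.DataFrame({"group": ["A", "A", "B", "B"],
                           "x": [0, 1, 0, 1], "y": [0, 1, 1, 2]})
        with pytest.raises(ValueError):
            st.ancova_equal_slopes(df)


def test_holm_sidak_adjustment_is_monotone():
    from statsmodels.stats.multitest import multipletests
    raw = np.array([0.001, 0.02, 0.04, 0.3, 0.7])
    adj = multipletests(raw, method="holm-sidak")[1]
    assert np.all(np.diff(adj) >= 0)
    assert np.all(adj >= raw)


class TestBands:
    def test_cohens_d_cutoffs(self):
        assert [st.band_cohens_d(v) for v in (0.19, 0.2, 0.5, 0.8, -0.9)] == [
            "none", "small", "medium", "large", "large"]

    def test_rank_biserial_cutoffs(self):
        assert [st.band_rank_biserial(v) for v in (0.05, 0.1, 0.3, 0.5)] == [
            "none", "small", "medium", "large"]

    def test_kendalls_w_cutoffs(self):
        assert [st.band_kendalls_w(v) for v in (0.1, 0.2, 0.39, 0.4)] == [
            "small", "medium", "medium", "large"]

    def test_odds_ratio_cutoffs_symmetric(self):
        assert st.band_odds_ratio(3.2) == "large"
        assert st.band_odds_ratio(1 / 3.2) == "large"
        assert st.band_odds_ratio(1.0) == "none"
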