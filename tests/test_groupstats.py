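"""Tests for the nonparametric statistics, matching and regression machinery."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import eegslope as es
from eegslope.groupstats import signed_rank_test


def ranksum_enumeration_p(a, b):
    """Brute-force two-sided rank-sum p by enumerating all label assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    mean = n1 * (len(pooled) + 1) / 2.0
    t_obs = ranks[:n1].sum()
    dev = abs(t_obs - mean)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        t = ranks[list(idx)].sum()
        total += 1
        if abs(t - mean) >= dev - 1e-9:
            count += 1
    return count / total


def bh_bruteforce(p, alpha):
    """Step-up by direct definition: largest k with p_(k) <= k alpha / m."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_star = k
    mask = np.zeros(m, dtype=bool)
    if k_star:
        mask[order[:k_star]] = True
    return mask


class TestBootstrapMedianSem:
    def test_identical_values_zero_sem(self):
        med, sem = es.bootstrap_median_sem([3.0] * 10, seed=0)
        assert med == 3.0 and sem == 0.0

    def test_sem_shrinks_with_n(self, rng):
        # average over draws: a single sample's bootstrap SEM is itself noisy
        sems = []
        for n in (50, 200):
            draws = [
                es.bootstrap_median_sem(rng.standard_normal(n), n_iter=2000, seed=1)[1]
                for _ in range(10)
            ]
            sems.append(np.mean(draws))
        ratio = sems[1] / sems[0]
        assert ratio == pytest.approx(0.5, abs=0.2)  # ~1/sqrt(4)

    def test_deterministic_per_seed(self, rng):
        vals = rng.standard_normal(30)
        assert es.bootstrap_median_sem(vals, seed=7) == es.bootstrap_median_sem(vals, seed=7)

    def test_all_missing(self):
        med, sem = es.bootstrap_median_sem([np.nan, np.nan])
        assert np.isnan(med) and np.isnan(sem)


class TestRankSum:
    def test_exact_textbook_case(self):
        assert es.rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        assert es.rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 4), (3, 7), (5, 5)])
    def test_exact_matches_enumeration(self, rng, n1, n2):
        for _ in range(3):
            a = rng.standard_normal(n1)
            b = rng.standard_normal(n2) + 0.5
            assert es.rank_sum_test(a, b) == pytest.approx(
                ranksum_enumeration_p(a, b), abs=1e-12
            )

    def test_asymptotic_matches_scipy(self, rng):
        for _ in range(5):
            a = rng.standard_normal(25)
            b = rng.standard_normal(30) + 0.3
            mine = es.rank_sum_test(a, b, exact_max_n=0)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert mine == pytest.approx(ref.pvalue, abs=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            es.rank_sum_test([], [1.0])


class TestKruskalWallis:
    def test_matches_scipy(self, rng):
        for _ in range(5):
            gs = [rng.standard_normal(10), rng.standard_normal(12) + 0.4,
                  rng.standard_normal(8) - 0.2]
            assert es.kruskal_wallis_test(gs) == pytest.approx(
                sps.kruskal(*gs).pvalue, abs=1e-10
            )

    def test_all_equal_p_one(self):
        assert es.kruskal_wallis_test([[2.0, 2.0], [2.0, 2.0, 2.0]]) == 1.0

    def test_two_groups_close_to_ranksum(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(30) + 0.4
        kw = es.kruskal_wallis_test([a, b])
        wrs = es.rank_sum_test(a, b, exact_max_n=0)
        assert abs(kw - wrs) < 0.01

    def test_type_one_error_rate(self, rng):
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            gs = rng.standard_normal((3, 10))
            if es.kruskal_wallis_test(list(gs)) < 0.05:
                hits += 1
        assert hits / n_sim == pytest.approx(0.05, abs=0.02)


class TestClusterSignificant:
    def test_hand_computed_mask(self):
        p = [0.04, 0.04, 0.04, 0.2, 0.04]
        np.testing.assert_array_equal(
            es.cluster_significant(p, 0.05), [True, True, True, False, False]
        )

    def test_two_bins_not_enough(self):
        assert not es.cluster_significant([0.01, 0.01, 0.5, 0.01], 0.05).any()

    def test_edge_run_counts(self):
        p = [0.5, 0.5, 0.01, 0.01, 0.01]
        np.testing.assert_array_equal(
            es.cluster_significant(p, 0.05), [False, False, True, True, True]
        )

    def test_restriction_property(self, rng):
        p = rng.uniform(0, 0.1, 30)
        mask = es.cluster_significant(p, 0.05)
        assert not np.any(mask & ~(p < 0.05))

    def test_nan_breaks_runs(self):
        p = [0.01, 0.01, np.nan, 0.01, 0.01]
        assert not es.cluster_significant(p, 0.05).any()


class TestBhFdr:
    def test_all_rejected(self):
        np.testing.assert_array_equal(
            es.bh_fdr([0.01, 0.02, 0.03, 0.04], alpha=0.05), [True] * 4
        )

    def test_none_rejected(self):
        assert not es.bh_fdr([0.9, 0.8]).any()

    def test_single_p_at_alpha(self):
        assert es.bh_fdr([0.05], alpha=0.05)[0]

    def test_matches_bruteforce_on_grid(self, rng):
        # all short p-vectors over a coarse grid
        grid = np.round(np.arange(0.01, 1.0, 0.07), 4)
        for m in (1, 2, 3):
            for combo in itertools.product(grid, repeat=m):
                p = np.array(combo)
                np.testing.assert_array_equal(
                    es.bh_fdr(p, 0.05), bh_bruteforce(p, 0.05), err_msg=str(p)
                )

    def test_matches_bruteforce_random_length6(self, rng):
        for _ in range(200):
            p = np.round(rng.uniform(0, 1, 6), 2)
            np.testing.assert_array_equal(es.bh_fdr(p, 0.05), bh_bruteforce(p, 0.05))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            es.bh_fdr([1.5])


class TestRegression:
    def test_exact_line(self):
        res = es.regress_slope_vs_age([50, 60, 70], [1.0, 0.8, 0.6])
        assert res.beta2 == pytest.approx(-0.02, abs=1e-12)
        assert res.beta1 == pytest.approx(2.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_scipy_linregress(self, rng):
        x = rng.uniform(50, 90, 40)
        y = 0.5 + 0.01 * x + rng.normal(0, 0.1, 40)
        res = es.regress_slope_vs_age(x, y)
        ref = sps.linregress(x, y)
        assert res.beta2 == pytest.approx(ref.slope, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        assert res.r_squared == pytest.approx(ref.rvalue**2, abs=1e-10)

    def test_null_rejection_rate(self, rng):
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            x = rng.uniform(50, 90, 100)
            y = rng.standard_normal(100)
            if es.regress_slope_vs_age(x, y).p_value < 0.05:
                hits += 1
        assert hits / n_sim == pytest.approx(0.05, abs=0.02)

    def test_degenerate_design(self):
        with pytest.raises(ValueError, match="variance"):
            es.regress_slope_vs_age([60, 60, 60], [1, 2, 3])


class TestPairCaseControls:
    CONTROLS = [("c1", 69.0, "M"), ("c2", 71.0, "M"), ("c3", 70.0, "F")]

    def test_gender_and_age_rule(self):
        metric = {"case": 1.0, "c1": 2.0, "c2": 4.0, "c3": 9.0}
        pairs = es.pair_case_controls([("case", 70.0, "M")], self.CONTROLS, metric)
        assert len(pairs) == 1
        assert pairs.n_controls == [2]  # c3 excluded by gender
        assert pairs.control_values[0] == pytest.approx(3.0)  # median of {2, 4}

    def test_unmatched_case_dropped(self):
        metric = {"case": 1.0, "c1": 2.0}
        pairs = es.pair_case_controls(
            [("case", 80.0, "F")], [("c1", 70.0, "F")], metric
        )
        assert len(pairs) == 0
        assert pairs.dropped_cases == ["case"]

    def test_identical_control_values(self):
        metric = {"case": 1.0, "c1": 5.0, "c2": 5.0}
        pairs = es.pair_case_controls(
            [("case", 70.0, "M")],
            [("c1", 70.0, "M"), ("c2", 70.5, "M")],
            metric,
        )
        assert pairs.control_values[0] == 5.0

    def test_invariant_under_control_permutation(self):
        metric = {"case": 1.0, "c1": 2.0, "c2": 4.0, "c3": 9.0}
        p1 = es.pair_case_controls([("case", 70.0, "M")], self.CONTROLS, metric)
        p2 = es.pair_case_controls([("case", 70.0, "M")], self.CONTROLS[::-1], metric)
        assert p1.control_values[0] == p2.control_values[0]

    def test_output_size_bounded_by_cases(self):
        metric = {"a": 1.0, "b": 2.0, "c1": 3.0}
        pairs = es.pair_case_controls(
            [("a", 70.0, "M"), ("b", 71.0, "M")], [("c1", 70.5, "M")], metric
        )
        assert len(pairs) <= 2


class TestSubsampleMatchR2:
    def test_identical_distributions_preserved(self, rng):
        r2 = rng.uniform(0.3, 0.9, 50)
        va, vb = es.subsample_match_r2(np.arange(50.0), r2, np.arange(50.0), r2, seed=0)
        assert va.size == 50 and vb.size == 50

    def test_disjoint_supports_error(self):
        with pytest.raises(ValueError, match="overlap"):
            es.subsample_match_r2([1.0, 2.0], [0.1, 0.12], [3.0, 4.0], [0.8, 0.9])

    def test_per_bin_counts_equal(self, rng):
        ra = rng.uniform(0, 1, 200)
        rb = rng.uniform(0.2, 1, 150)
        va, vb = es.subsample_match_r2(ra.copy(), ra, rb.copy(), rb, seed=3)
        # the retained values ARE the retained r2 here; histograms must match
        ha, _ = np.histogram(va, bins=np.arange(0, 1.05, 0.05))
        hb, _ = np.histogram(vb, bins=np.arange(0, 1.05, 0.05))
        np.testing.assert_array_equal(ha, hb)


class TestSignedRank:
    def test_matches_scipy(self, rng):
        a = rng.standard_normal(20)
        b = a + rng.normal(0.3, 0.5, 20)
        ref = sps.wilcoxon(a - b, alternative="two-sided").pvalue
        assert signed_rank_test(a, b) == pytest.approx(ref, abs=1e-10)

    def test_identical_pairs_p_one(self):
        a = np.arange(5.0)
        assert signed_rank_test(a, a) == 1.0


class TestCompareGroups:
    def _profiles(self, rng, shift=0.0, n=12, n_win=10):
        base = rng.normal(1.0, 0.1, (n, n_win))
        return base + shift

    def test_identical_subjects_p_one(self, rng):
        vals = self._profiles(rng)
        out = es.compare_groups(
            np.arange(10.0), {"a": vals, "b": vals.copy()}, n_boot=200
        )
        np.testing.assert_allclose(out.p_values, 1.0)
        assert not out.cluster_masks[0.05].any()

    def test_shifted_group_detected(self, rng):
        a = self._profiles(rng)
        b = self._profiles(rng, shift=0.5)
        out = es.compare_groups(np.arange(10.0), {"a": a, "b": b}, n_boot=200)
        assert out.cluster_masks[0.05].all()
        assert (out.medians["b"] > out.medians["a"]).all()

    def test_missing_dropped_pairwise(self, rng):
        a = self._profiles(rng)
        a[:, 0] = np.nan  # window 0 unusable in group a
        b = self._profiles(rng)
        out = es.compare_groups(np.arange(10.0), {"a": a, "b": b}, n_boot=100)
        assert np.isnan(out.p_values[0])
        assert out.n["a"][0] == 0

    def test_wrs_needs_two_groups(self, rng):
        with pytest.raises(ValueError):
            es.compare_groups(
                np.arange(5.0),
                {"a": np.ones((3, 5)), "b": np.ones((3, 5)), "c": np.ones((3, 5))},
                test="WRS",
            )
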