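import math

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sps

from tonepredict.stats import (
    cluster_perm_test,
    jzs_bf_one_sample,
    jzs_bf_two_sample,
    logistic_tinnitus_model,
    pointwise_vs_chance,
    spearman,
    subsample_bf_curve,
    tost_equivalence,
    welch_t,
)


class TestPointwiseVsChance:
    def test_exactly_chance_never_significant(self):
        rng = np.random.default_rng(0)
        acc = 0.25 + rng.normal(0, 1e-3, size=(20, 30))
        res = pointwise_vs_chance(acc)
        assert not res["significant"].any()

    def test_extreme_effect_at_one_point_detected(self):
        rng = np.random.default_rng(1)
        acc = 0.25 + rng.normal(0, 0.01, size=(20, 30))
        acc[:, 7] = 1.0 + rng.normal(0, 0.01, size=20)
        res = pointwise_vs_chance(acc)
        assert res["significant"][7]
        assert res["alpha_corrected"] == pytest.approx(0.05 / 30)

    def test_zero_variance_points_flagged_not_significant(self):
        rng = np.random.default_rng(2)
        acc = 0.25 + rng.normal(0, 0.01, size=(10, 5))
        acc[:, 2] = 0.25
        with pytest.warns(UserWarning, match="zero variance"):
            res = pointwise_vs_chance(acc)
        assert not res["significant"][2]


class TestClusterPermutation:
    def test_identical_groups_produce_no_clusters(self):
        a = np.full((5, 20), 0.3)
        res = cluster_perm_test(a, a.copy(), n_perm=100, seed=0)
        assert res.clusters == []

    def test_injected_shift_recovered_as_significant_cluster(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, size=(15, 40))
        b = rng.normal(0, 1, size=(15, 40))
        a[:, 10:20] += 2.0
        res = cluster_perm_test(a, b, tail="one_sided_pos", n_perm=500, seed=1)
        best = res.clusters[0]
        assert best.p_perm <= 0.05
        assert set(range(12, 18)).issubset(set(best.indices))

    def test_2d_blob_recovered_with_4_neighborhood(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, size=(12, 10, 10))
        b = rng.normal(0, 1, size=(12, 10, 10))
        a[:, 3:6, 4:8] += 2.5
        res = cluster_perm_test(a, b, tail="two_sided", n_perm=300, seed=2)
        best = res.clusters[0]
        assert best.p_perm <= 0.05
        mask = np.zeros((10, 10), dtype=bool).ravel()
        mask[best.indices] = True
        assert mask.reshape(10, 10)[4, 5]

    def test_one_sided_positive_reports_no_negative_sums(self):
        rng = np.random.default_rng(5)
        a = rng.normal(-1.0, 1, size=(10, 30))
        b = rng.normal(1.0, 1, size=(10, 30))
        res = cluster_perm_test(a, b, tail="one_sided_pos", n_perm=200, seed=3)
        assert all(c.t_sum > 0 for c in res.clusters)

    def test_p_values_respect_estimator_bounds(self):
        rng = np.random.default_rng(6)
        a = rng.normal(2, 1, size=(12, 25))
        b = rng.normal(0, 1, size=(12, 25))
        res = cluster_perm_test(a, b, tail="one_sided_pos", n_perm=200, seed=4)
        for c in res.clusters:
            assert 1.0 / 201.0 <= c.p_perm <= 1.0

    def test_one_sample_sign_flip_variant(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, size=(14, 30))
        x[:, 5:12] += 1.5
        res = cluster_perm_test(x, None, tail="one_sided_pos", n_perm=300, seed=5)
        assert res.clusters[0].p_perm <= 0.05

    def test_too_few_subjects_for_permutations_rejected(self):
        a = np.random.default_rng(8).normal(size=(2, 10))
        b = np.random.default_rng(9).normal(size=(2, 10))
        with pytest.raises(ValueError, match="relabelings"):
            cluster_perm_test(a, b, n_perm=1000, seed=0)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0.5, 1, size=(8, 20))
        b = rng.normal(0.0, 1, size=(8, 20))
        r1 = cluster_perm_test(a, b, n_perm=200, seed=6)
        r2 = cluster_perm_test(a[::-1], b[::-1], n_perm=200, seed=6)
        assert np.allclose(r1.t_obs, r2.t_obs)

    def test_observed_clusters_match_mne_reference(self):
        # deterministic part (t map, thresholding, contiguity, summed t)
        # checked against the reference implementation in mne
        mne_stats = pytest.importorskip("mne.stats")
        rng = np.random.default_rng(11)
        x = rng.normal(0.2, 1, size=(13, 35))
        ours = cluster_perm_test(x, None, tail="one_sided_pos", n_perm=100,
                                 cluster_alpha=0.05, seed=7)
        thr = sps.t.ppf(0.95, 12)
        _, clusters, _, _ = mne_stats.permutation_cluster_1samp_test(
            x, threshold=thr, tail=1, n_permutations=50, seed=0, out_type="indices",
            verbose="error",
        )
        ref = sorted(tuple(c[0]) for c in clusters)
        got = sorted(tuple(c.indices) for c in ours.clusters)
        assert got == ref
        for c in ours.clusters:
            assert c.t_sum == pytest.approx(ours.t_obs[c.indices].sum())


class TestCorrelationsAndT:
    def test_spearman_perfect_monotone(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert spearman(x, x)["rho"] == pytest.approx(1.0)
        assert spearman(x, -x)["rho"] == pytest.approx(-1.0)

    def test_spearman_monotone_transform_invariance(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r1 = spearman(x, y)["rho"]
        r2 = spearman(np.exp(x), y)["rho"]
        assert r1 == pytest.approx(r2)

    def test_spearman_constant_input_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            res = spearman(np.ones(6), np.arange(6.0))
        assert not res["valid"]

    def test_welch_identical_groups(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=20)
        assert welch_t(a, a.copy())["t"] == pytest.approx(0.0)

    def test_welch_matches_textbook_formula(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.4, 2, 20)
        res = welch_t(a, b)
        va, vb = a.var(ddof=1) / 12, b.var(ddof=1) / 20
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 11 + vb**2 / 19)
        assert res["t"] == pytest.approx(t, abs=1e-12)
        assert res["df"] == pytest.approx(df, abs=1e-9)

    def test_welch_equal_variance_equal_n_df_near_pooled(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0, 1, 200)
        b = rng.normal(0, 1, 200)
        assert welch_t(a, b)["df"] == pytest.approx(398, rel=0.02)

    def test_welch_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t(np.ones(5), np.full(5, 2.0))


class TestBayesFactors:
    def test_zero_t_favors_null(self):
        a = np.arange(10.0)
        res = jzs_bf_two_sample(a, a.copy())
        assert res.t == pytest.approx(0.0)
        assert res.bf10 < 1

    def test_large_effect_supports_difference(self):
        rng = np.random.default_rng(16)
        a = rng.normal(1.5, 1, 40)
        b = rng.normal(0.0, 1, 40)
        assert jzs_bf_two_sample(a, b).bf10 > 3

    def test_reciprocity(self):
        rng = np.random.default_rng(17)
        res = jzs_bf_two_sample(rng.normal(0, 1, 15), rng.normal(0.3, 1, 15))
        assert res.bf10 * res.bf01 == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("shift,n", [(0.0, 12), (0.8, 20), (2.0, 40)])
    def test_matches_effect_size_marginalization_oracle(self, shift, n):
        # independent route: marginalize the Cauchy prior on standardized
        # effect size against the noncentral-t likelihood of the observed t
        rng = np.random.default_rng(18)
        a = rng.normal(shift, 1, n)
        b = rng.normal(0, 1, n)
        res = jzs_bf_two_sample(a, b)
        n_eff = n * n / (2 * n)
        r = res.prior_scale

        def h1(delta):
            return sps.nct.pdf(res.t, res.df, delta * math.sqrt(n_eff)) * sps.cauchy.pdf(
                delta, scale=r
            )

        num, _ = integrate.quad(h1, -np.inf, np.inf, limit=200)
        oracle = num / sps.t.pdf(res.t, res.df)
        assert res.bf10 == pytest.approx(oracle, rel=0.01)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(19)
        a = rng.normal(0.6, 1, 25)
        b = rng.normal(0.0, 1, 25)
        res = jzs_bf_two_sample(a, b)
        ref = float(
            pingouin.bayesfactor_ttest(res.t, 25, 25, paired=False, r=res.prior_scale)
        )
        assert res.bf10 == pytest.approx(ref, rel=0.01)

    def test_one_sample_variant(self):
        rng = np.random.default_rng(20)
        x = rng.normal(1.0, 1, 30)
        assert jzs_bf_one_sample(x).bf10 > 3
        assert jzs_bf_one_sample(x - x.mean()).bf10 < 1


class TestEquivalence:
    def test_identical_large_samples_are_equivalent(self):
        rng = np.random.default_rng(21)
        a = rng.normal(0, 1, 200)
        b = rng.normal(0, 1, 200)
        res = tost_equivalence(a, b, bounds=0.5)
        assert res["equivalent"]

    def test_large_true_difference_not_equivalent(self):
        rng = np.random.default_rng(22)
        a = rng.normal(3.0, 1, 50)
        b = rng.normal(0.0, 1, 50)
        assert not tost_equivalence(a, b, bounds=0.5)["equivalent"]

    def test_p_values_match_one_sided_welch_oracle(self):
        rng = np.random.default_rng(23)
        a = rng.normal(0.1, 1, 30)
        b = rng.normal(0.0, 1.5, 40)
        delta = 0.4  # raw units
        res = tost_equivalence(a, b, bounds=delta, standardized=False)
        se = math.sqrt(a.var(ddof=1) / 30 + b.var(ddof=1) / 40)
        df = res["df"]
        diff = a.mean() - b.mean()
        assert res["p_lower"] == pytest.approx(sps.t.sf((diff + delta) / se, df), abs=1e-12)
        assert res["p_upper"] == pytest.approx(sps.t.cdf((diff - delta) / se, df), abs=1e-12)

    def test_nonpositive_bounds_rejected(self):
        with pytest.raises(ValueError):
            tost_equivalence(np.arange(5.0), np.arange(5.0), bounds=0.0)


class TestLogisticModel:
    def test_uninformative_score_has_null_coefficient(self):
        rng = np.random.default_rng(24)
        n = 200
        group = np.array(["tinnitus"] * (n // 2) + ["control"] * (n // 2))
        score = rng.normal(0, 1, n)           # independent of group
        pta = rng.normal(15, 5, n) + 5 * (group == "tinnitus")
        res = logistic_tinnitus_model(score, group, pta=pta)
        assert res.coefficients["prediction_score"]["p"] > 0.05

    def test_odds_ratio_is_exp_of_coef_times_sd(self):
        rng = np.random.default_rng(25)
        n = 150
        score = rng.normal(0, 0.01, n)
        logit = -0.2 + 120.0 * score
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        if len(np.unique(y)) < 2:
            y[:2] = [0, 1]
        res = logistic_tinnitus_model(score, y)
        b = res.coefficients["prediction_score"]["coef"]
        assert res.odds_ratio_per_sd == pytest.approx(
            math.exp(b * score.std(ddof=1)), abs=1e-12
        )

    def test_recovers_generative_slope(self):
        rng = np.random.default_rng(26)
        n = 4000
        score = rng.normal(0, 1, n)
        true_b = 0.8
        y = (rng.random(n) < 1 / (1 + np.exp(-true_b * score))).astype(float)
        res = logistic_tinnitus_model(score, y)
        b = res.coefficients["prediction_score"]
        assert abs(b["coef"] - true_b) < 3 * b["se"]

    def test_reversed_linear_model_reported(self):
        rng = np.random.default_rng(27)
        group = np.array(["tinnitus"] * 30 + ["control"] * 30)
        score = rng.normal(0, 1, 60) + 0.004 * (group == "tinnitus")
        res = logistic_tinnitus_model(score, group)
        diff = score[:30].mean() - score[30:].mean()
        assert res.reversed_model["coef"] == pytest.approx(diff, abs=1e-10)

    def test_perfect_separation_reported(self):
        score = np.concatenate([np.full(20, -2.0), np.full(20, 2.0)])
        y = np.repeat([0.0, 1.0], 20)
        with pytest.raises(ValueError, match="separation"):
            logistic_tinnitus_model(score, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_tinnitus_model(np.arange(5.0), np.ones(5))


class TestSubsampleCurve:
    def test_counts_reported_and_oversized_skipped(self, small_design, small_sensors, kernel):
        from conftest import make_subject

        cohort = []
        for i, (group, alpha) in enumerate(
            [("tinnitus", 0.0)] * 2 + [("control", -0.3)] * 2
        ):
            spec, _, ep = make_subject(
                small_design, small_sensors, kernel, alpha_pre=alpha, seed=30 + i,
                seq_seed=40 + i,
            )
            spec.group = group
            cohort.append((spec, ep))
        with pytest.warns(UserWarning, match="skipped"):
            curve = subsample_bf_curve(cohort, trial_counts=(40, 64, 100_000), seed=0)
        assert set(curve) == {40, 64}
        assert all(v > 0 for v in curve.values())
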