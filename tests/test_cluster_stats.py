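import numpy as np
import pytest

from codecide.cluster_stats import (ConditionedSample, equalize_conditions,
                                    f_thresholds, find_clusters, mass_anova,
                                    permutation_pvalues)


def brute_force_two_way_f(values, correct, confidence):
    """Textbook balanced two-way fixed-effects ANOVA by explicit sums of
    squares (independent of the vectorized implementation)."""
    values = np.asarray(values, float)
    cells = {(a, b): values[(correct == a) & (confidence == b)]
             for a in (0, 1) for b in (1, 2, 3, 4)}
    n = len(next(iter(cells.values())))
    grand = values.mean()
    a_means = {a: np.mean([cells[(a, b)].mean() for b in (1, 2, 3, 4)])
               for a in (0, 1)}
    b_means = {b: np.mean([cells[(a, b)].mean() for a in (0, 1)])
               for b in (1, 2, 3, 4)}
    ss_a = 4 * n * sum((a_means[a] - grand) ** 2 for a in (0, 1))
    ss_b = 2 * n * sum((b_means[b] - grand) ** 2 for b in (1, 2, 3, 4))
    ss_ab = n * sum((cells[(a, b)].mean() - a_means[a] - b_means[b] + grand) ** 2
                    for a in (0, 1) for b in (1, 2, 3, 4))
    ss_err = sum(((cells[(a, b)] - cells[(a, b)].mean()) ** 2).sum()
                 for a in (0, 1) for b in (1, 2, 3, 4))
    df_err = values.size - 8
    mse = ss_err / df_err
    return ss_a / 1 / mse, ss_b / 3 / mse, ss_ab / 3 / mse


def balanced_labels(n_per_cell):
    correct = np.repeat([0, 1], 4 * n_per_cell)
    confidence = np.tile(np.repeat([1, 2, 3, 4], n_per_cell), 2)
    return correct, confidence


class TestEqualize:
    def test_subsamples_every_cell_to_target(self, rng):
        correct, confidence = balanced_labels(10)
        extra = np.concatenate([correct, [0] * 5]), \
            np.concatenate([confidence, [1] * 5])
        data = rng.normal(size=(85, 20))
        sample = equalize_conditions(data, extra[0], extra[1], 10, rng)
        assert sample.n_per_cell == 10
        assert sample.data.shape == (80, 20)

    def test_min_cell_passes_unsampled(self, rng):
        correct, confidence = balanced_labels(6)
        data = rng.normal(size=(48, 10))
        sample = equalize_conditions(data, correct, confidence, 6, rng)
        # same rows, same order
        np.testing.assert_array_equal(sample.data, data)

    def test_identical_seed_identical_subsample(self, rng):
        correct, confidence = balanced_labels(12)
        data = rng.normal(size=(96, 10))
        a = equalize_conditions(data, correct, confidence, 8,
                                np.random.default_rng(5))
        b = equalize_conditions(data, correct, confidence, 8,
                                np.random.default_rng(5))
        np.testing.assert_array_equal(a.data, b.data)

    def test_underpopulated_cell_named(self, rng):
        correct, confidence = balanced_labels(4)
        data = rng.normal(size=(32, 5))
        with pytest.raises(ValueError, match="correct=0, confidence=1"):
            equalize_conditions(data, correct, confidence, 5, rng)


class TestMassAnova:
    def test_identical_values_give_zero_f(self):
        correct, confidence = balanced_labels(3)
        sample = ConditionedSample(np.ones((24, 7)), correct, confidence)
        f = mass_anova(sample)
        for eff in f:
            np.testing.assert_array_equal(f[eff], 0.0)

    def test_cell_shift_without_noise_blows_up_with_warning(self):
        correct, confidence = balanced_labels(3)
        data = np.zeros((24, 4))
        data[correct == 1] = 1.0  # deterministic between-cell difference
        sample = ConditionedSample(data, correct, confidence)
        with pytest.warns(UserWarning, match="within-cell"):
            f = mass_anova(sample)
        assert np.all(np.isinf(f["correct"]))

    def test_matches_brute_force_oracle(self, rng):
        correct, confidence = balanced_labels(3)
        data = rng.normal(size=(24, 5)) + 0.5 * correct[:, None]
        sample = ConditionedSample(data, correct, confidence)
        f = mass_anova(sample)
        for t in range(5):
            fa, fb, fab = brute_force_two_way_f(data[:, t], correct, confidence)
            assert f["correct"][t] == pytest.approx(fa, rel=1e-9)
            assert f["confidence"][t] == pytest.approx(fb, rel=1e-9)
            assert f["interaction"][t] == pytest.approx(fab, rel=1e-9)

    def test_pure_correct_shift_leaves_confidence_near_null(self):
        rng = np.random.default_rng(21)
        correct, confidence = balanced_labels(30)
        data = rng.normal(size=(240, 100)) + 1.0 * correct[:, None]
        sample = ConditionedSample(data, correct, confidence)
        f = mass_anova(sample)
        # F for confidence should hover around its null mean df2/(df2-2) ~ 1
        assert abs(f["confidence"].mean() - 1.0) < 0.15
        assert f["correct"].mean() > 10


class TestFindClusters:
    def test_all_subthreshold_empty(self):
        assert find_clusters(np.zeros(10), threshold=1.0) == []

    def test_single_run_sum(self):
        f = np.array([0, 4, 5, 6, 5, 4, 0], dtype=float)
        clusters = find_clusters(f, threshold=3.0)
        assert len(clusters) == 1
        assert clusters[0].start == 1 and clusters[0].stop == 5
        assert clusters[0].f_sum == pytest.approx(24.0)

    def test_gap_splits_runs(self):
        f = np.array([5, 5, 1, 5, 5], dtype=float)
        clusters = find_clusters(f, threshold=3.0)
        assert [(c.start, c.stop) for c in clusters] == [(0, 1), (3, 4)]


class TestPermutation:
    def test_identity_permutations_give_p_one(self, rng):
        # data with exactly one strong observed cluster
        correct, confidence = balanced_labels(4)
        data = rng.normal(size=(32, 40))
        data[correct == 1, 10:20] += 3.0

        class IdentityRng:
            def permutation(self, x):
                return np.array(x)

        sample = ConditionedSample(data, correct, confidence)
        results = permutation_pvalues(sample, n_permutations=100,
                                      rng=IdentityRng(), null_mode="max")
        clusters = results["correct"].clusters
        assert len(clusters) >= 1
        big = max(clusters, key=lambda c: c.f_sum)
        # every permutation reproduces the observed maximum -> p = 1
        assert big.p_value == pytest.approx(1.0)

        # pooled null: every observed cluster appears in all permutations,
        # so the largest cluster's p follows exactly from the counts
        pooled = permutation_pvalues(sample, n_permutations=100,
                                     rng=IdentityRng(), null_mode="pooled")
        k = len(pooled["correct"].clusters)
        big_p = max(pooled["correct"].clusters, key=lambda c: c.f_sum).p_value
        assert big_p == pytest.approx((1 + 100) / (1 + 100 * k))

    def test_retained_cluster_covers_injected_effect(self):
        rng = np.random.default_rng(33)
        correct, confidence = balanced_labels(20)
        data = rng.normal(size=(160, 100))
        data[correct == 1, 30:60] += 1.0  # 1 SD shift over samples 30..59
        sample = ConditionedSample(data, correct, confidence, dt=0.1)
        results = permutation_pvalues(sample, n_permutations=200,
                                      rng=np.random.default_rng(4))
        retained = results["correct"].retained()
        assert retained
        spans = [(c.start, c.stop) for c in retained]
        assert any(s <= 45 <= e for s, e in spans)

    def test_retained_clusters_invariant_to_additive_constant(self):
        rng = np.random.default_rng(8)
        correct, confidence = balanced_labels(10)
        data = rng.normal(size=(80, 60))
        data[correct == 1, 20:40] += 1.2
        out = {}
        for shift in (0.0, 57.0):
            sample = ConditionedSample(data + shift, correct, confidence)
            res = permutation_pvalues(sample, n_permutations=150,
                                      rng=np.random.default_rng(99))
            out[shift] = [(c.start, c.stop, round(c.p_value, 6))
                          for c in res["correct"].retained()]
        assert out[0.0] == out[57.0]

    def test_max_mode_no_less_conservative_than_pooled(self):
        rng = np.random.default_rng(12)
        correct, confidence = balanced_labels(12)
        data = rng.normal(size=(96, 80))
        data[correct == 1, 30:50] += 0.9
        sample = ConditionedSample(data, correct, confidence)
        pooled = permutation_pvalues(sample, 150,
                                     rng=np.random.default_rng(7))
        maxed = permutation_pvalues(sample, 150,
                                    rng=np.random.default_rng(7),
                                    null_mode="max")
        for cp, cm in zip(pooled["correct"].clusters,
                          maxed["correct"].clusters):
            assert cm.p_value >= cp.p_value - 1e-12


class TestAgainstMne:
    def test_observed_clusters_match_mne_clustering(self, rng):
        """Same observed clusters as MNE's cluster machinery when given the
        identical pointwise statistic and threshold."""
        from mne import stats as mne_stats
        correct, confidence = balanced_labels(8)
        data = rng.normal(size=(64, 50))
        data[correct == 1, 15:35] += 1.0
        sample = ConditionedSample(data, correct, confidence)
        threshold = f_thresholds(sample)["correct"]
        f_obs = mass_anova(sample)["correct"]

        def stat_fun(*groups):
            stacked = np.concatenate(groups, axis=0)
            return mass_anova(ConditionedSample(
                stacked, correct, confidence))["correct"]

        groups = [data[sample.cell_index == c] for c in range(8)]
        t_obs, clusters, _, _ = mne_stats.permutation_cluster_test(
            groups, threshold=threshold, n_permutations=100,
            stat_fun=stat_fun, tail=1, seed=0, out_type="mask", verbose=False)
        np.testing.assert_allclose(t_obs, f_obs, atol=1e-10)

        def span(cl):  # MNE may return a bool mask or a tuple of slices
            if isinstance(cl, tuple):
                sl = cl[0]
                return int(sl.start), int(sl.stop) - 1
            idx = np.flatnonzero(cl)
            return int(idx[0]), int(idx[-1])

        mne_spans = sorted(span(m) for m in clusters)
        own_spans = sorted((c.start, c.stop)
                           for c in find_clusters(f_obs, threshold))
        assert mne_spans == own_spans
        # and the summed F per cluster agrees
        for span, cluster in zip(mne_spans,
                                 sorted(find_clusters(f_obs, threshold),
                                        key=lambda c: c.start)):
            assert cluster.f_sum == pytest.approx(
                f_obs[span[0]:span[1] + 1].sum(), rel=1e-12)
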