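import numpy as np
import pytest

from sillyputty import (
    ClusterLabels,
    DegenerateClusteringError,
    SillyPutty,
    SillyPuttyConfig,
    SillyPuttyError,
    Termination,
    adjusted_rand_index,
    mean_silhouette,
    run_sillyputty,
    silhouette_profile,
    sillyputty_random,
    sillyputty_step,
    sillyputty_warm,
)

from .conftest import make_blobs, random_instance
from .oracles import naive_silhouette


class TestStep:
    def test_fixed_point_returns_unchanged(self, line4):
        labels, moved = sillyputty_step(line4, [0, 0, 1, 1])
        assert moved is None
        np.testing.assert_array_equal(labels.assignment, [0, 0, 1, 1])

    def test_mislabeled_pair_moves_lowest_index_of_tied_worst(self, line4):
        # {A,B,B,A}: oracle gives s = -0.5 for indices 0 and 3 (tied),
        # so index 0 must move, into the cluster of its near neighbors (B).
        _, _, s, nearest = naive_silhouette(line4.values, np.array([0, 1, 1, 0]))
        assert s[0] == s[3] == min(s)
        labels, moved = sillyputty_step(line4, [0, 1, 1, 0])
        assert moved == 0
        assert labels.assignment[0] == nearest[0] == 1

    def test_moved_sample_new_cohesion_equals_old_separation(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            D, labels = random_instance(rng)
            prof = silhouette_profile(D, labels)
            if prof.s.min() >= 0:
                continue
            new_labels, moved = sillyputty_step(D, labels)
            assert moved is not None
            new_a, _, new_s, _ = naive_silhouette(D.values, new_labels.assignment)
            assert new_a[moved] == pytest.approx(prof.b[moved], abs=1e-12)
            # the mover's own silhouette strictly improves
            assert new_s[moved] > prof.s[moved]

    def test_singleton_is_terminal_never_emptied(self):
        # a sample alone in its cluster has s = 0 (non-negative), so the loop
        # can never select it and the clustering can never collapse to k = 1:
        # runs on a 2-cluster problem with an outlier singleton just converge
        pos = np.array([0.0, 10.0, 11.0, 12.0])
        from sillyputty import validate_distance_matrix

        D = validate_distance_matrix(np.abs(np.subtract.outer(pos, pos)))
        res = run_sillyputty(D, [1, 1, 0, 1])
        assert res.termination is Termination.CONVERGED
        assert res.labels.k == 2
        assert res.profile.s.min() >= 0

    def test_single_cluster_labels_rejected(self, line4):
        with pytest.raises(DegenerateClusteringError):
            run_sillyputty(line4, [0, 0, 0, 0])


class TestRun:
    def test_perfect_init_converges_in_zero_iterations(self, blobs3):
        _, truth, D = blobs3
        res = run_sillyputty(D, truth)
        assert res.termination is Termination.CONVERGED
        assert res.n_iterations == 0 and res.trace == ()
        np.testing.assert_array_equal(res.labels.assignment, truth.assignment)

    def test_converged_run_is_a_fixed_point_with_nonnegative_widths(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            D, init = random_instance(rng, n_max=25, k_max=4)
            try:
                res = run_sillyputty(D, init)
            except DegenerateClusteringError:
                continue
            if res.termination is Termination.CONVERGED:
                assert res.profile.s.min() >= 0
                labels, moved = sillyputty_step(D, res.labels)
                assert moved is None
                np.testing.assert_array_equal(labels.assignment, res.labels.assignment)
            assert res.n_iterations <= SillyPuttyConfig().max_iter
            assert len(res.trace) == res.n_iterations

    def test_random_inits_recover_three_blobs(self):
        hits = 0
        n_runs = 40
        for i in range(n_runs):
            X, truth, D = make_blobs(60, 3, seed=100 + i)
            rng = np.random.default_rng(i)
            init = np.concatenate([np.arange(3), rng.integers(0, 3, size=57)])
            res = run_sillyputty(D, init)
            hits += adjusted_rand_index(res.labels, truth) == 1.0
        assert hits >= int(0.95 * n_runs)

    def test_max_iter_cap(self, blobs3):
        _, truth, D = blobs3
        rng = np.random.default_rng(0)
        bad = np.concatenate([np.arange(3), rng.integers(0, 3, size=57)])
        res = run_sillyputty(D, bad, SillyPuttyConfig(max_iter=1, loop_window=1))
        assert res.termination is Termination.MAX_ITER
        assert res.n_iterations == 1
        # best-ASW contract: returned state is at least as good as the start
        assert res.asw >= res.initial_asw

    def test_trajectory_scale_invariance(self):
        rng = np.random.default_rng(33)
        D, init = random_instance(rng, n_max=25, k_max=4)
        r1 = run_sillyputty(D, init)
        r2 = run_sillyputty(D.scaled(3.0), init)
        assert [t.sample_index for t in r1.trace] == [t.sample_index for t in r2.trace]
        np.testing.assert_array_equal(r1.labels.assignment, r2.labels.assignment)
        assert r1.termination is r2.termination

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(55)
        D, init = random_instance(rng, n_max=20, k_max=3)
        perm = rng.permutation(D.n_samples)
        D_perm = type(D)(D.values[np.ix_(perm, perm)])
        r1 = run_sillyputty(D, init)
        r2 = run_sillyputty(D_perm, init.assignment[perm])
        np.testing.assert_array_equal(r2.labels.assignment, r1.labels.assignment[perm])


class TestRandomStarts:
    def test_same_seed_is_bit_identical(self, blobs3):
        _, _, D = blobs3
        cfg = SillyPuttyConfig(n_starts=5, seed=123)
        r1 = sillyputty_random(D, 3, cfg)
        r2 = sillyputty_random(D, 3, cfg)
        np.testing.assert_array_equal(r1.labels.assignment, r2.labels.assignment)
        assert r1.asw == r2.asw and r1.n_iterations == r2.n_iterations

    def test_finds_truth_asw_or_better_on_separable_data(self, blobs3):
        _, truth, D = blobs3
        res = sillyputty_random(D, 3, SillyPuttyConfig(n_starts=20, seed=1))
        assert res.asw >= mean_silhouette(D, truth) - 1e-9

    def test_more_clusters_than_samples_rejected(self, line4):
        with pytest.raises(SillyPuttyError):
            sillyputty_random(line4, 5, SillyPuttyConfig(n_starts=2, seed=0))


class TestWarmStart:
    def test_perfect_init_unchanged(self, blobs3):
        _, truth, D = blobs3
        res = sillyputty_warm(D, truth)
        np.testing.assert_array_equal(res.labels.assignment, truth.assignment)

    def test_single_swapped_pair_repaired_quickly(self, blobs3):
        _, truth, D = blobs3
        bad = truth.assignment.copy()
        i = int(np.flatnonzero(bad == 0)[0])
        j = int(np.flatnonzero(bad == 1)[0])
        bad[i], bad[j] = bad[j], bad[i]
        res = sillyputty_warm(D, bad)
        assert adjusted_rand_index(res.labels, truth) == 1.0
        assert res.n_iterations <= 2

    def test_refinement_rarely_hurts_kmeans_inits(self):
        from sklearn.cluster import KMeans

        improved = 0
        trials = 20
        for i in range(trials):
            # overlapping blobs: moderate separation
            X, truth, D = make_blobs(45, 3, seed=500 + i, sep=2.5)
            km = KMeans(n_clusters=3, n_init=5, random_state=i).fit_predict(X.values)
            init_asw = mean_silhouette(D, km)
            res = sillyputty_warm(D, km)
            improved += res.asw >= init_asw - 1e-12
        assert improved >= int(0.9 * trials)


class TestModelInterface:
    def test_fit_from_features_and_summary(self, blobs3):
        X, truth, _ = blobs3
        model = SillyPutty.from_features(X, n_clusters=3, n_starts=10, seed=3)
        res = model.fit()
        assert adjusted_rand_index(res.labels, truth) == 1.0
        text = res.summary()
        assert "ASW" in text and "converged" in text
        assert res.labels_.shape == (60,)

    def test_from_dataframe_warm_start(self, blobs3):
        X, truth, _ = blobs3
        model = SillyPutty.from_dataframe(X.to_dataframe(), init_labels=truth)
        res = model.fit()
        assert res.n_iterations == 0

    def test_requires_init_or_k(self, blobs3):
        _, _, D = blobs3
        with pytest.raises(SillyPuttyError):
            SillyPutty(D)

    def test_config_validation(self):
        with pytest.raises(SillyPuttyError):
            SillyPuttyConfig(max_iter=0)
        with pytest.raises(SillyPuttyError):
            SillyPuttyConfig(max_iter=5, loop_window=10)


def test_cycle_detection_halts_and_returns_best_asw_state():
    """A lattice instance that provably oscillates: the loop must detect the
    recurring silhouette vector and return the best-ASW state seen."""
    from sillyputty import FeatureMatrix, euclidean_distances

    rng = np.random.default_rng(228)
    n, k = int(rng.integers(5, 12)), int(rng.integers(2, 4))
    pts = rng.integers(0, 3, size=(n, 2)).astype(float)
    D = euclidean_distances(FeatureMatrix(pts))
    init = np.concatenate([np.arange(k), rng.integers(0, k, size=n - k)])
    res = run_sillyputty(D, init, SillyPuttyConfig(max_iter=200, loop_window=20))
    assert res.termination is Termination.CYCLE_DETECTED
    assert res.asw >= res.initial_asw
    assert res.asw >= max(t.asw for t in res.trace)
    assert res.n_iterations < 200
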