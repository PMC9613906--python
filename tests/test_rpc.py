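import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.stats import spearmanr
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from scenescale import rpc, synth


def _same_partition(a, b):
    """Label-permutation-invariant partition equality."""
    a, b = np.asarray(a), np.asarray(b)
    mapping = {}
    for x, y in zip(a, b):
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


def _opposite_ramp_matrix(n_per_pool=20, scale_jitter=True, seed=0):
    rng = np.random.default_rng(seed)
    c = np.arange(1.0, 16.0)
    up = np.tile(c[:, None], (1, n_per_pool))
    down = np.tile(c[::-1][:, None], (1, n_per_pool))
    matrix = np.concatenate([down, up], axis=1)
    if scale_jitter:  # positive per-voxel gains: same correlation structure
        matrix = matrix * rng.uniform(0.5, 2.0, size=matrix.shape[1])[None, :]
    return matrix


class TestNormalizeProfiles:
    def test_zero_mean_unit_length(self):
        normalized, excluded = rpc.normalize_profiles(np.arange(1.0, 16.0)[:, None])
        assert excluded == []
        assert normalized[:, 0].mean() == pytest.approx(0.0, abs=1e-15)
        assert np.linalg.norm(normalized[:, 0]) == pytest.approx(1.0)

    def test_affine_copies_collapse(self):
        c = np.arange(1.0, 16.0)
        normalized, _ = rpc.normalize_profiles(np.column_stack([c, 5 * c + 7]))
        np.testing.assert_allclose(normalized[:, 0], normalized[:, 1], atol=1e-12)

    def test_constant_column_excluded_and_reported(self):
        matrix = np.column_stack([np.arange(15.0), np.full(15, 3.0)])
        normalized, excluded = rpc.normalize_profiles(matrix)
        assert excluded == [1]
        assert normalized.shape == (15, 1)
        with pytest.raises(ValueError):
            rpc.normalize_profiles(np.ones((15, 2)))


class TestClusterProfiles:
    def test_two_opposite_ramps_recovered_exactly(self):
        matrix = _opposite_ramp_matrix()
        sol = rpc.cluster_profiles(matrix, 2, seed=0)
        truth = np.repeat([1, 2], 20)
        assert _same_partition(sol.assignment, truth)
        assert sol.inertia == pytest.approx(0.0, abs=1e-12)

    def test_partition_invariant_to_column_order(self, rng):
        matrix = _opposite_ramp_matrix() + rng.normal(0, 0.5, size=(15, 40))
        perm = rng.permutation(40)
        sol = rpc.cluster_profiles(matrix, 2, seed=3)
        sol_perm = rpc.cluster_profiles(matrix[:, perm], 2, seed=3)
        assert _same_partition(sol.assignment[perm], sol_perm.assignment)

    def test_k_equals_voxels_gives_singletons(self, rng):
        matrix = rng.normal(size=(15, 6))
        sol = rpc.cluster_profiles(matrix, 6, seed=0)
        assert len(set(sol.assignment)) == 6
        assert sol.inertia == pytest.approx(0.0, abs=1e-12)

    def test_k_validation(self, rng):
        matrix = rng.normal(size=(15, 5))
        with pytest.raises(ValueError):
            rpc.cluster_profiles(matrix, 6)
        with pytest.raises(ValueError):
            rpc.cluster_profiles(matrix, 1)

    def test_constant_columns_rejected(self):
        matrix = np.column_stack([np.arange(15.0), np.ones(15), np.arange(15.0) ** 2])
        with pytest.raises(ValueError, match="constant"):
            rpc.cluster_profiles(matrix, 2)

    def test_inertia_descends_across_iterations(self, rng):
        matrix = rng.normal(size=(15, 120))
        sol = rpc.cluster_profiles(matrix, 5, replicates=1, seed=1)
        history = np.asarray(sol.inertia_history)
        assert np.all(np.diff(history) <= 1e-10)

    def test_seed_reproducibility(self, rng):
        matrix = rng.normal(size=(15, 50))
        a = rpc.cluster_profiles(matrix, 4, seed=9)
        b = rpc.cluster_profiles(matrix, 4, seed=9)
        assert np.array_equal(a.assignment, b.assignment)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_agrees_with_sklearn_on_separated_data(self, three_cluster_low_noise):
        """Independent cross-check: on normalized profiles of well-separated
        planted families, Euclidean k-means (sklearn) finds the same
        partition as correlation-distance k-means."""
        matrix = three_cluster_low_noise.group_matrix()
        sol = rpc.cluster_profiles(matrix, 3, seed=0)
        normalized, _ = rpc.normalize_profiles(matrix)
        sk = KMeans(n_clusters=3, n_init=10, random_state=0).fit(normalized.T)
        assert _same_partition(sol.assignment, sk.labels_ + 1)


class TestKScan:
    def test_vrc_hand_computation(self):
        points = np.array([[0.0], [1.0], [10.0], [11.0]])
        assert rpc.variance_ratio_criterion(points, np.array([1, 1, 2, 2])) == pytest.approx(200.0)

    def test_vrc_perfect_separation_is_infinite(self):
        points = np.array([[0.0], [0.0], [5.0], [5.0]])
        assert np.isinf(rpc.variance_ratio_criterion(points, np.array([1, 1, 2, 2])))

    def test_vrc_matches_sklearn(self, rng):
        points = rng.normal(size=(40, 5))
        labels = rng.integers(0, 3, size=40)
        assert rpc.variance_ratio_criterion(points, labels) == pytest.approx(
            calinski_harabasz_score(points, labels)
        )

    def test_identical_centroids_have_similarity_one(self):
        c = np.tile(np.arange(15.0), (3, 1))
        assert rpc.mean_centroid_similarity(c) == pytest.approx(1.0)

    def test_scan_reports_contiguous_range(self, three_cluster_low_noise):
        report = rpc.scan_k(
            three_cluster_low_noise.group_matrix(), range(2, 7), replicates=3, seed=0
        )
        assert np.array_equal(report.ks, [2, 3, 4, 5, 6])
        assert np.all(np.diff(report.ks) == 1)
        assert np.all(report.vrc > 0)
        # planted k=3 structure: VRC peaks at the true cluster count
        assert report.ks[np.argmax(report.vrc)] == 3


class TestClusterColors:
    def test_colors_within_unit_cube(self, rng):
        centroids = rpc.cluster_profiles(rng.normal(size=(15, 60)), 5, seed=0).centroids
        colors = rpc.cluster_colors(centroids)
        assert colors.shape == (5, 3)
        assert colors.min() >= 0.0 and colors.max() <= 1.0

    def test_two_clusters_occupy_opposite_corners_on_first_axis(self):
        c = np.vstack([np.arange(15.0), np.arange(15.0)[::-1]])
        colors = rpc.cluster_colors(c)
        assert sorted(colors[:, 0]) == [0.0, 1.0]

    def test_similar_centroids_get_similar_colors(self, rng):
        """Rank agreement: higher centroid correlation -> smaller RGB
        distance."""
        centroids = rpc.cluster_profiles(rng.normal(size=(15, 90)), 6, seed=0).centroids
        colors = rpc.cluster_colors(centroids)
        sims, dists = [], []
        for i in range(6):
            for j in range(i + 1, 6):
                sims.append(np.corrcoef(centroids[i], centroids[j])[0, 1])
                dists.append(np.linalg.norm(colors[i] - colors[j]))
        rho = spearmanr(sims, dists).statistic
        assert rho < -0.5


class TestCoassignmentStability:
    def test_self_agreement_is_perfect(self):
        labels = np.array([1, 1, 2, 3, 3, 3])
        report = rpc.coassignment_stability(labels, labels)
        assert report.dice == 1.0
        assert report.hit_rate == 1.0  # before clamping
        assert report.fa_rate == 0.0

    @pytest.mark.parametrize(
        "a, b, dice",
        [
            ([1, 1, 1, 2], [1, 1, 2, 2], 0.4),
            ([1, 1, 2, 2], [1, 2, 1, 2], 0.0),
        ],
    )
    def test_stated_enumeration_examples(self, a, b, dice):
        report = rpc.coassignment_stability(np.array(a), np.array(b))
        assert report.dice == pytest.approx(dice)

    @given(
        a=hnp.arrays(np.int64, 8, elements=st.integers(1, 3)),
        b=hnp.arrays(np.int64, 8, elements=st.integers(1, 3)),
    )
    def test_dice_symmetric_in_arguments(self, a, b):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ab = rpc.coassignment_stability(a, b)
            ba = rpc.coassignment_stability(b, a)
        if np.isnan(ab.dice) or np.isnan(ba.dice):
            return
        assert ab.dice == pytest.approx(ba.dice)

    def test_mismatched_voxel_sets_error(self):
        with pytest.raises(ValueError):
            rpc.coassignment_stability(np.array([1, 2]), np.array([1, 2, 3]))

    def test_degenerate_reference_warns_nan(self):
        with pytest.warns(RuntimeWarning):
            report = rpc.coassignment_stability(np.array([1, 1, 1]), np.array([1, 2, 3]))
        assert np.isnan(report.dice)

    def test_dprime_finite_under_clamping(self):
        labels = np.array([1, 1, 2, 2, 3, 3])
        report = rpc.coassignment_stability(labels, labels)
        assert np.isfinite(report.dprime)
        assert report.dprime > 0


class TestStimulusSplitStability:
    def test_noiseless_halves_agree_perfectly(self, three_cluster_noiseless):
        report, sol_a, sol_b = rpc.stimulus_splithalf_stability(
            three_cluster_noiseless, k=3, seed=0
        )
        assert report.dice == 1.0
        assert _same_partition(sol_a.assignment, sol_b.assignment)

    def test_permuted_labels_fall_to_permutation_chance(self, three_cluster_low_noise):
        """Destroying the voxel correspondence drops Dice into the
        permutation null distribution."""
        rng = np.random.default_rng(4)
        _, sol_a, sol_b = rpc.stimulus_splithalf_stability(
            three_cluster_low_noise, k=3, seed=0
        )
        null = np.array(
            [
                rpc.coassignment_stability(
                    sol_a.assignment, rng.permutation(sol_b.assignment)
                ).dice
                for _ in range(200)
            ]
        )
        observed = rpc.coassignment_stability(
            sol_a.assignment, rng.permutation(sol_b.assignment)
        ).dice
        lo, hi = np.quantile(null, [0.005, 0.995])
        assert lo - 0.05 <= observed <= hi + 0.05
        # and the aligned solutions sit far above that chance level
        aligned = rpc.coassignment_stability(sol_a.assignment, sol_b.assignment).dice
        assert aligned > hi


class TestParticipantSplitStability:
    def test_noiseless_data_perfectly_stable_at_true_k(self, three_cluster_noiseless):
        scan = rpc.participant_splithalf_stability(
            three_cluster_noiseless, k_range=range(3, 4), n_iterations=2, seed=0,
            replicates=3,
        )
        np.testing.assert_allclose(scan.dice, 1.0)

    def test_same_seed_identical_reports(self, three_cluster_low_noise):
        kwargs = dict(k_range=range(2, 4), n_iterations=2, seed=5, replicates=2)
        a = rpc.participant_splithalf_stability(three_cluster_low_noise, **kwargs)
        b = rpc.participant_splithalf_stability(three_cluster_low_noise, **kwargs)
        np.testing.assert_array_equal(a.dice, b.dice)
        np.testing.assert_array_equal(a.dprime, b.dprime)

    def test_true_k_more_stable_than_overclustering(self):
        """Planted 3-cluster data at moderate noise: mean Dice at k = 3
        exceeds mean Dice at k = 10."""
        from conftest import THREE_CLUSTER_SPECS

        dataset = synth.generate_dataset(
            synth.GeneratorConfig(cluster_specs=THREE_CLUSTER_SPECS, noise_sd=0.5, seed=2)
        )
        scan = rpc.participant_splithalf_stability(
            dataset, k_range=range(3, 11, 7), n_iterations=5, seed=1, replicates=3
        )
        assert np.array_equal(scan.ks, [3, 10])
        assert scan.dice_mean[0] > scan.dice_mean[1]

    def test_single_participant_rejected(self):
        config = synth.GeneratorConfig(
            n_participants=1,
            cluster_specs=(synth.ClusterSpec("ramp_up", {"intercept": 0.0, "slope": 1.0}, 4),),
        )
        with pytest.raises(ValueError):
            rpc.participant_splithalf_stability(synth.generate_dataset(config), range(2, 3))


class TestCrossvalProfiles:
    def test_noiseless_heldout_profiles_equal_centroids(self, three_cluster_noiseless):
        sol = rpc.cluster_profiles(three_cluster_noiseless.split_average(0), 3, seed=0)
        profiles, empty = rpc.crossval_cluster_profiles(
            sol, three_cluster_noiseless.split_average(1)
        )
        assert empty == []
        np.testing.assert_allclose(profiles, sol.centroids, atol=1e-10)

    def test_planted_ramp_cluster_heldout_profile_monotone(self, three_cluster_noiseless):
        sol = rpc.cluster_profiles(three_cluster_noiseless.split_average(0), 3, seed=0)
        profiles, _ = rpc.crossval_cluster_profiles(
            sol, three_cluster_noiseless.split_average(1)
        )
        monotone = [
            np.all(np.diff(p) > 0) or np.all(np.diff(p) < 0) for p in profiles
        ]
        assert sum(monotone) == 2  # the two opposing ramp families

    def test_voxel_set_mismatch_error(self, three_cluster_noiseless, rng):
        sol = rpc.cluster_profiles(three_cluster_noiseless.split_average(0), 3, seed=0)
        with pytest.raises(ValueError):
            rpc.crossval_cluster_profiles(sol, rng.normal(size=(15, 7)))

    def test_empty_cluster_flagged(self):
        sol = rpc.ClusteringSolution(
            k=3,
            assignment=np.array([1, 1, 2, 2]),
            centroids=np.zeros((3, 15)),
            inertia=0.0,
            seed=0,
        )
        profiles, empty = rpc.crossval_cluster_profiles(
            sol, np.arange(60.0).reshape(15, 4)
        )
        assert empty == [3]
        assert np.isnan(profiles[2]).all()
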