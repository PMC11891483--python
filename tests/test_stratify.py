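import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import SpectralClustering
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from connstrat import stratify


def two_blob_distance(n_per=20, sep=8.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per, 3))
    X[n_per:, 0] += sep
    truth = np.repeat([0, 1], n_per)
    return stratify.euclidean_distance(X), truth, X


class TestStandardize:
    def test_closed_form(self):
        out = stratify.standardize(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out[:, 0], [-1, 0, 1])

    def test_idempotent(self):
        X = np.random.default_rng(1).standard_normal((30, 4))
        Z = stratify.standardize(X)
        assert np.allclose(stratify.standardize(Z), Z, atol=1e-12)

    def test_column_means_vanish(self):
        X = np.random.default_rng(2).normal(3, 7, size=(156, 13))
        Z = stratify.standardize(X)
        assert np.max(np.abs(Z.mean(axis=0))) < 1e-10
        assert np.allclose(Z.std(axis=0, ddof=1), 1.0)

    def test_constant_column_names_feature(self):
        df = pd.DataFrame({"iq": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            stratify.standardize(df)


class TestEuclideanDistance:
    def test_toy_values(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0], [0.0, 0.0]])
        D = stratify.euclidean_distance(X)
        assert D[0, 1] == pytest.approx(5.0)
        assert D[0, 2] == 0.0

    def test_matches_double_loop_oracle(self):
        X = np.random.default_rng(3).standard_normal((12, 5))
        D = stratify.euclidean_distance(X)
        for i in range(12):
            for j in range(12):
                assert D[i, j] == pytest.approx(
                    np.sqrt(((X[i] - X[j]) ** 2).sum()), abs=1e-12)


class TestAffinityNetwork:
    def test_zero_distance_gives_unit_weight(self):
        D = stratify.euclidean_distance(
            np.array([[0.0], [0.0], [3.0], [5.0], [9.0]]))
        W = stratify.affinity_network(D, k=2, alpha=0.5).weights
        assert W[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(W), 1.0)

    def test_kernel_monotone_in_distance(self):
        eps = 2.0
        d = np.array([1.0, 2.0, 3.0])
        w = np.exp(-d**2 / (2 * (0.5 * eps) ** 2))
        assert np.all(np.diff(w) < 0)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((5, 2))
        D = stratify.euclidean_distance(X)
        k, alpha = 2, 0.5
        W = stratify.affinity_network(D, k, alpha).weights
        for i in range(5):
            for j in range(5):
                mu_i = np.sort(np.delete(D[i], i))[:k].mean()
                mu_j = np.sort(np.delete(D[j], j))[:k].mean()
                eps = (mu_i + mu_j + D[i, j]) / 3.0
                expect = np.exp(-D[i, j] ** 2 / (2 * (alpha * eps) ** 2))
                assert W[i, j] == pytest.approx(expect, abs=1e-12)

    def test_k_out_of_range_rejected(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError, match="K"):
            stratify.affinity_network(D, k=4, alpha=0.5)


class TestSpectralCluster:
    def test_separated_blobs_recovered(self):
        D, truth, _ = two_blob_distance()
        W = stratify.affinity_network(D, 10, 0.5)
        labels = stratify.spectral_cluster(W, 2, rng=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_block_diagonal_recovered_exactly(self):
        W = np.zeros((15, 15))
        for lo in (0, 5, 10):
            W[lo:lo + 5, lo:lo + 5] = 0.9
        W += 0.01
        np.fill_diagonal(W, 1.0)
        labels = stratify.spectral_cluster(W, 3, rng=1)
        truth = np.repeat([0, 1, 2], 5)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_agrees_with_sklearn_on_blobs(self):
        D, truth, _ = two_blob_distance(seed=5)
        W = stratify.affinity_network(D, 10, 0.5).weights
        ours = stratify.spectral_cluster(W, 2, rng=2)
        ref = SpectralClustering(n_clusters=2, affinity="precomputed",
                                 random_state=0).fit_predict(W)
        assert adjusted_rand_score(ours, ref) == 1.0

    def test_subject_permutation_equivariance(self):
        D, _, _ = two_blob_distance(seed=6)
        W = stratify.affinity_network(D, 10, 0.5).weights
        perm = np.random.default_rng(7).permutation(W.shape[0])
        a = stratify.spectral_cluster(W, 2, rng=3)
        b = stratify.spectral_cluster(W[np.ix_(perm, perm)], 2, rng=3)
        assert adjusted_rand_score(a[perm], b) == 1.0

    def test_c_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="C"):
            stratify.spectral_cluster(np.eye(5), 1, rng=0)


class TestBootstrapConsensus:
    def test_single_full_resample_is_comembership(self):
        D, _, _ = two_blob_distance(seed=8)
        W = stratify.affinity_network(D, 10, 0.5)
        cons, _ = stratify.bootstrap_consensus(W, 2, n_bootstrap=1,
                                               inner_subsample=1.0, rng=9)
        labels = stratify.spectral_cluster(W, 2, rng=np.random.default_rng(9))
        assert np.array_equal(cons.co_cluster,
                              (labels[:, None] == labels[None, :]).astype(float))

    def test_blobs_give_bimodal_consensus_and_perfect_labels(self):
        D, truth, _ = two_blob_distance(seed=10)
        W = stratify.affinity_network(D, 10, 0.5)
        cons, labels = stratify.bootstrap_consensus(W, 2, n_bootstrap=50,
                                                    rng=11)
        assert adjusted_rand_score(truth, labels) == 1.0
        off = cons.co_cluster[~np.eye(40, dtype=bool)]
        assert np.all((off < 0.1) | (off > 0.9))

    def test_symmetry_and_unit_diagonal(self):
        D, _, _ = two_blob_distance(seed=12)
        W = stratify.affinity_network(D, 5, 0.5)
        cons, _ = stratify.bootstrap_consensus(W, 2, n_bootstrap=10, rng=13)
        assert np.allclose(cons.co_cluster, cons.co_cluster.T)
        assert np.allclose(np.diag(cons.co_cluster)[np.diag(cons.co_sampled) > 0],
                           1.0)
        assert np.all((cons.co_cluster >= 0) & (cons.co_cluster <= 1))


class TestSilhouette:
    def test_two_tight_far_pairs(self):
        D = stratify.euclidean_distance(np.array([[0.0], [0.0], [10.0], [10.0]]))
        assert stratify.silhouette_width([1, 1, 2, 2], D) == pytest.approx(1.0)

    def test_identical_points_score_zero(self):
        D = np.zeros((6, 6))
        assert stratify.silhouette_width([1, 1, 1, 2, 2, 2], D) == 0.0

    def test_matches_brute_force_and_sklearn(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((25, 3))
        D = stratify.euclidean_distance(X)
        labels = rng.integers(1, 4, size=25)
        ours = stratify.silhouette_width(labels, D)
        # independent per-point formula
        s = []
        for i in range(25):
            own = (labels == labels[i]) & (np.arange(25) != i)
            if own.sum() == 0:
                s.append(0.0)
                continue
            a = D[i, own].mean()
            b = min(D[i, labels == c].mean()
                    for c in set(labels) if c != labels[i])
            s.append((b - a) / max(a, b))
        assert ours == pytest.approx(np.mean(s), abs=1e-12)
        assert ours == pytest.approx(
            silhouette_samples(D, labels, metric="precomputed").mean(),
            abs=1e-12)

    def test_label_permutation_invariance(self):
        D, truth, _ = two_blob_distance(seed=15)
        labels = truth + 1
        swapped = np.where(labels == 1, 2, 1)
        assert stratify.silhouette_width(labels, D) == pytest.approx(
            stratify.silhouette_width(swapped, D))

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            stratify.silhouette_width([1, 1, 1], np.zeros((3, 3)))


class TestGridSelection:
    def test_default_grid_evaluates_thirty_candidates(self):
        D, _, _ = two_blob_distance(n_per=18, seed=16)
        cfg = stratify.StratifyConfig(n_bootstrap=5, seed=17)
        assert cfg.grid_size == 30
        sol, _ = stratify.select_best_grid(n_clusters=2, config=cfg, dist=D)
        evaluated = [p for p in sol.provenance if "silhouette" in p]
        assert len(evaluated) == 30

    def test_single_point_grid_is_pass_through(self):
        D, truth, _ = two_blob_distance(seed=18)
        cfg = stratify.StratifyConfig(k_grid=(10,), alpha_grid=(0.5,),
                                      n_bootstrap=10, seed=19)
        sol, cons = stratify.select_best_grid(n_clusters=2, config=cfg, dist=D)
        W = stratify.affinity_network(D, 10, 0.5)
        cons2, labels2 = stratify.bootstrap_consensus(
            W, 2, 10, rng=np.random.default_rng(19))
        assert np.array_equal(cons.co_cluster, cons2.co_cluster)
        assert adjusted_rand_score(sol.labels, labels2) == 1.0

    def test_planted_structure_wins(self):
        D, truth, _ = two_blob_distance(seed=20)
        cfg = stratify.StratifyConfig(k_grid=(10, 20), alpha_grid=(0.4, 0.7),
                                      n_bootstrap=20, seed=21)
        sol, _ = stratify.select_best_grid(n_clusters=2, config=cfg, dist=D)
        assert adjusted_rand_score(truth, sol.labels) == 1.0


class TestSubsampleConsensus:
    def test_degenerate_outer_loop_reduces_to_grid_selection(self, planted_cohort):
        _, X, _ = planted_cohort
        X = X[:40]
        cfg = stratify.StratifyConfig(k_grid=(10,), alpha_grid=(0.5,),
                                      n_bootstrap=10, n_repeats=1,
                                      subsample_fraction=1.0, seed=22)
        cons, sol = stratify.subsample_consensus(X, 2, cfg)
        D = stratify.euclidean_distance(stratify.standardize(X))
        ss = np.random.SeedSequence(22)
        streams = [np.random.default_rng(s) for s in ss.spawn(2)]
        ref, _ = stratify.select_best_grid(n_clusters=2, config=cfg, dist=D,
                                           rng=streams[0])
        assert adjusted_rand_score(sol.labels, ref.labels) == 1.0

    def test_recovery_with_reduced_defaults(self, planted_cohort):
        _, X, truth = planted_cohort
        cfg = stratify.StratifyConfig(k_grid=(10, 20), alpha_grid=(0.4, 0.8),
                                      n_bootstrap=30, n_repeats=12, seed=24)
        _, sol = stratify.subsample_consensus(X, 2, cfg)
        assert adjusted_rand_score(truth, sol.labels) > 0.9

    def test_recovery_not_decreasing_in_effect_size(self):
        from connstrat import synthio
        cfg = stratify.StratifyConfig(k_grid=(10,), alpha_grid=(0.5,),
                                      n_bootstrap=20, n_repeats=8, seed=25)
        aris = []
        for d in (1.0, 2.0, 3.0):
            eff = np.concatenate([np.full(8, d), np.zeros(5)])
            spec = synthio.CohortSpec(n_subjects=80, feature_effects=eff,
                                      seed=26)
            _, X, truth = synthio.gen_cohort(spec)
            _, sol = stratify.subsample_consensus(X, 2, cfg)
            aris.append(adjusted_rand_score(truth, sol.labels))
        assert aris[2] >= aris[0]
        assert aris[2] > 0.9

    def test_null_cohort_gives_low_structural_silhouette(self, null_cohort):
        # on structure-free data the final split explains little of the
        # feature-space geometry (consensus-basis silhouette instead
        # measures split *stability*, which can stay high under the null)
        _, X, _ = null_cohort
        cfg = stratify.StratifyConfig(k_grid=(15,), alpha_grid=(0.5,),
                                      n_bootstrap=20, n_repeats=10,
                                      silhouette_basis="euclidean", seed=27)
        _, sol = stratify.subsample_consensus(X, 2, cfg)
        assert sol.mean_silhouette < 0.3


class TestEstimateNumClusters:
    @staticmethod
    def _blob_affinity(centers, n_per=15, seed=28):
        rng = np.random.default_rng(seed)
        X = np.concatenate([rng.standard_normal((n_per, 2)) + c
                            for c in centers])
        D = stratify.euclidean_distance(X)
        return stratify.affinity_network(D, 10, 0.5)

    def test_block_diagonal_eigengap(self):
        W = np.zeros((18, 18))
        for lo in (0, 6, 12):
            W[lo:lo + 6, lo:lo + 6] = 0.8
        np.fill_diagonal(W, 1.0)
        est = stratify.estimate_num_clusters(W, candidates=range(2, 7))
        assert est["eigengap"][0] == 3

    def test_two_blobs_both_criteria(self):
        W = self._blob_affinity([(0, 0), (12, 0)])
        est = stratify.estimate_num_clusters(W, candidates=range(2, 6))
        assert est["eigengap"][0] == 2
        assert est["rotation_cost"][0] == 2

    def test_third_blob_moves_best_c(self):
        W = self._blob_affinity([(0, 0), (12, 0), (0, 12)], seed=29)
        est = stratify.estimate_num_clusters(W, candidates=range(2, 6))
        assert est["eigengap"][0] == 3
        assert est["rotation_cost"][0] == 3

    def test_out_of_range_candidates_rejected(self):
        with pytest.raises(ValueError):
            stratify.estimate_num_clusters(np.eye(5), candidates=range(2, 6))
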