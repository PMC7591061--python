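import numpy as np
import pytest
from vocalatent.metrics import (ClusterLabels, cluster_gmm, cluster_hdbscan,
                                cluster_kmeans, compare_silhouette_kruskal,
                                drop_noise, hopkins, overlap, pca_reduce,
                                permutation_null_vmeasure, silhouette)


def blobs(centers, n_per, sigma, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(c, sigma, size=(n_per, len(np.atleast_1d(c))))
                   for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return X, labels


def brute_silhouette(X, labels):
    """O(n^2) straight-loop evaluation of the silhouette definition."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    s = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = min(np.mean([np.linalg.norm(X[i] - X[j])
                         for j in range(n) if labels[j] == c])
                for c in set(labels.tolist()) - {labels[i]})
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def brute_overlap(classes, clusters):
    """Contingency-table evaluation with explicit loops, entropies in bits."""
    classes, clusters = list(classes), list(clusters)
    n = len(classes)
    cs, ks = sorted(set(classes)), sorted(set(clusters))

    def H(counts):
        tot = sum(counts)
        return -sum((c / tot) * np.log2(c / tot) for c in counts if c)

    h_classes = H([classes.count(c) for c in cs])
    h_clusters = H([clusters.count(k) for k in ks])
    h_c_k = 0.0
    for k in ks:
        idx = [i for i in range(n) if clusters[i] == k]
        h_c_k += len(idx) / n * H([sum(classes[i] == c for i in idx) for c in cs])
    h_k_c = 0.0
    for c in cs:
        idx = [i for i in range(n) if classes[i] == c]
        h_k_c += len(idx) / n * H([sum(clusters[i] == k for i in idx) for k in ks])
    h = 1.0 if h_classes == 0 else 1 - h_c_k / h_classes
    comp = 1.0 if h_clusters == 0 else 1 - h_k_c / h_clusters
    v = 0.0 if h + comp == 0 else 2 * h * comp / (h + comp)
    return h, comp, v


class TestClusterHDBSCAN:
    def test_two_blobs_recovered(self):
        X, truth = blobs([(0, 0), (10, 10)], 500, 0.1)
        res = cluster_hdbscan(X)
        assert res.n_clusters == 2
        assert overlap(truth, res.labels).v_measure >= 0.99

    def test_single_blob_not_split(self):
        X, _ = blobs([(0, 0)], 400, 0.5)
        assert cluster_hdbscan(X).n_clusters <= 1

    def test_one_percent_rule(self):
        X, _ = blobs([(0, 0)], 1000, 0.5)
        assert cluster_hdbscan(X).params["min_cluster_size"] == 10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cluster_hdbscan(np.zeros((10, 2)), min_cluster_frac=0.01)


class TestClusterKMeans:
    def test_k_one_single_label(self):
        X, _ = blobs([(0, 0)], 50, 1.0)
        assert len(set(cluster_kmeans(X, 1).labels.tolist())) == 1

    def test_two_blobs_full_agreement(self):
        X, truth = blobs([(0, 0), (10, 10)], 100, 0.3)
        res = cluster_kmeans(X, 2, seed=0)
        assert overlap(truth, res.labels).v_measure == pytest.approx(1.0)

    def test_k_equals_n_zero_inertia(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 2))
        res = cluster_kmeans(X, 8, seed=0)
        assert len(set(res.labels.tolist())) == 8

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            cluster_kmeans(np.zeros((3, 2)), 5)


class TestClusterGMM:
    def test_single_component_mean_is_sample_mean(self):
        rng = np.random.default_rng(0)
        F = rng.normal(2.0, 1.0, size=(200, 3))
        res = cluster_gmm(F, 1, seed=0)
        assert np.abs(res.means_[0] - F.mean(axis=0)).max() < 1e-8

    def test_two_gaussians_means_recovered(self):
        rng = np.random.default_rng(1)
        F = np.vstack([rng.normal(0.0, 1.0, (1000, 2)),
                       rng.normal(8.0, 1.0, (1000, 2))])
        res = cluster_gmm(F, 2, seed=0)
        means = res.means_[np.argsort(res.means_[:, 0])]
        assert np.abs(means[0] - 0.0).max() < 0.1
        assert np.abs(means[1] - 8.0).max() < 0.1

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        F = rng.normal(size=(120, 2))
        a = cluster_gmm(F, 2, seed=3)
        b = cluster_gmm(F, 2, seed=3)
        assert np.array_equal(a.labels, b.labels)


class TestPcaReduce:
    def test_shape_contract_truncates_to_rank(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 200))
        assert pca_reduce(X, 100).shape == (30, 30)
        assert pca_reduce(X, 10).shape == (30, 10)

    def test_rank_one_input_single_informative_column(self):
        X = np.outer(np.linspace(0, 1, 20), np.ones(50))
        Z = pca_reduce(X, 5)
        assert Z[:, 0].var() > 0
        assert np.abs(Z[:, 1:]).max() < 1e-8

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 7))
        Z = pca_reduce(X, 4)
        C = np.cov(X - X.mean(axis=0), rowvar=False)
        vals, vecs = np.linalg.eigh(C)
        ref = (X - X.mean(axis=0)) @ vecs[:, np.argsort(vals)[::-1][:4]]
        for j in range(4):
            assert min(np.abs(Z[:, j] - ref[:, j]).max(),
                       np.abs(Z[:, j] + ref[:, j]).max()) <= 1e-8


class TestHopkins:
    def test_duplicated_points_give_zero(self):
        X = np.repeat(np.random.default_rng(0).normal(size=(20, 2)), 2, axis=0)
        assert hopkins(X, seed=0).statistic == 0.0

    def test_injected_reference_hand_evaluation(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        Y = np.array([[5.0, 0.5]])
        res = hopkins(X, m=1, seed=0, y_sample=Y)
        # u = distance from (5, 0.5) to nearest corner = sqrt(25.25);
        # w = the sampled corner's nearest neighbor = 1 (vertical pair)
        assert res.u[0] == pytest.approx(np.sqrt(25.25), abs=1e-12)
        assert res.w[0] == pytest.approx(1.0, abs=1e-12)
        expected = 1.0 / (25.25 + 1.0)
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_uniform_cloud_sits_near_half(self):
        stats = [hopkins(np.random.default_rng(100 + s).uniform(size=(300, 2)),
                         m=40, seed=s).statistic for s in range(60)]
        assert 0.35 <= np.mean(stats) <= 0.65

    def test_two_tight_blobs_strongly_clustered(self):
        X, _ = blobs([(0, 0), (10, 10)], 200, 0.1, seed=1)
        assert hopkins(X, m=50, seed=0).statistic < 0.1

    def test_statistic_decreases_with_separation(self):
        means = []
        for sep in (2.0, 5.0, 10.0):
            X, _ = blobs([(0, 0), (sep, 0)], 200, 1.0, seed=2)
            means.append(np.mean([hopkins(X, m=50, seed=s).statistic
                                  for s in range(15)]))
        assert means[0] > means[1] > means[2]

    def test_statistic_identity_invariant(self):
        res = hopkins(np.random.default_rng(0).normal(size=(50, 2)), seed=1)
        d = res.d
        expected = np.sum(res.w ** d) / (np.sum(res.u ** d) + np.sum(res.w ** d))
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_high_dimensional_falls_back_to_box(self):
        X = np.random.default_rng(0).normal(size=(40, 5))
        assert hopkins(X, seed=0).sampling == "bounding_box"


class TestSilhouette:
    def test_degenerate_two_point_clusters_score_one(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        res = silhouette(X, ["A", "A", "B", "B"])
        assert np.allclose(res.a, 0.0)
        assert np.allclose(res.b, 10.0)
        assert res.score == pytest.approx(1.0)

    def test_brute_force_value(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        res = silhouette(X, ["A", "A", "B", "B"])
        assert res.score == pytest.approx(0.899749373433584, abs=1e-12)

    def test_adversarial_labels_negative(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        assert silhouette(X, ["A", "B", "A", "B"]).score < 0

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = rng.integers(6, 15)
            X = rng.normal(size=(n, 2))
            labels = rng.integers(0, 3, n)
            if len(set(labels.tolist())) < 2:
                continue
            mine = silhouette(X, labels).coefficients
            assert np.abs(mine - brute_silhouette(X, labels)).max() <= 1e-10

    def test_isometry_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        labels = rng.integers(0, 3, 30)
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = X @ R.T + np.array([5.0, -2.0])
        assert silhouette(moved, labels).score == pytest.approx(
            silhouette(X, labels).score, abs=1e-10)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((4, 1)), ["A"] * 4)


class TestOverlap:
    def test_identical_labelings_perfect(self):
        res = overlap([1, 2, 3, 1], [1, 2, 3, 1])
        assert (res.homogeneity, res.completeness, res.v_measure) == (1, 1, 1)

    def test_hand_computed_contingency(self):
        res = overlap(["A", "A", "B", "B"], [1, 1, 2, 3])
        assert res.homogeneity == pytest.approx(1.0, abs=1e-12)
        assert res.completeness == pytest.approx(2 / 3, abs=1e-12)
        assert res.v_measure == pytest.approx(0.8, abs=1e-12)

    def test_single_cluster_over_two_classes(self):
        res = overlap(["A", "A", "B", "B"], [0, 0, 0, 0])
        assert res.homogeneity == 0.0
        assert res.completeness == 1.0

    def test_matches_brute_force_and_sklearn(self):
        from sklearn.metrics import homogeneity_completeness_v_measure

        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 25)
            classes = rng.integers(0, 4, n)
            clusters = rng.integers(0, 4, n)
            res = overlap(classes, clusters)
            bh, bc, bv = brute_overlap(classes, clusters)
            assert abs(res.homogeneity - bh) <= 1e-10
            assert abs(res.completeness - bc) <= 1e-10
            assert abs(res.v_measure - bv) <= 1e-10
            sh, sc, sv = homogeneity_completeness_v_measure(classes, clusters)
            assert abs(res.homogeneity - sh) <= 1e-8
            assert abs(res.v_measure - sv) <= 1e-8

    def test_symmetry_homogeneity_completeness(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 5, 40)
        assert overlap(a, b).homogeneity == pytest.approx(
            overlap(b, a).completeness, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlap([1, 2], [1, 2, 3])


class TestPermutationNull:
    def test_identical_labelings_minimal_p(self):
        classes = [0, 0, 1, 1, 2, 2] * 5
        chance, p = permutation_null_vmeasure(classes, classes, n_perm=200, seed=0)
        assert p == pytest.approx(1 / 201)

    def test_independent_labels_near_zero_chance_v(self):
        rng = np.random.default_rng(0)
        classes = rng.integers(0, 2, 1000)
        clusters = rng.integers(0, 2, 1000)
        chance, _ = permutation_null_vmeasure(classes, clusters, n_perm=50, seed=1)
        assert chance < 0.01

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_null_vmeasure([0, 1], [0, 1], n_perm=0)


class TestKruskal:
    def test_identical_groups_zero_h(self):
        res = compare_silhouette_kruskal([1.0, 2.0], [1.0, 2.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_rank_small_example(self):
        res = compare_silhouette_kruskal([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == pytest.approx(2.4, abs=1e-10)
        assert res.dof == 1

    def test_fully_separated_groups_of_five(self):
        res = compare_silhouette_kruskal(list(range(1, 6)), list(range(6, 11)))
        assert res.statistic == pytest.approx(6.818181818181818, abs=1e-10)

    def test_all_identical_values_h_zero_p_one(self):
        res = compare_silhouette_kruskal([1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_hand_rank_oracle_random(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            groups = [rng.normal(size=rng.integers(3, 8)) for _ in range(3)]
            res = compare_silhouette_kruskal(*groups)
            assert res.statistic == pytest.approx(_kw_hand(groups), abs=1e-10)


def _kw_hand(groups):
    allv = np.concatenate(groups)
    order = np.argsort(allv, kind="mergesort")
    ranks = np.empty(len(allv))
    ranks[order] = np.arange(1, len(allv) + 1)
    for v in np.unique(allv):
        m = allv == v
        ranks[m] = ranks[m].mean()
    N = len(allv)
    idx, H = 0, 0.0
    for g in groups:
        r = ranks[idx:idx + len(g)]
        idx += len(g)
        H += len(g) * (r.mean() - (N + 1) / 2) ** 2
    H *= 12 / (N * (N + 1))
    ties = np.array([np.sum(allv == v) for v in np.unique(allv)])
    return H / (1 - np.sum(ties ** 3 - ties) / (N ** 3 - N))


class TestDropNoise:
    def test_noise_points_masked(self):
        cl = ClusterLabels(labels=np.array([0, -1, 1, -1]), method="hdbscan",
                           params={}, noise_value=-1)
        truth, labs = drop_noise(np.array(["a", "b", "c", "d"]), cl)
        assert list(truth) == ["a", "c"] and list(labs) == [0, 1]
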