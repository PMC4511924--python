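"""Distance, pseudo-F, model selection, PCA and dendrogram contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

from tetrasig import cluster
from tetrasig.cluster import (
    DistanceMatrix,
    PerfectSeparationError,
    cluster_similarity_matrix,
    cosine_distance,
    distance_matrix,
    pca_profiles,
    pseudo_f,
    select_k,
    station_report,
)


class TestCosineDistance:
    def test_identical_vectors_zero(self):
        v = np.array([0.2, 0.3, 0.5])
        assert cosine_distance(v, v) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_vectors_one(self):
        u = np.zeros(8); u[0] = 1.0
        v = np.zeros(8); v[1] = 1.0
        assert cosine_distance(u, v) == pytest.approx(1.0)

    def test_closed_form_value(self):
        assert cosine_distance([1.0, 0.0], [1.0, 1.0]) == pytest.approx(1 - 1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance([0.0, 0.0], [1.0, 0.0])


class TestDistanceMatrix:
    def test_identical_rows_give_zero_matrix(self):
        m = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], index=["a", "b"])
        np.testing.assert_allclose(distance_matrix(m).values, 0.0, atol=1e-12)

    def test_matches_pairwise_brute_force(self, rng):
        """Matrix equals element-by-element cosine_distance recomputation."""
        X = pd.DataFrame(rng.random((10, 16)) + 1e-3)
        D = distance_matrix(X).values
        for i in range(10):
            for j in range(10):
                expected = 0.0 if i == j else cosine_distance(X.iloc[i], X.iloc[j])
                assert D[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(D, D.T)
        assert (D >= 0).all() and (D <= 1).all()

    def test_zero_row_rejected(self):
        m = pd.DataFrame([[1.0, 0.0], [0.0, 0.0]], index=["ok", "null"])
        with pytest.raises(ValueError, match="null"):
            distance_matrix(m)

    def test_planted_groups_separate(self, six_group_profiles, six_group_dataset):
        _, _, manifest = six_group_dataset
        D = distance_matrix(six_group_profiles).values
        labels = manifest.set_index("id").loc[six_group_profiles.index, "group"].to_numpy()
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        within = D[same].mean()
        between = D[~same & ~np.eye(len(D), dtype=bool)].mean()
        assert between > within


def brute_force_pseudo_f(X, labels):
    """Explicit centroid/sum-of-squares loops."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = len(X)
    grand = X.mean(axis=0)
    uniq = sorted(set(labels.tolist()))
    k = len(uniq)
    bgss = sum(
        (labels == u).sum() * float(((X[labels == u].mean(axis=0) - grand) ** 2).sum())
        for u in uniq
    )
    wgss = sum(
        float(((X[labels == u] - X[labels == u].mean(axis=0)) ** 2).sum()) for u in uniq
    )
    return (bgss / (k - 1)) / (wgss / (n - k))


class TestPseudoF:
    def test_hand_computed_value(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        assert pseudo_f(X, [0, 0, 1, 1]) == pytest.approx(200.0)

    def test_perfect_separation_signalled(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        with pytest.raises(PerfectSeparationError):
            pseudo_f(X, [0, 0, 1, 1])

    @pytest.mark.parametrize("bad_labels", [[0, 0, 0, 0], [0, 1, 2, 3]])
    def test_k_out_of_range_rejected(self, bad_labels):
        X = np.arange(8.0).reshape(4, 2)
        with pytest.raises(ValueError):
            pseudo_f(X, bad_labels)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_brute_force_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 30))
        X = rng.normal(size=(n, int(rng.integers(2, 6))))
        k = int(rng.integers(2, min(5, n - 1) + 1))
        labels = rng.integers(k, size=n)
        if len(set(labels.tolist())) < 2:
            labels[0] = (labels[0] + 1) % k
        f = pseudo_f(X, labels)
        assert f == pytest.approx(brute_force_pseudo_f(X, labels), rel=1e-9)
        assert f == pytest.approx(calinski_harabasz_score(X, labels), rel=1e-9)

    def test_true_labels_beat_random_labels(self, rng):
        centers = np.array([[0, 0], [20, 0], [0, 20]])
        truth = np.repeat([0, 1, 2], 20)
        X = centers[truth] + rng.normal(size=(60, 2))
        shuffled = rng.permutation(truth)
        assert pseudo_f(X, truth) > pseudo_f(X, shuffled)


class TestSelectK:
    def test_two_separated_blobs(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (30, 2)), rng.normal(20, 0.5, (30, 2))])
        res = select_k(X, (2, 6), restarts=10, seed=0)
        assert res.k == 2
        assert set(res.trace) == {2, 3, 4, 5, 6}

    def test_single_candidate(self, rng):
        X = rng.normal(size=(3, 2))
        assert select_k(X, (2, 2), restarts=5, seed=0).k == 2

    def test_invalid_range_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            select_k(X, (2, 5), restarts=5, seed=0)
        with pytest.raises(ValueError):
            select_k(X, (1, 3), restarts=5, seed=0)

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(30, 4))
        r1 = select_k(X, (2, 4), restarts=10, seed=7)
        r2 = select_k(X, (2, 4), restarts=10, seed=7)
        assert r1.k == r2.k
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.trace == r2.trace

    def test_recovers_planted_three_groups(self):
        from tetrasig import composition, simulate

        specs = tuple(
            simulate.GroupSpec(f"g{i}", 10, (400, 400), 0.45, 2.0, seed=40 + i)
            for i in range(3)
        )
        records, manifest = simulate.simulate_dataset(
            simulate.Scenario(groups=specs, master_seed=11)
        )
        prof = composition.profile_matrix([(r.id, r.sequence) for r in records])
        res = select_k(prof, (2, 6), restarts=20, seed=0)
        assert res.k == 3
        truth = manifest.set_index("id").loc[list(res.ids), "group"]
        assert adjusted_rand_score(truth, res.labels) == pytest.approx(1.0)


class TestPCA:
    def test_duplicated_rows_give_duplicated_scores(self, rng):
        X = rng.normal(size=(6, 8))
        X = np.vstack([X, X[0]])
        scores = pca_profiles(X, n_components=3).scores
        np.testing.assert_allclose(scores[0], scores[-1], atol=1e-9)

    def test_rank_deficiency_zero_variance_beyond_rank(self, rng):
        basis = rng.normal(size=(2, 10))
        coeff = rng.normal(size=(12, 2))
        X = coeff @ basis
        res = pca_profiles(X, n_components=3)
        assert res.explained_variance[2] == pytest.approx(0.0, abs=1e-9)
        assert np.all(np.diff(res.explained_variance) <= 1e-12)

    def test_rank3_scores_preserve_euclidean_distances(self, rng):
        basis = rng.normal(size=(3, 20))
        X = rng.normal(size=(15, 3)) @ basis
        scores = pca_profiles(X, n_components=3).scores
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(scores), pdist(X), atol=1e-8)

    def test_row_permutation_invariance_up_to_sign(self, rng):
        X = rng.normal(size=(10, 6))
        perm = rng.permutation(10)
        s1 = pca_profiles(X, n_components=3).scores
        s2 = pca_profiles(X[perm], n_components=3).scores
        for c in range(3):
            col = s2[np.argsort(perm), c]
            assert np.allclose(col, s1[:, c], atol=1e-8) or np.allclose(
                col, -s1[:, c], atol=1e-8
            )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pca_profiles(np.ones((5, 4)), n_components=3)


def brute_force_average_linkage(D):
    """Naive agglomeration: merge the pair with minimal mean pairwise distance."""
    clusters = {i: [i] for i in range(len(D))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters.pop(b)
    return sorted(heights)


class TestClusterSimilarityMatrix:
    def _dm(self, rng, n=8):
        X = rng.random((n, 12)) + 1e-3
        return distance_matrix(pd.DataFrame(X, index=[f"s{i}" for i in range(n)]))

    def test_identical_profile_rows_merge_first_at_zero(self, rng):
        X = rng.random((4, 10)) + 1e-3
        X[1] = X[0]
        dm = distance_matrix(pd.DataFrame(X, index=list("abcd")))
        Z, _ = cluster_similarity_matrix(dm)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_merge_heights_match_brute_force(self, seed):
        """Average-linkage heights equal an explicit agglomeration loop."""
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(seed)
        dm = self._dm(rng)
        S = 1.0 - dm.values
        D = squareform(pdist(S, metric="correlation"))
        Z, _ = cluster_similarity_matrix(dm)
        np.testing.assert_allclose(
            sorted(Z[:, 2]), brute_force_average_linkage(D), rtol=1e-9, atol=1e-12
        )

    def test_leaf_order_stable(self, rng):
        dm = self._dm(rng)
        _, order1 = cluster_similarity_matrix(dm)
        _, order2 = cluster_similarity_matrix(dm)
        assert order1 == order2
        assert sorted(order1) == sorted(dm.ids)

    def test_constant_rows_rejected(self):
        dm = DistanceMatrix(ids=("a", "b", "c"), values=np.zeros((3, 3)))
        with pytest.raises(ValueError, match="constant"):
            cluster_similarity_matrix(dm)


class TestStationReport:
    def _gc_table(self, spec):
        rows = []
        for station, (n, n_high) in spec.items():
            for i in range(n):
                rows.append({
                    "id": f"{station}_{i}",
                    "gc": 0.5 if i < n_high else 0.4,
                    "gc_class": "high" if i < n_high else "low",
                })
        gc = pd.DataFrame(rows)
        stations = {r["id"]: r["id"].rsplit("_", 1)[0] for r in rows}
        return gc, stations

    def test_survey_pattern(self):
        gc, stations = self._gc_table({"Malden": (20, 5), "Flint": (7, 0)})
        rep = station_report(gc, stations).set_index("station")
        assert rep.loc["Malden", "pct_high"] == 25.0
        assert rep.loc["Malden", "n"] == 20
        assert rep.loc["Flint", "pct_high"] == 0.0

    def test_overall_is_pooled_ratio_not_mean_of_stations(self):
        gc, stations = self._gc_table({"a": (10, 5), "b": (90, 9)})
        rep = station_report(gc, stations).set_index("station")
        # pooled 14/100 = 14.0; mean of station percentages would be 30.0
        assert rep.loc["overall", "pct_high"] == 14.0

    def test_missing_id_rejected(self):
        gc, stations = self._gc_table({"a": (4, 1)})
        del stations["a_0"]
        with pytest.raises(ValueError, match="missing"):
            station_report(gc, stations)
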