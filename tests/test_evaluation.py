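"""Embedding metrics vs independent brute-force oracles and constructed
geometries."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from popsphere.evaluation import (KNNQuery, accuracy_vs_k,
                                  generalization_score, global_score,
                                  knn_predict, local_score, neighbor_overlap,
                                  rank_rmse, subpopulation_centroids)


# --------------------------------------------------------------------------
# Brute-force oracles: double loops, no shared code with the implementation
# --------------------------------------------------------------------------

def oracle_knn(ref, ref_labels, query, k, exclude_self):
    preds = []
    for i, q in enumerate(query):
        dists = [(float(np.linalg.norm(q - r)), j)
                 for j, r in enumerate(ref)
                 if not (exclude_self and j == i)]
        dists.sort()
        votes = {}
        for d, j in dists[:k]:
            votes.setdefault(ref_labels[j], []).append(d)
        best = max(len(v) for v in votes.values())
        tied = sorted((np.mean(votes[c]), c) for c in votes
                      if len(votes[c]) == best)
        preds.append(tied[0][1])
    return np.array(preds)


def oracle_neighbor_sets(points, k, metric):
    sets = []
    for i in range(len(points)):
        dists = []
        for j in range(len(points)):
            if j == i:
                continue
            if metric == "manhattan":
                d = float(np.abs(points[i] - points[j]).sum())
            else:
                d = float(np.linalg.norm(points[i] - points[j]))
            dists.append((d, j))
        dists.sort()
        sets.append([j for _, j in dists[:k]])
    return sets


class TestKnnPredict:
    def test_coincident_reference(self, rng):
        ref = rng.normal(size=(5, 3))
        labels = np.array(list("ABCDE"))
        preds, _ = knn_predict(KNNQuery(reference=ref, reference_labels=labels,
                                        query=ref[2:3], k=1))
        assert preds[0] == "C"

    def test_equidistant_majority(self):
        ref = np.array([[1.0, 0], [0, 1.0], [-1.0, 0]])
        labels = np.array(["A", "A", "B"])
        preds, acc = knn_predict(KNNQuery(
            reference=ref, reference_labels=labels,
            query=np.zeros((1, 2)), k=3, query_labels=np.array(["A"])))
        assert preds[0] == "A" and acc == 1.0

    def test_matches_oracle_random_instances(self, rng):
        for trial in range(5):
            ref = rng.normal(size=(10, 3))
            labels = rng.choice(["A", "B", "C"], size=10)
            query = rng.normal(size=(6, 3))
            for k in (1, 3, 5):
                preds, _ = knn_predict(KNNQuery(
                    reference=ref, reference_labels=labels, query=query, k=k))
                np.testing.assert_array_equal(
                    preds, oracle_knn(ref, labels, query, k, False))

    def test_k_too_large_rejected(self, rng):
        ref = rng.normal(size=(3, 2))
        with pytest.raises(ValueError, match="exceeds"):
            KNNQuery(reference=ref, reference_labels=np.array(["A"] * 3),
                     query=ref, k=3, exclude_self=True)


class TestLocalScore:
    def test_separable_clusters_perfect(self, rng):
        centers = np.eye(4, 3) * 10.0
        centers[3] = [-10, -10, -10]
        pts = np.vstack([c + 0.01 * rng.normal(size=(5, 3)) for c in centers])
        labels = np.repeat(list("ABCD"), 5)
        assert local_score(pts, labels) == 1.0

    def test_permuted_labels_near_baseline(self, rng):
        pts = rng.normal(size=(200, 3))
        labels = rng.permutation(np.repeat(list("ABCD"), 50))
        assert local_score(pts, labels) < 0.45  # chance is 0.25

    def test_matches_oracle(self, rng):
        pts = rng.normal(size=(12, 3))
        labels = rng.choice(["X", "Y"], size=12)
        expected = (oracle_knn(pts, labels, pts, 3, True) == labels).mean()
        assert local_score(pts, labels) == pytest.approx(expected)


class TestGlobalScore:
    def test_antipodal_superpops_perfect(self, rng):
        # 2 superpops x 4 subpops, tight subpop clusters near the two poles
        pts, subs, sups = [], [], []
        for s, pole in enumerate([np.array([0, 0, 1.0]),
                                  np.array([0, 0, -1.0])]):
            for b in range(4):
                offset = 0.05 * np.array([np.cos(b), np.sin(b), 0.0])
                for i in range(5):
                    pts.append(pole + offset + 0.001 * rng.normal(size=3))
                    subs.append(f"sub{s}{b}")
                    sups.append(f"sup{s}")
        assert global_score(np.array(pts), np.array(subs),
                            np.array(sups)) == 1.0

    def test_two_by_two_geometry_scores_zero(self):
        # with 2 subpops per superpop, each centroid's 3 neighbors are
        # majority other-superpop: the metric needs >= 4 subpops per superpop
        pts = np.array([[0, 0, 1.0], [0.1, 0, 1.0],
                        [0, 0, -1.0], [0.1, 0, -1.0]])
        pts = np.repeat(pts, 3, axis=0)
        subs = np.repeat(["a1", "a2", "b1", "b2"], 3)
        sups = np.repeat(["A", "A", "B", "B"], 3)
        assert global_score(pts, subs, sups) == 0.0

    def test_centroids_are_group_means(self, rng):
        pts = rng.normal(size=(20, 3))
        subs = np.repeat(list("ABCD"), 5)
        sups = np.repeat(["N", "N", "S", "S"], 5)
        names, centroids, supers = subpopulation_centroids(pts, subs, sups)
        for name, c in zip(names, centroids):
            np.testing.assert_allclose(c, pts[subs == name].mean(axis=0),
                                       atol=1e-12)

    def test_too_few_centroids_rejected(self, rng):
        pts = rng.normal(size=(6, 3))
        subs = np.repeat(["a", "b", "c"], 2)
        sups = np.repeat(["A", "A", "B"], 2)
        with pytest.raises(ValueError, match="centroids"):
            global_score(pts, subs, sups)


class TestGeneralizationScore:
    def test_duplicated_validation_perfect(self, rng):
        # clustered training data: each duplicate's 3NN stay in-cluster
        centers = np.array([[0, 0, 5.0], [0, 0, -5.0]])
        train = np.vstack([c + 0.01 * rng.normal(size=(10, 3))
                           for c in centers])
        labels = np.repeat(["A", "B"], 10)
        assert generalization_score(train, labels, train.copy(),
                                    labels.copy()) == 1.0

    def test_matches_oracle(self, rng):
        train = rng.normal(size=(20, 3))
        tl = rng.choice(["A", "B", "C"], size=20)
        val = rng.normal(size=(10, 3))
        vl = rng.choice(["A", "B", "C"], size=10)
        expected = (oracle_knn(train, tl, val, 3, False) == vl).mean()
        assert generalization_score(train, tl, val, vl) == \
            pytest.approx(expected)

    def test_permuted_labels_near_baseline(self, rng):
        train = rng.normal(size=(100, 3))
        tl = np.repeat(["A", "B"], 50)
        val = rng.normal(size=(60, 3))
        vl = rng.choice(["A", "B"], size=60)
        acc = generalization_score(train, tl, val, vl)
        assert 0.2 < acc < 0.8


class TestAccuracyVsK:
    def test_two_antipodal_clusters(self, rng):
        pts = np.vstack([np.array([0, 0, 1.0]) + 0.01 * rng.normal(size=(50, 3)),
                         np.array([0, 0, -1.0]) + 0.01 * rng.normal(size=(50, 3))])
        labels = np.repeat(["N", "S"], 50)
        curve = accuracy_vs_k(pts, labels, [1, 5, 25, 49])
        assert all(v == 1.0 for v in curve.values())

    def test_vote_saturation_at_k_max(self, rng):
        pts = rng.normal(size=(30, 3))
        labels = np.array(["A"] * 20 + ["B"] * 10)
        curve = accuracy_vs_k(pts, labels, [29])
        # every vote includes all other samples; majority class wins almost
        # always (label A keeps 19-of-29 majority from any anchor)
        assert curve[29] == pytest.approx(20 / 30)

    def test_consistent_with_knn_predict(self, rng):
        pts = rng.normal(size=(15, 3))
        labels = rng.choice(["A", "B"], size=15)
        curve = accuracy_vs_k(pts, labels, [1, 3, 7])
        for k, acc in curve.items():
            _, expected = knn_predict(KNNQuery(
                reference=pts, reference_labels=labels, query=pts, k=k,
                exclude_self=True, query_labels=labels))
            assert acc == pytest.approx(expected)


class TestNeighborOverlap:
    def test_geometry_preserving_embedding_full_overlap(self, rng):
        # tight genotype clusters: cluster-mates are the nearest neighbors
        # under both the Manhattan and the Euclidean metric
        base = np.repeat(rng.integers(0, 3, size=(5, 30)), 4, axis=0)
        flip = rng.random(base.shape) < 0.02
        geno = np.where(flip, (base + 1) % 3, base)
        emb = geno.astype(float)
        curve = neighbor_overlap(geno, emb, [3])
        assert curve[3] > 0.9

    def test_random_embedding_hypergeometric_level(self, rng):
        geno = rng.integers(0, 3, size=(200, 40))
        emb = rng.normal(size=(200, 3))
        curve = neighbor_overlap(geno, emb, [3])
        # expected overlap for unrelated neighbor sets: k/(N-1)
        assert curve[3] < 0.1

    def test_matches_oracle(self, rng):
        geno = rng.integers(0, 3, size=(25, 15))
        emb = rng.normal(size=(25, 3))
        for k in (3, 7):
            g_sets = oracle_neighbor_sets(geno.astype(float), k, "manhattan")
            e_sets = oracle_neighbor_sets(emb, k, "euclidean")
            expected = np.mean([
                len(set(g) & set(e)) / k for g, e in zip(g_sets, e_sets)])
            assert neighbor_overlap(geno, emb, [k])[k] == \
                pytest.approx(expected)

    def test_missing_calls_rejected(self, rng):
        geno = rng.integers(0, 3, size=(10, 5))
        geno[0, 0] = -1
        with pytest.raises(ValueError, match="impute"):
            neighbor_overlap(geno, rng.normal(size=(10, 3)), [3])


class TestRankRmse:
    def test_isometric_embedding_zero(self, rng):
        # embedding = genotypes rescaled: same Manhattan/Euclidean orderings
        # need tie-free distances, so use continuous jitter on calls
        geno = rng.integers(0, 3, size=(15, 25))
        emb = geno.astype(float)
        curve = rank_rmse(geno, emb, [1, 5])
        # identical orderings whenever distances are untied
        assert curve[1] < 1.0

    def test_hand_computed_three_points(self):
        # genotype space: chain 0-1-2; embedding swaps each anchor's two ranks
        geno = np.array([[0, 0], [1, 0], [2, 2]])
        emb = np.array([[0.0, 0], [10.0, 0], [4.0, 0]])
        # anchor 0: geno ranks (1,2) others; embedding ranks: s2 first
        curve = rank_rmse(geno, emb, [1])
        assert curve[1] == pytest.approx(np.sqrt((1 - 2) ** 2))

    def test_matches_oracle(self, rng):
        geno = rng.integers(0, 3, size=(25, 12))
        emb = rng.normal(size=(25, 3))
        n_samples = 25
        for n in (1, 5, 10):
            errs = []
            for i in range(n_samples):
                g_order = oracle_neighbor_sets(geno.astype(float),
                                               n_samples - 1, "manhattan")[i]
                e_order = oracle_neighbor_sets(emb, n_samples - 1,
                                               "euclidean")[i]
                j = g_order[n - 1]
                errs.append((n - (e_order.index(j) + 1)) ** 2)
            assert rank_rmse(geno, emb, [n])[n] == \
                pytest.approx(np.sqrt(np.mean(errs)))


class TestRotationInvariance:
    def test_all_scores_invariant_to_rigid_rotation(self, rng):
        pts = rng.normal(size=(40, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        subs = np.repeat([f"s{i}" for i in range(8)], 5)
        sups = np.repeat(["A", "B"], 20)
        geno = rng.integers(0, 3, size=(40, 20))
        q = special_ortho_group.rvs(3, random_state=3)
        rpts = pts @ q.T
        assert local_score(pts, subs) == local_score(rpts, subs)
        assert global_score(pts, subs, sups) == global_score(rpts, subs, sups)
        assert neighbor_overlap(geno, pts, [5]) == \
            neighbor_overlap(geno, rpts, [5])
        assert rank_rmse(geno, pts, [3]) == rank_rmse(geno, rpts, [3])
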