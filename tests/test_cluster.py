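import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import _oracles
from idrsig.cluster import (
    ClusterAssignment,
    Dendrogram,
    annotate_query,
    average_linkage,
    cluster_centroids,
    cluster_signatures,
    composition_kmeans,
    composition_zscores,
    compute_item_weights,
    cut_clusters,
    distance_matrix,
    pairwise_similarity_distance,
    similarity_control,
    uncentered_correlation_distance,
    _subtree_leaves,
)
from idrsig.synth import gen_root_idr


class TestUncenteredDistance:
    def test_self_distance_zero(self):
        x = np.array([1.0, -2.0, 3.0])
        assert uncentered_correlation_distance(x, x) == pytest.approx(0.0)

    def test_opposite_is_two(self):
        x = np.array([1.0, 2.0])
        assert uncentered_correlation_distance(x, -x) == pytest.approx(2.0)

    def test_orthogonal_is_one(self):
        assert uncentered_correlation_distance(
            np.array([1.0, 0.0]), np.array([0.0, 1.0])
        ) == pytest.approx(1.0)

    def test_zero_norm_errors(self):
        with pytest.raises(ValueError, match="norm"):
            uncentered_correlation_distance(
                np.array([0.0, 0.0]), np.array([1.0, 1.0])
            )

    def test_pairwise_complete_missing(self):
        x = np.array([1.0, np.nan, 2.0])
        y = np.array([1.0, 5.0, 2.0])
        assert uncentered_correlation_distance(x, y) == pytest.approx(0.0)

    def test_weights_change_result(self):
        x = np.array([1.0, 0.0, 1.0])
        y = np.array([1.0, 1.0, 0.0])
        d1 = uncentered_correlation_distance(x, y)
        d2 = uncentered_correlation_distance(x, y, w=np.array([10.0, 1.0, 1.0]))
        assert d2 < d1

    def test_matrix_matches_pairwise_loop(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 20))
        X[rng.random(size=X.shape) < 0.1] = np.nan
        D = distance_matrix(X)
        for i in range(12):
            for j in range(12):
                if i == j:
                    continue
                assert D[i, j] == pytest.approx(
                    uncentered_correlation_distance(X[i], X[j]), abs=1e-10
                )


class TestItemWeights:
    def test_all_far_apart(self):
        X = np.eye(5) * 10  # mutually orthogonal -> distance 1 >= cutoff
        w = compute_item_weights(X, cutoff=0.8)
        assert np.allclose(w, 1.0)

    def test_duplicate_pair_halved(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        w = compute_item_weights(X, cutoff=0.8, exponent=1.0)
        assert w[0] == pytest.approx(0.5)
        assert w[1] == pytest.approx(0.5)
        assert w[2] == pytest.approx(1.0)

    def test_always_positive(self):
        rng = np.random.default_rng(1)
        w = compute_item_weights(rng.normal(size=(8, 5)))
        assert np.all(w > 0)


class TestAverageLinkage:
    def test_two_items(self):
        dend = average_linkage(np.array([[0.0, 0.7], [0.7, 0.0]]))
        assert dend.merges.shape == (1, 4)
        assert dend.merges[0, 2] == pytest.approx(0.7)

    def test_three_item_hand_example(self):
        D = np.array(
            [[0.0, 1.0, 4.0], [1.0, 0.0, 4.0], [4.0, 4.0, 0.0]]
        )
        dend = average_linkage(D)
        assert dend.merges[0, 2] == pytest.approx(1.0)
        assert {int(dend.merges[0, 0]), int(dend.merges[0, 1])} == {0, 1}
        assert dend.merges[1, 2] == pytest.approx(4.0)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_reference(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = 12
        D = rng.uniform(0.1, 2.0, size=(n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        dend = average_linkage(D)
        ours = []
        for row_idx, row in enumerate(dend.merges):
            a = frozenset(_subtree_leaves(dend, int(row[0])))
            b = frozenset(_subtree_leaves(dend, int(row[1])))
            ours.append((a, b, row[2]))
        brute = _oracles.upgma_brute(D.tolist())
        for (a1, b1, h1), (a2, b2, h2) in zip(ours, brute):
            assert {a1, b1} == {a2, b2}
            assert h1 == pytest.approx(h2)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        n = 10
        D = rng.uniform(0.1, 2.0, size=(n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = [f"i{k}" for k in range(n)]
        perm = rng.permutation(n)
        Dp = D[np.ix_(perm, perm)]
        a1 = cut_clusters(average_linkage(D, labels), k=3, min_size=1)
        a2 = cut_clusters(
            average_linkage(Dp, [labels[p] for p in perm]), k=3, min_size=1
        )
        part1 = {frozenset(m) for m in a1.clusters.values()}
        part2 = {frozenset(m) for m in a2.clusters.values()}
        assert part1 == part2


class TestCutClusters:
    def _dend(self):
        D = np.array(
            [
                [0.0, 0.2, 1.0, 1.0],
                [0.2, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.3],
                [1.0, 1.0, 0.3, 0.0],
            ]
        )
        return average_linkage(D, labels=list("abcd"))

    def test_cut_above_root_single_cluster(self):
        a = cut_clusters(self._dend(), height=10.0, min_size=1)
        assert len(a.clusters) == 1
        assert sorted(a.clusters["C01"]) == ["a", "b", "c", "d"]

    def test_cut_below_all_merges_singletons(self):
        a = cut_clusters(self._dend(), height=0.1, min_size=2)
        assert a.clusters == {}
        assert all(lab == "" for lab in a.labels.values())

    def test_k_cut(self):
        a = cut_clusters(self._dend(), k=2, min_size=2)
        part = {frozenset(m) for m in a.clusters.values()}
        assert part == {frozenset("ab"), frozenset("cd")}

    def test_exactly_one_of_height_or_k(self):
        with pytest.raises(ValueError):
            cut_clusters(self._dend(), height=1.0, k=2)

    def test_planted_groups_recovered(self):
        rng = np.random.default_rng(11)
        centers = np.zeros((3, 30))
        centers[0, :10] = 4.0
        centers[1, 10:20] = 4.0
        centers[2, 20:] = 4.0
        X, truth = [], []
        for g in range(3):
            for _ in range(15):
                X.append(centers[g] + rng.normal(size=30))
                truth.append(g)
        mat = pd.DataFrame(
            X, index=[f"i{k}" for k in range(45)]
        )
        assignment, dend, _ = cluster_signatures(mat, k=3, min_size=5)
        pred = [assignment.labels[f"i{k}"] for k in range(45)]
        assert adjusted_rand_score(truth, pred) >= 0.9


class TestCompositionKmeans:
    def test_k_equals_n_zero_cost(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(6, 4)))
        assignment, costs = composition_kmeans(df, k=6, seed=0)
        assert costs[-1] == pytest.approx(0.0)
        assert len(set(assignment.labels.values())) == 6

    def test_two_separated_groups(self):
        rng = np.random.default_rng(3)
        X = np.vstack(
            [rng.normal(0, 0.1, size=(10, 5)), rng.normal(20, 0.1, size=(10, 5))]
        )
        df = pd.DataFrame(X, index=[f"i{k}" for k in range(20)])
        assignment, _ = composition_kmeans(df, k=2, seed=1)
        left = {assignment.labels[f"i{k}"] for k in range(10)}
        right = {assignment.labels[f"i{k}"] for k in range(10, 20)}
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_same_seed_identical(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(20, 5)))
        a1, _ = composition_kmeans(df, k=4, seed=9)
        a2, _ = composition_kmeans(df, k=4, seed=9)
        assert a1.labels == a2.labels

    def test_cost_non_increasing(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(40, 6)))
        _, costs = composition_kmeans(df, k=5, seed=2)
        assert all(a >= b - 1e-9 for a, b in zip(costs, costs[1:]))

    def test_zscore_standardization(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.uniform(size=(30, 4)))
        z = composition_zscores(df)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)


class TestSimilarityControl:
    def test_identical_pair_flagged(self):
        rng = np.random.default_rng(8)
        seqs = {f"i{k}": gen_root_idr(60, seed=800 + k) for k in range(12)}
        seqs["i1"] = seqs["i0"]  # duplicate inside cluster A
        labels = {f"i{k}": ("A" if k < 6 else "B") for k in range(12)}
        out = similarity_control(ClusterAssignment(labels=labels), seqs)
        assert out["A"] >= 100 * 2 / 6 - 1e-9
        assert out["B"] == pytest.approx(0.0)

    def test_singleton_cluster_zero(self):
        seqs = {"a": "ACDEFGHIKL", "b": "MNPQRSTVWY", "c": "ACDEFGHIKL"}
        labels = {"a": "X", "b": "Y", "c": "Y"}
        out = similarity_control(ClusterAssignment(labels=labels), seqs)
        assert out["X"] == 0.0

    def test_distance_properties(self):
        a = gen_root_idr(50, seed=1)
        b = gen_root_idr(50, seed=2)
        assert pairwise_similarity_distance(a, a) == pytest.approx(0.0)
        d = pairwise_similarity_distance(a, b)
        assert d > 0
        assert d == pytest.approx(pairwise_similarity_distance(b, a))


class TestAnnotateQuery:
    def _setup(self):
        rng = np.random.default_rng(12)
        centers = {"C01": np.zeros(20), "C02": np.zeros(20)}
        centers["C01"][:10] = 5.0
        centers["C02"][10:] = 5.0
        rows, labels = {}, {}
        k = 0
        for lab, c in centers.items():
            for _ in range(10):
                rows[f"i{k}"] = c + rng.normal(size=20)
                labels[f"i{k}"] = lab
                k += 1
        mat = pd.DataFrame.from_dict(rows, orient="index")
        return mat, ClusterAssignment(labels=labels)

    def test_centroid_query_distance_zero(self):
        mat, assignment = self._setup()
        centroids = cluster_centroids(mat, assignment)
        res = annotate_query(
            centroids.loc["C01"].to_numpy(), centroids, {"C01": ["T1"]}
        )
        assert res["cluster"] == "C01"
        assert res["distance"] == pytest.approx(0.0)
        assert res["transferred_terms"] == ["T1"]

    def test_orthogonal_query_ambiguous(self):
        centroids = pd.DataFrame(
            [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]], index=["C01", "C02"]
        )
        res = annotate_query(np.array([0.0, 0.0, 1.0]), centroids)
        assert res["ambiguous"]
        assert all(d == pytest.approx(1.0) for _, d in res["ranked"])

    def test_held_out_recovery(self):
        mat, assignment = self._setup()
        correct = 0
        for held in mat.index:
            rest = mat.drop(index=held)
            sub_assignment = ClusterAssignment(
                labels={k: v for k, v in assignment.labels.items() if k != held}
            )
            centroids = cluster_centroids(rest, sub_assignment)
            res = annotate_query(mat.loc[held].to_numpy(), centroids)
            correct += res["cluster"] == assignment.labels[held]
        assert correct / len(mat.index) >= 0.9
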