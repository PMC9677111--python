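"""SAHN clustering, cophenetics, tree comparison, k-means, PCA."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from germdiv.clustering import (compare_dendrograms, cophenetic, cut_tree,
                                hierarchical, kmeans_select, pca, upgma)
from germdiv.errors import ConfigError, DegenerateDataError
from germdiv.io import DistanceMatrix


def three_point() -> DistanceMatrix:
    return DistanceMatrix(("A", "B", "C"),
                          np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float))


def random_distance(rng, n, dim=3, prefix="L") -> DistanceMatrix:
    pts = rng.random((n, dim))
    return DistanceMatrix(tuple(f"{prefix}{i:02d}" for i in range(n)),
                          squareform(pdist(pts)))


class TestHierarchical:
    def test_upgma_worked_example(self):
        t = upgma(three_point())
        assert t.merges[0][:2] == (0, 1) and t.merges[0][2] == pytest.approx(1.0)
        assert t.merges[1][2] == pytest.approx(3.0)

    def test_two_leaves_merge_at_half_distance(self):
        d = DistanceMatrix(("A", "B"), np.array([[0, 5], [5, 0]], float))
        assert upgma(d).merges[0][2] == pytest.approx(2.5)

    def test_complete_linkage_joins_at_max(self):
        t = hierarchical(three_point(), "complete")
        assert t.merges[1][2] == pytest.approx(6.0)

    def test_equal_distances_equal_heights(self):
        d = DistanceMatrix(("A", "B", "C", "D"),
                           np.ones((4, 4)) - np.eye(4))
        for linkage in ("upgma", "complete", "ward"):
            heights = [m[2] for m in hierarchical(d, linkage).merges]
            if linkage == "upgma":
                assert heights == pytest.approx([0.5, 0.5, 0.5])
            if linkage == "complete":
                assert heights == pytest.approx([1.0, 1.0, 1.0])

    def test_unknown_linkage_rejected(self):
        with pytest.raises(ConfigError):
            hierarchical(three_point(), "single")

    def test_deterministic_under_ties(self):
        d = DistanceMatrix(("B", "A", "C"),
                           np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
        t1 = upgma(d)
        t2 = upgma(d)
        assert t1.merges == t2.merges
        # lexicographic tie-break merges (A, B) first
        left, right, _ = t1.merges[0]
        assert {t1.labels[left], t1.labels[right]} == {"A", "B"}

    def test_upgma_matches_scipy_average_linkage(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 11))
            dm = random_distance(rng, n)
            mine = cophenetic(upgma(dm)).values
            from scipy.cluster.hierarchy import cophenet, linkage
            ref = squareform(cophenet(linkage(squareform(dm.values), "average")))
            np.testing.assert_allclose(mine, ref, atol=1e-10)


class TestCophenetic:
    def test_two_leaf_tree(self):
        d = DistanceMatrix(("A", "B"), np.array([[0, 2], [2, 0]], float))
        c = cophenetic(upgma(d))
        assert c[("A", "B")] == pytest.approx(2.0)

    def test_worked_three_leaf(self):
        c = cophenetic(upgma(three_point()))
        assert c[("A", "B")] == pytest.approx(2.0)
        assert c[("A", "C")] == c[("B", "C")] == pytest.approx(6.0)

    def test_ultrametric_inequality_on_random_upgma_trees(self, rng):
        for _ in range(20):
            dm = random_distance(rng, 8)
            c = cophenetic(upgma(dm)).values
            for i, j, k in itertools.permutations(range(8), 3):
                assert max(c[i, k], c[j, k]) >= c[i, j] - 1e-12


class TestCutTree:
    def test_extremes(self):
        t = upgma(three_point())
        assert cut_tree(t, 1).k == 1
        assert cut_tree(t, 3).k == 3

    def test_worked_k2(self):
        part = cut_tree(upgma(three_point()), 2)
        assert part.assignments["A"] == part.assignments["B"]
        assert part.assignments["A"] != part.assignments["C"]

    def test_refinement_with_k(self, rng):
        dm = random_distance(rng, 10)
        t = upgma(dm)
        labels = list(dm.labels)
        prev = cut_tree(t, 1).labels_for(labels)
        for k in range(2, 11):
            cur = cut_tree(t, k).labels_for(labels)
            # cuts are nested: same cluster at k implies same at k-1
            for i in range(10):
                for j in range(10):
                    if cur[i] == cur[j]:
                        assert prev[i] == prev[j]
            prev = cur

    def test_out_of_range_k(self):
        with pytest.raises(ConfigError):
            cut_tree(upgma(three_point()), 4)


class TestCompareDendrograms:
    def test_identical_trees(self, rng):
        dm = random_distance(rng, 8)
        t = upgma(dm)
        comp = compare_dendrograms(t, t, (2, 6))
        assert comp.cophenetic_correlation == pytest.approx(1.0)
        assert (comp.cut_agreement["ari"] == 1.0).all()
        assert (comp.cut_agreement["n_mismatched"] == 0).all()

    def test_leaf_order_invariance(self, rng):
        dm = random_distance(rng, 8)
        perm = rng.permutation(8)
        dm2 = dm.reorder([dm.labels[i] for i in perm])
        comp = compare_dendrograms(upgma(dm), upgma(dm2), (2, 6))
        assert comp.cophenetic_correlation == pytest.approx(1.0)
        np.testing.assert_allclose(comp.cut_agreement["ari"].to_numpy(), 1.0)

    def test_ari_matches_pair_counting_oracle(self, rng):
        def ari_oracle(a, b):
            n = len(a)
            s_both = s_a = s_b = 0
            for i in range(n):
                for j in range(i + 1, n):
                    ca, cb = a[i] == a[j], b[i] == b[j]
                    s_both += ca and cb
                    s_a += ca
                    s_b += cb
            n_pairs = n * (n - 1) // 2
            expected = s_a * s_b / n_pairs
            max_index = (s_a + s_b) / 2
            if max_index == expected:
                return 1.0
            return (s_both - expected) / (max_index - expected)

        for _ in range(10):
            d1 = random_distance(rng, 10)
            d2 = random_distance(rng, 10, prefix="L")  # same labels
            comp = compare_dendrograms(upgma(d1), upgma(d2), (3, 3))
            labels = list(d1.labels)
            a = cut_tree(upgma(d1), 3).labels_for(labels)
            b = cut_tree(upgma(d2), 3).labels_for(labels)
            assert comp.cut_agreement["ari"].iloc[0] == pytest.approx(
                ari_oracle(a, b), abs=1e-10)


class TestKmeansSelect:
    @staticmethod
    def blobs(rng, centers, n_per, sd=0.1):
        pts, labels = [], []
        for c, center in enumerate(centers):
            pts.append(rng.normal(center, sd, size=(n_per, len(center))))
            labels += [c] * n_per
        x = np.vstack(pts)
        idx = [f"A{i}" for i in range(len(x))]
        return pd.DataFrame(x, index=idx), np.array(labels)

    def test_two_separated_blobs(self, rng):
        data, truth = self.blobs(rng, [(0, 0), (10, 10)], 20)
        sel = kmeans_select(data, (2, 6), n_restarts=10, seed=0)
        assert sel.best_k == 2 and sel.supported
        from sklearn.metrics import adjusted_rand_score
        got = sel.partition.labels_for(list(data.index))
        assert adjusted_rand_score(truth, got) == 1.0

    def test_three_blobs(self, rng):
        data, _ = self.blobs(rng, [(0, 0), (10, 0), (0, 10)], 15)
        assert kmeans_select(data, (2, 6), 10, seed=0).best_k == 3

    def test_identical_points_rejected(self):
        data = pd.DataFrame(np.ones((5, 2)), index=[f"A{i}" for i in range(5)])
        with pytest.raises(DegenerateDataError):
            kmeans_select(data, (2, 4))

    def test_bitwise_reproducibility(self, rng):
        data, _ = self.blobs(rng, [(0, 0), (4, 4)], 12, sd=1.0)
        a = kmeans_select(data, (2, 5), 7, seed=3)
        b = kmeans_select(data, (2, 5), 7, seed=3)
        assert a.partition.assignments == b.partition.assignments
        pd.testing.assert_frame_equal(a.silhouette, b.silhouette)


class TestPca:
    def test_perfectly_correlated_traits(self):
        x = np.arange(10.0)
        data = pd.DataFrame({"t1": x, "t2": 3 * x + 1})
        res = pca(data, scale=True)
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_isotropic_traits_split_evenly(self, rng):
        data = pd.DataFrame(rng.normal(size=(4000, 2)), columns=["a", "b"])
        res = pca(data, scale=True)
        assert res.percent_variance[0] == pytest.approx(50.0, abs=5.0)

    def test_trace_identity_and_percent_sum(self, bundle):
        means = bundle.traits.genotype_means()
        res = pca(means, scale=True)
        assert res.eigenvalues.sum() == pytest.approx(means.shape[1])
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_accession_order_invariance(self, bundle, rng):
        means = bundle.traits.genotype_means()
        perm = rng.permutation(len(means))
        res1 = pca(means, scale=True)
        res2 = pca(means.iloc[perm], scale=True)
        np.testing.assert_allclose(res1.percent_variance, res2.percent_variance,
                                   atol=1e-9)

    def test_zero_variance_trait_named(self):
        data = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 3.0]})
        with pytest.raises(DegenerateDataError, match="flat"):
            pca(data, scale=True)
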