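import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuproscan.clusterer import (
    ClusterTree,
    cluster_types,
    hcluster,
    median_center,
    subset_cluster,
    to_newick,
    uncentered_correlation,
)
from cuproscan.profiler import SpeciesProfile

from .conftest import brute_force_agglomerate


class TestUncenteredCorrelation:
    def test_self_similarity_is_one(self):
        assert uncentered_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_orthogonal_vectors_zero(self):
        assert uncentered_correlation([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # (1*2 + 2*1) / (sqrt(5) * sqrt(5)) = 4/5
        assert uncentered_correlation([1, 2], [2, 1]) == pytest.approx(0.8)

    def test_all_zero_vector_convention(self):
        with pytest.warns(UserWarning):
            assert uncentered_correlation([0, 0], [1, 2]) == 0.0

    def test_no_mean_subtraction(self):
        # a constant shift changes uncentered correlation, unlike Pearson
        assert uncentered_correlation([1, 2], [3, 4]) != pytest.approx(
            np.corrcoef([1, 2], [3, 4])[0, 1]
        )

    @settings(max_examples=200, derandomize=True)
    @given(
        x=st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        y=st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        a=st.floats(0.01, 100),
    )
    def test_symmetry_scale_invariance_and_bound(self, x, y, a):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]), np.array(y[:n])
        if np.linalg.norm(x) == 0 or np.linalg.norm(y) == 0:
            return
        r = uncentered_correlation(x, y)
        assert abs(r) <= 1.0
        assert uncentered_correlation(y, x) == pytest.approx(r)
        assert uncentered_correlation(a * x, y) == pytest.approx(r, abs=1e-9)


class TestMedianCenter:
    def test_row_median_subtracted(self):
        out = median_center(np.array([[1.0, 2.0, 9.0]]), axis=1, scale=False)
        assert out.tolist() == [[-1.0, 0.0, 7.0]]

    def test_constant_row_unchanged_by_mad_guard(self):
        out = median_center(np.array([[4.0, 4.0, 4.0]]), axis=1, scale=True)
        assert out.tolist() == [[0.0, 0.0, 0.0]]

    def test_centered_rows_have_zero_median(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(0, 10, size=(10, 5))
        out = median_center(m, axis=1, scale=True)
        assert np.allclose(np.median(out, axis=1), 0.0)

    def test_input_not_mutated(self):
        m = np.ones((3, 3))
        median_center(m)
        assert np.all(m == 1.0)


class TestHcluster:
    def test_identical_rows_merge_first(self):
        m = np.array([[1.0, 2.0, 3.0], [9.0, 1.0, 4.0], [1.0, 2.0, 3.0]])
        tree = hcluster(m, labels=["a", "b", "c"])
        first_a, first_b, h = tree.merges[0]
        assert {first_a, first_b} == {0, 2}
        assert h == pytest.approx(0.0)

    def test_two_rows_single_merge_at_distance(self):
        m = np.array([[1.0, 0.0], [0.0, 1.0]])
        tree = hcluster(m)
        assert len(tree.merges) == 1
        assert tree.merges[0][2] == pytest.approx(1.0)  # 1 - r, r = 0

    def test_merge_count_invariant(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0, 5, size=(7, 4))
        tree = hcluster(m)
        assert len(tree.merges) == tree.n_leaves - 1

    def test_non_finite_distance_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            hcluster(dist=d, labels=["a", "b"])

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_agrees_with_brute_force_reference(self, linkage):
        rng = np.random.default_rng(42)
        for _ in range(150):
            n = int(rng.integers(3, 9))
            d = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            vals = rng.uniform(0.01, 2.0, size=len(iu[0]))
            d[iu] = vals
            d += d.T
            tree = hcluster(dist=d, linkage=linkage)
            ref = brute_force_agglomerate(d, linkage)
            for (a, b, h), (ra, rb, rh) in zip(tree.merges, ref):
                assert (a, b) == (min(ra, rb), max(ra, rb)) or (a, b) == (ra, rb)
                assert h == pytest.approx(rh, abs=1e-9)

    def test_matches_scipy_heights_on_random_data(self):
        # independent cross-check against scipy's UPGMA on tie-free distances
        from scipy.cluster.hierarchy import linkage as scipy_linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(3, 10))
            d = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            d[iu] = rng.uniform(0.05, 3.0, size=len(iu[0]))
            d += d.T
            ours = sorted(h for _, _, h in hcluster(dist=d, linkage="average").merges)
            theirs = sorted(scipy_linkage(squareform(d), method="average")[:, 2])
            assert np.allclose(ours, theirs, atol=1e-9)

    def test_row_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(11)
        m = rng.uniform(0, 5, size=(6, 4))
        labels = [f"s{i}" for i in range(6)]
        perm = rng.permutation(6)
        t1 = hcluster(m, labels=labels)
        t2 = hcluster(m[perm], labels=[labels[i] for i in perm])

        def label_partitions(tree):
            return sorted(
                tuple(sorted(tree.leaves[i] for i in s))
                for s in tree.leaf_sets().values()
            )

        assert label_partitions(t1) == label_partitions(t2)


class TestSubsetCluster:
    def _profiles(self, catalog, n=6):
        rng = np.random.default_rng(5)
        profs = []
        for i in range(n):
            counts = {
                t: int(rng.integers(0, 5)) for t in catalog.type_names
            }
            profs.append(SpeciesProfile(f"sp{i}", "E", 3000, counts))
        return profs

    def test_homeostasis_subset_uses_10_columns(self, catalog):
        from cuproscan.clusterer import profile_matrix

        profs = self._profiles(catalog)
        mat, _rows, cols = profile_matrix(profs, catalog, "homeostasis_only")
        assert len(cols) == 10
        assert "MCOs" in cols and "Csp3_Ccsp" in cols

    def test_all_copper_uses_31_columns(self, catalog):
        from cuproscan.clusterer import profile_matrix

        mat, _r, cols = profile_matrix(self._profiles(catalog), catalog, "all_copper")
        assert len(cols) == 31

    def test_row_subset_filter_and_empty_error(self, catalog):
        profs = self._profiles(catalog)
        tree = subset_cluster(profs, catalog, row_subset=["sp0", "sp1", "sp2"])
        assert set(tree.leaves) == {"sp0", "sp1", "sp2"}
        with pytest.raises(ValueError, match="empty"):
            subset_cluster(profs, catalog, row_subset=[])

    def test_type_cooccurrence_tree_covers_all_types(self, catalog):
        tree = cluster_types(self._profiles(catalog), catalog)
        assert set(tree.leaves) == set(catalog.type_names)


class TestNewick:
    def test_two_leaf_midpoint_convention(self):
        tree = ClusterTree(leaves=("A", "B"), merges=((0, 1, 0.4),))
        assert to_newick(tree) == "(A:0.2,B:0.2);"

    def test_round_trip_is_isomorphic(self):
        import skbio

        rng = np.random.default_rng(9)
        m = rng.uniform(0, 5, size=(8, 4))
        labels = [f"L{i}" for i in range(8)]
        tree = hcluster(m, labels=labels)
        parsed = skbio.TreeNode.read(io.StringIO(to_newick(tree)))
        assert sorted(t.name for t in parsed.tips()) == sorted(labels)
        # tip-to-tip distance between two leaves equals their merge elevation x2
        sets = tree.leaf_sets()
        first_a, first_b, h = tree.merges[0]
        la, lb = labels[first_a], labels[first_b]
        assert parsed.find(la).distance(parsed.find(lb)) == pytest.approx(h)

    def test_round_trip_rf_distance_zero(self):
        import skbio

        rng = np.random.default_rng(13)
        m = rng.uniform(0, 5, size=(8, 5))
        labels = [f"L{i}" for i in range(8)]
        nwk = to_newick(hcluster(m, labels=labels))
        t1 = skbio.TreeNode.read(io.StringIO(nwk))
        t2 = skbio.TreeNode.read(io.StringIO(nwk))
        assert t1.compare_rfd(t2) == 0.0

    def test_labels_with_spaces_quoted(self):
        tree = ClusterTree(leaves=("Cu ATPases", "B"), merges=((0, 1, 0.2),))
        assert to_newick(tree) == "('Cu ATPases':0.1,B:0.1);"
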