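import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import mdagkit as mk
from mdagkit.clustering import ClassicalMDS


def blobs(rng, centers, n_per, sd=1.0):
    pts = np.vstack([rng.normal(c, sd, size=(n_per, len(c))) for c in centers])
    return pts, squareform(pdist(pts))


def brute_force_silhouette(mat, labels):
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            out[i] = 0.0
            continue
        a = np.mean([mat[i, j] for j in own])
        b = min(
            np.mean([mat[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels) if lab != labels[i]
        )
        out[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return out


class TestHierarchicalCluster:
    def test_three_point_merge_order(self):
        mat = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        tree = mk.hierarchical_cluster(mat)
        Z = tree.linkage_matrix
        assert sorted(Z[0, :2]) == [0, 1] and Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.9)

    def test_all_zero_matrix_merges_at_zero(self):
        tree = mk.hierarchical_cluster(np.zeros((4, 4)))
        assert np.allclose(tree.linkage_matrix[:, 2], 0.0)

    def test_two_samples_single_merge(self):
        tree = mk.hierarchical_cluster(np.array([[0, 0.3], [0.3, 0]]))
        assert tree.linkage_matrix.shape[0] == 1
        assert tree.linkage_matrix[0, 2] == pytest.approx(0.3)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            mk.hierarchical_cluster(np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError):
            mk.hierarchical_cluster(np.array([[0, -1], [-1, 0]]))

    def test_cut_produces_exactly_k_groups(self):
        rng = np.random.default_rng(0)
        _, mat = blobs(rng, [(0, 0), (10, 0), (0, 10)], 5)
        tree = mk.hierarchical_cluster(mat)
        for k in range(2, 8):
            assert tree.cut(k).nunique() == k

    def test_newick_has_all_leaves(self):
        rng = np.random.default_rng(1)
        _, mat = blobs(rng, [(0, 0), (5, 5)], 4)
        tree = mk.hierarchical_cluster(mat)
        nwk = tree.to_newick()
        assert nwk.endswith(";") and all(f"{i}:" in nwk for i in map(str, range(8)))


class TestChooseK:
    def test_three_planted_blobs(self):
        rng = np.random.default_rng(1)
        _, mat = blobs(rng, [(0, 0), (30, 0), (0, 30)], 10)
        tree = mk.hierarchical_cluster(mat)
        sel = mk.choose_k(tree, mat)
        assert sel.recommended_k == 3

    def test_two_planted_blobs(self):
        rng = np.random.default_rng(2)
        _, mat = blobs(rng, [(0, 0), (25, 0)], 10)
        tree = mk.hierarchical_cluster(mat)
        assert mk.choose_k(tree, mat).recommended_k == 2

    def test_identical_samples_abstains(self):
        mat = np.zeros((6, 6))
        tree = mk.hierarchical_cluster(mat)
        with pytest.warns(UserWarning, match="silhouette undefined"):
            sel = mk.choose_k(tree, mat)
        assert sel.recommended_k is None

    def test_elbow_dispersion_decreases_with_k(self):
        rng = np.random.default_rng(3)
        _, mat = blobs(rng, [(0, 0), (20, 0), (0, 20)], 8)
        tree = mk.hierarchical_cluster(mat)
        sel = mk.choose_k(tree, mat, range(2, 8))
        assert all(np.diff(sel.elbow_w) <= 1e-9)

    def test_silhouette_matches_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(6, 21))
            mat = squareform(pdist(rng.normal(size=(n, 3))))
            tree = mk.hierarchical_cluster(mat)
            k = int(rng.integers(2, min(n - 1, 5) + 1))
            try:
                assignment = mk.cluster_assignment(tree, mat, k)
            except ValueError:
                continue
            labels = assignment["cluster"].to_numpy()
            np.testing.assert_allclose(
                assignment["silhouette"].to_numpy(),
                brute_force_silhouette(mat, labels),
                atol=1e-12,
            )


class TestClassicalMDS:
    def test_collinear_points_recovered_in_one_dimension(self):
        mat = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        coords, model = mk.embed_mds(mat, dims=1)
        rec = squareform(pdist(coords))
        assert np.abs(rec - mat).max() < 1e-9

    def test_euclidean_input_reproduced(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(15, 4))
        mat = squareform(pdist(pts))
        coords, _ = mk.embed_mds(mat, dims=4)
        assert np.abs(squareform(pdist(coords)) - mat).max() < 1e-8

    def test_identical_points_embed_to_zero(self):
        coords, _ = mk.embed_mds(np.zeros((5, 5)), dims=2)
        assert np.allclose(coords, 0.0)

    def test_square_has_two_equal_positive_eigenvalues(self):
        s = np.sqrt(2)
        mat = np.array(
            [[0, 1, s, 1], [1, 0, 1, s], [s, 1, 0, 1], [1, s, 1, 0]], float
        )
        model = ClassicalMDS(n_components=3).fit(mat)
        pos = model.eigenvalues_[model.eigenvalues_ > 1e-9]
        assert len(pos) == 2 and pos[0] == pytest.approx(pos[1])

    def test_dims_clipped_with_warning(self):
        mat = np.array([[0, 1], [1, 0]], float)
        with pytest.warns(UserWarning, match="clipped"):
            ClassicalMDS(n_components=5).fit(mat)


class TestAuBootstrap:
    def test_separated_blobs_strongly_supported(self):
        rng = np.random.default_rng(11)
        pts = np.vstack(
            [rng.normal(0, 1, (10, 3)), rng.normal(18, 1, (10, 3))]
        )
        au = mk.au_bootstrap(pts, replicates=200, seed=11)
        main = au.table[au.table["size"] == 10]
        assert len(main) == 2 and (main["au"] >= 0.95).all()

    def test_spurious_clades_weakly_supported(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(24, 3))
        au = mk.au_bootstrap(pts, replicates=200, seed=12)
        mid = au.table[au.table["size"].between(6, 18)]
        assert mid["au"].max() < 0.95

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(15, 2))
        a = mk.au_bootstrap(pts, replicates=100, seed=5)
        b = mk.au_bootstrap(pts, replicates=100, seed=5)
        assert (a.table["au"] == b.table["au"]).all()

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            mk.au_bootstrap(np.zeros((4, 2)), replicates=0)

    def test_always_recovered_clade_has_unit_support(self):
        rng = np.random.default_rng(14)
        pts = np.vstack([rng.normal(0, 0.01, (5, 2)), rng.normal(50, 0.01, (5, 2))])
        au = mk.au_bootstrap(pts, replicates=100, seed=1)
        main = au.table[au.table["size"] == 5]
        assert np.allclose(main["au"], 1.0)

    def test_au_values_in_unit_interval(self, synthetic_run):
        d = synthetic_run["dissimilarity"]
        coords, _ = mk.embed_mds(d, dims=5)
        au = mk.au_bootstrap(coords[:30], replicates=100, seed=2,
                             leaf_ids=d.sample_ids[:30])
        assert au.table["au"].between(0, 1).all()
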