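"""PCoA, PCA with supplementary projection, neighbor joining, Newick IO."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from poolkin import (
    DistanceMatrix,
    FrequencyMatrix,
    neighbor_joining,
    pairwise_matrix,
    pca_with_supplementary,
    pcoa,
    read_newick,
    write_newick,
)
from poolkin.ordination import tree_path_distances


def _dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or [f"x{i}" for i in range(points.shape[0])]
    return DistanceMatrix(ids, squareform(pdist(points)))


def _fm(rows, prefix="L"):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return FrequencyMatrix([f"{prefix}{i}" for i in range(rows.shape[0])],
                           [f"s{j}" for j in range(rows.shape[1])], rows)


class TestPcoa:
    def test_collinear_points_single_axis(self):
        D = _dm([[0.0], [1.0], [2.0]])
        res = pcoa(D)
        assert res.percent_inertia[0] == pytest.approx(100.0)
        assert res.coordinates.shape[1] == 1

    def test_euclidean_roundtrip_oracle(self, rng):
        pts = rng.normal(size=(7, 2))
        D = _dm(pts)
        res = pcoa(D)
        rec = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(rec, D.values, atol=1e-9)

    def test_duplicated_sample_identical_coordinates(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.5], [1.0, 0.5], [0.3, 2.0]])
        res = pcoa(_dm(pts))
        np.testing.assert_allclose(res.coordinates[1], res.coordinates[2],
                                   atol=1e-9)

    def test_truncation_warns_when_axes_exceed_rank(self):
        D = _dm([[0.0], [1.0], [2.0]])
        with pytest.warns(UserWarning):
            res = pcoa(D, n_axes=3)
        assert res.coordinates.shape[1] == 1

    def test_matches_skbio_eigenvalues(self, rng):
        """Cross-check positive eigenvalues against the scikit-bio PCoA."""
        import skbio
        pts = rng.normal(size=(6, 3))
        D = _dm(pts)
        ours = pcoa(D)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D.values, D.ids))
        np.testing.assert_allclose(ours.eigenvalues,
                                   ref.eigvals.to_numpy()[:3], atol=1e-8)


class TestPcaSupplementary:
    def test_active_row_reprojected_identically(self, rng):
        act = _fm(rng.random((6, 10)))
        sup = FrequencyMatrix(["dup"], act.locus_ids, act.values[2:3])
        res = pca_with_supplementary(act, sup)
        np.testing.assert_allclose(res.supplementary_coordinates[0],
                                   res.coordinates[2], atol=1e-9)

    def test_column_mean_row_projects_to_origin(self, rng):
        act = _fm(rng.random((5, 8)))
        sup = FrequencyMatrix(["mean"], act.locus_ids,
                              act.values.mean(axis=0, keepdims=True))
        res = pca_with_supplementary(act, sup)
        np.testing.assert_allclose(res.supplementary_coordinates[0], 0.0,
                                   atol=1e-9)

    def test_half_blend_projects_midway(self, rng):
        # two tight, well-separated groups; a 50/50 blend lands between
        g1 = np.clip(0.12 + 0.01 * rng.standard_normal((5, 30)), 0, 1)
        g2 = np.clip(0.88 + 0.01 * rng.standard_normal((5, 30)), 0, 1)
        act = _fm(np.vstack([g1, g2]))
        blend = (g1.mean(0) + g2.mean(0)) / 2
        sup = FrequencyMatrix(["blend"], act.locus_ids, blend[None, :])
        res = pca_with_supplementary(act, sup)
        c1 = res.coordinates[:5, 0].mean()
        c2 = res.coordinates[5:, 0].mean()
        assert res.supplementary_coordinates[0, 0] == pytest.approx(
            (c1 + c2) / 2, abs=1e-9)

    def test_percent_variance_non_increasing_sums_100(self, rng):
        res = pca_with_supplementary(_fm(rng.random((8, 12))))
        pv = res.percent_inertia
        assert np.all(np.diff(pv) <= 1e-9)
        assert pv.sum() == pytest.approx(100.0)

    def test_locus_mismatch_rejected(self, rng):
        act = _fm(rng.random((4, 5)))
        sup = FrequencyMatrix(["x"], [f"t{j}" for j in range(5)],
                              rng.random((1, 5)))
        with pytest.raises(ValueError):
            pca_with_supplementary(act, sup)

    def test_pcoa_of_rogers_equals_scaled_pca_scores(self, rng):
        """Cross-module consistency: modified Rogers PCoA == PCA/sqrt(L)."""
        fm = _fm(rng.random((6, 40)))
        D = pairwise_matrix(fm, "modified_rogers")
        a = pcoa(D).coordinates
        b = pca_with_supplementary(fm).coordinates / np.sqrt(fm.n_loci)
        k = min(a.shape[1], b.shape[1])
        for axis in range(k):
            assert (np.allclose(a[:, axis], b[:, axis], atol=1e-8)
                    or np.allclose(a[:, axis], -b[:, axis], atol=1e-8))


def _random_additive_tree(rng, n_taxa):
    """Random binary tree with uniform branch lengths; returns (newick, ids)."""
    ids = [f"t{i}" for i in range(n_taxa)]
    nodes = [f"{name}:{rng.uniform(0.1, 2.0):.6f}" for name in ids]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 2.0):.6f}"
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    return "(" + ",".join(nodes) + ");", ids


class TestNeighborJoining:
    def test_four_taxon_recovery_vs_topology_bruteforce(self):
        """dAB..dCD from ((A:1,B:2):1,(C:3,D:4)); NJ must find split AB|CD
        with exact lengths; brute force over the 3 unrooted topologies by
        least squares confirms AB|CD is the unique additive fit."""
        ids = list("ABCD")
        D = DistanceMatrix(ids, [[0, 3, 5, 6], [3, 0, 6, 7],
                                 [5, 6, 0, 7], [6, 7, 7, 0]])
        tree = neighbor_joining(D)
        np.testing.assert_allclose(tree_path_distances(tree, ids), D.values,
                                   atol=1e-9)
        # least-squares fit of each 4-taxon topology: pairs (x,y)|(z,w)
        best = None
        for (x, y, z, w) in [(0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2)]:
            # design matrix: 5 edges (ex, ey, ez, ew, internal)
            pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
            A = np.zeros((6, 5))
            for r, (i, j) in enumerate(pairs):
                for c, leaf in enumerate((x, y, z, w)):
                    if leaf in (i, j):
                        A[r, c] = 1
                same_side = {i, j} in ({x, y}, {z, w})
                A[r, 4] = 0 if same_side else 1
            d = np.array([D.values[i, j] for i, j in pairs])
            edge, res, *_ = np.linalg.lstsq(A, d, rcond=None)
            rss = float(np.sum((A @ edge - d) ** 2))
            if best is None or rss < best[0]:
                best = (rss, (x, y, z, w))
        assert best[1] == (0, 1, 2, 3)  # the AB|CD split fits exactly
        assert best[0] == pytest.approx(0.0, abs=1e-18)

    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(list("ABC"), [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        tree = neighbor_joining(D)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_additive_matrices_recovered_exactly(self, rng):
        for n_taxa in (5, 8):
            newick, ids = _random_additive_tree(rng, n_taxa)
            ref = read_newick(newick)
            D = DistanceMatrix(ids, tree_path_distances(ref, ids))
            out = neighbor_joining(D)
            np.testing.assert_allclose(tree_path_distances(out, ids),
                                       D.values, atol=1e-6)

    def test_matches_skbio_nj_on_random_additive_input(self, rng):
        from skbio.tree import nj as skbio_nj
        import skbio
        newick, ids = _random_additive_tree(rng, 6)
        ref = read_newick(newick)
        D = DistanceMatrix(ids, tree_path_distances(ref, ids))
        ours = neighbor_joining(D)
        theirs = skbio_nj(skbio.DistanceMatrix(D.values, ids))
        np.testing.assert_allclose(tree_path_distances(ours, ids),
                                   theirs.tip_tip_distances(ids).data,
                                   atol=1e-6)

    def test_label_order_invariance(self, rng):
        newick, ids = _random_additive_tree(rng, 6)
        ref = read_newick(newick)
        D = DistanceMatrix(ids, tree_path_distances(ref, ids))
        perm = list(rng.permutation(len(ids)))
        Dp = DistanceMatrix([ids[i] for i in perm],
                            D.values[np.ix_(perm, perm)])
        a = tree_path_distances(neighbor_joining(D), ids)
        b = tree_path_distances(neighbor_joining(Dp), ids)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], [[0, 1], [1, 0]]))


class TestNewick:
    def test_cherry_roundtrip(self):
        t = read_newick("(A:1,B:2);")
        back = read_newick(write_newick(t))
        tips = {x.name: x.length for x in back.tips()}
        assert tips == {"A": 1.0, "B": 2.0}

    def test_labels_with_spaces_survive_roundtrip(self):
        t = read_newick("('taxon one':1,'taxon two':2);")
        text = write_newick(t)
        back = read_newick(text)
        assert sorted(x.name for x in back.tips()) == ["taxon one", "taxon two"]

    def test_write_parse_write_fixed_point(self, rng):
        newick, ids = _random_additive_tree(rng, 8)
        t = read_newick(newick)
        once = write_newick(t)
        twice = write_newick(read_newick(once))
        assert once == twice
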