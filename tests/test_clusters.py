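"""Perfect-LD cluster building and UPGMA agglomeration."""
import warnings

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage

from ldblocks import (
    Cluster,
    LDMatrix,
    Marker,
    agglomerate,
    build_clusters,
    cluster_distance,
    leaf_order,
    to_newick,
)
from ldblocks.clusters import cluster_distance_matrix, to_scipy_linkage
from ldblocks.errors import ContractError, NonCliqueWarning, UndefinedLDError

from _oracles import clique_violations, naive_upgma, union_find_components


def ldm_from(r2, defined=None, positions=None):
    r2 = np.asarray(r2, dtype=float)
    k = r2.shape[0]
    if defined is None:
        defined = np.ones((k, k), dtype=bool)
    if positions is None:
        positions = [1000 * (i + 1) for i in range(k)]
    markers = [Marker(id=f"rs{i + 1}", chrom="1", pos=positions[i]) for i in range(k)]
    return LDMatrix(markers=markers, r2=r2, defined=np.asarray(defined, dtype=bool))


class TestBuildClusters:
    def test_all_perfect_is_one_cluster(self):
        ldm = ldm_from(np.ones((3, 3)))
        clusters, singles = build_clusters(ldm)
        assert [c.member_ids for c in clusters] == [("rs1", "rs2", "rs3")]
        assert singles == []
        assert clusters[0].name == "rs1"

    def test_two_separate_blocks(self):
        r2 = np.full((4, 4), 0.2)
        np.fill_diagonal(r2, 1.0)
        r2[0, 1] = r2[1, 0] = 1.0
        r2[2, 3] = r2[3, 2] = 1.0
        clusters, singles = build_clusters(ldm_from(r2))
        assert [c.member_ids for c in clusters] == [("rs1", "rs2"), ("rs3", "rs4")]
        assert singles == []

    def test_empty_matrix(self):
        clusters, singles = build_clusters(ldm_from(np.zeros((0, 0))))
        assert clusters == [] and singles == []

    def test_matches_union_find_and_clique_oracle(self, rng):
        """Components equal a union-find oracle; clique flags equal
        exhaustive pair checking, over 50 random thresholded matrices."""
        eps = 1e-6
        for _ in range(50):
            k = int(rng.integers(3, 10))
            r2 = np.round(rng.random((k, k)), 1)  # many exact 1.0 ties
            r2 = np.maximum(r2, r2.T)
            np.fill_diagonal(r2, 1.0)
            ldm = ldm_from(r2)
            adj = (r2 >= 1 - eps).copy()
            np.fill_diagonal(adj, False)
            expected = union_find_components(adj)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                clusters, singles = build_clusters(ldm, epsilon=eps)
            got = {frozenset(ldm.index(m) for m in c.member_ids) for c in clusters}
            got |= {frozenset({ldm.index(s)}) for s in singles}
            assert got == expected
            expect_bad = any(
                clique_violations(adj, comp) for comp in expected if len(comp) > 1
            )
            flagged = any(isinstance(w.message, NonCliqueWarning) for w in caught)
            assert flagged == expect_bad

    def test_membership_invariant_to_marker_order(self, rng):
        k = 6
        r2 = (rng.random((k, k)) > 0.5).astype(float)
        r2 = np.maximum(r2, r2.T)
        np.fill_diagonal(r2, 1.0)
        base = ldm_from(r2)
        perm = rng.permutation(k)
        shuffled = ldm_from(
            r2[np.ix_(perm, perm)],
            positions=[1000 * (int(p) + 1) for p in perm],
        )
        # rename shuffled markers to match originals
        shuffled.markers = [Marker(id=f"rs{int(p) + 1}", chrom="1",
                                   pos=1000 * (int(p) + 1)) for p in perm]
        shuffled._index = {m.id: i for i, m in enumerate(shuffled.markers)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonCliqueWarning)
            c1, s1 = build_clusters(base)
            c2, s2 = build_clusters(shuffled)
        assert {c.member_ids for c in c1} == {c.member_ids for c in c2}
        assert s1 == s2


class TestClusterDistance:
    def make_cluster(self, ldm, ids):
        markers = [ldm.markers[ldm.index(i)] for i in ids]
        return Cluster(members=tuple(markers))

    def test_mean_cross_r2(self):
        r2 = np.ones((4, 4))
        r2[np.ix_([0, 1], [2, 3])] = 0.75
        r2[np.ix_([2, 3], [0, 1])] = 0.75
        ldm = ldm_from(r2)
        a = self.make_cluster(ldm, ["rs1", "rs2"])
        b = self.make_cluster(ldm, ["rs3", "rs4"])
        assert cluster_distance(ldm, a, b) == 0.25

    def test_self_distance_zero(self):
        ldm = ldm_from(np.ones((2, 2)))
        c = self.make_cluster(ldm, ["rs1", "rs2"])
        assert cluster_distance(ldm, c, c) == 0.0

    def test_mean_equals_representative_on_perfect_blocks(self, two_block_panel):
        from ldblocks import r2_matrix

        panel, _ = two_block_panel
        ldm = r2_matrix(panel)
        clusters, _ = build_clusters(ldm)
        assert len(clusters) == 2
        a, b = clusters
        rep = 1.0 - ldm.r2[ldm.index(a.member_ids[0]), ldm.index(b.member_ids[0])]
        assert cluster_distance(ldm, a, b) == pytest.approx(rep, abs=1e-12)

    def test_undefined_cross_pairs(self):
        defined = np.ones((4, 4), dtype=bool)
        defined[np.ix_([0, 1], [2, 3])] = False
        defined[np.ix_([2, 3], [0, 1])] = False
        ldm = ldm_from(np.ones((4, 4)), defined=defined)
        a = self.make_cluster(ldm, ["rs1", "rs2"])
        b = self.make_cluster(ldm, ["rs3", "rs4"])
        with pytest.raises(UndefinedLDError):
            cluster_distance(ldm, a, b)
        with pytest.warns(Warning, match="maximal distance"):
            D = cluster_distance_matrix(ldm, [a, b])
        assert D[0, 1] == 1.0


class TestAgglomerate:
    def test_two_items(self):
        dendro = agglomerate([[0.0, 0.3], [0.3, 0.0]])
        assert dendro.merges == ((0, 1, 0.3),)

    def test_three_items_nested(self):
        D = np.array([[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]])
        dendro = agglomerate(D)
        assert dendro.merges[0] == (0, 1, 0.1)
        a, b, h = dendro.merges[1]
        assert (a, b) == (2, 3) and h == pytest.approx(0.5)

    def test_single_item(self):
        dendro = agglomerate([[0.0]])
        assert dendro.merges == () and leaf_order(dendro) == [0]

    @pytest.mark.parametrize("bad", [np.array([[0, 1], [2, 0]]),
                                     np.array([[0, -1.0], [-1.0, 0]])])
    def test_contract_errors(self, bad):
        with pytest.raises(ContractError):
            agglomerate(bad)

    def test_matches_naive_recompute_oracle(self, rng):
        """Merge sequence and heights equal an oracle that recomputes all
        average distances from the leaf matrix at every step."""
        for _ in range(25):
            k = 6
            D = rng.random((k, k))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            got = agglomerate(D).merges
            expected = naive_upgma(D)
            assert len(got) == len(expected)
            for (a, b, h), (ea, eb, eh) in zip(got, expected):
                assert (a, b) == (ea, eb)
                assert h == pytest.approx(eh, abs=1e-12)

    def test_heights_match_scipy_average_linkage(self, rng):
        from scipy.spatial.distance import squareform

        D = rng.random((7, 7))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        ours = sorted(agglomerate(D).heights)
        scipys = sorted(linkage(squareform(D, checks=False), method="average")[:, 2])
        assert np.allclose(ours, scipys, atol=1e-12)

    def test_heights_nondecreasing_and_constant_matrix(self, rng):
        D = rng.random((8, 8))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        h = agglomerate(D).heights
        assert all(x <= y + 1e-12 for x, y in zip(h, h[1:]))
        flat = np.full((5, 5), 0.7)
        np.fill_diagonal(flat, 0.0)
        assert all(x == pytest.approx(0.7, abs=1e-12)
                   for x in agglomerate(flat).heights)


class TestLeafOrder:
    def test_forced_by_nesting(self):
        D = np.array([[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]])
        assert leaf_order(agglomerate(D)) == [0, 1, 2]

    def test_permutation_and_contiguous_subtrees(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 9))
            D = rng.random((k, k))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            dendro = agglomerate(D)
            order = leaf_order(dendro)
            assert sorted(order) == list(range(k))
            # every subtree occupies a contiguous run of the order
            members = {i: {i} for i in range(k)}
            pos = {leaf: idx for idx, leaf in enumerate(order)}
            for t, (a, b, _) in enumerate(dendro.merges):
                merged = members[a] | members[b]
                members[k + t] = merged
                idxs = sorted(pos[leaf] for leaf in merged)
                assert idxs == list(range(idxs[0], idxs[0] + len(idxs)))


def test_newick_roundtrips_through_dendropy(rng):
    import dendropy

    k = 5
    D = rng.random((k, k))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    dendro = agglomerate(D)
    labels = [f"c{i}" for i in range(k)]
    tree = dendropy.Tree.get(data=to_newick(dendro, labels), schema="newick")
    assert sorted(t.label for t in tree.taxon_namespace) == sorted(labels)
    # ultrametric: root-to-leaf depth equals half the final merge height
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    assert np.allclose(depths, dendro.merges[-1][2] / 2, atol=1e-9)


def test_scipy_linkage_export_shape(rng):
    D = rng.random((4, 4))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    Z = to_scipy_linkage(agglomerate(D))
    assert Z.shape == (3, 4) and Z[-1, 3] == 4
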