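"""Distances, neighbor joining, patristic distances and threshold grouping."""

import itertools

import dendropy
import networkx as nx
import numpy as np
import pytest

from nrpslip import phylo
from tests.conftest import random_binary_newick


def _patristic_oracle(tree: phylo.PhyloTree) -> dict[tuple[str, str], float]:
    """Independent graph-shortest-path computation of leaf-pair distances."""
    g = nx.Graph()
    t = tree.dendropy_tree
    leaf_of = {}
    for edge in t.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        g.add_edge(id(edge.tail_node), id(edge.head_node), weight=edge.length)
    for lf in t.leaf_node_iter():
        leaf_of[lf.taxon.label] = id(lf)
    out = {}
    for a, b in itertools.combinations(sorted(leaf_of), 2):
        out[(a, b)] = nx.shortest_path_length(
            g, leaf_of[a], leaf_of[b], weight="weight"
        )
    return out


class TestPairwiseDistances:
    def test_identical_rows_have_zero_distance(self):
        aln = phylo.MultipleAlignment.from_pairs([("a", "ACDE"), ("b", "ACDE")])
        assert phylo.pairwise_distances(aln)[("a", "b")] == 0.0

    def test_quarter_difference(self):
        aln = phylo.MultipleAlignment.from_pairs([("a", "AAAA"), ("b", "AAAT")])
        assert phylo.pairwise_distances(aln)[("a", "b")] == 0.25

    def test_gapped_columns_excluded(self):
        aln = phylo.MultipleAlignment.from_pairs([("a", "A-AT"), ("b", "AC-T")])
        # only columns 0 and 3 comparable, both identical
        assert phylo.pairwise_distances(aln)[("a", "b")] == 0.0

    def test_matches_brute_force_column_count(self):
        rng = np.random.default_rng(5)
        alpha = "ACDEFG-"
        for _ in range(20):
            rows = [
                "".join(rng.choice(list(alpha), size=60)) for _ in range(4)
            ]
            labels = [f"s{i}" for i in range(4)]
            aln = phylo.MultipleAlignment.from_pairs(list(zip(labels, rows)))
            d = phylo.pairwise_distances(aln)
            for i in range(4):
                for j in range(i + 1, 4):
                    diff = comp = 0
                    for x, y in zip(rows[i], rows[j]):
                        if x == "-" or y == "-":
                            continue
                        comp += 1
                        diff += x != y
                    assert d[(labels[i], labels[j])] == pytest.approx(
                        diff / comp
                    )

    def test_poisson_correction(self):
        aln = phylo.MultipleAlignment.from_pairs([("a", "AAAA"), ("b", "AAAT")])
        d = phylo.pairwise_distances(aln, model="poisson")
        assert d[("a", "b")] == pytest.approx(-np.log(0.75))

    def test_saturated_pair_raises_naming_pair(self):
        aln = phylo.MultipleAlignment.from_pairs([("a", "AAAA"), ("b", "TTTT")])
        with pytest.raises(phylo.SaturatedPairError, match="'a'.*'b'"):
            phylo.pairwise_distances(aln, model="poisson")

    def test_no_comparable_columns_raises(self):
        aln = phylo.MultipleAlignment.from_pairs([("a", "A--"), ("b", "-CC")])
        with pytest.raises(ValueError, match="comparable"):
            phylo.pairwise_distances(aln)


def _additive_four_taxon(topology, lengths):
    """Distance matrix for ((x,y),(z,w)) with leaf lengths + internal edge."""
    (x, y), (z, w) = topology
    lx, ly, lz, lw, e = lengths
    labels = sorted([x, y, z, w])
    lmap = {x: lx, y: ly, z: lz, w: lw}
    d = np.zeros((4, 4))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i >= j:
                continue
            pair = {a, b}
            if pair == {x, y} or pair == {z, w}:
                dist = lmap[a] + lmap[b]
            else:
                dist = lmap[a] + lmap[b] + e
            d[i, j] = d[j, i] = dist
    return phylo.DistanceMatrix(labels, d)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = phylo.DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        t = phylo.nj_tree(d)
        pat = phylo.patristic_distances(t)
        for pair in (("a", "b"), ("a", "c"), ("b", "c")):
            assert pat[pair] == pytest.approx(d[pair], abs=1e-12)

    @pytest.mark.parametrize("split", [0, 1, 2])
    def test_four_taxon_additive_recovery(self, split):
        """NJ recovers the generating topology and exact branch lengths for
        additive matrices, for all three unrooted four-taxon topologies."""
        rng = np.random.default_rng(100 + split)
        others = [x for i, x in enumerate("bcd") if i != split]
        topology = (("a", "bcd"[split]), tuple(others))
        for _ in range(17):
            lengths = rng.uniform(0.05, 1.0, size=5)
            d = _additive_four_taxon(topology, lengths)
            t = phylo.nj_tree(d)
            pat = phylo.patristic_distances(t)
            for i, a in enumerate(d.labels):
                for b in d.labels[i + 1:]:
                    assert pat[(a, b)] == pytest.approx(d[(a, b)], abs=1e-9)

    def test_all_equal_distances_yield_valid_tree(self):
        d = phylo.DistanceMatrix(
            list("abcd"), np.full((4, 4), 0.8) - 0.8 * np.eye(4)
        )
        t = phylo.nj_tree(d)
        pat = phylo.patristic_distances(t)
        total = sum(
            e.length for e in t.dendropy_tree.preorder_edge_iter()
            if e.tail_node is not None
        )
        # least-squares fit of any topology: leaves at 0.4, internal 0
        assert total == pytest.approx(1.6, abs=1e-9)
        assert all(
            v >= 0 for v in np.ravel(pat.matrix)
        )

    def test_four_point_condition_on_additive_input(self):
        rng = np.random.default_rng(44)
        d = _additive_four_taxon(
            (("a", "b"), ("c", "d")), rng.uniform(0.1, 1.0, size=5)
        )
        pat = phylo.patristic_distances(phylo.nj_tree(d))
        s1 = pat[("a", "b")] + pat[("c", "d")]
        s2 = pat[("a", "c")] + pat[("b", "d")]
        s3 = pat[("a", "d")] + pat[("b", "c")]
        top2 = sorted([s1, s2, s3])[1:]
        assert top2[0] == pytest.approx(top2[1], abs=1e-9)

    def test_matches_scikit_bio_topology(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        rng = np.random.default_rng(8)
        d = _additive_four_taxon(
            (("a", "c"), ("b", "d")), rng.uniform(0.05, 1.0, size=5)
        )
        ours = phylo.patristic_distances(phylo.nj_tree(d))
        sk = sknj(SkDM(d.matrix, ids=list(d.labels)))
        for i, a in enumerate(d.labels):
            for b in d.labels[i + 1:]:
                assert ours[(a, b)] == pytest.approx(
                    sk.find(a).distance(sk.find(b)), abs=1e-9
                )

    def test_fewer_than_three_labels_is_error(self):
        d = phylo.DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError):
            phylo.nj_tree(d)

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            m = rng.uniform(0.01, 1.0, size=(n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            t = phylo.nj_tree(
                phylo.DistanceMatrix([f"x{i}" for i in range(n)], m)
            )
            for e in t.dendropy_tree.preorder_edge_iter():
                if e.tail_node is not None:
                    assert e.length >= 0


class TestPatristic:
    def test_cherry(self):
        t = phylo.PhyloTree.from_newick("(a:0.1,b:0.2);")
        assert phylo.patristic_distances(t)[("a", "b")] == pytest.approx(0.3)

    def test_self_distance_zero(self):
        t = phylo.PhyloTree.from_newick("(a:0.1,(b:0.2,c:0.3):0.1);")
        assert phylo.patristic_distances(t)[("a", "a")] == 0.0

    def test_matches_graph_path_oracle_on_random_trees(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            nwk = random_binary_newick(rng, int(rng.integers(4, 12)))
            t = phylo.PhyloTree.from_newick(nwk)
            pat = phylo.patristic_distances(t)
            for (a, b), expect in _patristic_oracle(t).items():
                assert pat[(a, b)] == pytest.approx(expect, abs=1e-9)


class TestGrouping:
    def test_all_far_apart_gives_singletons(self):
        d = phylo.DistanceMatrix(
            list("abc"), np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]]) * 1.0
        )
        assert phylo.group_by_patristic(d, 0.45) == [("a",), ("b",), ("c",)]

    def test_transitive_closure(self):
        d = phylo.DistanceMatrix(
            list("abc"),
            np.array([[0, 0.3, 0.6], [0.3, 0, 0.3], [0.6, 0.3, 0]]),
        )
        assert phylo.group_by_patristic(d, 0.45) == [("a", "b", "c")]

    def test_pairwise_mode_reports_edges_only(self):
        d = phylo.DistanceMatrix(
            list("abc"),
            np.array([[0, 0.3, 0.6], [0.3, 0, 0.3], [0.6, 0.3, 0]]),
        )
        edges = phylo.group_by_patristic(d, 0.45, mode="pairwise")
        assert edges == {frozenset({"a", "b"}), frozenset({"b", "c"})}

    def test_default_threshold_from_config(self):
        assert phylo.PhyloConfig().grouping_threshold == 0.45

    def test_nonpositive_threshold_rejected(self):
        d = phylo.DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        with pytest.raises(ValueError):
            phylo.group_by_patristic(d, 0.0)


class TestRootingAndNewick:
    def test_root_on_leaf_preserves_leaves_and_splits_edge(self):
        t = phylo.PhyloTree.from_newick("(a:0.1,b:0.2,c:0.4);")
        rooted = phylo.root_with_outgroup(t, "c")
        assert rooted.rooted
        assert sorted(rooted.leaf_labels) == ["a", "b", "c"]
        assert len(rooted.dendropy_tree.seed_node.child_nodes()) == 2

    def test_rooting_preserves_patristic_distances(self):
        rng = np.random.default_rng(9)
        nwk = random_binary_newick(rng, 7)
        t = phylo.PhyloTree.from_newick(nwk)
        before = phylo.patristic_distances(t)
        after = phylo.patristic_distances(
            phylo.root_with_outgroup(t, before.labels[0])
        )
        assert np.allclose(before.matrix, after.matrix, atol=1e-9)

    def test_rooting_on_missing_label_is_error(self):
        t = phylo.PhyloTree.from_newick("(a:0.1,b:0.2,c:0.4);")
        with pytest.raises(KeyError):
            phylo.root_with_outgroup(t, "zz")

    def test_newick_round_trip(self):
        rng = np.random.default_rng(321)
        for _ in range(10):
            nwk = random_binary_newick(rng, int(rng.integers(4, 10)))
            t = phylo.PhyloTree.from_newick(nwk)
            back = phylo.PhyloTree.from_newick(t.to_newick())
            assert sorted(back.leaf_labels) == sorted(t.leaf_labels)
            p1 = phylo.patristic_distances(t)
            p2 = phylo.patristic_distances(back)
            assert np.allclose(p1.matrix, p2.matrix, atol=1e-9)


class TestDistanceMatrixIO:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        m = rng.uniform(0.1, 1, size=(4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        d = phylo.DistanceMatrix(list("wxyz"), m)
        path = tmp_path / "d.tsv"
        d.to_tsv(path)
        back = phylo.DistanceMatrix.from_tsv(path)
        assert back.labels == d.labels
        assert np.allclose(back.matrix, d.matrix)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            phylo.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))
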