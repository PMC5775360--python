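"""Neighbor joining, Fitch parsimony, Robinson–Foulds vs independent oracles."""

import dendropy
import numpy as np
import pytest

from plastidkit.core_io import AlignmentMatrix
from plastidkit.divergence import DistanceMatrix
from plastidkit.phylo_lite import (
    fitch_score,
    nj_tree,
    rf_distance,
    tree_from_newick,
    write_tree,
    read_tree,
)

from oracles import all_unrooted_topologies, bipartitions_oracle, fitch_oracle


def _dm(ids, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(list(ids), d, np.zeros_like(d, dtype=np.int64))


def _tree_adjacency(tree):
    adj = {}
    for edge in tree.preorder_edge_iter():
        if edge.head_node is None or edge.tail_node is None:
            continue
        adj.setdefault(edge.tail_node, set()).add(edge.head_node)
        adj.setdefault(edge.head_node, set()).add(edge.tail_node)
    return adj


def _path_distance_matrix(newick, ids):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
    return _dm(ids, d)


class TestNeighborJoining:
    def test_three_taxa_additive_resolution(self):
        # d(A,B)=0.3, d(A,C)=0.4, d(B,C)=0.5 -> la=0.1, lb=0.2, lc=0.3
        dm = _dm("ABC", [[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        tree = nj_tree(dm)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.2)
        assert lengths["C"] == pytest.approx(0.3)

    @pytest.mark.parametrize(
        "newick",
        [
            "((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.07,E:0.3);",
            "(((A:0.11,B:0.07):0.09,C:0.23):0.04,(D:0.12,E:0.2):0.06,F:0.17);",
        ],
    )
    def test_recovers_additive_matrix_topology_exactly(self, newick):
        ids = sorted(set("".join(c for c in newick if c.isalpha())))
        dm = _path_distance_matrix(newick, ids)
        tree = nj_tree(dm)
        assert rf_distance(tree, tree_from_newick(newick)) == 0

    def test_matches_reference_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        ids = list("ABCDEF")
        pts = rng.random((6, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ours = nj_tree(_dm(ids, d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
        theirs_dp = tree_from_newick(str(theirs))
        assert rf_distance(ours, theirs_dp) == 0

    def test_synthetic_study_topology_recovered(self, default_bundle):
        from plastidkit.divergence import distance_matrix

        tree = nj_tree(distance_matrix(default_bundle.alignment))
        truth = tree_from_newick(default_bundle.config.tree_newick)
        assert rf_distance(tree, truth) == 0

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(_dm("AB", [[0, 0.1], [0.1, 0]]))


class TestFitch:
    def _aln(self, ids, rows):
        return AlignmentMatrix.from_strings(ids, rows)

    def test_identical_sequences_score_zero(self):
        tree = tree_from_newick("((A,B),(C,D));")
        aln = self._aln(list("ABCD"), ["ACGT"] * 4)
        assert fitch_score(tree, aln) == 0

    def test_informative_column_on_grouping_vs_conflicting_topology(self):
        aln = self._aln(list("ABCD"), ["A", "A", "C", "C"])
        grouping = tree_from_newick("((A,B),(C,D));")
        conflicting = tree_from_newick("((A,C),(B,D));")
        assert fitch_score(grouping, aln) == 1
        assert fitch_score(conflicting, aln) == 2

    def test_gapped_columns_excluded(self):
        tree = tree_from_newick("((A,B),(C,D));")
        aln = self._aln(list("ABCD"), ["AC", "A-", "CC", "CC"])
        assert fitch_score(tree, aln) == 1  # only column 0 analyzed

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_internal_labelling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = list("ABCDEF")
        topos = all_unrooted_topologies(labels)
        newick = topos[int(rng.integers(len(topos)))]
        tree = tree_from_newick(newick)
        rows = ["".join(rng.choice(list("ACGT"), 15)) for _ in labels]
        aln = self._aln(labels, rows)
        adj = _tree_adjacency(tree)
        internal = [n for n in adj if not n.is_leaf()]
        expected = 0
        for c in range(15):
            leaf_states = {
                leaf: rows[labels.index(leaf.taxon.label)][c]
                for leaf in adj
                if leaf.is_leaf()
            }
            expected += fitch_oracle(adj, leaf_states, internal)
        assert fitch_score(tree, aln) == expected

    def test_invariant_under_consistent_relabeling(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(5)]
        tree = tree_from_newick("((A,B),(C,D),E);")
        relabeled = tree_from_newick("((V,W),(X,Y),Z);")
        s1 = fitch_score(tree, self._aln(list("ABCDE"), rows))
        s2 = fitch_score(relabeled, self._aln(list("VWXYZ"), rows))
        assert s1 == s2

    def test_label_mismatch_rejected(self):
        tree = tree_from_newick("((A,B),(C,D));")
        with pytest.raises(ValueError, match="do not match"):
            fitch_score(tree, self._aln(list("ABCE"), ["A"] * 4))


class TestRobinsonFoulds:
    def test_identical_trees(self):
        t = "((A,B),(C,D),E);"
        assert rf_distance(tree_from_newick(t), tree_from_newick(t)) == 0

    def test_two_distinct_quartets(self):
        t1 = tree_from_newick("((A,B),(C,D));")
        t2 = tree_from_newick("((A,C),(B,D));")
        assert rf_distance(t1, t2) == 2

    @staticmethod
    def _label_bipartitions(tree):
        adj = _tree_adjacency(tree)
        leaves = {n for n in adj if n.is_leaf()}
        labels = {l.taxon.label for l in leaves}
        bips = set()
        for side in bipartitions_oracle(adj, leaves):
            side_labels = frozenset(x.taxon.label for x in side)
            # normalize: a split and its complement are the same bipartition
            bips.add(min(side_labels, frozenset(labels - side_labels), key=sorted))
        return bips

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bipartition_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        topos = all_unrooted_topologies(list("ABCDEFG"))
        pick = rng.integers(len(topos), size=2)
        t1 = tree_from_newick(topos[int(pick[0])])
        t2 = tree_from_newick(topos[int(pick[1])])
        expected = len(self._label_bipartitions(t1) ^ self._label_bipartitions(t2))
        assert rf_distance(t1, t2) == expected

    def test_leaf_set_mismatch_rejected(self):
        t1 = tree_from_newick("((A,B),(C,D));")
        t2 = tree_from_newick("((A,B),(C,E));")
        with pytest.raises(ValueError, match="leaf sets differ"):
            rf_distance(t1, t2)


class TestNewickIO:
    def test_round_trip(self, tmp_path):
        t = tree_from_newick("((A:0.1,B:0.2):0.05,(C:0.1,D:0.3):0.02,E:0.4);")
        p = tmp_path / "t.nwk"
        write_tree(t, p)
        back = read_tree(p)
        assert rf_distance(t, back) == 0
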