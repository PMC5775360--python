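"""Desk-scale phylogeny stage: neighbor joining, Fitch parsimony, RF distance.

Supplies topology checks for the pipeline (NJ from the p-distance matrix,
parsimony score of a fixed topology, Robinson–Foulds comparison) without
any ML/Bayesian machinery. Trees are dendropy objects; newick in/out.
"""

from __future__ import annotations

import numpy as np
import dendropy
from dendropy.calculate import treecompare

from .core_io import AlignmentMatrix
from .divergence import DistanceMatrix

_BASE_BIT = {ord("A"): 1, ord("C"): 2, ord("G"): 4, ord("T"): 8}


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n")


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Classical neighbor joining on a p-distance matrix.

    Deterministic: ties in the Q criterion are broken by the smallest leaf
    label contained in each candidate cluster pair. Branch lengths follow
    the standard NJ formulas (negative lengths are kept as computed).
    Returns an unrooted tree with a trifurcating seed node.
    """
    ids = list(dist.ids)
    m = len(ids)
    if m < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = {
        frozenset((i, j)): float(dist.p_distance[i, j])
        for i in range(m)
        for j in range(i + 1, m)
    }
    # each active cluster: (min leaf label for tie-breaks, newick fragment)
    active: dict[int, tuple[str, str]] = {
        i: (ids[i], _quote(ids[i])) for i in range(m)
    }
    next_id = m
    while len(active) > 3:
        keys = sorted(active, key=lambda k: active[k][0])
        r = len(keys)
        row_sum = {i: sum(d[frozenset((i, j))] for j in keys if j != i) for i in keys}
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                i, j = keys[ii], keys[jj]
                q = (r - 2) * d[frozenset((i, j))] - row_sum[i] - row_sum[j]
                tag = tuple(sorted((active[i][0], active[j][0])))
                if best is None or (q, tag) < (best[0], best[1]):
                    best = (q, tag, i, j)
        _, _, i, j = best
        dij = d[frozenset((i, j))]
        li = 0.5 * dij + (row_sum[i] - row_sum[j]) / (2 * (r - 2))
        lj = dij - li
        frag = f"({active[i][1]}:{li:.10g},{active[j][1]}:{lj:.10g})"
        label = min(active[i][0], active[j][0])
        for k in keys:
            if k in (i, j):
                continue
            dk = 0.5 * (d[frozenset((i, k))] + d[frozenset((j, k))] - dij)
            d[frozenset((next_id, k))] = dk
        del active[i], active[j]
        active[next_id] = (label, frag)
        next_id += 1
    ks = sorted(active, key=lambda k: active[k][0])
    a, b, c = ks
    dab = d[frozenset((a, b))]
    dac = d[frozenset((a, c))]
    dbc = d[frozenset((b, c))]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    newick = (
        f"({active[a][1]}:{la:.10g},{active[b][1]}:{lb:.10g},{active[c][1]}:{lc:.10g});"
    )
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def fitch_score(tree: dendropy.Tree, alignment: AlignmentMatrix) -> int:
    """Minimum substitution count over analyzed columns (Fitch's algorithm).

    Columns containing a gap or N are excluded (complete deletion). The
    tree is evaluated unrooted by rooting the recursion at its first leaf,
    which leaves the score unchanged.
    """
    leaf_labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    if leaf_labels != sorted(alignment.ids):
        raise ValueError(
            f"tree leaves {leaf_labels} do not match alignment ids {sorted(alignment.ids)}"
        )
    mat = alignment.matrix
    keep = np.ones(alignment.length, dtype=bool)
    for row in mat:
        keep &= np.isin(row, list(_BASE_BIT))
    mat = mat[:, keep]
    L = mat.shape[1]
    if L == 0:
        return 0
    masks = {}
    for idx, rec_id in enumerate(alignment.ids):
        bits = np.zeros(L, dtype=np.uint8)
        for code, bit in _BASE_BIT.items():
            bits[mat[idx] == code] = bit
        masks[rec_id] = bits

    adjacency: dict[dendropy.Node, list[dendropy.Node]] = {}
    for edge in tree.preorder_edge_iter():
        if edge.head_node is None or edge.tail_node is None:
            continue
        adjacency.setdefault(edge.tail_node, []).append(edge.head_node)
        adjacency.setdefault(edge.head_node, []).append(edge.tail_node)

    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    root_leaf = leaves[0]
    score = np.zeros(L, dtype=np.int64)

    def subtree_mask(node, parent) -> np.ndarray:
        if node.is_leaf():
            return masks[node.taxon.label]
        acc = None
        for child in adjacency[node]:
            if child is parent:
                continue
            cm = subtree_mask(child, node)
            if acc is None:
                acc = cm
            else:
                inter = acc & cm
                empty = inter == 0
                score[empty] += 1
                acc = np.where(empty, acc | cm, inter)
        return acc

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * len(adjacency) + 100))
    try:
        rest = subtree_mask(adjacency[root_leaf][0], root_leaf)
    finally:
        sys.setrecursionlimit(old_limit)
    score[(rest & masks[root_leaf.taxon.label]) == 0] += 1
    return int(score.sum())


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds distance: symmetric difference of non-trivial bipartitions."""
    l1 = {l.taxon.label for l in t1.leaf_node_iter()}
    l2 = {l.taxon.label for l in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=ns
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=ns
    )
    a.is_rooted = False
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))
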