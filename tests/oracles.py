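"""Independent brute-force oracles for cross-checking the fast implementations.

Everything here is deliberately naive: explicit Python loops over strings,
no numpy, no shared code with the package internals.
"""

from __future__ import annotations

from itertools import combinations

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _minimal_period(motif: str) -> int:
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return d
    return p


def ssr_oracle(s: str, min_units: dict[int, int]) -> set[tuple[str, int, int, int, int]]:
    """All maximal perfect SSR tracts as (motif, period, units, start, end).

    Enumerates every (start, period) pair, counts whole motif copies, and
    keeps starts that anchor a maximal repetitive run.
    """
    n = len(s)
    hits = set()
    for p, thr in min_units.items():
        for start in range(n - p + 1):
            motif = s[start : start + p]
            if "N" in motif or _minimal_period(motif) != p:
                continue
            u = 1
            while s[start + u * p : start + (u + 1) * p] == motif:
                u += 1
            if u < thr:
                continue
            # leftmost anchor of the repetitive run: the position before
            # must not continue the period-p match chain
            if start > 0 and s[start - 1] != "N" and s[start - 1] == s[start - 1 + p]:
                continue
            hits.add((motif, p, u, start, start + p * u))
    return hits


def _mismatch(x: str, y: str) -> bool:
    return x != y or x == "N"


def repeat_oracle(
    s: str, min_len: int, k: int, types: tuple[str, ...] = ("F", "R", "C", "P")
) -> set[tuple[str, tuple[int, int], tuple[int, int], int]]:
    """All maximal repeat pairs as (type, copy1, copy2, mismatches).

    For every anchor pair the window is greedily extended right to the
    longest run within the mismatch budget, then kept only if it cannot be
    extended left — exactly one enumeration per maximal window.
    """
    n = len(s)
    found = set()

    def norm(type_, c1, c2, mm):
        if c2 < c1:
            c1, c2 = c2, c1
        if c1 != c2:
            found.add((type_, c1, c2, mm))

    for type_ in types:
        if type_ in ("F", "C"):
            tr = (lambda c: c) if type_ == "F" else (lambda c: COMP[c])
            for a in range(n):
                for b in range(a + 1, n):
                    mm = 0
                    L = 0
                    while b + L < n:
                        bad = _mismatch(s[a + L], tr(s[b + L]))
                        if mm + bad > k:
                            break
                        mm += bad
                        L += 1
                    if L < min_len:
                        continue
                    # left-maximal: extending to (a-1, b-1) must bust the budget
                    if a > 0:
                        bad_left = _mismatch(s[a - 1], tr(s[b - 1]))
                        if not (bad_left and mm == k):
                            continue
                    norm(type_, (a, a + L), (b, b + L), mm)
        else:  # R, P: copy1 position a+t pairs with position e-t
            tr = (lambda c: c) if type_ == "R" else (lambda c: COMP[c])
            for a in range(n):
                for e in range(n):
                    mm = 0
                    L = 0
                    while a + L < n and e - L >= 0:
                        bad = _mismatch(s[a + L], tr(s[e - L]))
                        if mm + bad > k:
                            break
                        mm += bad
                        L += 1
                    if L < min_len:
                        continue
                    if a > 0 and e + 1 < n:
                        bad_left = _mismatch(s[a - 1], tr(s[e + 1]))
                        if not bad_left or mm < k:
                            continue
                    norm(type_, (a, a + L), (e - L + 1, e + 1), mm)
    return found


def pi_oracle(rows: list[str]) -> float:
    """Nucleotide diversity by explicit pairwise loops (complete deletion)."""
    n = len(rows)
    L = len(rows[0])
    keep = [
        c for c in range(L) if all(r[c] in "ACGT" for r in rows)
    ]
    if not keep:
        raise ValueError("no analyzable columns")
    total = 0.0
    for i, j in combinations(range(n), 2):
        diff = sum(1 for c in keep if rows[i][c] != rows[j][c])
        total += diff / len(keep)
    return total / (n * (n - 1) / 2)


def s_pi_counts_oracle(rows: list[str]) -> tuple[int, int]:
    """(variable, parsimony-informative) site counts, complete deletion."""
    L = len(rows[0])
    S = PI = 0
    for c in range(L):
        col = [r[c] for r in rows]
        if any(b not in "ACGT" for b in col):
            continue
        counts = {b: col.count(b) for b in set(col)}
        if len(counts) >= 2:
            S += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                PI += 1
    return S, PI


def p_distance_oracle(row_a: str, row_b: str) -> tuple[int, float]:
    """(n_diff, p_distance) with pairwise deletion, explicit loop."""
    compared = ndiff = 0
    for x, y in zip(row_a, row_b):
        if x in "ACGT" and y in "ACGT":
            compared += 1
            ndiff += x != y
    if compared == 0:
        raise ValueError("no comparable columns")
    return ndiff, ndiff / compared


def all_unrooted_topologies(labels: list[str]) -> list[str]:
    """Every unrooted binary topology over the labels, as newick strings.

    Built by stepwise addition: each new leaf is inserted into every edge
    of every smaller topology ((2n-5)!! trees).
    """
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")

    # tree as nested tuples; the root is an (x, y, z) trifurcation
    def edges_inserted(tree, leaf):
        # returns all trees with `leaf` inserted into each edge of `tree`
        out = []

        def insert_into(node, path):
            # replace node at path with (node, leaf)
            def rebuild(t, path, repl):
                if not path:
                    return repl
                t = list(t)
                t[path[0]] = rebuild(t[path[0]], path[1:], repl)
                return tuple(t)

            out.append(rebuild(tree, path, (node, leaf)))
            if isinstance(node, tuple):
                for idx, child in enumerate(node):
                    insert_into(child, path + [idx])

        for idx, child in enumerate(tree):
            insert_into(child, [idx])
        return out

    trees = [(labels[0], labels[1], labels[2])]
    for leaf in labels[3:]:
        trees = [t2 for t in trees for t2 in edges_inserted(t, leaf)]

    def to_newick(t):
        if isinstance(t, str):
            return t
        return "(" + ",".join(to_newick(c) for c in t) + ")"

    return [to_newick(t) + ";" for t in trees]


def fitch_oracle(adjacency, leaf_states: dict, internal_nodes: list) -> int:
    """Minimum substitutions for one column by trying every internal labelling."""
    from itertools import product

    edges = set()
    for u, nbrs in adjacency.items():
        for v in nbrs:
            edges.add(frozenset((u, v)))
    best = None
    for combo in product("ACGT", repeat=len(internal_nodes)):
        states = dict(leaf_states)
        states.update(zip(internal_nodes, combo))
        cost = sum(1 for e in edges if len({states[u] for u in e}) > 1)
        if best is None or cost < best:
            best = cost
    return best


def bipartitions_oracle(adjacency, leaves: set) -> set[frozenset]:
    """Non-trivial bipartitions by deleting each internal edge (leaf-set side)."""
    out = set()
    nodes = list(adjacency)
    for u in nodes:
        for v in adjacency[u]:
            # collect leaves on v's side of edge (u, v)
            stack, seen, side = [v], {u, v}, set()
            while stack:
                x = stack.pop()
                if x in leaves:
                    side.add(x)
                for y in adjacency[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            if 1 < len(side) < len(leaves) - 1:
                out.add(frozenset(side))
    return out
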