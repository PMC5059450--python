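"""Matrix representation with parsimony (MRP) supertree assembly.

Source trees are encoded as binary characters (Baum-Ragan coding: taxa
subtended by a node score 1, other taxa of that source tree 0, taxa
absent from the source tree '?'), rooted with an all-zero hypothetical
outgroup.  Most-parsimonious supertrees are found either exhaustively
(small taxon sets; the oracle) or by random-addition + NNI hill-climbing
(the workhorse), summarized by strict/majority consensus, and conflict
is pruned with rooted maximum agreement subtrees (MAST).

Parsimony scoring treats '?' as a free state (assigned whatever
minimizes changes).  Scoring of binary trees uses a bit-parallel Fitch
pass (all characters packed into Python integers); polytomous trees go
through Hartigan's generalization, which is exact on multifurcations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .phylo_core import (
    LabelError,
    TreeError,
    clade_sets,
    is_binary,
    tip_labels,
)

OUTGROUP = "MRP_Outgroup"

__all__ = [
    "OUTGROUP",
    "MRPMatrix",
    "OverlapReport",
    "SearchSizeError",
    "check_overlap",
    "mrp_encode",
    "fitch_score",
    "exhaustive_search",
    "heuristic_search",
    "consensus",
    "mast_pair",
    "iterated_mast",
]


class SearchSizeError(ValueError):
    """Taxon set too large for exhaustive enumeration."""


# ---------------------------------------------------------------------------
# matrix and overlap report


@dataclass
class MRPMatrix:
    """Taxa x binary characters with missing data.

    ``taxa`` starts with the hypothetical outgroup; ``data`` holds
    0/1 and -1 for '?'.  ``provenance[j]`` records which source tree and
    node produced column ``j``.
    """

    taxa: list[str]
    data: np.ndarray  # int8, shape (n_taxa, n_cols); -1 encodes '?'
    provenance: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    @property
    def real_taxa(self) -> list[str]:
        return [t for t in self.taxa if t != OUTGROUP]

    def as_nexus(self) -> str:
        sym = {1: "1", 0: "0", -1: "?"}
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"  DIMENSIONS NTAX={self.n_taxa} NCHAR={self.n_columns};",
            '  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
            "  MATRIX",
        ]
        for i, taxon in enumerate(self.taxa):
            row = "".join(sym[int(v)] for v in self.data[i])
            lines.append(f"    {taxon}  {row}")
        lines += ["  ;", "END;", ""]
        return "\n".join(lines)

    def as_tnt(self) -> str:
        sym = {1: "1", 0: "0", -1: "?"}
        lines = ["xread", f"{self.n_columns} {self.n_taxa}"]
        for i, taxon in enumerate(self.taxa):
            row = "".join(sym[int(v)] for v in self.data[i])
            lines.append(f"{taxon} {row}")
        lines.append(";")
        return "\n".join(lines)


@dataclass
class OverlapReport:
    """Pairwise shared-taxon counts and connectivity of the overlap graph."""

    labels: list[str]  # identifiers of the source trees (stringified index)
    shared: np.ndarray  # shape (k, k); diagonal = tree size
    connected: bool

    @property
    def valid(self) -> bool:
        return self.connected


def check_overlap(source_trees: list[dendropy.Tree]) -> OverlapReport:
    """Overlap report for a source-tree set.

    The dataset is valid when the graph whose edges join trees sharing at
    least two taxa is connected.
    """
    if not source_trees:
        raise ValueError("need at least one source tree")
    tip_sets = [tip_labels(t) for t in source_trees]
    k = len(tip_sets)
    shared = np.zeros((k, k), dtype=int)
    for i in range(k):
        shared[i, i] = len(tip_sets[i])
        for j in range(i + 1, k):
            shared[i, j] = shared[j, i] = len(tip_sets[i] & tip_sets[j])
    # BFS over edges with >=2 shared taxa
    seen = {0}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in range(k):
            if j not in seen and i != j and shared[i, j] >= 2:
                seen.add(j)
                stack.append(j)
    return OverlapReport(
        labels=[str(i) for i in range(k)],
        shared=shared,
        connected=(len(seen) == k),
    )


def mrp_encode(source_trees: list[dendropy.Tree]) -> MRPMatrix:
    """Baum-Ragan MRP encoding of a set of rooted source trees.

    One column per informative internal node (root excluded) per source
    tree; the taxon list is the union over all source trees plus the
    all-zero outgroup.  Source trees with fewer than 3 tips contribute no
    columns (warned, not fatal).
    """
    union: set[str] = set()
    for t in source_trees:
        union |= tip_labels(t)
    taxa = [OUTGROUP] + sorted(union)
    index = {t: i for i, t in enumerate(taxa)}

    columns: list[np.ndarray] = []
    provenance: list[tuple[int, int]] = []
    for ti, tree in enumerate(source_trees):
        tree_tips = tip_labels(tree)
        if len(tree_tips) < 3:
            warnings.warn(
                f"source tree {ti} has <3 tips; contributes no characters"
            )
            continue
        for ni, node in enumerate(tree.preorder_internal_node_iter()):
            if node.parent_node is None:
                continue  # root column uninformative given the outgroup
            inside = {l.taxon.label for l in node.leaf_iter()}
            outside = tree_tips - inside
            if len(inside) < 2 or len(outside) < 1:
                continue
            col = np.full(len(taxa), -1, dtype=np.int8)
            col[0] = 0  # outgroup
            for t in inside:
                col[index[t]] = 1
            for t in outside:
                col[index[t]] = 0
            columns.append(col)
            provenance.append((ti, ni))
    data = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(taxa), 0), dtype=np.int8)
    )
    return MRPMatrix(taxa=taxa, data=data, provenance=provenance)


# ---------------------------------------------------------------------------
# parsimony scoring

# Binary characters are scored with state *sets* per node, encoded as two
# bitmasks over columns (has0, has1).  A '?' leaf carries {0,1}.


def _leaf_masks(matrix: MRPMatrix, labels: list[str]):
    """Per-taxon (has0, has1) column bitmasks for the named tips."""
    idx = {t: i for i, t in enumerate(matrix.taxa)}
    full = (1 << matrix.n_columns) - 1
    masks = {}
    for lab in labels:
        if lab not in idx:
            raise LabelError(f"tip {lab!r} not in matrix")
        row = matrix.data[idx[lab]]
        h0 = h1 = 0
        for j, v in enumerate(row):
            if v == 0:
                h0 |= 1 << j
            elif v == 1:
                h1 |= 1 << j
            else:
                h0 |= 1 << j
                h1 |= 1 << j
        masks[lab] = (h0, h1)
    return masks, full


def _fitch_tuple(tr, masks, full):
    """Bit-parallel Fitch pass over a binary tuple-tree; returns (h0,h1,cost)."""
    if not isinstance(tr, tuple):
        h0, h1 = masks[tr]
        return h0, h1, 0
    a, b = tr
    a0, a1, ca = _fitch_tuple(a, masks, full)
    b0, b1, cb = _fitch_tuple(b, masks, full)
    i0 = a0 & b0
    i1 = a1 & b1
    ne = i0 | i1
    miss = full & ~ne
    h0 = i0 | ((a0 | b0) & miss)
    h1 = i1 | ((a1 | b1) & miss)
    return h0, h1, ca + cb + miss.bit_count()


def _hartigan_cost(tree: dendropy.Tree, matrix: MRPMatrix) -> int:
    """Exact minimum-change count on a (possibly polytomous) rooted tree.

    Hartigan's algorithm, vectorized over columns; ambiguous leaves
    ('?') vote for both states.
    """
    labels = sorted(tip_labels(tree))
    idx = {t: i for i, t in enumerate(matrix.taxa)}
    for lab in labels:
        if lab not in idx:
            raise LabelError(f"tip {lab!r} not in matrix")
    ncol = matrix.n_columns
    cost = np.zeros(ncol, dtype=np.int64)
    pref: dict[int, np.ndarray] = {}  # node id -> (ncol, 2) bool
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            row = matrix.data[idx[node.taxon.label]]
            p = np.zeros((ncol, 2), dtype=bool)
            p[:, 0] = (row == 0) | (row == -1)
            p[:, 1] = (row == 1) | (row == -1)
            pref[id(node)] = p
        else:
            kids = node.child_nodes()
            votes = np.zeros((ncol, 2), dtype=np.int64)
            for c in kids:
                votes += pref.pop(id(c))
            kmax = votes.max(axis=1)
            cost += len(kids) - kmax
            pref[id(node)] = votes == kmax[:, None]
    return int(cost.sum())


def fitch_score(tree: dendropy.Tree, matrix: MRPMatrix) -> int:
    """Parsimony length of ``tree`` on ``matrix``.

    Tips must be a subset of the matrix taxa (the outgroup row counts if
    present as a tip).  Polytomies are scored as given, not resolved.
    """
    if is_binary(tree):
        labels = sorted(tip_labels(tree))
        masks, full = _leaf_masks(matrix, labels)
        tup = _dendropy_to_tuple(tree)
        return _fitch_tuple(tup, masks, full)[2]
    return _hartigan_cost(tree, matrix)


# ---------------------------------------------------------------------------
# tuple-tree helpers (internal search representation)


def _dendropy_to_tuple(tree: dendropy.Tree):
    def rec(node):
        if node.is_leaf():
            return node.taxon.label
        kids = [rec(c) for c in node.child_nodes()]
        t = kids[0]
        for k in kids[1:]:  # left-comb any polytomy (only used for binary)
            t = (t, k)
        return t

    return rec(tree.seed_node)


def _tuple_to_dendropy(tr) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    def rec(tup, parent):
        node = dendropy.Node()
        parent.add_child(node)
        if isinstance(tup, tuple):
            rec(tup[0], node)
            rec(tup[1], node)
        else:
            node.taxon = tns.require_taxon(label=tup)
        return node

    if isinstance(tr, tuple):
        rec(tr[0], tree.seed_node)
        rec(tr[1], tree.seed_node)
    else:
        tree.seed_node.taxon = tns.require_taxon(label=tr)
    tree.is_rooted = True
    return tree


def _canon(tr) -> str:
    """Canonical string form of a tuple-tree (order-insensitive)."""
    if not isinstance(tr, tuple):
        return tr
    a, b = _canon(tr[0]), _canon(tr[1])
    return f"({a},{b})" if a <= b else f"({b},{a})"


def _insert_everywhere(tr, leaf):
    yield (tr, leaf)  # above the current root
    if isinstance(tr, tuple):
        a, b = tr
        for na in _insert_everywhere(a, leaf):
            yield (na, b)
        for nb in _insert_everywhere(b, leaf):
            yield (a, nb)


def _all_rooted_trees(taxa: list[str]):
    trees = [taxa[0]]
    for leaf in taxa[1:]:
        trees = [t for tr in trees for t in _insert_everywhere(tr, leaf)]
    return trees


def _nni_neighbors(tr):
    if not isinstance(tr, tuple):
        return
    a, b = tr
    if isinstance(b, tuple):
        c, d = b
        yield (c, (a, d))
        yield (d, (a, c))
    if isinstance(a, tuple):
        c, d = a
        yield ((c, b), d)
        yield ((d, b), c)
    for na in _nni_neighbors(a):
        yield (na, b)
    for nb in _nni_neighbors(b):
        yield (a, nb)


def _score_with_outgroup(tr, masks, full):
    return _fitch_tuple((OUTGROUP, tr), masks, full)[2]


def _search_masks(matrix: MRPMatrix):
    masks, full = _leaf_masks(matrix, matrix.taxa)
    return masks, full


# ---------------------------------------------------------------------------
# searches


def exhaustive_search(
    matrix: MRPMatrix, max_taxa: int = 9
) -> tuple[list[dendropy.Tree], int]:
    """All most-parsimonious rooted binary trees, by full enumeration.

    Enumerates every rooted binary topology over the matrix's real taxa
    (the outgroup sits above the root, fixing the rooting) and returns
    the ties at minimum length together with that length.
    """
    taxa = matrix.real_taxa
    if len(taxa) > max_taxa:
        raise SearchSizeError(
            f"{len(taxa)} taxa exceeds exhaustive limit {max_taxa}"
        )
    masks, full = _search_masks(matrix)
    best = None
    mpts: list = []
    for tr in _all_rooted_trees(taxa):
        s = _score_with_outgroup(tr, masks, full)
        if best is None or s < best:
            best, mpts = s, [tr]
        elif s == best:
            mpts.append(tr)
    return [_tuple_to_dendropy(t) for t in mpts], int(best)


def _random_addition_tree(taxa, masks, full, rng):
    order = list(taxa)
    rng.shuffle(order)
    tr = order[0]
    for leaf in order[1:]:
        best_s, best_t = None, None
        for cand in _insert_everywhere(tr, leaf):
            s = _score_with_outgroup(cand, masks, full)
            if best_s is None or s < best_s:
                best_s, best_t = s, cand
        tr = best_t
    return tr


def heuristic_search(
    matrix: MRPMatrix,
    replicates: int = 20,
    seed: int = 0,
    max_ties: int = 200,
) -> tuple[list[dendropy.Tree], int]:
    """Random-addition + NNI hill-climbing parsimony search.

    Each replicate builds a stepwise-addition starting tree from a random
    taxon order, then takes improving NNI moves until a local optimum.
    Equal-score neighbours of optima are explored (up to ``max_ties``
    distinct trees) so consensus sees the tie set.  Reproducible given
    ``seed``; returns (best trees found, best length).
    """
    import random

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    taxa = matrix.real_taxa
    masks, full = _search_masks(matrix)
    rng = random.Random(seed)
    best_score = None
    best_set: dict[tuple, object] = {}

    for _ in range(replicates):
        tr = _random_addition_tree(taxa, masks, full, rng)
        s = _score_with_outgroup(tr, masks, full)
        improved = True
        while improved:
            improved = False
            for nb in _nni_neighbors(tr):
                ns = _score_with_outgroup(nb, masks, full)
                if ns < s:
                    tr, s = nb, ns
                    improved = True
                    break
        if best_score is None or s < best_score:
            best_score = s
            best_set = {_canon(tr): tr}
        elif s == best_score:
            best_set.setdefault(_canon(tr), tr)

    # plateau sweep: collect equal-score neighbours of the optima
    frontier = list(best_set.values())
    while frontier and len(best_set) < max_ties:
        tr = frontier.pop()
        for nb in _nni_neighbors(tr):
            if _score_with_outgroup(nb, masks, full) == best_score:
                key = _canon(nb)
                if key not in best_set:
                    best_set[key] = nb
                    frontier.append(nb)
                    if len(best_set) >= max_ties:
                        break
    return [_tuple_to_dendropy(t) for t in best_set.values()], int(best_score)


# ---------------------------------------------------------------------------
# consensus and MAST


def _tree_from_clades(all_tips: frozenset, clades: set[frozenset]) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    nodes = sorted(clades | {all_tips}, key=lambda c: (-len(c), sorted(c)))

    def build(clade, node):
        remaining = set(clade)
        for sub in nodes:
            if sub < clade and sub <= frozenset(remaining) and len(sub) >= 2:
                # take only maximal sub-clades
                if any(sub < other < clade for other in nodes):
                    continue
                child = dendropy.Node()
                node.add_child(child)
                build(sub, child)
                remaining -= sub
        for lab in sorted(remaining):
            leaf = dendropy.Node()
            leaf.taxon = tns.require_taxon(label=lab)
            node.add_child(leaf)

    build(all_tips, tree.seed_node)
    return tree


def consensus(trees: list[dendropy.Tree], kind: str = "strict") -> dendropy.Tree:
    """Strict or majority-rule consensus of rooted trees on one tip set."""
    if kind not in ("strict", "majority"):
        raise ValueError(f"unknown consensus kind: {kind!r}")
    if not trees:
        raise ValueError("no trees given")
    tips = tip_labels(trees[0])
    for t in trees[1:]:
        if tip_labels(t) != tips:
            raise LabelError("consensus requires identical tip sets")
    counts: dict[frozenset, int] = {}
    for t in trees:
        for c in clade_sets(t):
            counts[c] = counts.get(c, 0) + 1
    n = len(trees)
    thr = n if kind == "strict" else n / 2.0
    keep = {
        c
        for c, k in counts.items()
        if (k >= thr if kind == "strict" else k > thr)
    }
    return _tree_from_clades(frozenset(tips), keep)


def _restrict(tree: dendropy.Tree, labels: set[str]) -> dendropy.Tree:
    sub = tree.extract_tree_with_taxa_labels(labels=list(labels))
    sub.is_rooted = True
    # drop branch lengths: MRP topology only
    for e in sub.preorder_edge_iter():
        e.length = None
    return sub


def mast_pair(tree1: dendropy.Tree, tree2: dendropy.Tree) -> dendropy.Tree:
    """Rooted maximum agreement subtree of two binary trees.

    Dynamic programming over node pairs; among equal-size agreement sets
    the lexicographically smallest taxon set wins, making the result
    deterministic and symmetric in its arguments.  Disjoint tip sets
    yield an empty tree with a warning.
    """
    shared = tip_labels(tree1) & tip_labels(tree2)
    if not shared:
        warnings.warn("tip sets are disjoint; agreement subtree is empty")
        return dendropy.Tree()
    t1 = _restrict(tree1, shared)
    t2 = _restrict(tree2, shared)
    if not (is_binary(t1) and is_binary(t2)):
        raise TreeError("mast_pair requires binary trees (after restriction)")

    leaves1 = {id(n): frozenset(l.taxon.label for l in n.leaf_iter())
               for n in t1.preorder_node_iter()}
    leaves2 = {id(n): frozenset(l.taxon.label for l in n.leaf_iter())
               for n in t2.preorder_node_iter()}

    def better(a, b):
        if a[0] != b[0]:
            return a if a[0] > b[0] else b
        return a if a[1] <= b[1] else b

    memo: dict[tuple[int, int], tuple[int, tuple]] = {}

    def solve(u, v):
        key = (id(u), id(v))
        if key in memo:
            return memo[key]
        if u.is_leaf():
            lab = u.taxon.label
            res = (1, (lab,)) if lab in leaves2[id(v)] else (0, ())
        elif v.is_leaf():
            lab = v.taxon.label
            res = (1, (lab,)) if lab in leaves1[id(u)] else (0, ())
        else:
            u1, u2 = u.child_nodes()
            v1, v2 = v.child_nodes()
            res = (0, ())
            for cand in (
                solve(u1, v), solve(u2, v), solve(u, v1), solve(u, v2)
            ):
                res = better(res, cand)
            for (x1, y1), (x2, y2) in (((u1, v1), (u2, v2)),
                                       ((u1, v2), (u2, v1))):
                s1, set1 = solve(x1, y1)
                s2, set2 = solve(x2, y2)
                merged = tuple(sorted(set1 + set2))
                res = better(res, (s1 + s2, merged))
        memo[key] = res
        return res

    size, labels = solve(t1.seed_node, t2.seed_node)
    if size == 0:
        warnings.warn("no agreement subtree found")
        return dendropy.Tree()
    return _restrict(tree1, set(labels))


def iterated_mast(trees: list[dendropy.Tree]) -> dendropy.Tree:
    """Heuristic multi-tree MAST: fold pairwise MAST in input order."""
    if not trees:
        raise ValueError("no trees given")
    acc = trees[0]
    for t in trees[1:]:
        acc = mast_pair(acc, t)
    return acc
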