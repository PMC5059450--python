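"""Tree data model and traversal utilities.

All other stages of the pipeline (supertree assembly, fossil time-scaling,
birth-death shift inference, rate-through-time extraction) build on this
module.  Trees are :class:`dendropy.Tree` objects; this module adds the
age bookkeeping the pipeline needs.

Conventions
-----------
* Ages are in Ma before present; the present is 0 and ages increase into
  the past.  Dated trees carry a float ``node.age`` on every node and all
  tips of an extant-only tree sit at age 0.
* Branch durations are in Myr and equal parent age minus child age.
* A branch is said to *cross* an age ``a`` when ``child.age <= a <
  parent.age`` (half-open, child-inclusive), which makes bin counting at
  node ages unambiguous.
* Underscores in labels are preserved verbatim on read and write.
"""

from __future__ import annotations

from typing import Iterable

import dendropy

__all__ = [
    "TreeError",
    "ParseError",
    "LabelError",
    "parse_tree",
    "parse_trees",
    "write_tree",
    "mrca",
    "branches_crossing",
    "tip_labels",
    "clade_sets",
    "rf_distance",
    "set_ages_from_lengths",
    "set_lengths_from_ages",
    "is_binary",
    "root_age",
]


class TreeError(ValueError):
    """Invalid tree state or operation."""


class ParseError(TreeError):
    """Malformed Newick/NEXUS input."""


class LabelError(TreeError):
    """A requested tip label is absent from the tree."""


def _schema_of(text: str) -> str:
    return "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"


def _check_unique_tips(tree: dendropy.Tree) -> None:
    seen: set[str] = set()
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else None
        if label is None:
            raise ParseError("unlabelled tip in input tree")
        if label in seen:
            raise ParseError(f"duplicate tip label: {label!r}")
        seen.add(label)


def parse_tree(text: str) -> dendropy.Tree:
    """Parse a single tree from Newick or a NEXUS TREES block.

    Rooting is taken as given (trees are treated as rooted); polytomies
    and quoted labels are preserved.  Raises :class:`ParseError` on
    malformed input or duplicate tip labels.
    """
    schema = _schema_of(text)
    try:
        tree = dendropy.Tree.get(
            data=text, schema=schema, preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"could not parse {schema} input: {exc}") from exc
    tree.is_rooted = True
    _check_unique_tips(tree)
    return tree


def parse_trees(text: str) -> list[dendropy.Tree]:
    """Parse every tree in the input (multi-tree NEXUS or newline Newick)."""
    schema = _schema_of(text)
    try:
        trees = dendropy.TreeList.get(
            data=text, schema=schema, preserve_underscores=True
        )
    except Exception as exc:
        raise ParseError(f"could not parse {schema} input: {exc}") from exc
    out = []
    for tree in trees:
        tree.is_rooted = True
        _check_unique_tips(tree)
        out.append(tree)
    return out


def write_tree(tree: dendropy.Tree, format: str = "newick") -> str:
    """Serialize a tree; ``format`` is ``newick`` or ``nexus``."""
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported format: {format!r}")
    return tree.as_string(schema=format, unquoted_underscores=True)


def tip_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def mrca(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of the named tips.

    Returns the unique deepest node ancestral to all of ``taxa``; raises
    :class:`LabelError` if any label is missing from the tree.
    """
    taxa = set(taxa)
    if not taxa:
        raise LabelError("empty taxon set")
    present = tip_labels(tree)
    missing = taxa - present
    if missing:
        raise LabelError(f"labels not in tree: {sorted(missing)}")
    if len(taxa) == 1:
        (label,) = taxa
        return tree.find_node_with_taxon_label(label)
    node = tree.mrca(taxon_labels=list(taxa))
    if node is None:
        raise LabelError(f"no common ancestor found for {sorted(taxa)}")
    return node


def set_ages_from_lengths(tree: dendropy.Tree, ultrametricity_precision=1e-6):
    """Assign ``node.age`` from edge lengths of an ultrametric tree."""
    tree.calc_node_ages(ultrametricity_precision=ultrametricity_precision)
    return tree


def set_lengths_from_ages(tree: dendropy.Tree) -> dendropy.Tree:
    """Set each edge length to parent age minus child age."""
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age
    return tree


def root_age(tree: dendropy.Tree) -> float:
    age = getattr(tree.seed_node, "age", None)
    if age is None:
        raise TreeError("tree is not dated (no node ages set)")
    return age


def branches_crossing(tree: dendropy.Tree, age: float) -> list[dendropy.Node]:
    """Branches alive at ``age``, as the child node of each crossing branch.

    A branch crosses when ``child.age <= age < parent.age``.  ``age`` must
    lie in ``[0, root age]``.
    """
    top = root_age(tree)
    if not (0.0 <= age <= top):
        raise TreeError(f"age {age} outside [0, {top}]")
    out = []
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        if node.age <= age < parent.age:
            out.append(node)
    return out


def is_binary(tree: dendropy.Tree) -> bool:
    for node in tree.preorder_internal_node_iter():
        if len(node.child_nodes()) != 2:
            return False
    return True


def clade_sets(tree: dendropy.Tree, include_trivial: bool = False):
    """Tip-label sets of internal nodes (root and leaves excluded by default).

    These rooted clades ("clusters") are what consensus construction and
    Robinson-Foulds comparison operate on.
    """
    all_tips = frozenset(tip_labels(tree))
    out: set[frozenset[str]] = set()
    for node in tree.preorder_internal_node_iter():
        tips = frozenset(l.taxon.label for l in node.leaf_iter())
        if not include_trivial and (tips == all_tips or len(tips) < 2):
            continue
        out.add(tips)
    if include_trivial:
        out.add(all_tips)
    return out


def rf_distance(tree1: dendropy.Tree, tree2: dendropy.Tree) -> int:
    """Rooted Robinson-Foulds distance: symmetric difference of clade sets.

    Requires identical tip sets.
    """
    t1, t2 = tip_labels(tree1), tip_labels(tree2)
    if t1 != t2:
        raise LabelError("tip sets differ; RF distance undefined")
    return len(clade_sets(tree1) ^ clade_sets(tree2))
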