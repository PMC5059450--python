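"""Fossil-calibrated time-scaling of an undated supertree.

Fossil first occurrences supply hard *minimum* ages on nodes (stem or
crown placement).  The 'equal' rule dates the remaining nodes: each
maximal chain of uncalibrated nodes between a dated (or root) ancestor
and its oldest dated descendant divides the free time interval equally
among its branches, every branch is at least ``min_bl`` Myr long, and
the root is pushed older when nothing else can give.  Calibration sets
can be perturbed (moved to a parent or child node) for the robustness
reruns of the pipeline.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass

import dendropy
import pandas as pd

from .phylo_core import TreeError, mrca, set_lengths_from_ages

__all__ = [
    "Calibration",
    "load_calibrations",
    "save_calibrations",
    "resolve_calibrations",
    "equal_scale",
    "perturb_calibrations",
]


@dataclass(frozen=True)
class Calibration:
    """A fossil first-occurrence constraint.

    ``clade`` is an unordered set of tip labels; the constrained node is
    their MRCA (crown placement) or its parent (stem placement); ``age``
    is the fossil age in Ma, a minimum for the node's true age.
    """

    clade: frozenset[str]
    placement: str  # "crown" | "stem"
    age: float

    def __post_init__(self):
        if self.placement not in ("crown", "stem"):
            raise ValueError(f"placement must be crown|stem, got {self.placement!r}")
        if self.age <= 0:
            raise ValueError("calibration age must be > 0")


def load_calibrations(path: str) -> list[Calibration]:
    """Read a calibration CSV: clade_taxa (';'-separated), placement, age_ma."""
    df = pd.read_csv(path)
    needed = {"clade_taxa", "placement", "age_ma"}
    if not needed <= set(df.columns):
        raise ValueError(f"calibration CSV needs columns {sorted(needed)}")
    out = []
    for _, row in df.iterrows():
        taxa = frozenset(t.strip() for t in str(row["clade_taxa"]).split(";") if t.strip())
        out.append(Calibration(taxa, str(row["placement"]).strip(), float(row["age_ma"])))
    return out


def save_calibrations(cals: list[Calibration], path: str) -> None:
    pd.DataFrame(
        {
            "clade_taxa": [";".join(sorted(c.clade)) for c in cals],
            "placement": [c.placement for c in cals],
            "age_ma": [c.age for c in cals],
        }
    ).to_csv(path, index=False)


def _cal_node(tree: dendropy.Tree, cal: Calibration) -> dendropy.Node:
    node = mrca(tree, cal.clade)
    if cal.placement == "stem" and node.parent_node is not None:
        node = node.parent_node
    return node


def resolve_calibrations(
    tree: dendropy.Tree, cals: list[Calibration]
) -> dict[dendropy.Node, float]:
    """Map calibrations to nodes; on conflicts the older age wins (warned)."""
    ages: dict[dendropy.Node, float] = {}
    for cal in cals:
        node = _cal_node(tree, cal)
        if node in ages:
            warnings.warn(
                f"two calibrations resolve to one node; keeping the older "
                f"({max(ages[node], cal.age)} Ma)"
            )
            ages[node] = max(ages[node], cal.age)
        else:
            ages[node] = cal.age
    return ages


def equal_scale(
    tree: dendropy.Tree,
    node_ages: dict[dendropy.Node, float],
    min_bl: float = 0.1,
) -> dendropy.Tree:
    """Date a tree with the 'equal' rule under minimum-age calibrations.

    Calibrated nodes sit at their minimum ages unless a descendant's
    calibration plus the ``min_bl`` floor forces them older (warned);
    chains of uncalibrated nodes split their free interval equally; the
    root extends as far back as its constraints require.  Mutates and
    returns ``tree`` with ``node.age`` set on every node and edge
    lengths updated.  Deterministic.
    """
    if not node_ages:
        raise ValueError("need at least one calibrated node")
    if min_bl <= 0:
        raise ValueError("min_bl must be > 0")
    for node, age in node_ages.items():
        if node.is_leaf():
            raise TreeError("cannot calibrate a tip (extant tips are at 0 Ma)")
        if age <= 0:
            raise ValueError("calibration ages must be > 0")

    # hard floor per node: calibration age and min_bl stacking from below
    floor: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            floor[node] = 0.0
            continue
        h = max(floor[c] for c in node.child_nodes()) + min_bl
        cal = node_ages.get(node)
        if cal is not None:
            if cal < h - 1e-12 and any(
                c in node_ages and node_ages[c] >= cal for c in node.child_nodes()
            ):
                warnings.warn(
                    f"calibration {cal} Ma conflicts with a descendant; node "
                    f"pushed older to {h} Ma"
                )
            h = max(h, cal)
        floor[node] = h

    calibrated = set(node_ages)

    def chain_target(node: dendropy.Node) -> tuple[int, float]:
        """Length of the uncalibrated chain below ``node`` and its anchor age."""
        k = 0
        cur = node
        while True:
            if cur.is_leaf():
                return k, 0.0
            if cur in calibrated:
                return k, floor[cur]
            k += 1  # cur joins the uncalibrated chain
            # descend along the child with the tightest floor (ties: first)
            cur = max(cur.child_nodes(), key=lambda c: floor[c])

    def assign(node: dendropy.Node, parent_age: float | None):
        if node.is_leaf():
            node.age = 0.0
        elif parent_age is None:  # root
            node.age = floor[node]
        elif node in calibrated:
            node.age = floor[node]
        else:
            k, target = chain_target(node)
            equal_val = parent_age - (parent_age - target) / (k + 1.0)
            node.age = max(equal_val, floor[node])
        for child in node.child_nodes():
            assign(child, node.age)

    assign(tree.seed_node, None)
    set_lengths_from_ages(tree)
    return tree


def perturb_calibrations(
    tree: dendropy.Tree,
    cals: list[Calibration],
    fraction: float,
    seed: int,
) -> list[Calibration]:
    """Move a fraction of calibrations to a parent or child node at random.

    ``ceil(fraction * n)`` entries are chosen without replacement; each is
    re-attached to the parent of its resolved node or to a uniformly
    chosen (internal) child — coin flip, except at the root where only
    children are available.  Ages are unchanged; reproducible per seed.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    rng = random.Random(seed)
    n_move = math.ceil(fraction * len(cals))
    move_idx = set(rng.sample(range(len(cals)), n_move)) if n_move else set()
    out: list[Calibration] = []
    for i, cal in enumerate(cals):
        if i not in move_idx:
            out.append(cal)
            continue
        node = _cal_node(tree, cal)
        internal_children = [c for c in node.child_nodes() if not c.is_leaf()]
        at_root = node.parent_node is None
        if at_root or (internal_children and rng.random() < 0.5):
            if not internal_children:
                warnings.warn("root calibration has no internal child; kept in place")
                out.append(cal)
                continue
            target = rng.choice(internal_children)
        elif node.parent_node is not None:
            target = node.parent_node
        else:  # pragma: no cover - covered by at_root branch
            target = node
        tips = frozenset(l.taxon.label for l in target.leaf_iter())
        out.append(Calibration(tips, "crown", cal.age))
    return out
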