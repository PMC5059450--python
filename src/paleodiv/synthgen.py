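"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the four real inputs of the analysis: overlapping
rooted source trees (decomposed from a known model tree), fossil
minimum-age calibrations with a controlled underestimation error,
birth-death trees with known shift regimes and per-tip sampling
fractions, and an autocorrelated delta-18O-like series optionally coupled
to the speciation rate.  Every generator is reproducible from its seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import dendropy
import numpy as np

from .chronogram import Calibration
from .paleoclim import IsotopeSeries
from .phylo_core import set_lengths_from_ages, tip_labels
from .shiftbd import Regime
from .supertree_build import check_overlap

__all__ = [
    "simulate_bd_tree",
    "simulate_proxy",
    "simulate_coupled_history",
    "decompose_to_source_trees",
    "sample_fossil_calibrations",
    "TrueShift",
]


@dataclass
class TrueShift:
    """Ground-truth regime change: all surviving descendants of ``tips``
    below ``age`` evolved under ``regime``."""

    tips: frozenset[str]
    age: float
    regime: Regime


class _Lineage:
    __slots__ = ("birth", "death", "children", "regime", "label")

    def __init__(self, birth, regime):
        self.birth = birth  # forward time since simulation start
        self.death = None
        self.children = []
        self.regime = regime
        self.label = None


def _build_tree(root_lin: _Lineage, total_time: float,
                keep: set[int] | None) -> dendropy.Tree:
    """Convert a lineage forest into a pruned, dated dendropy tree.

    ``keep``: ids of retained tip lineages (survivors after sampling).
    """
    def surviving(lin: _Lineage) -> bool:
        if not lin.children:
            return lin.death is None and (keep is None or id(lin) in keep)
        return any(surviving(c) for c in lin.children)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True

    def rec(lin: _Lineage, node: dendropy.Node):
        kids = [c for c in lin.children if surviving(c)]
        if not lin.children:  # extant tip
            node.taxon = tns.require_taxon(label=lin.label)
            node.age = 0.0
            return
        if len(kids) == 1:  # suppress the unifurcation
            rec(kids[0], node)
            return
        node.age = total_time - lin.children[0].birth
        for c in kids:
            child = dendropy.Node()
            node.add_child(child)
            rec(c, child)

    root = tree.seed_node
    rec(root_lin, root)
    set_lengths_from_ages(tree)
    return tree


def simulate_bd_tree(
    lam: float,
    mu: float = 0.0,
    age: float | None = None,
    ntips: int | None = None,
    f: float = 1.0,
    shifts: list[tuple[float, float, float]] | None = None,
    seed: int = 0,
    max_retries: int = 100,
    max_tips: int = 10000,
):
    """Forward birth-death simulation from a single lineage.

    Stopping rule: either a crown-to-present duration ``age`` (Ma) or a
    tip count ``ntips`` (exclusive choice).  ``shifts`` is an optional
    plan of (age Ma, new lambda, new mu): at each listed age one random
    surviving lineage and its descendants switch regime.  Tips are then
    subsampled with probability ``f``.  Returns ``(tree, truth)`` where
    ``truth`` is a dict with the root :class:`Regime` and a list of
    :class:`TrueShift` entries restricted to surviving taxa.  Total
    extinction (or <2 surviving tips) triggers a resimulation, up to
    ``max_retries``.
    """
    if (age is None) == (ntips is None):
        raise ValueError("specify exactly one of age= or ntips=")
    if not (0.0 < f <= 1.0):
        raise ValueError("sampling fraction must be in (0, 1]")
    shifts = sorted(shifts or [], key=lambda s: -s[0])  # oldest first
    rng = random.Random(seed)

    for attempt in range(max_retries):
        result = _simulate_once(lam, mu, age, ntips, f, shifts, rng, max_tips)
        if result is not None:
            return result
    raise RuntimeError(f"no surviving tree in {max_retries} attempts")


def _simulate_once(lam, mu, age, ntips, f, shift_plan, rng, max_tips=10000):
    root_regime = Regime(lam, mu)
    horizon = age  # None for ntips stopping
    t = 0.0
    root = _Lineage(0.0, root_regime)
    alive = [root]
    # shift schedule in forward time (only meaningful with age stopping)
    if shift_plan and horizon is None:
        raise ValueError("a shift plan requires the age stopping rule")
    pending = [(horizon - s_age, Regime(s_lam, s_mu))
               for s_age, s_lam, s_mu in shift_plan] if shift_plan else []
    marked: list[tuple[_Lineage, float, Regime]] = []

    while True:
        if not alive:
            return None
        if len(alive) > max_tips:
            raise ValueError(
                f"simulation exceeded {max_tips} tips; rates imply runaway growth"
            )
        if ntips is not None and len(alive) >= ntips:
            # place the present uniformly within the interval over which
            # the count stays at ntips, so pendant branches have length
            rate_now = sum(l.regime.lam + l.regime.mu for l in alive)
            dt_next = rng.expovariate(rate_now) if rate_now > 0 else 1.0
            total_time = t + rng.random() * dt_next
            break
        total_rate = sum(l.regime.lam + l.regime.mu for l in alive)
        dt = rng.expovariate(total_rate) if total_rate > 0 else math.inf
        t_next = t + dt
        if pending and t_next >= pending[0][0]:
            t, (_, regime) = pending[0][0], pending[0]
            lin = rng.choice(alive)
            marked.append((lin, horizon - t, regime))
            _repaint(lin, regime)
            pending.pop(0)
            continue
        if horizon is not None and t_next >= horizon:
            total_time = horizon
            break
        t = t_next
        # choose lineage proportional to its total event rate
        u = rng.random() * total_rate
        acc = 0.0
        for lin in alive:
            acc += lin.regime.lam + lin.regime.mu
            if acc >= u:
                break
        if rng.random() < lin.regime.lam / (lin.regime.lam + lin.regime.mu):
            c1, c2 = _Lineage(t, lin.regime), _Lineage(t, lin.regime)
            lin.children = [c1, c2]
            alive.remove(lin)
            alive.extend([c1, c2])
        else:
            lin.death = t
            alive.remove(lin)

    # label tips, apply sampling
    tips = [l for l in alive]
    for i, lin in enumerate(tips):
        lin.label = f"t{i + 1}"
    kept = [lin for lin in tips if rng.random() < f] if f < 1.0 else tips
    if len(kept) < 2:
        return None
    keep_ids = {id(l) for l in kept}
    tree = _build_tree(root, total_time, keep_ids)
    if len(tip_labels(tree)) < 2:
        return None

    true_shifts = []
    kept_labels = {l.label for l in kept}
    for lin, s_age, regime in marked:
        below = {d.label for d in _descendant_tips(lin)} & kept_labels
        if below:
            true_shifts.append(TrueShift(frozenset(below), s_age, regime))
    truth = {"root_regime": root_regime, "shifts": true_shifts}
    return tree, truth


def _repaint(lin: _Lineage, regime: Regime):
    lin.regime = regime
    for c in lin.children:
        _repaint(c, regime)


def _descendant_tips(lin: _Lineage):
    if not lin.children:
        if lin.death is None:
            yield lin
        return
    for c in lin.children:
        yield from _descendant_tips(c)


def simulate_proxy(
    phi: float,
    innovation_sd: float,
    span: tuple[float, float] = (0.0, 100.0),
    step: float = 0.1,
    mean: float = 0.0,
    trend: float = 0.0,
    seed: int = 0,
) -> IsotopeSeries:
    """AR(1) isotope-like series on a uniform age grid.

    ``phi`` is the lag-1 coefficient (|phi| < 1); the process runs
    forward in time (old to young) and starts from its stationary
    distribution.  ``trend`` adds a deterministic drift in value units
    per Myr toward the present: a positive trend raises the isotope
    value as ages approach 0, i.e. a cooling-trend record.
    """
    if not (-1.0 < phi < 1.0):
        raise ValueError("phi must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = float(span[0]), float(span[1])
    ages = lo + step * np.arange(int(round((hi - lo) / step)) + 1)
    n = len(ages)
    x = np.empty(n)
    if innovation_sd == 0.0:
        x[:] = 0.0
    else:
        x[0] = rng.normal(0.0, innovation_sd / math.sqrt(1.0 - phi * phi))
        eps = rng.normal(0.0, innovation_sd, size=n - 1)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i - 1]
    # x[0] is the oldest point; ages ascend, so reverse onto the age axis
    values = mean + x[::-1] + trend * (hi - ages)
    return IsotopeSeries(ages, values)


def simulate_coupled_history(
    a: float,
    b: float,
    series: IsotopeSeries | None = None,
    phi: float = 0.95,
    innovation_sd: float = 0.05,
    trend: float = 0.025,
    span: tuple[float, float] = (0.0, 60.0),
    step: float = 0.1,
    seed: int = 0,
    max_tips: int = 100000,
    max_retries: int = 100,
    mode: str = "continuous",
    renewal_rate: float = 0.01,
):
    """Pure-birth history whose speciation rate tracks the temperature proxy.

    Two coupling modes share the rate law lambda = exp(a + b * proxy)
    with proxy = the negated isotope value (warmth-increasing), so b < 0
    makes speciation faster when the climate is cooler:

    * ``continuous`` — every lineage's instantaneous rate is
      lambda(t) = exp(a + b * proxy(t)); simulated by thinning.  The
      signal is synchronous across lineages and diffuse in time.
    * ``episodic`` — each lineage keeps a constant rate that is *renewed*
      at per-lineage Poisson rate ``renewal_rate`` (events/lineage/Myr):
      at a renewal the lineage (and its descendants, until their own
      renewal) adopts lambda = exp(a + b * proxy(t_renewal)).  The
      climate signal is then carried by discrete clade-level regimes,
      the structure a compound-Poisson shift model can represent.

    Returns (tree, series, b); in episodic mode the tree carries the
    realized renewals as ground truth in ``tree.coupling_truth``.
    """
    rng = random.Random(seed)
    if series is None:
        series = simulate_proxy(
            phi, innovation_sd, span=span, step=step, trend=trend,
            seed=rng.randrange(2**31),
        )
    if mode not in ("continuous", "episodic"):
        raise ValueError("mode must be 'continuous' or 'episodic'")
    proxy_age = series.age
    proxy_val = -series.value
    horizon = float(proxy_age[-1] - proxy_age[0])
    offset = float(proxy_age[0])

    def lam_at(t_fwd: float) -> float:
        age_ma = offset + horizon - t_fwd
        v = float(np.interp(age_ma, proxy_age, proxy_val))
        return math.exp(a + b * v)

    lam_max = float(math.exp(a + max(b * proxy_val.max(), b * proxy_val.min())))
    lam_bar = float(np.mean(np.exp(a + b * proxy_val)))
    log_expected = lam_bar * horizon
    # the expectation under the continuous law; episodic growth lags it
    # (lineages keep stale rates between renewals), so there only the
    # in-loop tip cap applies
    if mode == "continuous" and log_expected > math.log(max_tips) + 3.0:
        raise ValueError(
            f"runaway growth: expected tip count ~e^{log_expected:.1f} exceeds cap"
        )

    for attempt in range(max_retries):
        t = 0.0
        root = _Lineage(0.0, Regime(max(lam_at(0.0), 1e-12), 0.0))
        alive = [root]
        renewals: list[tuple[_Lineage, float, float]] = []
        ok = True
        while True:
            if mode == "continuous":
                rate = len(alive) * lam_max
            else:
                rate = sum(l.regime.lam for l in alive) + len(alive) * renewal_rate
            t += rng.expovariate(rate)
            if t >= horizon:
                break
            if mode == "continuous":
                accept_birth = rng.random() < lam_at(t) / lam_max
                lin = rng.choice(alive) if accept_birth else None
            else:
                u = rng.random() * rate
                if u < len(alive) * renewal_rate:  # regime renewal
                    lin = rng.choice(alive)
                    new_lam = max(lam_at(t), 1e-12)
                    lin.regime = Regime(new_lam, 0.0)
                    renewals.append((lin, t, new_lam))
                    continue
                # birth: choose lineage proportional to its current rate
                u -= len(alive) * renewal_rate
                acc = 0.0
                lin = None
                for cand in alive:
                    acc += cand.regime.lam
                    if acc >= u:
                        lin = cand
                        break
                accept_birth = lin is not None
            if accept_birth:
                c1 = _Lineage(t, lin.regime)
                c2 = _Lineage(t, lin.regime)
                lin.children = [c1, c2]
                alive.remove(lin)
                alive.extend([c1, c2])
                if len(alive) > max_tips:
                    ok = False
                    break
        if ok and len(alive) >= 2:
            for i, lin in enumerate(alive):
                lin.label = f"t{i + 1}"
            tree = _build_tree(root, horizon, None)
            # shift tip ages onto the proxy's age axis offset
            if offset:
                for node in tree.preorder_node_iter():
                    node.age += offset
                for node in tree.leaf_node_iter():
                    node.age = offset
            truth = []
            if mode == "episodic":
                labels = {l.label for l in alive}
                for lin, t_ren, new_lam in renewals:
                    below = {d.label for d in _descendant_tips(lin)} & labels
                    if below:
                        truth.append(
                            TrueShift(frozenset(below), offset + horizon - t_ren,
                                      Regime(new_lam, 0.0))
                        )
            tree.coupling_truth = truth
            return tree, series, b
    raise RuntimeError(f"no usable history in {max_retries} attempts")


def decompose_to_source_trees(
    tree: dendropy.Tree,
    k: int,
    tips_per_tree: int,
    seed: int = 0,
    max_retries: int = 1000,
) -> list[dendropy.Tree]:
    """Induced subtrees on random tip subsets, with guaranteed overlap.

    Draws ``k`` subsets of ``tips_per_tree`` tips, restricted to the
    model tree's induced topology (branch lengths dropped), rejection
    sampling until the >=2-shared-taxa overlap graph is connected.
    """
    if k < 2:
        raise ValueError("need k >= 2 source trees")
    if tips_per_tree < 4:
        raise ValueError("need tips_per_tree >= 4")
    labels = sorted(tip_labels(tree))
    if tips_per_tree > len(labels):
        raise ValueError("tips_per_tree exceeds the model tree size")
    rng = random.Random(seed)
    for attempt in range(max_retries):
        subsets = [rng.sample(labels, tips_per_tree) for _ in range(k)]
        sources = []
        for sub in subsets:
            st = tree.extract_tree_with_taxa_labels(labels=sub)
            st.is_rooted = True
            for e in st.preorder_edge_iter():
                e.length = None
            sources.append(st)
        if check_overlap(sources).connected:
            return sources
    raise RuntimeError("could not draw a connected source-tree set")


def sample_fossil_calibrations(
    tree: dendropy.Tree,
    n: int,
    underestimate_sd: float = 0.1,
    seed: int = 0,
) -> list[Calibration]:
    """Fossil-like minimum-age calibrations from a dated tree.

    ``n`` distinct internal nodes are drawn; each gets a crown
    calibration at age ``true_age * (1 - |eps|)`` with eps ~
    Normal(0, underestimate_sd), so every calibration is a valid minimum
    for its node.
    """
    internals = [nd for nd in tree.preorder_internal_node_iter()]
    if n > len(internals):
        raise ValueError(f"only {len(internals)} internal nodes available")
    rng = random.Random(seed)
    nrng = np.random.default_rng(seed)
    chosen = rng.sample(internals, n)
    cals = []
    for node in chosen:
        eps = abs(float(nrng.normal(0.0, underestimate_sd))) if underestimate_sd else 0.0
        cal_age = node.age * (1.0 - min(eps, 0.999))
        tips = frozenset(l.taxon.label for l in node.leaf_iter())
        cals.append(Calibration(tips, "crown", max(cal_age, 1e-6)))
    return cals
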