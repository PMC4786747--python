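"""Timescaling cladograms against first appearance dates.

Two standard a-posteriori timescaling rules for fossil cladograms:

``basic``
    Every internal node is drawn down to the oldest first appearance datum
    (FAD) among its descendant tips.  This minimises total implied ghost
    lineage and therefore gives the minimum phylogenetic diversity.

``equal``
    Start from the basic dating (optionally pushing the root older by a
    buffer), then remove zero-duration branches by borrowing time from the
    nearest ancestral branch of positive duration: the positive branch and
    the chain of zero branches below it share its duration equally.  Tip
    ages and the root age are unchanged, so root-to-tip path lengths are
    conserved.

Polytomies are permitted and dated by the same rules; no resolution is done.
Zero branches with no positive ancestor to draw from (e.g. hanging directly
off a root at the oldest FAD with zero buffer) legitimately stay at zero.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Literal, Sequence

import dendropy

from .strat import TaxonRange
from .trees import TimescaledTree

__all__ = ["timescale_basic", "timescale_equal", "timescale_set"]

Method = Literal["basic", "equal"]


def _fad_lookup(cladogram: dendropy.Tree, ranges: Iterable[TaxonRange]) -> dict[str, float]:
    fads = {r.taxon: r.fad for r in ranges}
    missing = [
        leaf.taxon.label
        for leaf in cladogram.leaf_node_iter()
        if leaf.taxon.label not in fads
    ]
    if missing:
        raise ValueError(f"tips without a stratigraphic range: {missing}")
    return fads


def timescale_basic(
    cladogram: dendropy.Tree,
    ranges: Iterable[TaxonRange],
    label: str = "basic",
) -> TimescaledTree:
    """Date nodes at the oldest descendant FAD (minimum ghost lineage)."""
    fads = _fad_lookup(cladogram, ranges)
    tree = cladogram.clone(depth=1)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.age = fads[node.taxon.label]
        else:
            node.age = max(child.age for child in node.child_nodes())
    return TimescaledTree(tree=tree, label=label)


def timescale_equal(
    cladogram: dendropy.Tree,
    ranges: Iterable[TaxonRange],
    root_buffer: float = 0.0,
    label: str = "equal",
) -> TimescaledTree:
    """Share each positive branch equally with the zero branches below it."""
    if root_buffer < 0:
        raise ValueError("root_buffer must be >= 0")
    ts = timescale_basic(cladogram, ranges, label=label)
    tree = ts.tree
    tree.seed_node.age += root_buffer

    # Postorder (deepest first): each zero branch walks up through the chain
    # of zero branches to the first positive ancestral branch, then the whole
    # chain — the positive branch plus the k zero branches below it — is
    # respaced evenly at d/(k+1).  Deepest-first processing lets a full chain
    # claim its share in one step; remaining sibling zero branches then see
    # the updated ages, which keeps the procedure deterministic.
    for node in tree.postorder_node_iter():
        parent = node.parent_node
        if parent is None or parent.age - node.age > 0:
            continue
        # walk up through the chain of zero branches
        top = parent
        chain = [parent]  # nodes whose ages will move (all currently == node.age)
        while top.parent_node is not None and top.parent_node.age - top.age <= 0:
            top = top.parent_node
            chain.append(top)
        anchor = top.parent_node
        if anchor is None or anchor.age <= node.age:
            continue  # no positive ancestor branch to draw from
        # respace: anchor.age > node.age; chain holds the intermediate nodes
        # from nearest (parent) to furthest (child of anchor)
        m = len(chain)
        step = (anchor.age - node.age) / (m + 1)
        for i, mid in enumerate(chain, start=1):
            mid.age = node.age + step * i
    return TimescaledTree(tree=tree, label=label)


def timescale_set(
    cladograms: Sequence[dendropy.Tree],
    ranges: Iterable[TaxonRange],
    methods: Sequence[Method] = ("basic", "equal"),
    root_buffer: float = 0.0,
) -> list[TimescaledTree]:
    """Timescale every tree under every method (Cartesian product), labeled."""
    ranges = list(ranges)
    if not cladograms:
        raise ValueError("need at least one cladogram")
    if not methods:
        raise ValueError("need at least one timescaling method")
    out: list[TimescaledTree] = []
    for (i, tree), method in product(enumerate(cladograms), methods):
        label = f"tree{i}:{method}"
        if method == "basic":
            out.append(timescale_basic(tree, ranges, label=label))
        elif method == "equal":
            out.append(timescale_equal(tree, ranges, root_buffer, label=label))
        else:
            raise ValueError(f"unknown timescaling method {method!r}")
    return out
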