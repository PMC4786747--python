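"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest

from cladewane.strat import BinSequence, TimeBin, TaxonRange
from cladewane.trees import TimescaledTree


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def cherry_plus_outgroup() -> dendropy.Tree:
    """((A,B),C); rooted."""
    t = dendropy.Tree.get(data="((A,B),C);", schema="newick")
    t.is_rooted = True
    return t


@pytest.fixture
def example_ranges() -> list[TaxonRange]:
    return [
        TaxonRange("A", 100.0, 95.0),
        TaxonRange("B", 90.0, 85.0),
        TaxonRange("C", 110.0, 100.0),
    ]


@pytest.fixture
def five_my_bins() -> BinSequence:
    edges = np.arange(130.0, 79.0, -5.0)
    return BinSequence(
        TimeBin(f"b{o:.0f}", o, y) for o, y in zip(edges[:-1], edges[1:])
    )


# ---------------------------------------------------------------------------
# tree helpers


def random_topology(labels: list[str], rng: np.random.Generator) -> dendropy.Tree:
    """Random rooted binary topology by sequential attachment."""
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    a, b = labels[0], labels[1]
    for lab in (a, b):
        child = dendropy.Node()
        child.taxon = tns.new_taxon(lab)
        tree.seed_node.add_child(child)
    for lab in labels[2:]:
        edges = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
        target = edges[rng.integers(len(edges))]
        parent = target.parent_node
        mid = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(mid)
        mid.add_child(target)
        leaf = dendropy.Node()
        leaf.taxon = tns.new_taxon(lab)
        mid.add_child(leaf)
    return tree


def ages_of(ts: TimescaledTree) -> dict[str, float]:
    out = {}
    for node in ts.tree.preorder_node_iter():
        if node.is_leaf():
            out[node.taxon.label] = node.age
    return out


# ---------------------------------------------------------------------------
# oracle: exhaustive most-parsimonious-reconstruction enumeration


def brute_force_mpr(
    tree: dendropy.Tree,
    tip_states: dict[str, float],
    n_states: int,
    ordered: bool,
) -> tuple[dict[int, set[int]], float]:
    """Enumerate every internal-state assignment; return per-node MPR sets."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = np.inf
    sets: dict[int, set[int]] = {id(n): set() for n in internals}

    def cost_of(assign: dict[int, int]) -> float:
        total = 0.0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.is_leaf():
                s = tip_states.get(node.taxon.label, np.nan)
                if np.isnan(s):
                    continue
                s = int(s)
            else:
                s = assign[id(node)]
            p = assign[id(node.parent_node)]
            total += abs(p - s) if ordered else (p != s)
        return total

    for combo in itertools.product(range(n_states), repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        c = cost_of(assign)
        if c < best - 1e-9:
            best = c
            sets = {id(n): {assign[id(n)]} for n in internals}
        elif abs(c - best) <= 1e-9:
            for n in internals:
                sets[id(n)].add(assign[id(n)])
    return sets, best


# ---------------------------------------------------------------------------
# oracle: greedy minimum-variance (Ward) agglomeration


def _ess(X: np.ndarray) -> float:
    return float(((X - X.mean(axis=0)) ** 2).sum())


def brute_force_ward(X: np.ndarray) -> list[frozenset]:
    """Greedy merges minimising the increase in within-cluster sum of squares.

    Ties broken by the lexicographically smallest member-index pair.  Returns
    the merged member sets in order.
    """
    clusters: list[tuple[int, ...]] = [(i,) for i in range(len(X))]
    merges: list[frozenset] = []
    while len(clusters) > 1:
        best_pair = None
        best_inc = np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                inc = _ess(X[list(a + b)]) - _ess(X[list(a)]) - _ess(X[list(b)])
                key = tuple(sorted(a + b))
                if inc < best_inc - 1e-12 or (
                    abs(inc - best_inc) <= 1e-12
                    and best_pair is not None
                    and key < tuple(sorted(best_pair[0] + best_pair[1]))
                ):
                    best_inc = inc
                    best_pair = (a, b)
        a, b = best_pair
        clusters.remove(a)
        clusters.remove(b)
        merged = tuple(sorted(a + b))
        clusters.append(merged)
        merges.append(frozenset(merged))
    return merges


# ---------------------------------------------------------------------------
# oracle: minimal total branch duration over a node-age grid


def brute_force_min_tree_duration(
    tree: dendropy.Tree, fads: dict[str, float], grid: np.ndarray
) -> float:
    """Min total branch duration over all grid datings with parent >= child
    and every node at or above its descendants' oldest FAD."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    tip_age = {id(n): fads[n.taxon.label] for n in tree.leaf_node_iter()}
    best = np.inf
    for combo in itertools.product(grid, repeat=len(internals)):
        ages = dict(tip_age)
        for n, a in zip(internals, combo):
            ages[id(n)] = a
        ok = True
        total = 0.0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            d = ages[id(node.parent_node)] - ages[id(node)]
            if d < 0:
                ok = False
                break
            total += d
        if ok:
            best = min(best, total)
    return best
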