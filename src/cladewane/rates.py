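"""Per-bin evolutionary dynamics: cladogenesis, extinction, turnover, and
per-branch discrete-character change rates.

Cladogenesis events are internal-node ages on a timescaled tree; extinction
events are range-through last appearances.  Rates default to raw per-bin
counts (with per-My normalisation available, since stage durations differ);
per-lineage ("relative") extinction is the percentage of lineages present in
a bin whose last appearance falls in it.  Turnover is cladogenesis plus
extinction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .strat import BinSequence, TaxonRange
from .trees import TimescaledTree
from .charmatrix import CharacterMatrix
from .ancstates import ancestor_node_labels
from .diversity import DiversityCurve

__all__ = [
    "RateSeries",
    "BranchRate",
    "cladogenesis_per_bin",
    "extinction_per_bin",
    "per_lineage_extinction",
    "turnover",
    "branch_character_rates",
]


@dataclass
class RateSeries:
    bins: BinSequence
    counts: np.ndarray          # point estimate per bin (median across trees)
    counts_lo: np.ndarray       # min across trees (range envelope)
    counts_hi: np.ndarray       # max across trees
    kind: str

    @property
    def per_my(self) -> np.ndarray:
        return self.counts / self.bins.durations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.bins.names,
                "count": self.counts,
                "count_lo": self.counts_lo,
                "count_hi": self.counts_hi,
                "per_my": self.per_my,
                "kind": self.kind,
            }
        )


@dataclass
class BranchRate:
    branch: str          # label of the branch's child node
    changes: float
    duration: float
    rate: float          # changes per My


def _bin_index(bins: BinSequence, age: float) -> int | None:
    for i, b in enumerate(bins):
        if b.contains(age):
            return i
    return None


def cladogenesis_per_bin(
    trees: Sequence[TimescaledTree], bins: BinSequence
) -> RateSeries:
    """Count internal-node (splitting) ages per bin; median and range across trees."""
    if not trees:
        raise ValueError("need at least one timescaled tree")
    stack = np.zeros((len(trees), len(bins)))
    for t_i, tree in enumerate(trees):
        for age in tree.internal_node_ages():
            i = _bin_index(bins, age)
            if i is not None:
                stack[t_i, i] += 1
    return RateSeries(
        bins=bins,
        counts=np.median(stack, axis=0),
        counts_lo=stack.min(axis=0),
        counts_hi=stack.max(axis=0),
        kind="cladogenesis",
    )


def extinction_per_bin(ranges: Sequence[TaxonRange], bins: BinSequence) -> RateSeries:
    """Count range-through last appearances (LADs) per bin."""
    counts = np.zeros(len(bins))
    for r in ranges:
        i = _bin_index(bins, r.lad)
        if i is not None:
            counts[i] += 1
    return RateSeries(bins=bins, counts=counts, counts_lo=counts.copy(),
                      counts_hi=counts.copy(), kind="extinction")


def per_lineage_extinction(
    extinctions: RateSeries, diversity: DiversityCurve
) -> RateSeries:
    """Percentage of lineages present in a bin that go extinct in it.

    Denominator is the supplied diversity curve (phylogenetic by default in
    the pipeline); bins with zero lineages are undefined (nan).
    """
    denom = np.asarray(diversity.values, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(denom > 0, 100.0 * extinctions.counts / denom, np.nan)
    return RateSeries(bins=extinctions.bins, counts=pct, counts_lo=pct.copy(),
                      counts_hi=pct.copy(), kind="per_lineage_extinction")


def turnover(cladogenesis: RateSeries, extinctions: RateSeries) -> RateSeries:
    """Turnover = cladogenesis + extinction, bin by bin."""
    return RateSeries(
        bins=cladogenesis.bins,
        counts=cladogenesis.counts + extinctions.counts,
        counts_lo=cladogenesis.counts_lo + extinctions.counts_lo,
        counts_hi=cladogenesis.counts_hi + extinctions.counts_hi,
        kind="turnover",
    )


def branch_character_rates(
    ancestor_matrix: CharacterMatrix,
    tree: TimescaledTree,
) -> list[BranchRate]:
    """Parsimony-based change counts per branch, divided by branch duration.

    Changes on a branch sum |state difference| (ordered) or the inequality
    indicator (unordered) over characters scored at both endpoints; characters
    missing at either endpoint are skipped, so counts are conservative.
    Zero-duration branches are excluded (rate undefined).
    """
    anc = ancestor_node_labels(tree)
    row = {t: i for i, t in enumerate(ancestor_matrix.taxa)}

    def label_of(node):
        return node.taxon.label if node.is_leaf() else anc[id(node)]

    out: list[BranchRate] = []
    X = ancestor_matrix.states
    ordered = ancestor_matrix.ordered
    for node, older, younger in tree.branches():
        duration = older - younger
        if duration <= 0:
            continue
        a = X[row[label_of(node.parent_node)]]
        b = X[row[label_of(node)]]
        both = ~np.isnan(a) & ~np.isnan(b)
        diff = np.abs(a[both] - b[both])
        changes = float(np.where(ordered[both], diff, diff > 0).sum())
        out.append(BranchRate(branch=label_of(node), changes=changes,
                              duration=duration, rate=changes / duration))
    return out
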