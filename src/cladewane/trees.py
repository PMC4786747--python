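"""Rooted cladograms and timescaled trees.

Trees are dendropy :class:`~dendropy.Tree` objects throughout.  A timescaled
tree additionally carries an ``age`` attribute (Ma) on every node; branch
durations in My are derived as ``parent.age - child.age`` and are never stored
separately, which makes root-to-tip path lengths conserved by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["TimescaledTree", "read_trees", "write_trees"]


@dataclass
class TimescaledTree:
    """A rooted tree with node ages in Ma (tips at their first appearance).

    Invariants checked on construction: every node has an ``age``;
    ``parent.age >= child.age`` for every branch; ages are finite.
    """

    tree: dendropy.Tree
    label: str = ""

    def __post_init__(self) -> None:
        for node in self.tree:
            age = getattr(node, "age", None)
            if age is None or not np.isfinite(age):
                raise ValueError("every node needs a finite age (Ma)")
            if node.parent_node is not None and node.parent_node.age < age - 1e-9:
                raise ValueError(
                    f"branch to {node_label(node)!r}: parent age "
                    f"{node.parent_node.age} < child age {age}"
                )

    @property
    def root_age(self) -> float:
        return self.tree.seed_node.age

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def branch_duration(self, node: dendropy.Node) -> float:
        if node.parent_node is None:
            return 0.0
        return node.parent_node.age - node.age

    def branches(self):
        """Yield (node, older_end, younger_end) for every non-root branch."""
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                yield node, node.parent_node.age, node.age

    def internal_node_ages(self) -> np.ndarray:
        return np.array(
            [n.age for n in self.tree.preorder_internal_node_iter()]
        )

    def total_branch_duration(self) -> float:
        return float(sum(older - younger for _, older, younger in self.branches()))

    def clone(self) -> "TimescaledTree":
        t = self.tree.clone(depth=1)
        for src, dst in zip(self.tree.preorder_node_iter(), t.preorder_node_iter()):
            dst.age = src.age
        return TimescaledTree(tree=t, label=self.label)

    def sync_edge_lengths(self) -> None:
        """Write branch durations onto dendropy edge lengths (for output)."""
        for node in self.tree.preorder_node_iter():
            node.edge.length = (
                None
                if node.parent_node is None
                else node.parent_node.age - node.age
            )

    @classmethod
    def from_edge_lengths(cls, tree: dendropy.Tree, root_age: float,
                          label: str = "") -> "TimescaledTree":
        """Anchor a tree with branch lengths (My) at a known root age."""
        t = tree.clone(depth=1)
        t.seed_node.age = root_age
        for node in t.preorder_node_iter():
            if node.parent_node is not None:
                length = node.edge.length or 0.0
                node.age = node.parent_node.age - length
        return cls(tree=t, label=label)


def node_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or f"node@{id(node):x}"


def read_trees(path, schema: str | None = None) -> list[dendropy.Tree]:
    """Read one or more rooted trees from Newick or NEXUS."""
    if schema is None:
        head = open(path).read(400).lstrip().lower()
        schema = "nexus" if head.startswith("#nexus") else "newick"
    trees = dendropy.TreeList.get(path=str(path), schema=schema)
    for t in trees:
        t.is_rooted = True
    return list(trees)


def write_trees(trees: list[TimescaledTree], path) -> None:
    """Write timescaled trees as Newick with durations as branch lengths."""
    tl = dendropy.TreeList()
    for ts in trees:
        ts.sync_edge_lengths()
        tree = ts.tree
        tree.label = ts.label
        if tl.taxon_namespace is not tree.taxon_namespace:
            tree.migrate_taxon_namespace(tl.taxon_namespace)
        tl.append(tree)
    tl.write(path=str(path), schema="newick", suppress_rooting=False)
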