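"""Most-parsimonious ancestral state reconstruction with ambiguity tracking.

For each character the full set of most-parsimonious reconstructions (MPRs)
is characterised exactly by a Sankoff down-pass/up-pass over the step-cost
matrix (0/1 steps for unordered characters, |i - j| for ordered ones, i.e.
Fitch and the Farris interval method respectively).  A state belongs to a
node's MPR set iff fixing the node to that state still attains the global
minimum cost; a node is assigned a state only when that set is a singleton —
the "unambiguous" reconstruction convention.  Missing tips contribute zero
cost for every state and so never constrain the reconstruction.
"""

from __future__ import annotations

import numpy as np

from .charmatrix import CharacterMatrix
from .trees import TimescaledTree

__all__ = ["mpr_state_sets", "reconstruct_ancestors", "ancestor_node_labels"]

_INF = np.inf


def _step_costs(n_states: int, ordered: bool) -> np.ndarray:
    idx = np.arange(n_states)
    if ordered:
        return np.abs(idx[:, None] - idx[None, :]).astype(float)
    return (idx[:, None] != idx[None, :]).astype(float)


def mpr_state_sets(
    tree: TimescaledTree,
    tip_states: dict[str, float],
    n_states: int,
    ordered: bool,
) -> tuple[dict[int, set[int]], float]:
    """MPR state set per node (keyed by ``id(node)``) and the minimum cost.

    ``tip_states`` maps tip labels to states; ``nan`` marks missing tips.
    """
    cost = _step_costs(n_states, ordered)
    nodes = list(tree.tree.postorder_node_iter())
    down: dict[int, np.ndarray] = {}
    for node in nodes:
        if node.is_leaf():
            s = tip_states.get(node.taxon.label, np.nan)
            vec = np.zeros(n_states)
            if not np.isnan(s):
                vec = np.full(n_states, _INF)
                vec[int(s)] = 0.0
        else:
            vec = np.zeros(n_states)
            for child in node.child_nodes():
                vec = vec + np.min(cost + down[id(child)][None, :], axis=1)
        down[id(node)] = vec

    root = tree.tree.seed_node
    best = float(np.min(down[id(root)]))
    up: dict[int, np.ndarray] = {id(root): np.zeros(n_states)}
    for node in tree.tree.preorder_node_iter():
        for child in node.child_nodes():
            # cost of the rest of the tree if the *parent* takes state t,
            # excluding child's own subtree
            child_contrib = np.min(cost + down[id(child)][None, :], axis=1)
            rest = up[id(node)] + down[id(node)] - child_contrib
            up[id(child)] = np.min(rest[:, None] + cost, axis=0)

    sets: dict[int, set[int]] = {}
    for node in nodes:
        total = down[id(node)] + up[id(node)]
        sets[id(node)] = {int(s) for s in np.flatnonzero(total <= best + 1e-9)}
    return sets, best


def ancestor_node_labels(tree: TimescaledTree) -> dict[int, str]:
    """Stable labels for internal nodes, assigned in preorder."""
    labels: dict[int, str] = {}
    k = 0
    for node in tree.tree.preorder_node_iter():
        if not node.is_leaf():
            k += 1
            labels[id(node)] = node.label or f"anc_{k}"
    return labels


def reconstruct_ancestors(
    matrix: CharacterMatrix,
    tree: TimescaledTree,
) -> CharacterMatrix:
    """Extend a matrix with unambiguously reconstructed ancestral rows.

    Tip rows are passed through unchanged.  Each internal node receives, per
    character, its MPR state when all most-parsimonious reconstructions agree,
    and missing otherwise.  Characters with fewer than one scored tip stay
    missing everywhere in the ancestral rows.
    """
    tips = tree.tip_labels()
    missing_from_matrix = [t for t in tips if t not in matrix.taxa]
    if missing_from_matrix:
        raise ValueError(f"tree tips absent from matrix: {missing_from_matrix}")
    anc_labels = ancestor_node_labels(tree)
    internal_nodes = [n for n in tree.tree.preorder_node_iter() if not n.is_leaf()]
    n_anc = len(internal_nodes)
    tip_grid = np.vstack([matrix.row(t) for t in tips])
    anc_grid = np.full((n_anc, matrix.n_characters), np.nan)

    for j in range(matrix.n_characters):
        col = {t: tip_grid[i, j] for i, t in enumerate(tips)}
        scored = [v for v in col.values() if not np.isnan(v)]
        if not scored:
            continue
        lo, hi = int(min(scored)), int(max(scored))
        if lo == hi:
            anc_grid[:, j] = lo  # invariant character
            continue
        if matrix.ordered[j]:
            # contiguous state space [lo, hi]; shift to 0-based for the DP
            shifted = {t: (v - lo if not np.isnan(v) else np.nan)
                       for t, v in col.items()}
            sets, _ = mpr_state_sets(tree, shifted, hi - lo + 1, ordered=True)
            offset = lo
        else:
            observed = sorted({int(v) for v in scored})
            remap = {v: i for i, v in enumerate(observed)}
            shifted = {t: (remap[int(v)] if not np.isnan(v) else np.nan)
                       for t, v in col.items()}
            sets, _ = mpr_state_sets(tree, shifted, len(observed), ordered=False)
            offset = None
        for i, node in enumerate(internal_nodes):
            s = sets[id(node)]
            if len(s) == 1:
                state = next(iter(s))
                if matrix.ordered[j]:
                    anc_grid[i, j] = state + offset
                else:
                    anc_grid[i, j] = observed[state]

    taxa = tips + [anc_labels[id(n)] for n in internal_nodes]
    grid = np.vstack([tip_grid, anc_grid])
    return CharacterMatrix(taxa=taxa, states=grid, ordered=matrix.ordered.copy())
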