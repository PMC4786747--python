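"""Morphological disparity through time from discrete character data.

Two complementary routes:

* **Pairwise dissimilarity** on the raw matrix: per taxon pair, the mean
  per-character difference over mutually scored characters (ordered
  characters contribute ``|a-b| / state range``), weighted per pair by the
  number of comparable characters.  Per-bin weighted mean (or median) with
  bootstrap confidence intervals.

* **Sum of variances of principal-coordinate scores** on a tips+ancestors
  matrix: the same dissimilarity computed on the ancestrally reconstructed
  matrix is double-centered and eigendecomposed (classical PCoA); per bin,
  the variances of the retained axis scores of the rows present in the bin
  are summed, with bootstrap confidence intervals.

Negative PCoA eigenvalues (possible for non-Euclidean character distances)
are dropped and variance fractions are reported over the positive spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .strat import BinSequence, TaxonRange, bin_membership, interval_in_bin
from .charmatrix import CharacterMatrix
from .trees import TimescaledTree
from .ancstates import ancestor_node_labels

__all__ = [
    "DissimilarityMatrix",
    "Ordination",
    "DisparityCurve",
    "pairwise_dissimilarity",
    "binned_dissimilarity",
    "pcoa",
    "axes_for_variance",
    "presence_table",
    "sum_of_variances",
    "interval_average",
]


@dataclass
class DissimilarityMatrix:
    labels: list[str]
    values: np.ndarray   # (n, n), nan where no comparable characters
    weights: np.ndarray  # (n, n) int, number of mutually scored characters

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def submatrix(self, labels: list[str]) -> "DissimilarityMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DissimilarityMatrix(
            labels=list(labels),
            values=self.values[np.ix_(idx, idx)],
            weights=self.weights[np.ix_(idx, idx)],
        )


@dataclass
class Ordination:
    labels: list[str]
    eigenvalues: np.ndarray       # descending, positive part retained
    scores: np.ndarray            # (n, n_axes), axis j scaled by sqrt(eigenvalue j)
    variance_fraction: np.ndarray # eigenvalues / sum(positive eigenvalues)
    negative_eigenvalues: np.ndarray


@dataclass
class DisparityCurve:
    bins: BinSequence
    values: np.ndarray   # nan where undefined (<2 contributors)
    lower: np.ndarray
    upper: np.ndarray
    n_rows: np.ndarray   # contributors per bin
    statistic: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.bins.names,
                "value": self.values,
                "lower": self.lower,
                "upper": self.upper,
                "n": self.n_rows,
                "statistic": self.statistic,
            }
        )


def pairwise_dissimilarity(matrix: CharacterMatrix) -> DissimilarityMatrix:
    """Character-based dissimilarity with per-pair comparable-character weights."""
    if matrix.n_taxa < 2:
        raise ValueError("need at least two taxa")
    X = matrix.states
    n = matrix.n_taxa
    scored = ~np.isnan(X)
    span = matrix.state_range
    # per-character contribution scale: ordered -> |a-b|/span, unordered -> 0/1
    values = np.zeros((n, n))
    weights = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = scored[i] & scored[i + 1:]
        diff = np.abs(X[i] - X[i + 1:])
        contrib = np.where(matrix.ordered & (span > 0), diff / np.where(span > 0, span, 1.0),
                           (diff > 0).astype(float))
        contrib = np.where(both, contrib, 0.0)
        w = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(w > 0, contrib.sum(axis=1) / np.maximum(w, 1), np.nan)
        values[i, i + 1:] = d
        values[i + 1:, i] = d
        weights[i, i + 1:] = w
        weights[i + 1:, i] = w
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(labels=list(matrix.taxa), values=values, weights=weights)


def _weighted_mean(d: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * d) / np.sum(w))


def binned_dissimilarity(
    dissim: DissimilarityMatrix,
    ranges: list[TaxonRange],
    bins: BinSequence,
    stat: str = "weighted_mean",
    n_boot: int = 10_000,
    seed: int = 0,
) -> DisparityCurve:
    """Per-bin weighted mean (or median) pairwise dissimilarity with bootstrap CI.

    The bootstrap resamples taxa within the bin; replicates with fewer than
    two distinct taxa or no defined pair are discarded.
    """
    if stat not in {"weighted_mean", "median"}:
        raise ValueError("stat must be 'weighted_mean' or 'median'")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    by_taxon = {r.taxon: r for r in ranges}
    nb = len(bins)
    values = np.full(nb, np.nan)
    lower = np.full(nb, np.nan)
    upper = np.full(nb, np.nan)
    n_rows = np.zeros(nb, dtype=int)

    def _stat(idx: np.ndarray) -> float:
        ii, jj = np.triu_indices(len(idx), k=1)
        a, b = np.asarray(idx)[ii], np.asarray(idx)[jj]
        d = dissim.values[a, b]
        w = dissim.weights[a, b]
        ok = ~np.isnan(d) & (w > 0)
        if not ok.any():
            return np.nan
        if stat == "weighted_mean":
            return _weighted_mean(d[ok], w[ok])
        return float(np.median(d[ok]))

    for i, b in enumerate(bins):
        present = [
            k for k, lab in enumerate(dissim.labels)
            if lab in by_taxon and bin_membership(by_taxon[lab], b)
        ]
        n_rows[i] = len(present)
        if len(present) < 2:
            continue
        point = _stat(np.array(present))
        if np.isnan(point):
            continue
        values[i] = point
        reps = []
        for _ in range(n_boot):
            samp = rng.choice(present, size=len(present), replace=True)
            if len(set(samp.tolist())) < 2:
                continue
            v = _stat(samp)
            if not np.isnan(v):
                reps.append(v)
        if reps:
            lower[i], upper[i] = np.percentile(reps, [2.5, 97.5])
    return DisparityCurve(bins=bins, values=values, lower=lower, upper=upper,
                          n_rows=n_rows, statistic=stat)


def pcoa(dissim: DissimilarityMatrix) -> Ordination:
    """Classical metric scaling (principal coordinates) of a dissimilarity matrix.

    Requires every pair defined; undefined pairs are reported so the caller
    can reconstruct ancestors or prune taxa first.
    """
    D = dissim.values
    undefined = np.argwhere(np.isnan(np.triu(D, k=1)) & ~np.tri(len(D), dtype=bool))
    undef_pairs = [(dissim.labels[i], dissim.labels[j]) for i, j in undefined]
    if undef_pairs:
        raise ValueError(f"undefined dissimilarities for pairs: {undef_pairs[:10]}")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = scipy.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigval[0]), 1.0))
    pos = eigval > tol
    lam = eigval[pos]
    scores = eigvec[:, pos] * np.sqrt(lam)[None, :]
    return Ordination(
        labels=list(dissim.labels),
        eigenvalues=lam,
        scores=scores,
        variance_fraction=lam / lam.sum() if lam.size else lam,
        negative_eigenvalues=eigval[eigval < -tol],
    )


def axes_for_variance(ordination: Ordination, target: float = 0.95) -> int:
    """Smallest axis count whose cumulative variance fraction reaches ``target``."""
    if ordination.eigenvalues.size == 0:
        raise ValueError("ordination has no positive axes")
    cum = np.cumsum(ordination.variance_fraction)
    return int(np.searchsorted(cum, target - 1e-12) + 1)


def presence_table(
    labels: list[str],
    bins: BinSequence,
    ranges: list[TaxonRange],
    tree: TimescaledTree | None = None,
) -> pd.DataFrame:
    """Boolean rows-by-bins presence table for ordination rows.

    Tips are present where their stratigraphic range meets a bin; ancestral
    rows (labelled as by :func:`ancestor_node_labels`) are present over their
    subtending branch's duration interval (the root over its own age only).
    """
    by_taxon = {r.taxon: r for r in ranges}
    intervals: dict[str, tuple[float, float]] = {}
    if tree is not None:
        anc = ancestor_node_labels(tree)
        for node in tree.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            older = node.parent_node.age if node.parent_node is not None else node.age
            intervals[anc[id(node)]] = (older, node.age)
    out = np.zeros((len(labels), len(bins)), dtype=bool)
    for i, lab in enumerate(labels):
        if lab in by_taxon:
            out[i] = [bin_membership(by_taxon[lab], b) for b in bins]
        elif lab in intervals:
            older, younger = intervals[lab]
            out[i] = [interval_in_bin(older, younger, b) for b in bins]
        else:
            raise KeyError(f"row {lab!r} has neither a range nor a branch interval")
    return pd.DataFrame(out, index=labels, columns=bins.names)


def sum_of_variances(
    ordination: Ordination,
    presence: pd.DataFrame,
    bins: BinSequence,
    k: int,
    n_boot: int = 10_000,
    seed: int = 0,
) -> DisparityCurve:
    """Per-bin sum over the first ``k`` axes of the score variances (ddof=1).

    95% CI by bootstrapping rows within each bin; bins with fewer than two
    present rows are undefined.
    """
    if k > ordination.scores.shape[1]:
        raise ValueError(f"k={k} exceeds retained axes ({ordination.scores.shape[1]})")
    rng = np.random.default_rng(seed)
    S = ordination.scores[:, :k]
    row_index = {lab: i for i, lab in enumerate(ordination.labels)}
    nb = len(bins)
    values = np.full(nb, np.nan)
    lower = np.full(nb, np.nan)
    upper = np.full(nb, np.nan)
    n_rows = np.zeros(nb, dtype=int)
    for i, name in enumerate(bins.names):
        rows = [row_index[lab] for lab in presence.index
                if presence.loc[lab, name] and lab in row_index]
        n_rows[i] = len(rows)
        if len(rows) < 2:
            continue
        X = S[rows]
        values[i] = float(X.var(axis=0, ddof=1).sum())
        reps = []
        for _ in range(n_boot):
            samp = rng.integers(len(rows), size=len(rows))
            Xb = X[samp]
            if len(set(samp.tolist())) < 2:
                continue
            reps.append(float(Xb.var(axis=0, ddof=1).sum()))
        if reps:
            lower[i], upper[i] = np.percentile(reps, [2.5, 97.5])
    return DisparityCurve(bins=bins, values=values, lower=lower, upper=upper,
                          n_rows=n_rows, statistic="sum_of_variances")


def interval_average(curve: DisparityCurve, bin_names: list[str]) -> float:
    """Unweighted mean of the defined per-bin values over a bin subset."""
    idx = [curve.bins.names.index(n) for n in bin_names]
    vals = curve.values[idx]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("all bins in the subset are undefined")
    return float(vals.mean())
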