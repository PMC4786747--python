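"""Ecomorphological guild discovery from continuous trait data.

Traits are centered and scaled to unit variance, converted to Euclidean
distances, and clustered by Ward's minimum-variance agglomeration.  Cluster
support uses the multiscale bootstrap: trait columns are resampled with
replacement at a ladder of sizes around the original, the recovery frequency
of each original cluster is probit-transformed, the signed distance ``v`` and
curvature ``c`` of the cluster boundary are fitted by weighted least squares
to ``z(r) = v*sqrt(r) + c/sqrt(r)``, and the approximately unbiased support is
``AU = 1 - Phi(v - c)`` (the plain bootstrap probability is the recovery
frequency at scale 1).

With only seven traits the resampling ladder covers sizes of roughly 4-10
columns; AU values in this small-feature regime are indicative rather than
sharply calibrated, which mirrors how such support values are used on real
ecomorphological tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import norm

__all__ = [
    "Dendrogram",
    "scale_traits",
    "ward_cluster",
    "multiscale_bootstrap_support",
    "cut_guilds",
    "guilds_per_bin",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 1))


@dataclass
class ClusterSupport:
    members: frozenset
    bp: float                     # recovery frequency at scale 1
    au: float
    v: float                      # fitted signed distance
    c: float                      # fitted curvature
    never_recovered: bool = False


@dataclass
class Dendrogram:
    labels: list[str]
    linkage_matrix: np.ndarray            # scipy linkage, heights on distance scale
    support: dict[frozenset, ClusterSupport] = field(default_factory=dict)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def clusters(self) -> list[frozenset]:
        """Member sets of all internal nodes, in merge order (root last)."""
        n = len(self.labels)
        sets: list[frozenset] = []
        current: dict[int, frozenset] = {i: frozenset([self.labels[i]]) for i in range(n)}
        for step, (a, b, _, _) in enumerate(self.linkage_matrix):
            merged = current[int(a)] | current[int(b)]
            current[n + step] = merged
            sets.append(merged)
        return sets


def scale_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Center each trait to mean 0 and scale to unit variance (ddof=1)."""
    if len(table) < 2:
        raise ValueError("need at least two taxa")
    if table.isna().any().any():
        cells = [(i, c) for i, r in table.iterrows() for c in table.columns
                 if pd.isna(r[c])]
        raise ValueError(f"missing trait values at {cells}")
    sd = table.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance traits: {zero}")
    return (table - table.mean()) / sd


def ward_cluster(scaled: pd.DataFrame) -> Dendrogram:
    """Ward minimum-variance agglomeration on Euclidean distances."""
    if len(scaled) < 2:
        raise ValueError("need at least two taxa")
    Z = linkage(scaled.to_numpy(), method="ward")
    return Dendrogram(labels=list(scaled.index), linkage_matrix=Z)


def _cluster_sets(X: np.ndarray, labels: list[str]) -> set[frozenset]:
    Z = linkage(X, method="ward")
    n = len(labels)
    current: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out: set[frozenset] = set()
    for step, (a, b, _, _) in enumerate(Z):
        merged = current[int(a)] | current[int(b)]
        current[n + step] = merged
        out.add(merged)
    return out


def multiscale_bootstrap_support(
    scaled: pd.DataFrame,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    B: int = 1000,
    seed: int = 0,
) -> Dendrogram:
    """Attach BP and AU support to every cluster of the Ward dendrogram.

    For each scale ``r`` the trait columns are resampled with replacement to
    ``round(r * n_traits)`` columns, the rows reclustered, and each original
    cluster's recovery frequency recorded; the probit-transformed frequencies
    are fitted across scales by weighted least squares (binomial weights) to
    ``v*sqrt(r) + c/sqrt(r)``.  Clusters never recovered at any scale get
    ``AU = 0`` with a flag.
    """
    if B < 100:
        raise ValueError("B must be >= 100 per scale")
    dendro = ward_cluster(scaled)
    clusters = dendro.clusters()
    labels = dendro.labels
    X = scaled.to_numpy()
    n_traits = X.shape[1]
    rng = np.random.default_rng(seed)

    counts = {cl: np.zeros(len(scales)) for cl in clusters}
    for s_i, r in enumerate(scales):
        m = max(1, int(round(r * n_traits)))
        for _ in range(B):
            cols = rng.integers(n_traits, size=m)
            rec = _cluster_sets(X[:, cols], labels)
            for cl in clusters:
                if cl in rec:
                    counts[cl][s_i] += 1

    sqrt_r = np.sqrt(np.asarray(scales))
    design = np.column_stack([sqrt_r, 1.0 / sqrt_r])
    root = frozenset(labels)
    for cl in clusters:
        bp_r = counts[cl] / B
        s1 = int(np.argmin(np.abs(np.asarray(scales) - 1.0)))
        bp_at_1 = float(bp_r[s1])
        if cl == root:
            dendro.support[cl] = ClusterSupport(cl, 1.0, 1.0, -np.inf, 0.0)
            continue
        if np.all(bp_r == 0):
            dendro.support[cl] = ClusterSupport(cl, 0.0, 0.0, np.inf, 0.0,
                                                never_recovered=True)
            continue
        clipped = np.clip(bp_r, 1.0 / (2 * B), 1.0 - 1.0 / (2 * B))
        z = norm.ppf(1.0 - clipped)
        if np.ptp(clipped) == 0:
            # scale-constant recovery: the {sqrt(r), 1/sqrt(r)} basis cannot
            # represent a constant, so the boundary is treated as flat
            # (zero curvature) and AU coincides with BP
            v = float(z[0])
            dendro.support[cl] = ClusterSupport(cl, bp_at_1, float(1.0 - norm.cdf(v)),
                                                v, 0.0)
            continue
        # binomial variance of the probit-transformed frequency
        w = B * norm.pdf(z) ** 2 / (clipped * (1.0 - clipped))
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * W[:, None], z * W, rcond=None)
        v, c = float(coef[0]), float(coef[1])
        au = float(1.0 - norm.cdf(v - c))
        dendro.support[cl] = ClusterSupport(cl, bp_at_1, au, v, c)
    return dendro


def cut_guilds(
    dendro: Dendrogram,
    k: int | None = None,
    au_threshold: float | None = None,
) -> pd.Series:
    """Guild labels per taxon, by a k-cluster cut or by AU-supported clusters.

    With ``au_threshold``, the dendrogram is walked from the root and the
    maximal non-root clusters with ``AU >= threshold`` become guilds; taxa in
    no supported cluster become singleton guilds.
    """
    labels = dendro.labels
    if (k is None) == (au_threshold is None):
        raise ValueError("give exactly one of k or au_threshold")
    if k is not None:
        if not 1 <= k <= len(labels):
            raise ValueError(f"cannot cut {len(labels)} taxa into {k} guilds")
        flat = fcluster(dendro.linkage_matrix, t=k, criterion="maxclust")
        if len(set(flat)) != k:
            raise ValueError(f"dendrogram does not admit a cut into exactly {k} guilds")
        return pd.Series(flat, index=labels, name="guild")
    if not dendro.support:
        raise ValueError("AU threshold cut requires bootstrap support")
    clusters = sorted(dendro.clusters(), key=len, reverse=True)
    root = frozenset(labels)
    assignment: dict[str, int] = {}
    g = 0
    for cl in clusters:
        if cl == root:
            continue
        sup = dendro.support.get(cl)
        if sup is None or sup.au < au_threshold:
            continue
        if any(t in assignment for t in cl):
            continue  # an enclosing (maximal) cluster already claimed these taxa
        g += 1
        for t in cl:
            assignment[t] = g
    for t in labels:
        if t not in assignment:
            g += 1
            assignment[t] = g
    return pd.Series([assignment[t] for t in labels], index=labels, name="guild")


def guilds_per_bin(assignment: pd.Series, ranges, bins) -> pd.Series:
    """Number of distinct guilds among taxa present (range-through) per bin."""
    from .strat import bin_membership

    by_taxon = {r.taxon: r for r in ranges}
    missing = [t for t in assignment.index if t not in by_taxon]
    if missing:
        raise ValueError(f"assigned taxa without ranges: {missing}")
    out = []
    for b in bins:
        present = {assignment[t] for t in assignment.index
                   if bin_membership(by_taxon[t], b)}
        out.append(len(present))
    return pd.Series(out, index=bins.names, name="n_guilds")
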