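"""Synthetic clades with known truth.

Forward-time birth--death clades, Mk-evolved discrete characters (ordered and
unordered, with missing data), homogeneous-Poisson fossil preservation giving
FAD/LAD ranges and per-bin formation counts, Gaussian-mixture ecomorph traits
with planted guilds, and AR(1) environmental series.  Everything is
deterministic under a seed, and every generator returns its ground truth so
downstream estimators can be validated against it.

Conventions: time runs in Ma, decreasing toward the present.  A taxon is a
tip lineage; its true duration runs from the age of its subtending branch's
origin (its parent node) to its tip age (extinction, or 0 if extant at the
end of the simulation).  Preservation is a homogeneous Poisson process per
lineage, matching the constant-recovery assumption of the stratigraphic
confidence-interval machinery this package validates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .strat import BinSequence, TaxonRange, interval_in_bin
from .charmatrix import CharacterMatrix
from .trees import TimescaledTree

__all__ = [
    "SimConfig",
    "SimOutput",
    "CladeDiedOut",
    "simulate_birth_death",
    "simulate_preservation",
    "simulate_characters",
    "simulate_ecotraits",
    "simulate_env",
    "ar1_series",
    "simulate_clade",
]


class CladeDiedOut(RuntimeError):
    """Raised when a birth--death run leaves fewer than two tips."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic clade.

    Defaults describe a moderately sized marine-reptile-like clade: ~160 My
    of history, slow net diversification, sparse fossil sampling, a character
    matrix the size and missingness of a real morphological data set, three
    ecomorph guilds and moderately autocorrelated environments.
    """

    speciation_rate: float = 0.07   # events/My/lineage
    extinction_rate: float = 0.05   # events/My/lineage
    preservation_rate: float = 0.1  # finds/My/lineage
    n_characters: int = 88
    fraction_ordered: float = 3 / 88
    char_rate: float = 0.02         # changes/My/character
    missing_fraction: float = 0.453
    n_guilds: int = 3
    guild_separation: float = 6.0   # distance between guild means, in SD units
    env_phi: float = 0.5            # AR(1) coefficient
    env_sigma: float = 1.0
    origin_age: float = 160.0       # Ma
    pulse_age: float | None = None  # optional mass-extinction pulse
    pulse_kill: float = 0.8         # per-lineage death probability at the pulse
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("speciation_rate", "extinction_rate", "preservation_rate",
                     "char_rate", "env_sigma", "origin_age"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fraction_ordered", "missing_fraction", "pulse_kill"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(self.env_phi) >= 1:
            raise ValueError("env_phi must satisfy |phi| < 1")
        if self.n_guilds < 1:
            raise ValueError("n_guilds must be >= 1")


@dataclass
class SimOutput:
    config: SimConfig
    true_tree: TimescaledTree
    ranges: list[TaxonRange]
    matrix: CharacterMatrix
    traits: pd.DataFrame
    guild_labels: pd.Series
    env: pd.DataFrame
    occurrences: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# Birth--death tree


def simulate_birth_death(config: SimConfig, rng: np.random.Generator | None = None
                         ) -> TimescaledTree:
    """Forward-time birth--death clade from ``origin_age`` toward the present.

    Event-driven (Gillespie) simulation over the whole set of live lineages.
    If ``pulse_age`` is set, each lineage alive at that instant dies with
    probability ``pulse_kill`` — a piecewise extinction spike planted so that
    per-bin extinction-rate estimators can be checked against known truth.
    """
    if config.speciation_rate <= 0 and config.extinction_rate <= 0:
        raise ValueError("need a positive speciation or extinction rate")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.is_rooted = True
    root = tree.seed_node
    root.age = config.origin_age

    live: list[dendropy.Node] = [root]
    t = config.origin_age
    pulse_pending = config.pulse_age is not None
    per_event = config.speciation_rate + config.extinction_rate
    counter = 0

    while live and t > 0:
        total = per_event * len(live)
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        t_next = t - wait
        if pulse_pending and t_next < config.pulse_age <= t:
            # apply the pulse before the next ordinary event
            t = config.pulse_age
            survivors = []
            for node in live:
                if rng.random() < config.pulse_kill:
                    node.age = t
                else:
                    survivors.append(node)
            live = survivors
            pulse_pending = False
            continue
        if t_next <= 0:
            break
        t = t_next
        idx = rng.integers(len(live))
        node = live.pop(idx)
        node.age = t
        if rng.random() < config.speciation_rate / per_event:
            for _ in range(2):
                child = dendropy.Node()
                node.add_child(child)
                live.append(child)
        # else: extinction — node simply leaves the live set with age t

    for node in live:  # lineages surviving to the present
        node.age = 0.0

    leaves = [n for n in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise CladeDiedOut(
            f"clade left {len(leaves)} tip(s) under seed {config.seed}"
        )
    for leaf in leaves:
        counter += 1
        leaf.taxon = taxon_ns.new_taxon(f"t{counter}")
    return TimescaledTree(tree=tree, label="true")


# ---------------------------------------------------------------------------
# Fossil preservation


def simulate_preservation(
    true_tree: TimescaledTree,
    preservation_rate: float,
    bins: BinSequence,
    rng: np.random.Generator,
    formation_factor: float = 0.5,
    background_formations: float = 3.0,
) -> tuple[list[TaxonRange], pd.DataFrame, dict[str, np.ndarray]]:
    """Poisson fossil finds along each tip lineage.

    Returns observed ranges (FAD = oldest find, LAD = youngest; unsampled
    lineages dropped), a per-bin occurrence table, and the raw find ages.
    Per-bin focal formation counts are Poisson with mean proportional to the
    number of finds in the bin; group formation counts add a Poisson
    background so ``n_focal <= n_group`` always holds.
    """
    if preservation_rate < 0:
        raise ValueError("preservation_rate must be >= 0")
    ranges: list[TaxonRange] = []
    finds: dict[str, np.ndarray] = {}
    finds_per_bin = np.zeros(len(bins))
    for leaf in true_tree.tree.leaf_node_iter():
        origin = leaf.parent_node.age if leaf.parent_node is not None else true_tree.root_age
        duration = origin - leaf.age
        n = rng.poisson(preservation_rate * duration)
        if n == 0:
            continue
        ages = leaf.age + rng.random(n) * duration
        finds[leaf.taxon.label] = np.sort(ages)[::-1]
        ranges.append(TaxonRange(taxon=leaf.taxon.label,
                                 fad=float(ages.max()), lad=float(ages.min())))
        for a in ages:
            for i, b in enumerate(bins):
                if b.contains(a):
                    finds_per_bin[i] += 1
                    break
    n_focal = rng.poisson(formation_factor * finds_per_bin)
    n_group = n_focal + rng.poisson(background_formations, size=len(bins))
    occ = pd.DataFrame(
        {
            "bin": bins.names,
            "n_finds": finds_per_bin.astype(int),
            "n_focal_formations": n_focal,
            "n_group_formations": n_group,
        }
    )
    return ranges, occ, finds


# ---------------------------------------------------------------------------
# Discrete characters (Mk)


def _simulate_char_on_tree(true_tree, rate, n_states, ordered, rng):
    """One character: CTMC jumps along each branch; returns tip states + #changes."""
    states: dict[int, int] = {}
    n_changes = 0
    root = true_tree.tree.seed_node
    states[id(root)] = int(rng.integers(n_states))  # stationary = uniform
    for node in true_tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        s = states[id(node.parent_node)]
        remaining = node.parent_node.age - node.age
        while True:
            # leave rate: `rate` in the interior; rate/2 at ordered endpoints
            leave = rate
            if ordered and n_states > 1 and (s == 0 or s == n_states - 1):
                leave = rate / 2
            if leave <= 0:
                break
            wait = rng.exponential(1.0 / leave)
            if wait >= remaining:
                break
            remaining -= wait
            if ordered:
                if s == 0:
                    s = 1
                elif s == n_states - 1:
                    s = n_states - 2
                else:
                    s += 1 if rng.random() < 0.5 else -1
            else:
                others = [k for k in range(n_states) if k != s]
                s = others[rng.integers(len(others))]
            n_changes += 1
        states[id(node)] = s
    tips = {leaf.taxon.label: states[id(leaf)]
            for leaf in true_tree.tree.leaf_node_iter()}
    return tips, n_changes


def simulate_characters(
    true_tree: TimescaledTree,
    config: SimConfig,
    rng: np.random.Generator,
    taxa: list[str] | None = None,
) -> tuple[CharacterMatrix, int]:
    """Mk tip states for ``n_characters`` characters, with a missing-data mask.

    Unordered characters use a symmetric k-state chain (k drawn from {2,3,4});
    ordered ones a stepwise ±1 chain over {3,4,5} states.  Root states come
    from the stationary (uniform) distribution.  Returns the matrix restricted
    to ``taxa`` (default: all tips) and the total number of true changes.
    """
    all_tips = true_tree.tip_labels()
    taxa = list(taxa) if taxa is not None else all_tips
    n_ord = int(round(config.fraction_ordered * config.n_characters))
    ordered_flags = np.zeros(config.n_characters, dtype=bool)
    ordered_flags[:n_ord] = True
    grid = np.full((len(taxa), config.n_characters), np.nan)
    total_changes = 0
    for j in range(config.n_characters):
        if ordered_flags[j]:
            k = int(rng.choice([3, 4, 5]))
        else:
            k = int(rng.choice([2, 3, 4], p=[0.6, 0.3, 0.1]))
        tips, changes = _simulate_char_on_tree(
            true_tree, config.char_rate, k, ordered_flags[j], rng
        )
        total_changes += changes
        for i, t in enumerate(taxa):
            grid[i, j] = tips[t]
    if config.missing_fraction > 0:
        mask = rng.random(grid.shape) < config.missing_fraction
        grid[mask] = np.nan
    return CharacterMatrix(taxa=taxa, states=grid, ordered=ordered_flags), total_changes


# ---------------------------------------------------------------------------
# Ecomorph traits

TRAIT_NAMES = [
    "tooth_size",
    "crown_shape",
    "crown_size_vs_gullet",
    "symphysial_length",
    "snout_depth",
    "sclerotic_aperture",
    "tooth_wear",
]


def simulate_ecotraits(
    taxa: list[str],
    n_guilds: int,
    separation: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gaussian-mixture traits with planted guilds.

    Seven unit-variance traits; guild means are vertices of a regular simplex
    with edge length ``separation`` (in within-guild SD units), rotated by a
    fixed orthonormal frame so the shift is spread over all traits.  Spreading
    matters: per-trait standardisation then shrinks signal and noise almost
    uniformly, preserving the planted geometry, whereas a mean shift confined
    to one trait would be crushed by that trait's inflated variance.
    """
    if n_guilds < 1:
        raise ValueError("n_guilds must be >= 1")
    if n_guilds > len(TRAIT_NAMES):
        raise ValueError("n_guilds cannot exceed the number of traits")
    labels = rng.integers(n_guilds, size=len(taxa))
    # guarantee every guild is represented when possible
    if len(taxa) >= n_guilds:
        labels[:n_guilds] = np.arange(n_guilds)
        rng.shuffle(labels)
    p = len(TRAIT_NAMES)
    # deterministic generic orthonormal frame (independent of the rng)
    seedmat = np.sin(np.arange(1, p * p + 1, dtype=float)).reshape(p, p)
    frame, _ = np.linalg.qr(seedmat)
    means = (separation / np.sqrt(2)) * np.eye(n_guilds, p) @ frame.T
    values = means[labels] + rng.standard_normal((len(taxa), len(TRAIT_NAMES)))
    traits = pd.DataFrame(values, index=taxa, columns=TRAIT_NAMES)
    return traits, pd.Series(labels, index=taxa, name="guild")


# ---------------------------------------------------------------------------
# Environmental series


def ar1_series(n: int, phi: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1): x_t = phi x_{t-1} + e_t, e ~ N(0, sigma^2)."""
    if abs(phi) >= 1:
        raise ValueError("|phi| must be < 1")
    x = np.empty(n)
    if sigma == 0:
        x[:] = 0.0
        return x
    x[0] = rng.normal(0.0, sigma / np.sqrt(1 - phi**2))
    eps = rng.normal(0.0, sigma, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


ENV_VARIABLES = ["sea_level_short", "sea_level_long", "d18o", "d13c"]


def simulate_env(
    bins: BinSequence,
    phi: float,
    sigma: float,
    rng: np.random.Generator,
    steps_per_bin: int = 20,
) -> pd.DataFrame:
    """Per-bin mean and within-bin variance of AR(1) environmental variables."""
    out = {"bin": bins.names}
    for var in ENV_VARIABLES:
        series = ar1_series(len(bins) * steps_per_bin, phi, sigma, rng)
        chunks = series.reshape(len(bins), steps_per_bin)
        out[f"{var}_mean"] = chunks.mean(axis=1)
        out[f"{var}_var"] = chunks.var(axis=1, ddof=1)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Whole-bundle driver


def default_bins(config: SimConfig, width: float = 5.0) -> BinSequence:
    """Contiguous bins of ``width`` My spanning the clade's whole history."""
    from .strat import TimeBin

    edges = np.arange(0.0, config.origin_age + width, width)[::-1]
    return BinSequence(
        TimeBin(f"bin_{old:.0f}_{young:.0f}", float(old), float(young))
        for old, young in zip(edges[:-1], edges[1:])
    )


def true_standing_diversity(true_tree: TimescaledTree, bins: BinSequence) -> np.ndarray:
    """Per-bin count of tip lineages alive (origin-to-extinction interval)."""
    counts = np.zeros(len(bins), dtype=int)
    for leaf in true_tree.tree.leaf_node_iter():
        origin = leaf.parent_node.age if leaf.parent_node is not None else true_tree.root_age
        for i, b in enumerate(bins):
            if interval_in_bin(origin, leaf.age, b):
                counts[i] += 1
    return counts


def observed_cladogram(bundle: "SimOutput") -> dendropy.Tree:
    """True tree pruned to the preserved taxa, with ages stripped.

    This is the cladogram an empiricist would have: topology over observed
    taxa only, no branch-duration information.
    """
    keep = [r.taxon for r in bundle.ranges]
    tree = bundle.true_tree.tree.clone(depth=1)
    tree.retain_taxa_with_labels(keep)
    for node in tree:
        if hasattr(node, "age"):
            del node.age
        node.edge.length = None
    return tree


def simulate_clade(
    config: SimConfig,
    bins: BinSequence | None = None,
    max_retries: int = 20,
) -> SimOutput:
    """Generate a full synthetic input bundle plus its truth record.

    Retries with consecutive seeds (recorded in the truth block) if the clade
    dies before leaving two tips or before any lineage is preserved.
    """
    attempt = 0
    last_err: Exception | None = None
    while attempt <= max_retries:
        cfg = replace(config, seed=config.seed + attempt)
        rng = np.random.default_rng(cfg.seed)
        try:
            tree = simulate_birth_death(cfg, rng)
        except CladeDiedOut as err:
            last_err = err
            attempt += 1
            continue
        use_bins = bins if bins is not None else default_bins(cfg)
        ranges, occ, finds = simulate_preservation(
            tree, cfg.preservation_rate, use_bins, rng
        )
        if len(ranges) < 2:
            last_err = CladeDiedOut("fewer than two lineages preserved")
            attempt += 1
            continue
        observed = [r.taxon for r in ranges]
        matrix, n_changes = simulate_characters(tree, cfg, rng, taxa=observed)
        traits, guilds = simulate_ecotraits(
            observed, cfg.n_guilds, cfg.guild_separation, rng
        )
        env = simulate_env(use_bins, cfg.env_phi, cfg.env_sigma, rng)
        truth = {
            "seed_used": cfg.seed,
            "retries": attempt,
            "n_tips_true": len(tree.tip_labels()),
            "n_tips_observed": len(observed),
            "true_standing_diversity": true_standing_diversity(tree, use_bins).tolist(),
            "true_character_changes": n_changes,
            "true_guilds": guilds.to_dict(),
            "rates": {
                "speciation": cfg.speciation_rate,
                "extinction": cfg.extinction_rate,
                "preservation": cfg.preservation_rate,
            },
            "pulse_age": cfg.pulse_age,
            "bin_names": use_bins.names,
        }
        return SimOutput(
            config=cfg,
            true_tree=tree,
            ranges=ranges,
            matrix=matrix,
            traits=traits,
            guild_labels=guilds,
            env=env,
            occurrences=occ,
            truth=truth,
        )
    raise CladeDiedOut(
        f"no viable clade in {max_retries + 1} attempts: {last_err}"
    )
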