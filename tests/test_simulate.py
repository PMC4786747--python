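"""Synthetic clade generator: determinism, distributional sanity and truth."""

import numpy as np
import pytest

from cladewane.strat import BinSequence, TimeBin
from cladewane.simulate import (
    CladeDiedOut,
    SimConfig,
    ar1_series,
    default_bins,
    simulate_birth_death,
    simulate_characters,
    simulate_clade,
    simulate_ecotraits,
    simulate_env,
    simulate_preservation,
    true_standing_diversity,
)
from cladewane.diversity import taxic_diversity


class TestBirthDeath:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=42)
        a = simulate_birth_death(cfg, np.random.default_rng(42))
        b = simulate_birth_death(cfg, np.random.default_rng(42))
        assert a.tree.as_string(schema="newick") == b.tree.as_string(schema="newick")
        assert [n.age for n in a.tree] == [n.age for n in b.tree]

    def test_extinct_clade_flagged(self):
        cfg = SimConfig(speciation_rate=0.01, extinction_rate=2.0, seed=1)
        with pytest.raises(CladeDiedOut):
            simulate_birth_death(cfg, np.random.default_rng(1))

    def test_yule_expected_tip_count(self):
        """With no extinction, mean tip count approaches e^(lambda t)."""
        lam, t = 0.05, 40.0
        expected = np.exp(lam * t)
        rng = np.random.default_rng(0)
        counts = []
        cfg = SimConfig(speciation_rate=lam, extinction_rate=0.0, origin_age=t)
        for _ in range(1000):
            tree = None
            try:
                tree = simulate_birth_death(cfg, rng)
                counts.append(len(tree.tip_labels()))
            except CladeDiedOut:
                counts.append(1)
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - expected) < 3 * se + 0.05

    def test_pulse_kills_lineages_at_pulse_age(self):
        cfg = SimConfig(speciation_rate=0.1, extinction_rate=0.02,
                        origin_age=80.0, pulse_age=30.0, pulse_kill=1.0, seed=3)
        tree = simulate_birth_death(cfg, np.random.default_rng(3))
        ages = [n.age for n in tree.tree.leaf_node_iter()]
        assert max(ages) >= 30.0
        assert all(a >= 30.0 for a in ages)  # nothing survives the pulse


def _viable_tree(cfg: SimConfig):
    """First seed at or above cfg.seed whose clade leaves >= 2 tips."""
    from dataclasses import replace

    for offset in range(50):
        trial = replace(cfg, seed=cfg.seed + offset)
        try:
            return trial, simulate_birth_death(trial, np.random.default_rng(trial.seed))
        except CladeDiedOut:
            continue
    raise AssertionError("no viable clade in 50 seeds")


class TestPreservation:
    def _tree(self, seed=5):
        return _viable_tree(SimConfig(seed=seed))

    def test_ranges_inside_true_durations(self):
        cfg, tree = self._tree()
        bins = default_bins(cfg)
        ranges, occ, finds = simulate_preservation(tree, 0.3, bins,
                                                   np.random.default_rng(0))
        origin = {l.taxon.label: (l.parent_node.age, l.age)
                  for l in tree.tree.leaf_node_iter()}
        for r in ranges:
            o, e = origin[r.taxon]
            assert o >= r.fad >= r.lad >= e

    def test_unsampled_fraction_matches_poisson_zero_class(self):
        cfg, tree = self._tree()
        durations = [l.parent_node.age - l.age for l in tree.tree.leaf_node_iter()]
        lam = 0.1
        expected_sampled = sum(1 - np.exp(-lam * d) for d in durations)
        bins = default_bins(cfg)
        rng = np.random.default_rng(1)
        n_sampled = [len(simulate_preservation(tree, lam, bins, rng)[0])
                     for _ in range(200)]
        assert np.mean(n_sampled) == pytest.approx(expected_sampled, rel=0.15)

    def test_high_rate_fad_approaches_origin(self):
        cfg, tree = self._tree()
        bins = default_bins(cfg)
        errs = {}
        for lam in (0.5, 5.0):
            ranges, _, _ = simulate_preservation(tree, lam, bins,
                                                 np.random.default_rng(2))
            origin = {l.taxon.label: l.parent_node.age
                      for l in tree.tree.leaf_node_iter()}
            errs[lam] = np.mean([origin[r.taxon] - r.fad for r in ranges])
        assert errs[5.0] < errs[0.5]

    def test_formation_counts_bounded(self):
        cfg, tree = self._tree()
        bins = default_bins(cfg)
        _, occ, _ = simulate_preservation(tree, 0.3, bins, np.random.default_rng(3))
        assert (occ["n_focal_formations"] <= occ["n_group_formations"]).all()


class TestCharacters:
    def test_zero_rate_uniform_tips(self):
        cfg, tree = _viable_tree(
            SimConfig(char_rate=0.0, missing_fraction=0.0, n_characters=10, seed=7)
        )
        m, changes = simulate_characters(tree, cfg, np.random.default_rng(0))
        assert changes == 0
        for j in range(m.n_characters):
            assert len(set(m.states[:, j])) == 1

    def test_expected_change_count(self):
        """Total changes track rate x tree length x characters (all-unordered
        chains have leave rate == char_rate everywhere)."""
        cfg, tree = _viable_tree(
            SimConfig(char_rate=0.02, fraction_ordered=0.0, n_characters=30,
                      missing_fraction=0.0, seed=8)
        )
        length = tree.total_branch_duration()
        expected = cfg.char_rate * length * cfg.n_characters
        rng = np.random.default_rng(1)
        totals = [simulate_characters(tree, cfg, rng)[1] for _ in range(60)]
        se = np.std(totals) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - expected) < 3 * se + 0.5

    def test_missing_mask_fraction(self):
        cfg, tree = _viable_tree(SimConfig(missing_fraction=0.453, seed=9))
        m, _ = simulate_characters(tree, cfg, np.random.default_rng(2))
        assert m.missing_fraction == pytest.approx(0.453, abs=0.04)


class TestEcotraits:
    def test_separated_guilds_recoverable(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(10)
        taxa = [f"t{i}" for i in range(30)]
        traits, labels = simulate_ecotraits(taxa, 3, 10.0, rng)
        assert silhouette_score(traits, labels) > 0.5

    def test_no_separation_single_cloud(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(11)
        taxa = [f"t{i}" for i in range(40)]
        traits, labels = simulate_ecotraits(taxa, 3, 0.0, rng)
        assert silhouette_score(traits, labels) < 0.1

    def test_every_guild_represented(self):
        rng = np.random.default_rng(12)
        _, labels = simulate_ecotraits([f"t{i}" for i in range(9)], 3, 5.0, rng)
        assert set(labels) == {0, 1, 2}


class TestEnv:
    def test_white_noise_variance(self):
        rng = np.random.default_rng(13)
        x = ar1_series(20000, 0.0, 1.5, rng)
        assert x.var() == pytest.approx(1.5**2, rel=0.05)

    def test_stationary_variance_closed_form(self):
        rng = np.random.default_rng(14)
        phi, sigma = 0.7, 1.0
        x = ar1_series(40000, phi, sigma, rng)
        assert x.var() == pytest.approx(sigma**2 / (1 - phi**2), rel=0.06)

    def test_zero_sigma_constant(self):
        rng = np.random.default_rng(15)
        x = ar1_series(100, 0.5, 0.0, rng)
        np.testing.assert_allclose(x, 0.0)

    def test_env_table_shape(self):
        bins = BinSequence([TimeBin("a", 20, 10), TimeBin("b", 10, 0)])
        env = simulate_env(bins, 0.5, 1.0, np.random.default_rng(16))
        assert list(env["bin"]) == ["a", "b"]
        assert (env.filter(like="_var") >= 0).all().all()


class TestBundle:
    def test_deterministic(self):
        a = simulate_clade(SimConfig(seed=21))
        b = simulate_clade(SimConfig(seed=21))
        assert [r.taxon for r in a.ranges] == [r.taxon for r in b.ranges]
        np.testing.assert_array_equal(
            np.nan_to_num(a.matrix.states, nan=-1),
            np.nan_to_num(b.matrix.states, nan=-1),
        )
        assert a.truth == b.truth

    def test_truth_recovery_under_dense_sampling(self):
        """With near-exhaustive preservation, taxic diversity from observed
        ranges tracks true standing diversity within one lineage per bin."""
        cfg = SimConfig(origin_age=80.0, preservation_rate=50.0,
                        missing_fraction=0.0, seed=22)
        bundle = simulate_clade(cfg)
        bins = default_bins(bundle.config)
        tde = taxic_diversity(bundle.ranges, bins)
        truth = true_standing_diversity(bundle.true_tree, bins)
        assert np.max(np.abs(tde.values - truth)) <= 1

    def test_every_observed_taxon_preserved(self):
        bundle = simulate_clade(SimConfig(seed=23))
        matrix_taxa = set(bundle.matrix.taxa)
        assert {r.taxon for r in bundle.ranges} == matrix_taxa
        assert set(bundle.traits.index) == matrix_taxa
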