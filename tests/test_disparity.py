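"""Dissimilarity, ancestral reconstruction, PCoA and disparity curves."""

import numpy as np
import pytest

from conftest import brute_force_mpr, random_topology

from cladewane.strat import BinSequence, TaxonRange, TimeBin
from cladewane.charmatrix import CharacterMatrix
from cladewane.timescale import timescale_basic
from cladewane.trees import TimescaledTree
from cladewane.ancstates import mpr_state_sets, reconstruct_ancestors
from cladewane.disparity import (
    DissimilarityMatrix,
    axes_for_variance,
    binned_dissimilarity,
    interval_average,
    pairwise_dissimilarity,
    pcoa,
    presence_table,
    sum_of_variances,
)


def _matrix(rows, ordered=None, taxa=None):
    rows = np.asarray(rows, dtype=float)
    return CharacterMatrix(
        taxa=taxa or [f"t{i}" for i in range(rows.shape[0])],
        states=rows,
        ordered=ordered if ordered is not None else np.zeros(rows.shape[1], bool),
    )


def _bins(edges):
    return BinSequence(TimeBin(f"b{o}", o, y) for o, y in zip(edges[:-1], edges[1:]))


class TestDissimilarity:
    def test_identical_rows(self):
        m = _matrix([[0, 1, 2], [0, 1, 2]])
        d = pairwise_dissimilarity(m)
        assert d.values[0, 1] == 0
        assert d.weights[0, 1] == 3

    def test_missing_restricts_comparable(self):
        m = _matrix([[0, 1, np.nan], [0, 0, 1]])
        d = pairwise_dissimilarity(m)
        assert d.values[0, 1] == pytest.approx(0.5)
        assert d.weights[0, 1] == 2

    def test_ordered_scales_by_state_range(self):
        m = _matrix([[0, 0], [2, 2], [1, 0]],
                    ordered=np.array([True, False]))
        d = pairwise_dissimilarity(m)
        # char 1 ordered, range 2: |0-2|/2 = 1; char 2 unordered: 0 vs 2 -> 1
        assert d.values[0, 1] == pytest.approx(1.0)
        # |0-1|/2 = 0.5 and 0 == 0 -> mean 0.25
        assert d.values[0, 2] == pytest.approx(0.25)

    def test_no_shared_characters_undefined(self):
        m = _matrix([[0, np.nan], [np.nan, 1]])
        d = pairwise_dissimilarity(m)
        assert np.isnan(d.values[0, 1])
        assert d.weights[0, 1] == 0

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(1)
        grid = rng.integers(0, 3, size=(6, 10)).astype(float)
        grid[rng.random(grid.shape) < 0.3] = np.nan
        d = pairwise_dissimilarity(_matrix(grid))
        assert np.allclose(d.values, d.values.T, equal_nan=True)
        assert np.all(np.diag(d.values) == 0)


class TestBinnedDissimilarity:
    def test_weighted_mean_example(self):
        # three co-binned taxa engineered to give pair weights (2, 4) with
        # dissimilarities (0.5, 1.0): weighted mean 5/6
        values = np.array([[0, 0.5, np.nan], [0.5, 0, 1.0], [np.nan, 1.0, 0]])
        weights = np.array([[0, 2, 0], [2, 0, 4], [0, 4, 0]])
        d = DissimilarityMatrix(labels=["a", "b", "c"], values=values, weights=weights)
        ranges = [TaxonRange(t, 100, 95) for t in "abc"]
        curve = binned_dissimilarity(d, ranges, _bins([105, 95]), n_boot=10, seed=0)
        assert curve.values[0] == pytest.approx(5 / 6)

    def test_single_taxon_bin_undefined(self):
        m = _matrix([[0, 1], [1, 1]], taxa=["a", "b"])
        d = pairwise_dissimilarity(m)
        ranges = [TaxonRange("a", 100, 95), TaxonRange("b", 90, 85)]
        curve = binned_dissimilarity(d, ranges, _bins([105, 92.5, 80]), n_boot=10, seed=0)
        assert np.isnan(curve.values[0]) and np.isnan(curve.values[1])

    def test_identical_taxa_zero_width_ci(self):
        m = _matrix([[0, 1], [0, 1], [0, 1]])
        d = pairwise_dissimilarity(m)
        ranges = [TaxonRange(t, 100, 95) for t in m.taxa]
        curve = binned_dissimilarity(d, ranges, _bins([105, 90]), n_boot=50, seed=0)
        assert curve.values[0] == 0
        assert curve.lower[0] == curve.upper[0] == 0


class TestAncestralReconstruction:
    def test_unordered_worked_example(self, cherry_plus_outgroup, example_ranges):
        ts = timescale_basic(cherry_plus_outgroup, example_ranges)
        m = _matrix([[0.0], [0.0], [1.0]], taxa=["A", "B", "C"])
        anc = reconstruct_ancestors(m, ts)
        states = dict(zip(anc.taxa, anc.states[:, 0]))
        assert states["anc_2"] == 0          # the (A,B) node is unambiguous
        assert np.isnan(states["anc_1"])     # the root is ambiguous {0, 1}

    def test_ordered_cherry_ambiguous(self):
        import dendropy

        t = dendropy.Tree.get(data="(A,B);", schema="newick")
        t.is_rooted = True
        ranges = [TaxonRange("A", 100, 95), TaxonRange("B", 100, 95)]
        ts = timescale_basic(t, ranges)
        m = _matrix([[0.0], [2.0]], taxa=["A", "B"],
                    ordered=np.array([True]))
        anc = reconstruct_ancestors(m, ts)
        assert np.isnan(anc.states[-1, 0])  # {0,1,2} all cost 2

    def test_invariant_character_fills_all_ancestors(self, cherry_plus_outgroup,
                                                     example_ranges):
        ts = timescale_basic(cherry_plus_outgroup, example_ranges)
        m = _matrix([[1.0], [1.0], [1.0]], taxa=["A", "B", "C"])
        anc = reconstruct_ancestors(m, ts)
        assert np.all(anc.states == 1.0)

    def test_missing_fraction_never_increases(self, cherry_plus_outgroup,
                                              example_ranges):
        rng = np.random.default_rng(3)
        grid = rng.integers(0, 2, size=(3, 30)).astype(float)
        grid[rng.random(grid.shape) < 0.4] = np.nan
        m = _matrix(grid, taxa=["A", "B", "C"])
        ts = timescale_basic(cherry_plus_outgroup, example_ranges)
        anc = reconstruct_ancestors(m, ts)
        n_internal = 2
        blank = (m.missing_fraction * m.n_taxa + n_internal) / (m.n_taxa + n_internal)
        assert anc.missing_fraction <= blank + 1e-12

    @pytest.mark.parametrize("ordered", [False, True])
    def test_agrees_with_exhaustive_enumeration(self, ordered):
        """MPR sets match brute-force enumeration over random instances
        (trees to 6 tips, to 4 states, with missing tips)."""
        rng = np.random.default_rng(2024 + int(ordered))
        for rep in range(60):
            n_tips = int(rng.integers(3, 7))
            n_states = int(rng.integers(2, 5))
            labels = [f"t{i}" for i in range(n_tips)]
            topo = random_topology(labels, rng)
            for node in topo:
                node.age = 0.0  # ages are irrelevant to parsimony
            ts = TimescaledTree.__new__(TimescaledTree)
            ts.tree = topo
            ts.label = ""
            tip_states = {
                t: (np.nan if rng.random() < 0.2 else float(rng.integers(n_states)))
                for t in labels
            }
            got_sets, got_cost = mpr_state_sets(ts, tip_states, n_states, ordered)
            want_sets, want_cost = brute_force_mpr(topo, tip_states, n_states, ordered)
            assert got_cost == pytest.approx(want_cost)
            for node_id, want in want_sets.items():
                assert got_sets[node_id] == want


class TestPcoa:
    def test_equilateral_triangle_spectrum(self):
        d = DissimilarityMatrix(
            labels=["a", "b", "c"],
            values=np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
            weights=np.full((3, 3), 1),
        )
        ordn = pcoa(d)
        np.testing.assert_allclose(ordn.eigenvalues, [0.5, 0.5], atol=1e-9)

    def test_identical_points_collapse(self):
        d = DissimilarityMatrix(
            labels=["a", "b"], values=np.zeros((2, 2)), weights=np.full((2, 2), 1)
        )
        ordn = pcoa(d)
        assert ordn.eigenvalues.size == 0

    def test_collinear_points_single_axis(self):
        pts = np.array([0.0, 1.0, 3.0])
        D = np.abs(pts[:, None] - pts[None, :])
        d = DissimilarityMatrix(labels=list("abc"), values=D, weights=np.full((3, 3), 1))
        ordn = pcoa(d)
        assert ordn.eigenvalues.size == 1
        # recovered inter-point distances match the line
        got = np.abs(ordn.scores[:, 0][:, None] - ordn.scores[:, 0][None, :])
        np.testing.assert_allclose(got, D, atol=1e-9)

    def test_matches_scikit_bio(self):
        """Independent cross-check of the eigen-spectrum against skbio."""
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(5)
        pts = rng.standard_normal((7, 3))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d = DissimilarityMatrix(labels=[f"t{i}" for i in range(7)], values=D,
                                weights=np.full((7, 7), 1))
        ours = pcoa(d)
        theirs = skbio_pcoa(D, number_of_dimensions=6)
        np.testing.assert_allclose(
            ours.eigenvalues, theirs.eigvals.to_numpy()[: len(ours.eigenvalues)],
            atol=1e-8,
        )

    def test_undefined_pairs_rejected(self):
        vals = np.array([[0, np.nan], [np.nan, 0]])
        d = DissimilarityMatrix(labels=["a", "b"], values=vals, weights=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="undefined"):
            pcoa(d)


class TestAxesAndSov:
    def test_axes_for_variance(self):
        ordn_like = pcoa(
            DissimilarityMatrix(
                labels=list("abc"),
                values=np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
                weights=np.full((3, 3), 1),
            )
        )
        assert axes_for_variance(ordn_like, target=0.5) == 1
        assert axes_for_variance(ordn_like, target=0.75) == 2
        assert axes_for_variance(ordn_like, target=1.0) == 2

    def test_sum_of_variances_triangle(self):
        d = DissimilarityMatrix(
            labels=list("abc"),
            values=np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
            weights=np.full((3, 3), 1),
        )
        ordn = pcoa(d)
        bins = _bins([105, 95])
        ranges = [TaxonRange(t, 100, 96) for t in "abc"]
        pres = presence_table(list("abc"), bins, ranges)
        curve = sum_of_variances(ordn, pres, bins, k=2, n_boot=10, seed=0)
        # sum of eigenvalues / (n-1) = 1/2
        assert curve.values[0] == pytest.approx(0.5)

    def test_total_variance_conservation(self):
        """Sum of variances over all positive axes equals the total variance
        of the centered score cloud."""
        rng = np.random.default_rng(9)
        pts = rng.standard_normal((9, 4))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d = DissimilarityMatrix(labels=[f"t{i}" for i in range(9)], values=D,
                                weights=np.full((9, 9), 1))
        ordn = pcoa(d)
        direct = ordn.scores.var(axis=0, ddof=1).sum()
        assert direct == pytest.approx(ordn.eigenvalues.sum() / 8, abs=1e-9)

    def test_single_row_bin_undefined(self):
        d = DissimilarityMatrix(
            labels=list("ab"),
            values=np.array([[0.0, 1.0], [1.0, 0.0]]),
            weights=np.full((2, 2), 1),
        )
        ordn = pcoa(d)
        bins = _bins([105, 95, 85])
        ranges = [TaxonRange("a", 100, 96), TaxonRange("b", 92, 88)]
        pres = presence_table(list("ab"), bins, ranges)
        curve = sum_of_variances(ordn, pres, bins, k=1, n_boot=10, seed=0)
        assert np.isnan(curve.values).all()

    def test_interval_average(self):
        d = DissimilarityMatrix(
            labels=list("abc"),
            values=np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
            weights=np.full((3, 3), 1),
        )
        ordn = pcoa(d)
        bins = _bins([105, 95, 85])
        ranges = [TaxonRange(t, 100, 96) for t in "abc"]
        pres = presence_table(list("abc"), bins, ranges)
        curve = sum_of_variances(ordn, pres, bins, k=2, n_boot=10, seed=0)
        # second bin undefined -> excluded from the average
        assert interval_average(curve, ["b105", "b95"]) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            interval_average(curve, ["b95"])
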