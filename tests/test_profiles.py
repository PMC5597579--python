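"""Metagene matrices, 1-D 2-means classification and hypergeometric
overlap, each checked against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import spikechip as sc
from spikechip.profiles import (
    DegenerateClusteringError,
    average_profile,
    heatmap_order,
    hypergeom_overlap,
    kmeans_high_low,
    metagene_matrix,
)


def _const_track(layout, value, bin_width=50):
    t = sc.BinnedTrack.zeros(layout, bin_width, kind="ratio")
    for c in t.values:
        t.values[c][:] = value
    return t


class TestMetageneMatrix:
    def test_constant_track_gives_constant_matrix(self, tiny_layout):
        m = metagene_matrix(_const_track(tiny_layout, 2.5), tiny_layout,
                            upstream=100, downstream=100, body_bins=10)
        assert m.values.shape == (3, 2 + 10 + 2)
        finite = m.values[np.isfinite(m.values)]
        np.testing.assert_allclose(finite, 2.5)
        np.testing.assert_allclose(
            average_profile(m), 2.5
        )

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_impulse_at_tss_lands_in_first_body_column(self, strand):
        layout = sc.GenomeLayout(
            chromosomes=[("chrA", 4000)],
            genes=[sc.Gene("g", "chrA", 1000, 2500, strand)],
        )
        track = sc.BinnedTrack.zeros(layout, 50, kind="ratio")
        gene = layout.genes[0]
        five = gene.five_prime if strand == "+" else gene.five_prime - 1
        track.values["chrA"][five // 50] = 9.0
        m = metagene_matrix(track, layout, 500, 500, body_bins=100)
        row = m.values[0]
        assert int(np.argmax(row)) == m.n_upstream

    def test_genome_mean_conservation_under_full_coverage(self, rng):
        """Genes tiling the whole chromosome with no flanks: the matrix
        mean equals the genome-wide track mean."""
        layout = sc.GenomeLayout(
            chromosomes=[("chrA", 4000)],
            genes=[
                sc.Gene(f"g{i}", "chrA", i * 500, (i + 1) * 500, "+")
                for i in range(8)
            ],
        )
        track = sc.BinnedTrack(
            layout, 50, {"chrA": rng.uniform(0, 10, 80)}, kind="ratio"
        )
        m = metagene_matrix(track, layout, 0, 0, body_bins=10)
        assert m.values.mean() == pytest.approx(
            track.values["chrA"].mean(), abs=1e-9
        )

    def test_strand_flip_with_mirrored_track_is_identity(self, rng):
        """Mirroring the genome (coordinates and strands) and the track
        leaves every metagene row unchanged."""
        L = 4000
        genes = [
            sc.Gene("g1", "chrA", 800, 2000, "+"),
            sc.Gene("g2", "chrA", 2400, 3300, "-"),
        ]
        layout = sc.GenomeLayout(chromosomes=[("chrA", L)], genes=genes)
        vals = rng.uniform(0, 5, L // 50)
        track = sc.BinnedTrack(layout, 50, {"chrA": vals}, kind="ratio")
        flipped = sc.GenomeLayout(
            chromosomes=[("chrA", L)],
            genes=[
                sc.Gene(g.gene_id, "chrA", L - g.tes, L - g.tss,
                        "-" if g.strand == "+" else "+")
                for g in genes
            ],
        )
        mirrored = sc.BinnedTrack(
            layout, 50, {"chrA": vals[::-1].copy()}, kind="ratio"
        )
        m = metagene_matrix(track, layout, 500, 500, 20)
        m_flip = metagene_matrix(mirrored, flipped, 500, 500, 20)
        np.testing.assert_allclose(m_flip.values, m.values, atol=1e-9)

    def test_out_of_range_columns_are_missing(self):
        layout = sc.GenomeLayout(
            chromosomes=[("chrA", 1000)],
            genes=[sc.Gene("g", "chrA", 100, 900, "+")],
        )
        m = metagene_matrix(
            _const_track(layout, 1.0), layout, 500, 500, body_bins=10
        )
        row = m.values[0]
        assert np.isnan(row[:8]).all()        # flank before base 0
        assert np.isfinite(row[8:10]).all()
        assert np.isnan(row[-8:]).all()       # flank past chromosome end
        assert np.isfinite(m.summary.iloc[0])

    def test_short_gene_is_flagged_but_profiled(self):
        layout = sc.GenomeLayout(
            chromosomes=[("chrA", 1000)],
            genes=[sc.Gene("tiny", "chrA", 500, 520, "+")],
        )
        m = metagene_matrix(
            _const_track(layout, 3.0), layout, 0, 0, body_bins=100
        )
        assert m.short_genes == ["tiny"]
        np.testing.assert_allclose(m.values[0], 3.0)

    def test_summary_is_body_mean(self, tiny_layout, rng):
        track = sc.BinnedTrack(
            tiny_layout, 50,
            {c: rng.uniform(0, 4, n)
             for c, n in tiny_layout.n_bins(50).items()},
            kind="ratio",
        )
        m = metagene_matrix(track, tiny_layout, 100, 100, 10)
        np.testing.assert_allclose(
            m.summary.to_numpy(),
            np.nanmean(m.values[:, 2:12], axis=1),
        )


class TestAverageProfileAndOrder:
    def test_single_row_matrix_is_its_own_profile(self):
        m = sc.GeneProfileMatrix(["g"], np.array([[1.0, 2.0, 3.0]]), 1, 1, 1, 50)
        np.testing.assert_allclose(average_profile(m), [1, 2, 3])

    def test_profile_equals_bruteforce_column_mean(self, rng):
        vals = rng.uniform(0, 1, (6, 5))
        vals[2, 1] = np.nan
        m = sc.GeneProfileMatrix(
            [f"g{i}" for i in range(6)], vals, 1, 3, 1, 50
        )
        expected = [
            np.mean([v for v in vals[:, j] if not math.isnan(v)])
            for j in range(5)
        ]
        np.testing.assert_allclose(average_profile(m), expected)

    def test_descending_order_with_id_tiebreak(self):
        vals = np.array([[3.0], [1.0], [2.0], [2.0]])
        m = sc.GeneProfileMatrix(["a", "b", "c", "d"], vals, 0, 1, 0, 50)
        assert heatmap_order(m) == ["a", "c", "d", "b"]


def wcss(x, labels):
    out = 0.0
    for lab in (0, 1):
        grp = x[labels == lab]
        if grp.size:
            out += np.sum((grp - grp.mean()) ** 2)
    return out


def kmeans_bruteforce(x):
    """Global 2-means optimum by trying all 2^n labelings."""
    n = len(x)
    best, best_labels = np.inf, None
    for bits in itertools.product([0, 1], repeat=n):
        labels = np.array(bits)
        if labels.sum() in (0, n):
            continue
        obj = wcss(x, labels)
        if obj < best - 1e-12:
            best, best_labels = obj, labels
    return best, best_labels


class TestKmeansHighLow:
    def test_separated_clusters(self):
        high, low = kmeans_high_low(
            pd.Series([1, 1, 1, 9, 9, 9], index=list("abcdef"))
        )
        assert high == {"d", "e", "f"} and low == {"a", "b", "c"}

    def test_threshold_scan_example(self):
        high, low = kmeans_high_low(pd.Series([1, 2, 8, 9]))
        assert high == {2, 3} and low == {0, 1}

    def test_identical_scores_rejected(self):
        with pytest.raises(DegenerateClusteringError):
            kmeans_high_low(pd.Series([2.0, 2.0, 2.0]))

    def test_seed_has_no_effect(self, rng):
        s = pd.Series(rng.normal(size=40))
        assert kmeans_high_low(s, seed=1) == kmeans_high_low(s, seed=999)

    def test_achieves_bruteforce_optimum(self, rng):
        """The threshold scan reaches the global WCSS minimum over all
        2^n labelings for n <= 12."""
        for n in range(2, 13):
            x = np.round(rng.normal(size=n), 3)
            if np.unique(x).size < 2:
                continue
            high, low = kmeans_high_low(pd.Series(x))
            labels = np.array([1 if i in high else 0 for i in range(n)])
            best, _ = kmeans_bruteforce(x)
            assert wcss(x, labels) <= best + 1e-9
            assert x[labels == 1].mean() > x[labels == 0].mean()


def hypergeom_enumeration(m, a, b, k):
    """P(X >= k) by summing the closed-form pmf with exact binomials."""
    total = 0
    for j in range(k, min(a, b) + 1):
        total += math.comb(a, j) * math.comb(m - a, b - j)
    return total / math.comb(m, b)


class TestHypergeomOverlap:
    def test_zero_overlap_is_certain(self):
        r = hypergeom_overlap(set(range(10)), {0, 1}, {5, 6})
        assert r.p_value == pytest.approx(1.0)

    def test_full_overlap_10_5_5(self):
        u = set(range(10))
        a = set(range(5))
        r = hypergeom_overlap(u, a, a)
        assert r.p_value == pytest.approx(1 / 252, rel=1e-12)

    def test_hand_enumeration_6_3_2_2(self):
        u = set(range(6))
        r = hypergeom_overlap(u, {0, 1, 2}, {0, 1})
        assert r.p_value == pytest.approx(0.2, rel=1e-12)

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_overlap({1, 2}, {3}, {1})

    def test_matches_enumeration_for_small_universes(self, rng):
        """p-values agree with exact pmf summation for every draw
        configuration with universe <= 12."""
        for m in range(2, 13):
            u = set(range(m))
            for _ in range(10):
                a = set(rng.choice(m, rng.integers(1, m + 1), replace=False))
                b = set(rng.choice(m, rng.integers(1, m + 1), replace=False))
                r = hypergeom_overlap(u, a, b)
                expected = hypergeom_enumeration(
                    m, len(a), len(b), len(a & b)
                )
                assert r.p_value == pytest.approx(expected, rel=1e-9)
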