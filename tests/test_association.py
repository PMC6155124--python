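"""Peak-TSS distances, distance binning, Q-Q curves, histograms, enrichment."""

import math

import numpy as np
import pytest

from oracles import (
    oracle_bin_assignment, oracle_hypergeom_upper_tail, oracle_tss_distance,
)
from peakscape.association import (
    DEFAULT_BINS, DistanceBin, GeneAnnotation, bin_enrichment_table,
    bin_enrichment_test, bin_genes_by_nearest_peak, differential_histogram,
    peak_tss_distance, qq_curve, read_gene_table, subset_statistics,
    write_gene_table,
)
from peakscape.diffexp import DifferentialRecord
from peakscape.intervals import GenomicInterval, PeakSet


def random_genes(rng, n, chroms=("chr1", "chr2"), span=100_000):
    genes = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(200, 2000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(f"g{i}", chroms[rng.integers(len(chroms))],
                                    strand, start, start + length))
    return genes


class TestPeakTssDistance:
    def test_tss_inside_peak_is_zero(self):
        g = GeneAnnotation("g", "chr1", "+", 150, 1000)
        assert peak_tss_distance(GenomicInterval("chr1", 100, 200), g) == 0

    def test_nearest_edge_half_open(self):
        # last covered base of [100, 200) is 199, so TSS 250 is 51 bp away
        g = GeneAnnotation("g", "chr1", "+", 250, 1000)
        assert peak_tss_distance(GenomicInterval("chr1", 100, 200), g) == 51

    def test_cross_chromosome_is_infinite(self):
        g = GeneAnnotation("g", "chr2", "+", 150, 1000)
        assert math.isinf(peak_tss_distance(GenomicInterval("chr1", 100, 200), g))

    def test_minus_strand_tss_is_last_base(self):
        g = GeneAnnotation("g", "chr1", "-", 100, 301)  # TSS at 300
        assert peak_tss_distance(GenomicInterval("chr1", 310, 400), g) == 10

    def test_matches_per_base_oracle(self, rng):
        genes = random_genes(rng, 30)
        for g in genes:
            peak = GenomicInterval("chr1", int(rng.integers(0, 99_000)) + 1,
                                   int(rng.integers(99_001, 101_000)))
            assert peak_tss_distance(peak, g) == oracle_tss_distance(peak, g)


class TestBinAssignment:
    def test_default_ladder_examples(self):
        genes = [GeneAnnotation("near", "chr1", "+", 103_000, 104_000),
                 GeneAnnotation("far", "chr1", "+", 550_000, 551_000)]
        peaks = PeakSet("p", [GenomicInterval("chr1", 99_000, 100_000)])
        assignment = bin_genes_by_nearest_peak(genes, peaks)
        assert "near" in assignment["0-5kb"]       # 3 kb away
        assert "far" in assignment["200-500kb"]    # 450 kb away

    def test_beyond_all_bins_unassigned(self):
        genes = [GeneAnnotation("g", "chr1", "+", 9_000_000, 9_001_000)]
        peaks = PeakSet("p", [GenomicInterval("chr1", 0, 1000)])
        assignment = bin_genes_by_nearest_peak(genes, peaks)
        assert all("g" not in s for s in assignment.values())

    def test_empty_peak_set_unassigns_everything(self, rng):
        genes = random_genes(rng, 5)
        assignment = bin_genes_by_nearest_peak(genes, PeakSet("p", []))
        assert all(not s for s in assignment.values())

    def test_each_gene_in_at_most_one_bin(self, rng, make_peak_set):
        genes = random_genes(rng, 200)
        peaks = make_peak_set(rng, "p", 50, span=100_000)
        assignment = bin_genes_by_nearest_peak(genes, peaks)
        seen = [g for s in assignment.values() for g in s]
        assert len(seen) == len(set(seen))

    def test_matches_brute_force_scan(self, rng, make_peak_set):
        bins = (DistanceBin("0", 0, 1), DistanceBin("1-2k", 1, 2_000),
                DistanceBin("2-50k", 2_000, 50_000))
        for _ in range(15):
            genes = random_genes(rng, 60)
            peaks = make_peak_set(rng, "p", 30, span=80_000)
            got = bin_genes_by_nearest_peak(genes, peaks, bins)
            assert got == oracle_bin_assignment(genes, peaks, bins)


class TestSubsetStatistics:
    def _records(self):
        return [DifferentialRecord("g1", 1.0, 0.01, qvalue=0.1, D=1.0),
                DifferentialRecord("g2", -2.0, 0.01, qvalue=0.1, D=-2.0),
                DifferentialRecord("g3", 0.0, 0.5, qvalue=0.9, D=0.0)]

    def test_per_bin_vectors(self):
        per_bin, background = subset_statistics(
            {"a": {"g1", "g2"}, "b": set()}, self._records())
        assert sorted(per_bin["a"]) == [-2.0, 1.0]
        assert per_bin["b"].size == 0
        assert sorted(background) == [-2.0, 0.0, 1.0]

    def test_unknown_gene_id_is_error(self):
        with pytest.raises(KeyError, match="gX"):
            subset_statistics({"a": {"gX"}}, self._records())


class TestQQCurve:
    def test_identity_when_subset_is_background(self, rng):
        vals = rng.normal(size=500)
        qq = qq_curve(vals, vals)
        assert np.allclose(qq.subset_q["subset"], qq.background_q)

    def test_location_shift_moves_quantiles(self, rng):
        bg = rng.normal(size=2000)
        qq = qq_curve(bg + 1.0, bg)
        assert np.allclose(qq.subset_q["subset"] - qq.background_q, 1.0,
                           atol=1e-9)

    def test_linear_interpolation_rule(self):
        qq = qq_curve(np.array([1, 2, 3, 4, 5.0]),
                      np.array([1, 2, 3, 4, 5.0]), n_points=3)
        assert np.allclose(qq.quantile_grid, [0.25, 0.5, 0.75])
        assert np.allclose(qq.subset_q["subset"], [2.0, 3.0, 4.0])

    def test_permutation_invariant_and_monotone(self, rng):
        vals = rng.normal(size=300)
        bg = rng.normal(size=1000)
        a = qq_curve(vals, bg)
        b = qq_curve(rng.permutation(vals), bg)
        assert np.allclose(a.subset_q["subset"], b.subset_q["subset"])
        assert np.all(np.diff(a.subset_q["subset"]) >= 0)
        assert np.all(np.diff(a.background_q) >= 0)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            qq_curve(np.array([]), np.array([1.0, 2.0]))


class TestDifferentialHistogram:
    def test_single_value_lands_in_its_bin(self):
        hist = differential_histogram({"s": np.array([0.25])},
                                      np.linspace(0, 1, 11))
        assert hist.densities["s"][2] == 1.0
        assert hist.densities["s"].sum() == pytest.approx(1.0)

    def test_uniform_draws_are_flat(self, rng):
        hist = differential_histogram({"s": rng.uniform(size=10_000)},
                                      np.linspace(0, 1, 11))
        assert np.allclose(hist.densities["s"], 0.1, atol=0.01)

    def test_identical_subsets_identical_histograms(self, rng):
        vals = rng.normal(size=400)
        hist = differential_histogram({"a": vals, "b": vals.copy()},
                                      np.linspace(-4, 4, 21))
        assert np.array_equal(hist.densities["a"], hist.densities["b"])

    def test_out_of_range_values_clipped_into_end_bins(self):
        hist = differential_histogram({"s": np.array([-10.0, 10.0])},
                                      np.linspace(0, 1, 3))
        assert hist.densities["s"][0] == 0.5
        assert hist.densities["s"][-1] == 0.5


class TestBinEnrichment:
    def test_no_overlap_gives_p_near_one(self):
        universe = {f"g{i}" for i in range(1000)}
        p = bin_enrichment_test({"g0", "g1"}, {"g500", "g501"}, universe)
        assert p > 0.99

    def test_total_containment_is_significant(self):
        universe = {f"g{i}" for i in range(1000)}
        signif = {f"g{i}" for i in range(30)}
        p = bin_enrichment_test(set(list(signif)[:20]), signif, universe)
        assert p < 1e-10

    def test_matches_tail_summation_on_2x2_table(self):
        # overlap 20, bin-only 80, signif-only 30, neither 870
        universe = {f"g{i}" for i in range(1000)}
        bin_genes = {f"g{i}" for i in range(100)}
        signif = {f"g{i}" for i in range(80, 130)}
        p = bin_enrichment_test(bin_genes, signif, universe)
        assert p == pytest.approx(
            oracle_hypergeom_upper_tail(20, 1000, 50, 100), rel=1e-10)

    def test_table_applies_bh_across_bins(self):
        universe = {f"g{i}" for i in range(100)}
        assignment = {"a": {f"g{i}" for i in range(10)},
                      "b": {f"g{i}" for i in range(50, 60)}}
        df = bin_enrichment_table(assignment, {f"g{i}" for i in range(10)},
                                  universe)
        assert set(df.columns) >= {"p_enrichment", "q_enrichment"}
        assert (df["q_enrichment"] >= df["p_enrichment"] - 1e-12).all()


def test_gene_table_roundtrip(tmp_path, rng):
    genes = random_genes(rng, 20)
    path = tmp_path / "genes.tsv"
    write_gene_table(genes, path)
    assert read_gene_table(path) == genes
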