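"""Tn5 shift, nucleosome classification, region tiling, tracks, footprints."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import oracle_dense_coverage, oracle_footprint
from peakscape.fragments import (
    CLASS_RANGES, FragmentRecord, SignalTrack, classify_fragment,
    correlate_tracks, coverage_track, cutsite_track, footprint_profile,
    nucleosome_regions, read_bedgraph, read_fragments_bed, read_fragments_sam,
    tn5_shift, tn5_shift_fragment, write_bedgraph,
)
from peakscape.intervals import GenomicInterval


class TestTn5Shift:
    def test_plus_strand_shifts_plus_four(self):
        assert tn5_shift("chr1", 100, 150, "+") == (104, 154)

    def test_minus_strand_shifts_minus_five(self):
        assert tn5_shift("chr1", 100, 150, "-") == (95, 145)

    def test_unstranded_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            tn5_shift("chr1", 100, 150, ".")

    def test_shift_then_unshift_is_identity(self):
        s, e = tn5_shift("chr1", 100, 150, "+")
        assert (s - 4, e - 4) == (100, 150)
        s, e = tn5_shift("chr1", 100, 150, "-")
        assert (s + 5, e + 5) == (100, 150)

    def test_fragment_shift_applies_both_ends(self):
        assert tn5_shift_fragment(100, 300) == (104, 295)


class TestClassifyFragment:
    @pytest.mark.parametrize("size,expected", [
        (90, "NFR"), (99, "NFR"), (100, "unclassified"),
        (180, "mono"), (200, "mono"), (247, "mono"), (248, "unclassified"),
        (315, "di"), (400, "di"), (473, "di"),
        (558, "tri"), (600, "tri"), (615, "tri"), (616, "unclassified"),
        (150, "unclassified"),
    ])
    def test_size_ranges(self, size, expected):
        assert classify_fragment(size) == expected

    def test_every_size_maps_to_exactly_one_class(self):
        for size in range(1, 1000):
            cls = classify_fragment(size)
            in_ranges = [c for c, (lo, hi) in CLASS_RANGES.items()
                         if lo <= size <= hi]
            assert len(in_ranges) <= 1
            assert cls == (in_ranges[0] if in_ranges else "unclassified")


class TestNucleosomeRegions:
    def test_dinucleosome_splits_in_half(self):
        regions = nucleosome_regions(FragmentRecord("chr1", 1000, 1400))
        assert [(r.start, r.end) for r in regions] == [(1000, 1200), (1200, 1400)]

    def test_trinucleosome_splits_in_thirds(self):
        regions = nucleosome_regions(FragmentRecord("chr1", 0, 600))
        assert [(r.start, r.end) for r in regions] == \
               [(0, 200), (200, 400), (400, 600)]

    def test_odd_length_remainder_goes_to_last_region(self):
        regions = nucleosome_regions(FragmentRecord("chr1", 0, 401))
        assert [(r.end - r.start) for r in regions] == [200, 201]
        assert regions[-1].end == 401

    def test_unclassified_fragment_is_error(self):
        with pytest.raises(ValueError, match="unclassified"):
            nucleosome_regions(FragmentRecord("chr1", 0, 150))

    @given(st.integers(0, 10_000), st.sampled_from(
        [(1, 99), (180, 247), (315, 473), (558, 615)]))
    @settings(max_examples=200, deadline=None)
    def test_regions_tile_fragment_exactly(self, start, size_range):
        size = np.random.default_rng(start).integers(size_range[0],
                                                     size_range[1] + 1)
        frag = FragmentRecord("chr1", start, start + int(size))
        regions = nucleosome_regions(frag)
        assert regions[0].start == frag.start
        assert regions[-1].end == frag.end
        for a, b in zip(regions, regions[1:]):
            assert a.end == b.start
        assert sum(r.length for r in regions) == frag.size


class TestCoverageTrack:
    def test_single_interval_depth_one(self):
        track = coverage_track([GenomicInterval("chr1", 0, 10)])
        assert np.all(track.values("chr1", 0, 10) == 1.0)
        assert np.all(track.values("chr1", 10, 20) == 0.0)

    def test_stacked_intervals_depth_two(self):
        track = coverage_track([GenomicInterval("chr1", 0, 10),
                                GenomicInterval("chr1", 5, 15)])
        vals = track.values("chr1", 0, 15)
        assert list(vals) == [1] * 5 + [2] * 5 + [1] * 5

    def test_mass_conserved_under_normalization(self, rng, make_peak_set):
        ivs = make_peak_set(rng, "x", 1000, span=50_000).intervals
        raw = coverage_track(ivs)
        total_bp = sum(iv.length for iv in ivs)
        assert raw.total_mass() == pytest.approx(total_bp)
        norm = coverage_track(ivs, normalization="per_billion_aligned_bp")
        assert norm.total_mass() == pytest.approx(total_bp * 1e9 / total_bp)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            coverage_track([])


class TestCutsiteTrack:
    def test_plus_alignment_first_base(self):
        track = cutsite_track([("chr1", 100, 150, "+")])
        assert track.values("chr1", 100, 101)[0] == 1.0
        assert track.values("chr1", 101, 150).sum() == 0.0

    def test_minus_alignment_last_base(self):
        track = cutsite_track([("chr1", 100, 150, "-")])
        assert track.values("chr1", 149, 150)[0] == 1.0
        assert track.values("chr1", 100, 149).sum() == 0.0

    def test_per_million_total_mass(self, rng):
        alns = [("chr1", int(p), int(p) + 50, "+" if rng.random() < 0.5 else "-")
                for p in rng.integers(100, 10_000, size=250)]
        track = cutsite_track(alns, normalization="per_million_alignments")
        assert track.total_mass() == pytest.approx(1e6)

    def test_unstranded_record_is_error(self):
        with pytest.raises(ValueError):
            cutsite_track([("chr1", 0, 10, ".")])


class TestFootprintProfile:
    def test_constant_track_gives_constant_profile(self):
        track = coverage_track([GenomicInterval("chr1", 0, 10_000)])
        prof = footprint_profile(track, [("chr1", 5000)], half_width=1000,
                                 bin_width=10)
        assert prof.values.shape == (200,)
        assert np.allclose(prof.values, 1.0)

    def test_impulse_contributes_only_central_bin(self):
        track = cutsite_track([("chr1", 5000, 5040, "+")])  # mass at 5000
        prof = footprint_profile(track, [("chr1", 5000)], half_width=100,
                                 bin_width=10)
        nonzero = np.nonzero(prof.values)[0]
        assert list(nonzero) == [10]  # bin starting at the center

    def test_matches_per_base_oracle(self, rng):
        ivs = [GenomicInterval("chr1", int(s), int(s) + int(l))
               for s, l in zip(rng.integers(0, 8000, 300),
                               rng.integers(1, 300, 300))]
        track = coverage_track(ivs)
        centers = [("chr1", int(p)) for p in rng.integers(400, 8000, 50)]
        prof = footprint_profile(track, centers, half_width=200, bin_width=10)
        dense = {"chr1": oracle_dense_coverage(ivs, "chr1", 10_000)}
        expected = oracle_footprint(dense, centers, 200, 10)
        assert np.allclose(prof.values, expected, atol=1e-9)

    def test_linearity_in_the_track(self, rng):
        ivs_a = [GenomicInterval("chr1", int(s), int(s) + 50)
                 for s in rng.integers(500, 5000, 40)]
        ivs_b = [GenomicInterval("chr1", int(s), int(s) + 80)
                 for s in rng.integers(500, 5000, 40)]
        centers = [("chr1", 2000), ("chr1", 3000)]
        pa = footprint_profile(coverage_track(ivs_a), centers, 200, 10).values
        pb = footprint_profile(coverage_track(ivs_b), centers, 200, 10).values
        pab = footprint_profile(coverage_track(ivs_a + ivs_b), centers,
                                200, 10).values
        assert np.allclose(pab, pa + pb, atol=1e-9)

    def test_truncated_window_excluded_by_default(self):
        track = coverage_track([GenomicInterval("chr1", 0, 10_000)])
        prof = footprint_profile(track, [("chr1", 50), ("chr1", 5000)],
                                 half_width=1000, bin_width=10)
        assert prof.n_regions == 1


class TestCorrelateTracks:
    def _track(self, values, start=0):
        starts = np.arange(start, start + len(values))
        return SignalTrack({"chr1": (starts, starts + 1, np.asarray(values,
                                                                    float))})

    def test_identical_tracks_correlate_perfectly(self):
        a = self._track([1, 3, 2, 5, 4])
        r, rho = correlate_tracks(a, a, GenomicInterval("chr1", 0, 5))
        assert (r, rho) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_negated_track_gives_pearson_minus_one(self):
        vals = np.array([1.0, 3, 2, 5, 4])
        a, b = self._track(vals), self._track(-vals)
        r, _ = correlate_tracks(a, b, GenomicInterval("chr1", 0, 5))
        assert r == pytest.approx(-1.0)

    def test_monotone_transform_preserves_spearman_only(self, rng):
        vals = rng.normal(size=200)
        a, b = self._track(vals), self._track(np.exp(vals))
        r, rho = correlate_tracks(a, b, GenomicInterval("chr1", 0, 200))
        assert rho == pytest.approx(1.0)
        assert r < 1.0

    def test_zero_variance_yields_nan(self):
        a = self._track([2.0, 2.0, 2.0])
        b = self._track([1.0, 2.0, 3.0])
        r, rho = correlate_tracks(a, b, GenomicInterval("chr1", 0, 3))
        assert np.isnan(r) and np.isnan(rho)


class TestFragmentIO:
    def test_bed_roundtrip(self, tmp_path):
        frags = [FragmentRecord("chr1", 100, 300),
                 FragmentRecord("chr2", 50, 250)]
        path = tmp_path / "frags.bed"
        from peakscape.fragments import write_fragments_bed
        write_fragments_bed(frags, path)
        assert read_fragments_bed(path) == frags

    def test_bedgraph_roundtrip(self, tmp_path, rng, make_peak_set):
        track = coverage_track(make_peak_set(rng, "x", 100).intervals)
        path = tmp_path / "t.bedGraph"
        write_bedgraph(track, path)
        back = read_bedgraph(path)
        for chrom in track.chroms():
            assert np.allclose(track.values(chrom, 0, 6000),
                               back.values(chrom, 0, 6000), atol=1e-5)

    def test_sam_proper_pairs_become_fragments(self, tmp_path):
        sam = tmp_path / "pairs.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:queryname\n"
            "@SQ\tSN:chr1\tLN:10000\n"
            "r1\t99\tchr1\t101\t60\t50M\t=\t251\t200\t*\t*\n"
            "r1\t147\tchr1\t251\t60\t50M\t=\t101\t-200\t*\t*\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
        )
        frags = read_fragments_sam(sam)
        assert frags == [FragmentRecord("chr1", 100, 300)]
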