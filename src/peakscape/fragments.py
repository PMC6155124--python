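"""ATAC-seq fragment processing.

Tn5 insertion-site correction (+4 bp on the + strand, -5 bp on the - strand),
fragment-size nucleosome classification (<100 bp nucleosome-free; 180-247 bp
mono-; 315-473 bp di-; 558-615 bp tri-nucleosome), replacement of classified
fragments by equal BED sub-regions (one/two/three spans), normalised coverage
and cut-site signal tracks, center-aligned 10-bp-binned footprint profiles,
and Pearson/Spearman track correlation.

Sizes falling in the gaps between the stated class ranges are 'unclassified'
and excluded from nucleosome analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

NUC_CLASSES = ("NFR", "mono", "di", "tri", "unclassified")

#: Inclusive fragment-size ranges per nucleosome class.
CLASS_RANGES = {
    "NFR": (1, 99),
    "mono": (180, 247),
    "di": (315, 473),
    "tri": (558, 615),
}

_N_REGIONS = {"NFR": 1, "mono": 1, "di": 2, "tri": 3}

TN5_PLUS_SHIFT = 4
TN5_MINUS_SHIFT = -5


def tn5_shift(chrom: str, start: int, end: int, strand: str) -> tuple[int, int]:
    """Shift a single-read alignment for the Tn5 insertion offset.

    '+' strand: both coordinates +4; '-' strand: both coordinates -5.
    Unstranded input is an error (the shift is undefined).
    """
    if strand == "+":
        return start + TN5_PLUS_SHIFT, end + TN5_PLUS_SHIFT
    if strand == "-":
        return start + TN5_MINUS_SHIFT, end + TN5_MINUS_SHIFT
    raise ValueError(f"Tn5 shift undefined for strand {strand!r}")


def tn5_shift_fragment(start: int, end: int) -> tuple[int, int]:
    """Tn5 dyad correction for a paired fragment: + end +4, - end -5.

    A fragment's left edge is the + -strand insertion and its right edge the
    - -strand insertion, so the per-alignment rule becomes (start+4, end-5).
    """
    new_start, new_end = start + TN5_PLUS_SHIFT, end + TN5_MINUS_SHIFT
    if new_start >= new_end:
        raise ValueError(f"fragment {start}-{end} collapses under Tn5 shift")
    return new_start, new_end


def classify_fragment(size: int) -> str:
    """Nucleosome class from fragment size (bp): NFR, mono, di, tri, unclassified."""
    if size < 1:
        raise ValueError("fragment size must be >= 1")
    for cls, (lo, hi) in CLASS_RANGES.items():
        if lo <= size <= hi:
            return cls
    return "unclassified"


@dataclass(frozen=True)
class FragmentRecord:
    """A (possibly Tn5-shifted) paired-end fragment."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"fragment {self.chrom}:{self.start}-{self.end}")

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def nuc_class(self) -> str:
        return classify_fragment(self.size)


def nucleosome_regions(fragment: FragmentRecord) -> list[GenomicInterval]:
    """Replace a classified fragment by its BED sub-regions.

    NFR and mononucleosome fragments map to a single region spanning the
    fragment; dinucleosomes to two half-spans; trinucleosomes to three
    third-spans. Sub-regions tile the fragment exactly: integer division with
    the remainder absorbed by the last region. 'unclassified' is an error.
    """
    cls = fragment.nuc_class
    if cls == "unclassified":
        raise ValueError(
            f"fragment of size {fragment.size} is unclassified; no region replacement"
        )
    n = _N_REGIONS[cls]
    span = fragment.size // n
    regions = []
    for i in range(n):
        lo = fragment.start + i * span
        hi = fragment.end if i == n - 1 else lo + span
        regions.append(GenomicInterval(fragment.chrom, lo, hi))
    return regions


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------

NORMALIZATIONS = ("raw", "per_billion_aligned_bp", "per_million_alignments")


class SignalTrack:
    """Piecewise-constant non-negative per-bp signal, sparse by chromosome.

    Stored per chromosome as parallel (starts, ends, values) arrays of
    non-overlapping sorted segments; uncovered bases are implicitly zero.
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 normalization: str = "raw") -> None:
        if normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {normalization!r}")
        self.data = data
        self.normalization = normalization

    def chroms(self) -> list[str]:
        return sorted(self.data)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-bp values over [start, end); zeros where uncovered."""
        if end <= start:
            raise ValueError("require start < end")
        out = np.zeros(end - start)
        if chrom not in self.data:
            return out
        starts, ends, vals = self.data[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for i in range(lo, hi):
            a = max(starts[i], start) - start
            b = min(ends[i], end) - start
            if b > a:
                out[a:b] = vals[i]
        return out

    def total_mass(self) -> float:
        """Sum over segments of value x width."""
        return float(
            sum(((e - s) * v).sum() for s, e, v in self.data.values())
        )

    def scale(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {c: (s, e, v * factor) for c, (s, e, v) in self.data.items()},
            normalization=self.normalization,
        )


def _segments_from_events(
    positions: np.ndarray, deltas: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Breakpoint sweep: piecewise depth from +1/-1 (or weighted) events."""
    order = np.argsort(positions, kind="stable")
    positions, deltas = positions[order], deltas[order]
    uniq, idx = np.unique(positions, return_index=True)
    summed = np.add.reduceat(deltas, idx)
    depth = np.cumsum(summed)[:-1]
    starts, ends = uniq[:-1], uniq[1:]
    keep = depth != 0
    return starts[keep], ends[keep], depth[keep].astype(float)


def coverage_track(
    intervals: Sequence[GenomicInterval], normalization: str = "raw"
) -> SignalTrack:
    """Per-bp depth of a set of intervals, bedGraph-style.

    'per_billion_aligned_bp' scales by 1e9 / (sum of interval lengths), the
    open-chromatin enrichment-track normalisation.
    """
    if not intervals:
        raise ValueError("coverage of an empty interval list is undefined")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    total_bp = 0
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        total_bp += iv.length
    data = {}
    for chrom, pairs in by_chrom.items():
        arr = np.array(pairs)
        positions = np.concatenate([arr[:, 0], arr[:, 1]])
        deltas = np.concatenate([np.ones(len(pairs)), -np.ones(len(pairs))])
        data[chrom] = _segments_from_events(positions, deltas)
    track = SignalTrack(data, normalization="raw")
    if normalization == "per_billion_aligned_bp":
        track = track.scale(1e9 / total_bp)
        track.normalization = normalization
    elif normalization != "raw":
        raise ValueError(f"coverage_track does not support {normalization!r}")
    return track


def cutsite_track(
    alignments: Sequence[tuple[str, int, int, str]],
    normalization: str = "raw",
) -> SignalTrack:
    """Unit mass at each alignment's strand-appropriate terminal base.

    '+' alignments contribute at their first base (start); '-' alignments at
    their last base (end - 1). 'per_million_alignments' scales by 1e6 / N so
    the total track mass is one million.
    """
    if not alignments:
        raise ValueError("cut-site track of an empty alignment list is undefined")
    by_chrom: dict[str, list[int]] = {}
    for chrom, start, end, strand in alignments:
        if strand == "+":
            pos = start
        elif strand == "-":
            pos = end - 1
        else:
            raise ValueError(f"cut site undefined for strand {strand!r}")
        by_chrom.setdefault(chrom, []).append(pos)
    data = {}
    for chrom, poss in by_chrom.items():
        arr = np.array(poss)
        positions = np.concatenate([arr, arr + 1])
        deltas = np.concatenate([np.ones(arr.size), -np.ones(arr.size)])
        data[chrom] = _segments_from_events(positions, deltas)
    track = SignalTrack(data, normalization="raw")
    if normalization == "per_million_alignments":
        track = track.scale(1e6 / len(alignments))
        track.normalization = normalization
    elif normalization != "raw":
        raise ValueError(f"cutsite_track does not support {normalization!r}")
    return track


@dataclass
class FootprintProfile:
    """Center-aligned average signal in fixed-width bins around regions."""

    bin_width: int
    half_width: int
    values: np.ndarray
    n_regions: int


def footprint_profile(
    track: SignalTrack,
    centers: Sequence[tuple[str, int]],
    half_width: int = 1000,
    bin_width: int = 10,
    drop_truncated: bool = True,
) -> FootprintProfile:
    """Average track signal in ``bin_width`` bins over +/- ``half_width``
    windows around each center, then average across centers.

    Windows running off the chromosome start are flagged and, by default,
    excluded. ``bin_width`` must divide ``2 * half_width``.
    """
    if not centers:
        raise ValueError("no centers given")
    width = 2 * half_width
    if width % bin_width != 0:
        raise ValueError("bin_width must divide 2 * half_width")
    n_bins = width // bin_width
    acc = np.zeros(n_bins)
    n_used = 0
    for chrom, pos in centers:
        lo = pos - half_width
        if lo < 0:
            logger.warning("window at %s:%d truncated at chrom start", chrom, pos)
            if drop_truncated:
                continue
            lo = 0
        window = track.values(chrom, lo, pos + half_width)
        if window.size < width:  # truncated and kept: left-pad with zeros
            window = np.concatenate([np.zeros(width - window.size), window])
        acc += window.reshape(n_bins, bin_width).mean(axis=1)
        n_used += 1
    if n_used == 0:
        raise ValueError("all windows truncated; no profile")
    return FootprintProfile(
        bin_width=bin_width, half_width=half_width,
        values=acc / n_used, n_regions=n_used,
    )


def correlate_tracks(
    a: SignalTrack, b: SignalTrack, region: GenomicInterval
) -> tuple[float, float]:
    """Pearson and Spearman correlation of per-bp values within a region.

    Spearman tempers the influence of very high enrichment. Bases not covered
    by a track count as zero; zero-variance input yields NaN with a warning.
    """
    va = a.values(region.chrom, region.start, region.end)
    vb = b.values(region.chrom, region.start, region.end)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        logger.warning("zero-variance track in region; correlation undefined")
        return float("nan"), float("nan")
    pearson = float(stats.pearsonr(va, vb).statistic)
    spearman = float(stats.spearmanr(va, vb).statistic)
    return pearson, spearman


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fragments_bed(path: str | Path) -> list[FragmentRecord]:
    """Read fragments from a 3+ column BED (chrom, start, end per line)."""
    frags = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                frags.append(FragmentRecord(fields[0], int(fields[1]), int(fields[2])))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return frags


def read_fragments_sam(path: str | Path) -> list[FragmentRecord]:
    """Extract fragments from name-sorted proper pairs in a SAM/BAM file.

    One fragment per read pair, spanning from the leftmost mate's start to
    leftmost start + template length. Secondary/supplementary/unmapped records
    and improper pairs are skipped.
    """
    import pysam

    frags = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if (aln.is_unmapped or aln.is_secondary or aln.is_supplementary
                    or not aln.is_proper_pair or aln.template_length <= 0):
                continue
            start = aln.reference_start
            frags.append(
                FragmentRecord(aln.reference_name, start,
                               start + aln.template_length)
            )
    return frags


def write_fragments_bed(frags: Iterable[FragmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in frags:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write the track as sorted 4-column bedGraph."""
    with open(path, "w") as fh:
        for chrom in track.chroms():
            starts, ends, vals = track.data[chrom]
            for s, e, v in zip(starts, ends, vals):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.6g}\n")


def read_bedgraph(path: str | Path, normalization: str = "raw") -> SignalTrack:
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                by_chrom.setdefault(fields[0], []).append(
                    (int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    data = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        data[chrom] = (
            np.array([r[0] for r in rows]),
            np.array([r[1] for r in rows]),
            np.array([r[2] for r in rows]),
        )
    return SignalTrack(data, normalization=normalization)
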