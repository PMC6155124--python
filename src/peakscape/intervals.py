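"""Genomic-interval data model, overlap algebra, and multi-set Venn partitioning.

Coordinates are 0-based, half-open throughout (BED native). Every other module
consumes the types defined here: :class:`GenomicInterval` for peaks, histone-mark
regions, and nucleosome sub-fragments; :class:`PeakSet` for a labelled, sorted
collection from one sample/condition; :class:`VennPartition` for the exclusive
assignment of peaks to subset-membership regions across 2-5 samples.

The Venn partition is built from connected components of the cross-set overlap
graph: two peaks from *different* input sets are linked when they share at least
``min_bp`` bases, and each component's region label is the set of input labels it
contains. This is the only definition that is simultaneously exclusive (every
peak lands in exactly one region) and exhaustive under chained overlaps, where a
peak can overlap peaks of two other sets that do not overlap each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """A file line that does not parse in the declared dialect."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``score`` is the unitless peak-caller score (e.g. MACS2 column 5);
    ``strand`` is '+', '-' or '.' for unstranded.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two intervals (0 if different chroms)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 10) -> bool:
    """True iff ``a`` and ``b`` share at least ``min_bp`` bases.

    The default reproduces the peak-group rule of considering regions
    overlapping by at least 10 bp; ``min_bp=1`` is the standard interval
    intersection test.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return overlap_bp(a, b) >= min_bp


@dataclass
class PeakSet:
    """A labelled, sorted, deduplicated collection of intervals from one sample."""

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    assay: str = ""

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        deduped: list[GenomicInterval] = []
        for iv in ivs:
            if deduped and (
                iv.chrom == deduped[-1].chrom
                and iv.start == deduped[-1].start
                and iv.end == deduped[-1].end
            ):
                logger.warning(
                    "%s: dropping duplicate interval %s:%d-%d",
                    self.label, iv.chrom, iv.start, iv.end,
                )
                continue
            deduped.append(iv)
        self.intervals = deduped

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)


def filter_by_score(peaks: PeakSet, threshold: float) -> PeakSet:
    """Keep peaks with score strictly greater than ``threshold``.

    Mirrors the retention rule "peaks with a score > 5 were retained": the
    comparison is strict. Raises if any peak lacks a score, because the filter
    is undefined there.
    """
    for iv in peaks:
        if iv.score is None:
            raise ValueError(
                f"{peaks.label}: interval {iv.chrom}:{iv.start}-{iv.end} has no "
                "score; score filter undefined"
            )
    kept = [iv for iv in peaks if iv.score > threshold]
    return PeakSet(label=peaks.label, intervals=kept, assay=peaks.assay)


def merge_set(peaks: PeakSet) -> PeakSet:
    """Union of all intervals: disjoint, sorted, total covered bp preserved."""
    merged: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    for iv in peaks:
        if cur is not None and iv.chrom == cur.chrom and iv.start <= cur.end:
            if iv.end > cur.end:
                cur = replace(cur, end=iv.end)
            continue
        if cur is not None:
            merged.append(cur)
        cur = GenomicInterval(iv.chrom, iv.start, iv.end)
    if cur is not None:
        merged.append(cur)
    return PeakSet(label=peaks.label, intervals=merged, assay=peaks.assay)


# ---------------------------------------------------------------------------
# Venn partitioning
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj


@dataclass
class VennPartition:
    """Exclusive assignment of every input peak to one subset-membership region.

    ``regions`` maps a frozenset of input labels to, per input set, the indices
    of that set's peaks assigned to the region. Only non-empty regions are
    stored.
    """

    set_labels: tuple[str, ...]
    regions: dict[frozenset[str], dict[str, list[int]]]
    peak_sets: tuple[PeakSet, ...]

    def region_count(self, subset: frozenset[str]) -> int:
        members = self.regions.get(subset, {})
        return sum(len(v) for v in members.values())

    def per_set_totals(self) -> dict[str, int]:
        totals = {lab: 0 for lab in self.set_labels}
        for members in self.regions.values():
            for lab, idxs in members.items():
                totals[lab] += len(idxs)
        return totals

    def counts_table(self):
        """Long-format table: one row per (region, input set) with a count."""
        import pandas as pd

        rows = []
        for subset in sorted(self.regions, key=lambda s: (len(s), sorted(s))):
            label = "&".join(lab for lab in self.set_labels if lab in subset)
            for lab in self.set_labels:
                if lab in subset:
                    rows.append(
                        {"region": label, "set": lab,
                         "n_peaks": len(self.regions[subset].get(lab, []))}
                    )
        return pd.DataFrame(rows, columns=["region", "set", "n_peaks"])

    def region_intervals(self, subset: frozenset[str]) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for lab, idxs in self.regions.get(subset, {}).items():
            pset = self.peak_sets[self.set_labels.index(lab)]
            out[lab] = [pset.intervals[i] for i in idxs]
        return out


def _cross_set_overlap_pairs(
    entries: list[tuple[str, int, int, int]], min_bp: int
) -> Iterator[tuple[int, int]]:
    """Yield global-index pairs of intervals (any set) overlapping >= min_bp.

    ``entries``: (chrom, start, end, global_index), sorted by (chrom, start).
    Plane-sweep with pruning: an active interval whose end can no longer reach
    ``min_bp`` overlap with the current start never can again.
    """
    active: list[tuple[str, int, int, int]] = []
    for chrom, start, end, gi in entries:
        active = [a for a in active if a[0] == chrom and a[2] >= start + min_bp]
        for _, _, aend, agi in active:
            if min(aend, end) - start >= min_bp:
                yield agi, gi
        active.append((chrom, start, end, gi))


def venn_partition(
    peak_sets: Sequence[PeakSet], min_bp: int = 10
) -> VennPartition:
    """Partition peaks of 2-5 sets into exclusive Venn regions.

    Peaks are linked into connected components by cross-set pairwise overlap of
    at least ``min_bp`` bases; a component's region is the set of input labels
    represented in it. Within-set overlaps do not link peaks (two same-set
    peaks fall in the same region only through shared cross-set partners).
    """
    if not (2 <= len(peak_sets) <= 5):
        raise ValueError("venn_partition requires 2 to 5 peak sets")
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    labels = tuple(ps.label for ps in peak_sets)
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate set labels: {labels}")

    flat: list[tuple[str, int, int, int]] = []  # chrom, start, end, global idx
    owner: list[tuple[int, int]] = []  # global idx -> (set idx, peak idx)
    for si, ps in enumerate(peak_sets):
        for pi, iv in enumerate(ps):
            flat.append((iv.chrom, iv.start, iv.end, len(owner)))
            owner.append((si, pi))
    flat.sort(key=lambda t: (t[0], t[1], t[2]))

    uf = _UnionFind(len(owner))
    for gi, gj in _cross_set_overlap_pairs(flat, min_bp):
        if owner[gi][0] != owner[gj][0]:
            uf.union(gi, gj)

    comp_sets: dict[int, set[str]] = {}
    for gi in range(len(owner)):
        comp_sets.setdefault(uf.find(gi), set()).add(labels[owner[gi][0]])

    regions: dict[frozenset[str], dict[str, list[int]]] = {}
    for gi in range(len(owner)):
        subset = frozenset(comp_sets[uf.find(gi)])
        si, pi = owner[gi]
        regions.setdefault(subset, {}).setdefault(labels[si], []).append(pi)
    for members in regions.values():
        for idxs in members.values():
            idxs.sort()
    return VennPartition(set_labels=labels, regions=regions,
                         peak_sets=tuple(peak_sets))


# ---------------------------------------------------------------------------
# I/O: BED3/BED6 and ENCODE narrowPeak
# ---------------------------------------------------------------------------

def _parse_bed_line(fields: list[str], lineno: int, path: str) -> GenomicInterval:
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
        strand = fields[5] if len(fields) > 5 else "."
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
    return GenomicInterval(chrom, start, end, strand=strand, score=score, name=name)


def _parse_narrowpeak_line(fields: list[str], lineno: int, path: str) -> GenomicInterval:
    if len(fields) < 10:
        raise ParseError(f"{path}:{lineno}: narrowPeak needs 10 columns, got {len(fields)}")
    return _parse_bed_line(fields[:6], lineno, path)


def read_peaks(path: str | Path, format: str | None = None,
               label: str | None = None, assay: str = "") -> PeakSet:
    """Read a BED3/BED6 or narrowPeak file into a sorted :class:`PeakSet`.

    ``format`` is 'BED' or 'narrowPeak'; when None it is inferred from the file
    extension (``.narrowPeak`` vs anything else). Coordinates are kept 0-based
    half-open; narrowPeak column 5 populates ``score``. Malformed lines raise
    :class:`ParseError` naming the line number; start >= end raises ValueError.
    """
    path = Path(path)
    if format is None:
        format = "narrowPeak" if path.suffix == ".narrowPeak" else "BED"
    if format not in {"BED", "narrowPeak"}:
        raise ValueError(f"unknown format {format!r}")
    parse = _parse_narrowpeak_line if format == "narrowPeak" else _parse_bed_line
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            try:
                intervals.append(parse(line.split("\t"), lineno, str(path)))
            except ValueError as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(label=label or path.stem, intervals=intervals, assay=assay)


def write_peaks(peaks: PeakSet | Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (name/score '.' when absent). Lossless round-trip."""
    ivs = peaks.intervals if isinstance(peaks, PeakSet) else list(peaks)
    with open(path, "w") as fh:
        for iv in ivs:
            score = "." if iv.score is None else repr(iv.score)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


def write_venn_tsv(partition: VennPartition, path: str | Path) -> None:
    partition.counts_table().to_csv(path, sep="\t", index=False)


def write_venn_region_beds(partition: VennPartition, outdir: str | Path) -> list[Path]:
    """One BED per non-empty Venn region, peaks from all member sets pooled."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for subset in sorted(partition.regions, key=lambda s: (len(s), sorted(s))):
        label = "_".join(lab for lab in partition.set_labels if lab in subset)
        pooled: list[GenomicInterval] = []
        for ivs in partition.region_intervals(subset).values():
            pooled.extend(ivs)
        pooled.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        dest = outdir / f"region_{label}.bed"
        write_peaks(pooled, dest)
        written.append(dest)
    return written
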