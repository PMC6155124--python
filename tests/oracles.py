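"""Independent brute-force oracles used to validate the optimised paths.

Each oracle is a direct, quadratic or per-base transcription of the relevant
definition and never shares code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np

from peakscape.association import GeneAnnotation
from peakscape.intervals import GenomicInterval, PeakSet


def oracle_overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    shared = 0
    for pos in range(min(a.start, b.start), max(a.end, b.end)):
        if a.start <= pos < a.end and b.start <= pos < b.end:
            shared += 1
    return shared


def oracle_venn(peak_sets: list[PeakSet], min_bp: int) -> dict:
    """Exhaustive pairwise union-find over all cross-set peak pairs.

    Returns {frozenset(labels): {label: sorted peak indices}}.
    """
    items = []  # (set label, peak index, interval)
    for ps in peak_sets:
        for i, iv in enumerate(ps):
            items.append((ps.label, i, iv))
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if items[i][0] == items[j][0]:
                continue
            a, b = items[i][2], items[j][2]
            if a.chrom == b.chrom and \
                    min(a.end, b.end) - max(a.start, b.start) >= min_bp:
                parent[find(i)] = find(j)

    comps: dict[int, list[int]] = {}
    for i in range(len(items)):
        comps.setdefault(find(i), []).append(i)
    regions: dict[frozenset, dict[str, list[int]]] = {}
    for members in comps.values():
        labels = frozenset(items[i][0] for i in members)
        reg = regions.setdefault(labels, {})
        for i in members:
            reg.setdefault(items[i][0], []).append(items[i][1])
    for reg in regions.values():
        for idxs in reg.values():
            idxs.sort()
    return regions


def oracle_covered_bp(intervals: list[GenomicInterval]) -> int:
    """Total covered bases via a per-bp boolean array."""
    total = 0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom.values():
        hi = max(iv.end for iv in ivs)
        mask = np.zeros(hi, dtype=bool)
        for iv in ivs:
            mask[iv.start:iv.end] = True
        total += int(mask.sum())
    return total


def oracle_tss_distance(peak: GenomicInterval, gene: GeneAnnotation) -> float:
    if peak.chrom != gene.chrom:
        return float("inf")
    tss = gene.tss
    return min(abs(tss - pos) for pos in range(peak.start, peak.end))


def oracle_bin_assignment(genes, peaks: PeakSet, bins) -> dict[str, set[str]]:
    """Per-gene scan over every peak; nearest distance mapped to its bin."""
    out = {b.label: set() for b in bins}
    for g in genes:
        d = float("inf")
        for iv in peaks:
            d = min(d, oracle_tss_distance(iv, g))
        for b in bins:
            if b.lo <= d < b.hi:
                out[b.label].add(g.gene_id)
                break
    return out


def oracle_enhancer_flags(atac: PeakSet, mark1: PeakSet, mark2: PeakSet,
                          min_bp: int) -> list[bool]:
    flags = []
    for p in atac:
        hit1 = any(
            m.chrom == p.chrom and min(m.end, p.end) - max(m.start, p.start) >= min_bp
            for m in mark1
        )
        hit2 = any(
            m.chrom == p.chrom and min(m.end, p.end) - max(m.start, p.start) >= min_bp
            for m in mark2
        )
        flags.append(hit1 and hit2)
    return flags


def oracle_region_class(peak: GenomicInterval, genes) -> str:
    """Per-bp window test: promoter > intragenic > intergenic."""
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        tss = g.tss
        if g.strand == "+":
            window = range(tss - 1000, tss + 500)
        else:
            window = range(tss - 499, tss + 1001)
        if any(peak.start <= pos < peak.end for pos in window):
            return "promoter"
    for g in genes:
        if g.chrom == peak.chrom and any(
            peak.start <= pos < peak.end for pos in range(g.tx_start, g.tx_end)
        ):
            return "intragenic"
    return "intergenic"


def oracle_dense_coverage(intervals, chrom: str, length: int) -> np.ndarray:
    dense = np.zeros(length)
    for iv in intervals:
        if iv.chrom == chrom:
            dense[iv.start:iv.end] += 1
    return dense


def oracle_footprint(dense_by_chrom: dict[str, np.ndarray], centers,
                     half_width: int, bin_width: int) -> np.ndarray:
    """Per-bp mean in each bin of each window, averaged across centers."""
    n_bins = 2 * half_width // bin_width
    acc = np.zeros(n_bins)
    used = 0
    for chrom, pos in centers:
        if pos - half_width < 0:
            continue
        dense = dense_by_chrom[chrom]
        window = dense[pos - half_width:pos + half_width]
        if window.size < 2 * half_width:
            window = np.concatenate(
                [window, np.zeros(2 * half_width - window.size)]
            )
        for b in range(n_bins):
            acc[b] += window[b * bin_width:(b + 1) * bin_width].mean()
        used += 1
    return acc / used


def oracle_hypergeom_upper_tail(k: int, universe: int, n_marked: int,
                                n_drawn: int) -> float:
    """Direct summation of the hypergeometric tail P(X >= k)."""
    from math import comb

    total = 0.0
    for x in range(k, min(n_marked, n_drawn) + 1):
        total += (comb(n_marked, x) * comb(universe - n_marked, n_drawn - x)
                  / comb(universe, n_drawn))
    return total
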