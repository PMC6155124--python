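"""Enhancer classification and genomic-context annotation of peaks.

A peak is called an accessible enhancer when it overlaps at least one peak in
EACH of two histone-mark sets (canonically H3K4me1 and H3K27ac; the marks are
plain inputs, so H3K4me3 or any other pair can be substituted). Each peak is
also assigned a mutually exclusive genomic context: promoter (strand-aware
window from -1 kb to +500 bp around a TSS), intragenic (inside a gene body),
or intergenic, with precedence promoter > intragenic > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import GeneAnnotation
from .intervals import GenomicInterval, PeakSet, VennPartition

REGION_CLASSES = ("promoter", "intragenic", "intergenic")

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 500


@dataclass(frozen=True)
class EnhancerAnnotation:
    peak: GenomicInterval
    is_enhancer: bool
    region_class: str


def _any_overlap(peaks: Sequence[GenomicInterval],
                 others: Sequence[GenomicInterval],
                 min_bp: int) -> np.ndarray:
    """Per-peak flag: overlaps any interval of ``others`` by >= min_bp.

    Both inputs sorted by (chrom, start); plane sweep over the merged stream.
    """
    flags = np.zeros(len(peaks), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in others:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for i, p in enumerate(peaks):
        cands = by_chrom.get(p.chrom)
        if not cands:
            continue
        starts = [c[0] for c in cands]
        import bisect
        j = bisect.bisect_left(starts, p.end)
        for s, e in cands[:j]:
            if min(e, p.end) - max(s, p.start) >= min_bp:
                flags[i] = True
                break
    return flags


def classify_enhancers(
    atac_peaks: PeakSet,
    mark1: PeakSet,
    mark2: PeakSet,
    min_bp: int = 1,
) -> np.ndarray:
    """Boolean flag per accessibility peak: overlaps both mark sets >= min_bp.

    ``min_bp`` defaults to 1 (any overlap); pass 10 for the peak-group rule.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    in1 = _any_overlap(atac_peaks.intervals, mark1.intervals, min_bp)
    in2 = _any_overlap(atac_peaks.intervals, mark2.intervals, min_bp)
    return in1 & in2


def promoter_window(gene: GeneAnnotation) -> tuple[int, int]:
    """Strand-aware promoter window [TSS-1000, TSS+500) in genomic coordinates.

    For '-' strand genes upstream is to the right, so the window mirrors to
    [TSS-499, TSS+1001) around the TSS base.
    """
    tss = gene.tss
    if gene.strand == "+":
        lo, hi = tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
    else:
        lo, hi = tss - PROMOTER_DOWNSTREAM + 1, tss + PROMOTER_UPSTREAM + 1
    return max(0, lo), hi


def annotate_genomic_region(
    peak: GenomicInterval, genes: Sequence[GeneAnnotation]
) -> str:
    """Assign promoter / intragenic / intergenic with promoter precedence."""
    if not genes:
        raise ValueError("gene annotation is empty")
    intragenic = False
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        lo, hi = promoter_window(g)
        if min(hi, peak.end) > max(lo, peak.start):
            return "promoter"
        if min(g.tx_end, peak.end) > max(g.tx_start, peak.start):
            intragenic = True
    return "intragenic" if intragenic else "intergenic"


def annotate_regions(
    peaks: PeakSet, genes: Sequence[GeneAnnotation]
) -> list[str]:
    return [annotate_genomic_region(iv, genes) for iv in peaks]


def venn_enhancer_summary(
    partition: VennPartition,
    enhancer_flags: Mapping[str, Sequence[bool]],
    region_classes: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-Venn-region composition: peak count, enhancer fraction, and
    promoter/intragenic/intergenic enhancer counts.

    ``enhancer_flags`` and ``region_classes`` are keyed by input-set label and
    aligned with each input PeakSet's interval order; every partitioned peak
    must be covered.
    """
    for lab, pset in zip(partition.set_labels, partition.peak_sets):
        if lab not in enhancer_flags or len(enhancer_flags[lab]) != len(pset):
            raise ValueError(f"enhancer flags missing or misaligned for set {lab!r}")
        if lab not in region_classes or len(region_classes[lab]) != len(pset):
            raise ValueError(f"region classes missing or misaligned for set {lab!r}")
    rows = []
    for subset in sorted(partition.regions, key=lambda s: (len(s), sorted(s))):
        label = "&".join(lab for lab in partition.set_labels if lab in subset)
        n_peaks = 0
        n_enh = 0
        by_class = {c: 0 for c in REGION_CLASSES}
        for lab, idxs in partition.regions[subset].items():
            flags = enhancer_flags[lab]
            classes = region_classes[lab]
            for i in idxs:
                n_peaks += 1
                if flags[i]:
                    n_enh += 1
                    if classes[i] not in by_class:
                        raise ValueError(f"unknown region class {classes[i]!r}")
                    by_class[classes[i]] += 1
        rows.append(
            {
                "region": label,
                "n_peaks": n_peaks,
                "n_enhancers": n_enh,
                "enhancer_fraction": n_enh / n_peaks if n_peaks else 0.0,
                "n_promoter": by_class["promoter"],
                "n_intragenic": by_class["intragenic"],
                "n_intergenic": by_class["intergenic"],
            }
        )
    return pd.DataFrame(rows)


def write_annotated_peaks(
    peaks: PeakSet,
    flags: Sequence[bool],
    classes: Sequence[str],
    path: str | Path,
) -> None:
    """BED6 plus is_enhancer and region_class columns."""
    with open(path, "w") as fh:
        for iv, flag, cls in zip(peaks, flags, classes):
            score = "." if iv.score is None else repr(iv.score)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t"
                f"{iv.strand}\t{int(flag)}\t{cls}\n"
            )
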