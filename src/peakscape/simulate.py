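"""Seeded synthetic-data generators for the full pipeline.

The generators emit data with the statistical structure the analysis stages
assume, together with the planted truth, so every stage can be exercised and
validated end to end without any external download.

Layout of the default synthetic genome (4 chromosomes x 50 Mb):

* chr1/chr2 carry sparse "gained-accessibility" anchor peaks (present only in
  condition A). Up-regulated and unchanged genes are planted on these
  chromosomes with nearest-anchor TSS distances spread uniformly across the
  seven distance bins, so every bin of the gained-peak analysis is enriched
  for up-genes: increased accessibility associates with increased
  transcription at all distances.
* chr3 carries "lost-accessibility" peaks (condition B only): a few sparse
  anchors plus one dedicated peak within 5 kb of every down-regulated gene.
  The remaining chr3 genes are an up/unchanged mix at the genome-wide rate
  with unconstrained positions, so non-proximal bins of the lost-peak
  analysis match the background composition: decreased accessibility
  associates with decreased transcription only within 5 kb.
* chr4 is a peak-free desert of unchanged genes (unassigned in both
  analyses); it supplies the reservoir that lets gained-analysis bins run
  up-rich without distorting the background.

All generators are pure functions of (spec, seed): one global seed fans out
to independent per-generator streams, so a module's data can be regenerated
without touching the others.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .association import (
    DEFAULT_BINS, DistanceBin, GeneAnnotation, nearest_peak_distances,
    write_gene_table,
)
from .diffexp import DifferentialRecord, bh_fdr, merged_statistic
from .fragments import CLASS_RANGES, FragmentRecord, write_fragments_bed
from .intervals import GenomicInterval, PeakSet, write_peaks

_STREAMS = {
    "anchors": 11, "genome": 12, "table": 13, "peaks": 14,
    "fragments": 15, "marks": 16,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """All knobs of the synthetic study, with the defaults forming the
    reference conditions used throughout the test-suite and acceptance runs."""

    seed: int = 0
    # genome geometry
    chrom_length: int = 50_000_000
    gene_length: tuple[int, int] = (150, 400)
    # gene-class counts (see module docstring for the per-chromosome layout)
    n_up_planted: int = 300
    n_noc_planted: int = 300
    n_up_background: int = 150
    n_noc_background: int = 870
    n_down: int = 60
    n_noc_desert: int = 1320
    # differential-effect model
    effect_log2fc_mean: float = 1.5
    effect_log2fc_sd: float = 0.4
    null_log2fc_sd: float = 0.5
    effect_neglog10p_range: tuple[float, float] = (2.5, 8.0)
    # peak geometry
    n_gained_anchors_per_chrom: int = 5
    gained_anchor_width: int = 5_000
    n_lost_anchors: int = 12
    lost_anchor_width: int = 1_000
    down_peak_width: int = 400
    proximal_max_distance: int = 5_000
    n_shared_peaks: int = 300
    shared_peak_width: int = 400
    # fragment mixture
    n_fragments: int = 100_000
    fragment_weights: tuple[tuple[str, float], ...] = (
        ("NFR", 0.5), ("mono", 0.3), ("di", 0.15), ("tri", 0.05),
    )
    n_dyads: int = 200
    dyad_spacing: int = 400  # long linkers keep planted dyads resolvable
    dyad_jitter_sd: float = 5.0
    nfr_size_range: tuple[int, int] = (30, 99)
    # enhancer marking
    enhancer_fraction: float = 0.3
    mark_overlap_bp: int = 150
    # analysis bins the planted distances are drawn from
    bins: tuple[DistanceBin, ...] = DEFAULT_BINS

    def __post_init__(self) -> None:
        weights = dict(self.fragment_weights)
        if abs(sum(weights.values()) - 1.0) > 1e-9:
            raise ValueError("fragment mixture weights must sum to 1")
        if any(n < 0 for n in (self.n_up_planted, self.n_noc_planted,
                               self.n_up_background, self.n_noc_background,
                               self.n_down, self.n_noc_desert)):
            raise ValueError("gene-class counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return (self.n_up_planted + self.n_noc_planted + self.n_up_background
                + self.n_noc_background + self.n_down + self.n_noc_desert)

    @classmethod
    def all_null(cls, seed: int = 0, n_genes: int = 1000) -> "SyntheticSpec":
        """A spec with no planted effects: every gene is unchanged."""
        return cls(
            seed=seed, n_up_planted=0, n_noc_planted=0, n_up_background=0,
            n_noc_background=0, n_down=0, n_noc_desert=n_genes,
        )


def _rng(spec: SyntheticSpec, stream: str) -> np.random.Generator:
    return np.random.default_rng([spec.seed, _STREAMS[stream]])


# ---------------------------------------------------------------------------
# Gene classes and cohorts (deterministic by gene index)
# ---------------------------------------------------------------------------

def gene_classes(spec: SyntheticSpec) -> pd.DataFrame:
    """Planted truth: gene_id, expression class, placement cohort, target bin.

    Cohorts: 'planted_gained' (chr1/2, nearest-gained-anchor distance planted
    per bin), 'background' (chr3, free position), 'down_proximal' (chr3, a
    dedicated lost peak within 5 kb), 'desert' (chr4, no peaks).
    """
    rows = []
    bins = spec.bins

    def add(n: int, cls: str, cohort: str, planted: bool) -> None:
        for i in range(n):
            rows.append(
                {
                    "class": cls,
                    "cohort": cohort,
                    "target_bin": bins[i % len(bins)].label if planted else "",
                }
            )

    add(spec.n_up_planted, "up", "planted_gained", True)
    add(spec.n_noc_planted, "noc", "planted_gained", True)
    add(spec.n_up_background, "up", "background", False)
    add(spec.n_noc_background, "noc", "background", False)
    add(spec.n_down, "down", "down_proximal", False)
    add(spec.n_noc_desert, "noc", "desert", False)
    df = pd.DataFrame(rows)
    width = max(4, len(str(max(len(df) - 1, 0))))
    df.insert(0, "gene_id", [f"g{i:0{width}d}" for i in range(len(df))])
    return df


# ---------------------------------------------------------------------------
# Anchor layout (shared between gen_genome and gen_peaks...)
# ---------------------------------------------------------------------------

def anchor_layout(spec: SyntheticSpec) -> dict[str, list[GenomicInterval]]:
    """Deterministic differential-peak anchors: gained on chr1/2, lost on chr3."""
    rng = _rng(spec, "anchors")
    gained: list[GenomicInterval] = []
    for chrom in ("chr1", "chr2"):
        for i in range(spec.n_gained_anchors_per_chrom):
            center = 10_000_000 + i * 4_000_000 + int(rng.integers(-200_000, 200_000))
            half = spec.gained_anchor_width // 2
            gained.append(GenomicInterval(chrom, center - half, center + half,
                                          name=f"gained_{chrom}_{i}"))
    lost: list[GenomicInterval] = []
    for i in range(spec.n_lost_anchors):
        span = spec.chrom_length - 4_000_000
        center = 2_000_000 + int(round(span * (i + 0.5) / spec.n_lost_anchors))
        center += int(rng.integers(-150_000, 150_000))
        half = spec.lost_anchor_width // 2
        lost.append(GenomicInterval("chr3", center - half, center + half,
                                    name=f"lost_anchor_{i}"))
    return {"gained": gained, "lost": lost}


# ---------------------------------------------------------------------------
# gen_genome
# ---------------------------------------------------------------------------

class _Occupancy:
    """Per-chromosome non-overlap bookkeeping for gene placement."""

    def __init__(self) -> None:
        self.by_chrom: dict[str, list[tuple[int, int]]] = {}

    def fits(self, chrom: str, start: int, end: int) -> bool:
        ivs = self.by_chrom.setdefault(chrom, [])
        i = bisect.bisect_left(ivs, (start, end))
        if i > 0 and ivs[i - 1][1] > start:
            return False
        if i < len(ivs) and ivs[i][0] < end:
            return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        bisect.insort(self.by_chrom[chrom], (start, end))


def _gene_body(tss: int, strand: str, length: int) -> tuple[int, int]:
    if strand == "+":
        return tss, tss + length
    return tss - length + 1, tss + 1


def _realized_anchor_distance(tss: int, chrom: str,
                              anchors: Sequence[GenomicInterval]) -> float:
    best = math.inf
    for a in anchors:
        if a.chrom != chrom:
            continue
        if a.start <= tss < a.end:
            return 0.0
        best = min(best, abs(tss - a.start), abs(tss - (a.end - 1)))
    return best


def gen_genome(spec: SyntheticSpec, max_retries: int = 300) -> list[GeneAnnotation]:
    """Place non-overlapping genes per the cohort layout; pure in (spec, seed)."""
    rng = _rng(spec, "genome")
    truth = gene_classes(spec)
    anchors = anchor_layout(spec)
    gained = anchors["gained"]
    bin_by_label = {b.label: b for b in spec.bins}
    occ = _Occupancy()
    genes: list[GeneAnnotation] = []
    lo_bound, hi_bound = 10_000, spec.chrom_length - 10_000

    for row in truth.itertuples(index=False):
        length = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        placed = False
        for _ in range(max_retries):
            if row.cohort == "planted_gained":
                target = bin_by_label[row.target_bin]
                anchor = gained[int(rng.integers(len(gained)))]
                if target.lo == 0 and target.hi == 1:  # exact-zero bin
                    tss = int(rng.integers(anchor.start, anchor.end))
                else:
                    d = int(rng.integers(target.lo, target.hi))
                    if rng.random() < 0.5:
                        tss = anchor.start - d
                    else:
                        tss = anchor.end - 1 + d
                chrom = anchor.chrom
                if not (lo_bound <= tss <= hi_bound):
                    continue
                realized = _realized_anchor_distance(tss, chrom, gained)
                if not target.contains(realized):
                    continue
            elif row.cohort in ("background", "down_proximal"):
                chrom = "chr3"
                tss = int(rng.integers(lo_bound, hi_bound))
            else:  # desert
                chrom = "chr4"
                tss = int(rng.integers(lo_bound, hi_bound))
            start, end = _gene_body(tss, strand, length)
            if start < 0 or not occ.fits(chrom, start, end):
                continue
            occ.add(chrom, start, end)
            genes.append(GeneAnnotation(row.gene_id, chrom, strand, start, end))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place gene {row.gene_id} ({row.cohort}) after "
                f"{max_retries} retries: packing infeasible"
            )
    return genes


# ---------------------------------------------------------------------------
# gen_differential_table
# ---------------------------------------------------------------------------

def gen_differential_table(spec: SyntheticSpec) -> list[DifferentialRecord]:
    """Per-gene log2FC and p with planted up/down/null classes; q via BH, D merged.

    Up genes: log2FC ~ N(+mean, sd) folded positive, p = 10^-U(range); down
    genes mirrored; unchanged genes: log2FC ~ N(0, sd_null), p ~ Uniform(0,1).
    """
    rng = _rng(spec, "table")
    truth = gene_classes(spec)
    n = len(truth)
    log2fc = np.empty(n)
    pvals = np.empty(n)
    cls = truth["class"].to_numpy()
    for mask, sign in ((cls == "up", 1.0), (cls == "down", -1.0)):
        k = int(mask.sum())
        if k:
            log2fc[mask] = sign * np.abs(
                rng.normal(spec.effect_log2fc_mean, spec.effect_log2fc_sd, size=k)
            )
            lo, hi = spec.effect_neglog10p_range
            pvals[mask] = 10.0 ** (-rng.uniform(lo, hi, size=k))
    mask = cls == "noc"
    k = int(mask.sum())
    if k:
        log2fc[mask] = rng.normal(0.0, spec.null_log2fc_sd, size=k)
        pvals[mask] = rng.uniform(0.0, 1.0, size=k)
    qvals = bh_fdr(pvals)
    return [
        DifferentialRecord(
            gene_id=gid, log2fc=float(l), pvalue=float(p), qvalue=float(q),
            D=merged_statistic(float(l), float(q)),
        )
        for gid, l, p, q in zip(truth["gene_id"], log2fc, pvals, qvals)
    ]


# ---------------------------------------------------------------------------
# gen_peaks_with_distance_model
# ---------------------------------------------------------------------------

def _score(rng: np.random.Generator) -> float:
    # MACS2-like monotone score column, everything above the score>5 filter
    return float(round(10.0 ** rng.uniform(0.72, 2.5), 3))


def gen_peaks_with_distance_model(
    spec: SyntheticSpec,
    genes: Sequence[GeneAnnotation],
    table: Sequence[DifferentialRecord] | None = None,
) -> tuple[PeakSet, PeakSet]:
    """Condition A and B peak sets realising the planted distance model.

    A-specific peaks are the gained anchors around which up/unchanged genes
    were planted; B-specific peaks are the chr3 lost anchors plus a dedicated
    peak within 5 kb of every down gene; shared peaks (identical in A and B)
    are scattered on chr1-chr3 clear of the differential peaks.
    """
    rng = _rng(spec, "peaks")
    anchors = anchor_layout(spec)
    truth = gene_classes(spec)
    gene_by_id = {g.gene_id: g for g in genes}

    gained = [
        GenomicInterval(a.chrom, a.start, a.end, score=_score(rng), name=a.name)
        for a in anchors["gained"]
    ]
    lost = [
        GenomicInterval(a.chrom, a.start, a.end, score=_score(rng), name=a.name)
        for a in anchors["lost"]
    ]
    # dedicated lost peak per down gene: half at distance 0, half within 5 kb
    down_ids = truth.loc[truth["cohort"] == "down_proximal", "gene_id"].tolist()
    w = spec.down_peak_width
    for j, gid in enumerate(down_ids):
        tss = gene_by_id[gid].tss
        if j % 2 == 0:
            start = tss - int(rng.integers(0, w))
        else:
            d = int(rng.integers(1, spec.proximal_max_distance))
            if rng.random() < 0.5:
                start = tss + d  # peak's left edge at distance d
            else:
                start = tss - d - w + 1  # right-most base at distance d
        start = max(0, start)
        lost.append(GenomicInterval("chr3", start, start + w,
                                    score=_score(rng), name=f"lost_{gid}"))

    differential = gained + lost
    shared: list[GenomicInterval] = []
    buffer = 2_000
    while len(shared) < spec.n_shared_peaks:
        chrom = ("chr1", "chr2", "chr3")[int(rng.integers(3))]
        start = int(rng.integers(10_000, spec.chrom_length - 10_000))
        end = start + spec.shared_peak_width
        clash = any(
            d.chrom == chrom and min(d.end, end + buffer) > max(d.start, start - buffer)
            for d in differential
        )
        if clash:
            continue
        shared.append(GenomicInterval(chrom, start, end, score=_score(rng),
                                      name=f"shared_{len(shared)}"))

    peaks_a = PeakSet(label="conditionA", intervals=shared + gained, assay="ATAC")
    peaks_b = PeakSet(label="conditionB", intervals=shared + lost, assay="ATAC")
    return peaks_a, peaks_b


def differential_peak_sets(spec: SyntheticSpec,
                           genes: Sequence[GeneAnnotation]) -> tuple[PeakSet, PeakSet]:
    """Convenience: the planted gained-only and lost-only peak sets."""
    peaks_a, peaks_b = gen_peaks_with_distance_model(spec, genes)
    shared_names = {iv.name for iv in peaks_a if iv.name and iv.name.startswith("shared_")}
    gained = [iv for iv in peaks_a if iv.name not in shared_names]
    lost = [iv for iv in peaks_b if iv.name not in shared_names]
    return (PeakSet("gained", gained, assay="ATAC"),
            PeakSet("lost", lost, assay="ATAC"))


# ---------------------------------------------------------------------------
# gen_fragments
# ---------------------------------------------------------------------------

def dyad_positions(spec: SyntheticSpec) -> np.ndarray:
    """Planted nucleosome dyad centers: a regular array on chr1."""
    return 30_000_000 + np.arange(spec.n_dyads) * spec.dyad_spacing


def gen_fragments(spec: SyntheticSpec) -> list[FragmentRecord]:
    """Pre-shift paired-end fragments from the nucleosome mixture.

    Sizes are drawn within each class's stated range; mono/di/tri fragments
    are centered (with small jitter) on planted dyads, nucleosome-free
    fragments fall uniformly on chr1/chr2. Coordinates are emitted *before*
    Tn5 correction, i.e. shifted by (-4, +5) relative to the planted geometry,
    so that the +4/-5 fragment shift restores it.
    """
    rng = _rng(spec, "fragments")
    weights = dict(spec.fragment_weights)
    classes = list(weights)
    counts = rng.multinomial(spec.n_fragments, [weights[c] for c in classes])
    dyads = dyad_positions(spec)
    frags: list[FragmentRecord] = []
    for cls, count in zip(classes, counts):
        if count == 0:
            continue
        if cls == "NFR":
            sizes = rng.integers(spec.nfr_size_range[0],
                                 spec.nfr_size_range[1] + 1, size=count)
            chroms = np.where(rng.random(count) < 0.5, "chr1", "chr2")
            centers = rng.integers(1_000_000, spec.chrom_length - 1_000_000,
                                   size=count)
        else:
            lo, hi = CLASS_RANGES[cls]
            sizes = rng.integers(lo, hi + 1, size=count)
            chroms = np.full(count, "chr1", dtype=object)
            n_span = {"mono": 1, "di": 2, "tri": 3}[cls]
            first = rng.integers(0, len(dyads) - n_span + 1, size=count)
            centers = ((dyads[first] + dyads[first + n_span - 1]) // 2
                       + np.rint(rng.normal(0, spec.dyad_jitter_sd, size=count))
                       .astype(int))
        starts = centers - sizes // 2
        ends = starts + sizes
        for c, s, e in zip(chroms, starts, ends):
            frags.append(FragmentRecord(str(c), int(s - 4), int(e + 5)))
    order = rng.permutation(len(frags))
    return [frags[i] for i in order]


# ---------------------------------------------------------------------------
# gen_marked_enhancers
# ---------------------------------------------------------------------------

def gen_marked_enhancers(
    spec: SyntheticSpec, peaks: PeakSet
) -> tuple[PeakSet, PeakSet, np.ndarray]:
    """Two histone-mark peak sets plus the planted enhancer truth flags.

    A planted fraction of accessibility peaks receives an interval in BOTH
    mark sets, nested inside the peak so the overlap is guaranteed; half of
    the remaining peaks receive only the first mark, the rest none. A few
    decoy mark intervals are placed on the peak-free chr4.
    """
    rng = _rng(spec, "marks")
    truth = rng.random(len(peaks)) < spec.enhancer_fraction
    mark1: list[GenomicInterval] = []
    mark2: list[GenomicInterval] = []
    for iv, is_enh in zip(peaks, truth):
        span = max(spec.mark_overlap_bp, iv.length // 3)
        span = min(span, iv.length)
        if is_enh:
            mark1.append(GenomicInterval(iv.chrom, iv.start, iv.start + span))
            mark2.append(GenomicInterval(iv.chrom, iv.end - span, iv.end))
        elif rng.random() < 0.5:
            mark1.append(GenomicInterval(iv.chrom, iv.start, iv.start + span))
    for i in range(20):
        start = int(rng.integers(1_000_000, spec.chrom_length - 1_000_000))
        target = mark1 if i % 2 == 0 else mark2
        target.append(GenomicInterval("chr4", start, start + 500))
    return (
        PeakSet("H3K4me1", mark1, assay="ChIP"),
        PeakSet("H3K27ac", mark2, assay="ChIP"),
        truth,
    )


# ---------------------------------------------------------------------------
# Bundled dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    genes: list[GeneAnnotation]
    table: list[DifferentialRecord]
    peaks_a: PeakSet
    peaks_b: PeakSet
    gained: PeakSet
    lost: PeakSet
    fragments: list[FragmentRecord]
    mark1: PeakSet
    mark2: PeakSet
    enhancer_truth: np.ndarray
    truth: pd.DataFrame


def generate_dataset(spec: SyntheticSpec,
                     with_fragments: bool = True) -> SyntheticDataset:
    """Run every generator once and bundle outputs with the planted truth."""
    genes = gen_genome(spec)
    table = gen_differential_table(spec)
    peaks_a, peaks_b = gen_peaks_with_distance_model(spec, genes, table)
    gained, lost = differential_peak_sets(spec, genes)
    fragments = gen_fragments(spec) if with_fragments else []
    mark1, mark2, enh_truth = gen_marked_enhancers(spec, peaks_a)
    truth = gene_classes(spec)
    truth["gained_distance"] = nearest_peak_distances(genes, gained)
    truth["lost_distance"] = nearest_peak_distances(genes, lost)
    return SyntheticDataset(
        spec=spec, genes=genes, table=table, peaks_a=peaks_a, peaks_b=peaks_b,
        gained=gained, lost=lost, fragments=fragments, mark1=mark1,
        mark2=mark2, enhancer_truth=enh_truth, truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the standard formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.tsv",
        "diffexp": outdir / "diffexp.tsv",
        "peaks_a": outdir / "peaks_conditionA.bed",
        "peaks_b": outdir / "peaks_conditionB.bed",
        "gained": outdir / "peaks_gained.bed",
        "lost": outdir / "peaks_lost.bed",
        "fragments": outdir / "fragments.bed",
        "mark1": outdir / "mark_H3K4me1.bed",
        "mark2": outdir / "mark_H3K27ac.bed",
        "truth": outdir / "truth.tsv",
    }
    write_gene_table(ds.genes, paths["genes"])
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in ds.table],
            "log2fc": [r.log2fc for r in ds.table],
            "pvalue": [r.pvalue for r in ds.table],
            "qvalue": [r.qvalue for r in ds.table],
            "D": [r.D for r in ds.table],
        }
    ).to_csv(paths["diffexp"], sep="\t", index=False)
    write_peaks(ds.peaks_a, paths["peaks_a"])
    write_peaks(ds.peaks_b, paths["peaks_b"])
    write_peaks(ds.gained, paths["gained"])
    write_peaks(ds.lost, paths["lost"])
    write_fragments_bed(ds.fragments, paths["fragments"])
    write_peaks(ds.mark1, paths["mark1"])
    write_peaks(ds.mark2, paths["mark2"])
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["enhancer_truth"] = outdir / "enhancer_truth.tsv"
    pd.DataFrame(
        {
            "peak_name": [iv.name or "." for iv in ds.peaks_a],
            "is_enhancer": ds.enhancer_truth.astype(int),
        }
    ).to_csv(paths["enhancer_truth"], sep="\t", index=False)
    return paths
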