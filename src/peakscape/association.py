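"""Distance-resolved association between peak sets and gene-expression change.

The central inference: group genes by the distance from their TSS to the
nearest peak of a chosen set, then compare each distance bin's merged
differential statistic D against the all-gene background, as matched empirical
quantiles (Q-Q), probability histograms, and hypergeometric per-bin enrichment
of significantly changed genes.

Distances are nearest-bp: 0 when the TSS lies inside a peak, otherwise the gap
to the closest covered base. The default bin scheme is the non-overlapping
half-open ladder 0, (0,5k), [5k,20k), [20k,100k), [100k,200k), [200k,500k),
[500k,5Mb); the exact-zero bin is represented as [0,1) over integer distances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import DifferentialRecord, bh_fdr
from .intervals import GenomicInterval, PeakSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its transcription start site derived from strand."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: require tx_start < tx_end")

    @property
    def tss(self) -> int:
        """TSS base: tx_start for + genes, tx_end - 1 for - genes (half-open)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass(frozen=True)
class DistanceBin:
    """Half-open distance bin [lo, hi) in bp."""

    label: str
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"bin {self.label}: require 0 <= lo < hi")

    def contains(self, distance: float) -> bool:
        return self.lo <= distance < self.hi


#: Non-overlapping ladder: 0-0, 0-5 kb, 5-20 kb, 20-100 kb, 100-200 kb,
#: 200-500 kb, 500 kb-5 Mb (the exact-zero bin is [0,1) over integer bp).
DEFAULT_BINS: tuple[DistanceBin, ...] = (
    DistanceBin("0", 0, 1),
    DistanceBin("0-5kb", 1, 5_000),
    DistanceBin("5-20kb", 5_000, 20_000),
    DistanceBin("20-100kb", 20_000, 100_000),
    DistanceBin("100-200kb", 100_000, 200_000),
    DistanceBin("200-500kb", 200_000, 500_000),
    DistanceBin("500kb-5Mb", 500_000, 5_000_000),
)


def validate_bins(bins: Sequence[DistanceBin]) -> None:
    for a, b in zip(bins, bins[1:]):
        if a.hi > b.lo:
            raise ValueError(f"bins {a.label} and {b.label} overlap or are unordered")


@dataclass
class QQData:
    """Matched empirical quantiles of subset statistics vs the background."""

    quantile_grid: np.ndarray
    background_q: np.ndarray
    subset_q: dict[str, np.ndarray]


@dataclass
class DifferentialHistogram:
    """Per-subset probability masses over shared statistic-value bin edges."""

    bin_edges: np.ndarray
    densities: dict[str, np.ndarray]


def peak_tss_distance(peak: GenomicInterval, gene: GeneAnnotation) -> float:
    """bp between a peak and a gene's TSS; 0 if the TSS lies inside the peak.

    Nearest-edge convention on half-open intervals: the closest covered base
    is ``start`` or ``end - 1``. Different chromosome returns +inf.
    """
    if peak.chrom != gene.chrom:
        return math.inf
    tss = gene.tss
    if peak.start <= tss < peak.end:
        return 0.0
    return float(min(abs(tss - peak.start), abs(tss - (peak.end - 1))))


def nearest_peak_distances(
    genes: Sequence[GeneAnnotation], peaks: PeakSet
) -> np.ndarray:
    """Distance from each gene's TSS to its nearest peak (inf if none on chrom).

    Vectorised per chromosome with sorted edge arrays; ties between equally
    near peaks resolve to the same distance regardless of which peak wins, so
    the smaller-coordinate tie-break has no effect on the value.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in peaks:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    edge_arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        starts = np.array([iv.start for iv in ivs])  # already sorted
        last = np.array([iv.end - 1 for iv in ivs])
        max_last = np.maximum.accumulate(last)
        edge_arrays[chrom] = (starts, np.sort(last), max_last)

    out = np.full(len(genes), np.inf)
    tss_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, g in enumerate(genes):
        tss_by_chrom.setdefault(g.chrom, []).append((i, g.tss))
    for chrom, items in tss_by_chrom.items():
        if chrom not in edge_arrays:
            continue
        starts, lasts_sorted, max_last = edge_arrays[chrom]
        idx = np.array([i for i, _ in items])
        tss = np.array([t for _, t in items])
        # containment: some peak with start <= tss has end - 1 >= tss
        pos = np.searchsorted(starts, tss, side="right") - 1
        contained = (pos >= 0) & (max_last[np.clip(pos, 0, None)] >= tss)
        # nearest start edge
        d = np.full(tss.shape, np.inf)
        j = np.searchsorted(starts, tss)
        left_ok = j > 0
        d[left_ok] = np.minimum(d[left_ok], tss[left_ok] - starts[j[left_ok] - 1])
        right_ok = j < starts.size
        d[right_ok] = np.minimum(d[right_ok], starts[j[right_ok]] - tss[right_ok])
        # nearest end edge
        j = np.searchsorted(lasts_sorted, tss)
        left_ok = j > 0
        d[left_ok] = np.minimum(d[left_ok], tss[left_ok] - lasts_sorted[j[left_ok] - 1])
        right_ok = j < lasts_sorted.size
        d[right_ok] = np.minimum(d[right_ok], lasts_sorted[j[right_ok]] - tss[right_ok])
        d = np.abs(d)
        d[contained] = 0.0
        out[idx] = d
    return out


def bin_genes_by_nearest_peak(
    genes: Sequence[GeneAnnotation],
    peaks: PeakSet,
    bins: Sequence[DistanceBin] = DEFAULT_BINS,
) -> dict[str, set[str]]:
    """Assign each gene to the bin containing its nearest-peak distance.

    Genes whose distance falls outside every bin (including infinite distance
    when no peak shares the chromosome) are left unassigned.
    """
    validate_bins(bins)
    if len(peaks) == 0:
        logger.warning("empty peak set: all genes unassigned")
        return {b.label: set() for b in bins}
    distances = nearest_peak_distances(genes, peaks)
    assignment: dict[str, set[str]] = {b.label: set() for b in bins}
    for g, d in zip(genes, distances):
        for b in bins:
            if b.contains(d):
                assignment[b.label].add(g.gene_id)
                break
    return assignment


def subset_statistics(
    bin_assignment: Mapping[str, set[str]],
    records: Sequence[DifferentialRecord],
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-bin vectors of the merged statistic D, plus the all-gene background."""
    d_by_gene: dict[str, float] = {}
    for rec in records:
        if rec.D is None:
            raise ValueError(f"{rec.gene_id}: merged statistic D not filled")
        d_by_gene[rec.gene_id] = rec.D
    missing = sorted(
        gid for gids in bin_assignment.values() for gid in gids
        if gid not in d_by_gene
    )
    if missing:
        raise KeyError(f"gene ids without differential records: {missing[:10]}")
    per_bin: dict[str, np.ndarray] = {}
    for label, gids in bin_assignment.items():
        if not gids:
            logger.warning("bin %s is empty", label)
        per_bin[label] = np.array(sorted(d_by_gene[g] for g in gids), dtype=float)
    background = np.array([rec.D for rec in records], dtype=float)
    return per_bin, background


def qq_curve(
    subset: np.ndarray,
    background: np.ndarray,
    n_points: int = 199,
) -> QQData:
    """Matched empirical quantiles of subset vs background on a shared grid.

    The probability grid is i/(n_points+1) for i = 1..n_points; quantiles use
    linear interpolation between order statistics. When the subset equals the
    background the curve lies on the identity line.
    """
    subset = np.asarray(subset, dtype=float)
    background = np.asarray(background, dtype=float)
    if subset.size == 0:
        raise ValueError("empty subset")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.arange(1, n_points + 1) / (n_points + 1)
    return QQData(
        quantile_grid=grid,
        background_q=np.quantile(background, grid),
        subset_q={"subset": np.quantile(subset, grid)},
    )


def qq_curves(
    subsets: Mapping[str, np.ndarray],
    background: np.ndarray,
    n_points: int = 199,
) -> QQData:
    """Q-Q curves for several labelled subsets against one shared background."""
    grid = np.arange(1, n_points + 1) / (n_points + 1)
    out = QQData(
        quantile_grid=grid,
        background_q=np.quantile(np.asarray(background, dtype=float), grid),
        subset_q={},
    )
    for label, values in subsets.items():
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            logger.warning("subset %s empty: no Q-Q curve", label)
            continue
        out.subset_q[label] = np.quantile(values, grid)
    return out


def differential_histogram(
    subsets: Mapping[str, np.ndarray],
    bin_edges: np.ndarray | Sequence[float],
) -> DifferentialHistogram:
    """Per-subset probability masses over shared edges; out-of-range values
    are clipped into the end bins (logged)."""
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    densities: dict[str, np.ndarray] = {}
    for label, values in subsets.items():
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            densities[label] = np.zeros(edges.size - 1)
            continue
        n_out = int(np.sum((values < edges[0]) | (values > edges[-1])))
        if n_out:
            logger.info("%s: clipping %d values into end bins", label, n_out)
        clipped = np.clip(values, edges[0], edges[-1])
        counts, _ = np.histogram(clipped, bins=edges)
        densities[label] = counts / counts.sum()
    return DifferentialHistogram(bin_edges=edges, densities=densities)


def bin_enrichment_test(
    bin_genes: set[str], signif_genes: set[str], universe: set[str]
) -> float:
    """Hypergeometric upper-tail p for enrichment of significant genes in a bin."""
    if not universe:
        raise ValueError("empty universe")
    if not (bin_genes <= universe and signif_genes <= universe):
        raise ValueError("gene sets must be subsets of the universe")
    k = len(bin_genes & signif_genes)
    return float(
        stats.hypergeom.sf(k - 1, len(universe), len(signif_genes), len(bin_genes))
    )


def bin_enrichment_table(
    bin_assignment: Mapping[str, set[str]],
    signif_genes: set[str],
    universe: set[str],
) -> pd.DataFrame:
    """Per-bin enrichment p-values with BH correction across bins."""
    labels = list(bin_assignment)
    pvals = [
        bin_enrichment_test(bin_assignment[lab], signif_genes, universe)
        if bin_assignment[lab] else 1.0
        for lab in labels
    ]
    return pd.DataFrame(
        {
            "bin": labels,
            "n_genes": [len(bin_assignment[lab]) for lab in labels],
            "n_signif": [len(bin_assignment[lab] & signif_genes) for lab in labels],
            "p_enrichment": pvals,
            "q_enrichment": bh_fdr(pvals),
        }
    )


# ---------------------------------------------------------------------------
# Gene-annotation I/O
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    """Read a flat TSV with header gene_id, chrom, strand, tx_start, tx_end."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "tx_start", "tx_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        GeneAnnotation(str(r.gene_id), str(r.chrom), str(r.strand),
                       int(r.tx_start), int(r.tx_end))
        for r in df.itertuples(index=False)
    ]


def read_genes_bed12(path: str | Path) -> list[GeneAnnotation]:
    """Read gene models from BED12 (uses columns chrom, start, end, name, strand)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns")
            genes.append(
                GeneAnnotation(fields[3], fields[0], fields[5],
                               int(fields[1]), int(fields[2]))
            )
    return genes


def write_gene_table(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tx_start": [g.tx_start for g in genes],
            "tx_end": [g.tx_end for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def percent_captured(n_captured: int, n_total: int) -> float:
    """Percentage of a gene universe captured within a distance cutoff."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_captured / n_total
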