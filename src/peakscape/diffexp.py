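"""Differential-expression bookkeeping.

Benjamini-Hochberg FDR, strict q < threshold up/down/unchanged classification,
the merged differential statistic D = log2FC x (-log10 q), and gene-set log2
enrichment with a hypergeometric tail p-value.

D combines effect size and significance into a single signed, ordinal value:
its sign is the direction of change and its magnitude grows with both |log2FC|
and significance. Downstream it is only used through quantiles and ranks, so
the logarithm base (fixed to 10 here, configurable) rescales without
reordering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_Q_FLOOR = 1e-300


@dataclass
class DifferentialRecord:
    """Per-gene differential result: log2 fold-change, raw p, BH q, merged D."""

    gene_id: str
    log2fc: float
    pvalue: float
    qvalue: float | None = None
    D: float | None = None


@dataclass
class GeneClassLabels:
    """Partition of the gene universe into up / down / unchanged (noc)."""

    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)
    noc: set[str] = field(default_factory=set)

    @property
    def universe(self) -> set[str]:
        return self.up | self.down | self.noc


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_i = min over j with p_(j) >= p_(i) of n * p_(j) / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def merged_statistic(
    log2fc: float, qvalue: float, q_floor: float = DEFAULT_Q_FLOOR,
    base: float = 10.0,
) -> float:
    """Merged differential statistic: log2fc x (-log_base(max(q, q_floor))).

    ``q_floor`` keeps the statistic finite when an upstream tool reports q = 0;
    q = 0 with q_floor = 0 is an error (infinite statistic).
    """
    if not (0.0 <= qvalue <= 1.0):
        raise ValueError(f"qvalue {qvalue} outside [0, 1]")
    q = max(qvalue, q_floor)
    if q <= 0.0:
        raise ValueError("qvalue 0 with q_floor 0: statistic is infinite")
    return log2fc * (-math.log(q, base))


def classify_genes(
    records: Iterable[DifferentialRecord], q_threshold: float = 0.05
) -> GeneClassLabels:
    """Strict q < threshold classification into up / down / noc.

    A gene exactly at the threshold, or significant with log2fc = 0, is 'noc'.
    Duplicate gene ids are an error.
    """
    labels = GeneClassLabels()
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene id {rec.gene_id!r}")
        seen.add(rec.gene_id)
        if rec.qvalue is None:
            raise ValueError(f"{rec.gene_id}: qvalue not filled")
        if rec.qvalue < q_threshold and rec.log2fc > 0:
            labels.up.add(rec.gene_id)
        elif rec.qvalue < q_threshold and rec.log2fc < 0:
            labels.down.add(rec.gene_id)
        else:
            labels.noc.add(rec.gene_id)
    return labels


def set_log2_enrichment(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> tuple[float, float]:
    """Log2 enrichment of the overlap of two gene sets over independence.

    enrichment = log2( (|A&B|/|U|) / ((|A|/|U|) * (|B|/|U|)) ); the p-value is
    the hypergeometric upper tail for an overlap >= |A&B| when drawing |B|
    genes from a universe containing |A| marked ones.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set_a or not set_b:
        raise ValueError("empty gene set")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    n_u, n_a, n_b = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    if k == 0:
        enrichment = -math.inf
    else:
        enrichment = math.log2((k * n_u) / (n_a * n_b))
    p = float(stats.hypergeom.sf(k - 1, n_u, n_a, n_b))
    return enrichment, p


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def read_differential_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV differential table with header gene_id, log2fc, pvalue[, qvalue]."""
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"gene_id", "log2fc", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()[:5]
        raise ValueError(f"{path}: duplicate gene ids, e.g. {dupes}")
    return df


def augment_table(df: pd.DataFrame, q_floor: float = DEFAULT_Q_FLOOR,
                  base: float = 10.0) -> pd.DataFrame:
    """Return a copy with qvalue (BH over pvalue, unless supplied) and D columns."""
    out = df.copy()
    if "qvalue" not in out.columns:
        out["qvalue"] = bh_fdr(out["pvalue"].to_numpy())
    out["D"] = [
        merged_statistic(lfc, q, q_floor=q_floor, base=base)
        for lfc, q in zip(out["log2fc"], out["qvalue"])
    ]
    return out


def records_from_frame(df: pd.DataFrame) -> list[DifferentialRecord]:
    cols = ["gene_id", "log2fc", "pvalue"]
    has_q = "qvalue" in df.columns
    has_d = "D" in df.columns
    records = []
    for row in df.itertuples(index=False):
        records.append(
            DifferentialRecord(
                gene_id=str(row.gene_id),
                log2fc=float(row.log2fc),
                pvalue=float(row.pvalue),
                qvalue=float(row.qvalue) if has_q else None,
                D=float(row.D) if has_d else None,
            )
        )
    return records


def write_differential_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
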