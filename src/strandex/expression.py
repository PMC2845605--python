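"""Gene expression quantification and sense/antisense density statistics.

Expression is reported as RPKM — reads per kilobase of gene (exonic)
length per million mapped reads:

    rpkm = C / ((L_g / 1000) * (M_total / 1e6))

where C is the gene's sense exonic read count, L_g its exonic length and
M_total the sample's total mapped reads (both strands).  Region-level
statistics are the relative tag density

    D(t, s) = N(t, s) / (L(t) * M(s))

(read count in regions of type t on strand relation s, normalized by the
total length of those regions and by the total strand-s reads assigned to
the annotation) and the antisense fraction

    r(t) = N(t, antisense) / (N(t, sense) + N(t, antisense)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation import GeneModel, RegionPartition, REGION_TYPES
from .read_assignment import AlignedRead

__all__ = [
    "ExpressionRecord",
    "compute_rpkm",
    "gene_read_counts",
    "expression_table",
    "expressed_gene_sets",
    "antisense_gene_flags",
    "density_table",
    "pairwise_sample_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene expression: sense exonic count, exonic length, RPKM."""

    gene_id: str
    count: int
    exonic_length: int
    rpkm: float


def compute_rpkm(count: float, length_bp: float, m_total: float) -> float:
    """Reads per kilobase of (exonic) length per million mapped reads.

    Linear in *count*, inversely proportional to *length_bp*; zero iff the
    count is zero.
    """
    if length_bp <= 0:
        raise ValueError(f"length must be positive, got {length_bp}")
    if m_total <= 0:
        raise ValueError(f"total read count must be positive, got {m_total}")
    return count / ((length_bp / 1000.0) * (m_total / 1e6))


class _ExonIndex:
    """Containment lookup read -> genes with an exon fully containing it."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        self._strand: dict[str, str] = {}
        for g in genes:
            self._strand[g.gene_id] = g.strand
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            for e in g.exons:
                tree.addi(e.start, e.end, g.gene_id)

    def containing_genes(self, read: AlignedRead) -> set[str]:
        tree = self._trees.get(read.interval.chrom)
        if tree is None:
            return set()
        s, e = read.interval.start, read.interval.end
        return {h.data for h in tree.overlap(s, e) if h.begin <= s and e <= h.end}

    def strand(self, gene_id: str) -> str:
        return self._strand[gene_id]


def gene_read_counts(
    reads: Sequence[AlignedRead],
    genes: Sequence[GeneModel],
    antisense: bool = False,
) -> dict[str, int]:
    """Per-gene count of reads entirely within any exon, on the gene strand.

    With ``antisense=True`` counts reads on the opposite strand instead.
    A read contained in exons of several genes counts toward each (the
    per-gene aggregate is not a partition).
    """
    index = _ExonIndex(genes)
    counts = {g.gene_id: 0 for g in genes}
    for read in reads:
        for gid in index.containing_genes(read):
            same = read.interval.strand == index.strand(gid)
            if same != antisense:
                counts[gid] += 1
    return counts


def expression_table(
    reads: Sequence[AlignedRead],
    genes: Sequence[GeneModel],
    m_total: int | None = None,
) -> pd.DataFrame:
    """Per-gene expression table (gene_id, count, exonic length, RPKM).

    *m_total* defaults to the number of input reads (the sample's total
    uniquely mapped reads, both strands).
    """
    if m_total is None:
        m_total = len(reads)
    counts = gene_read_counts(reads, genes)
    rows = [
        (
            g.gene_id,
            counts[g.gene_id],
            g.exonic_length,
            compute_rpkm(counts[g.gene_id], g.exonic_length, m_total)
            if m_total > 0
            else 0.0,
        )
        for g in genes
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "count", "exonic_length", "rpkm"]
    ).set_index("gene_id")


def expressed_gene_sets(
    counts_per_sample: Mapping[str, Mapping[str, int]],
    threshold: int = 1,
) -> dict:
    """Expressed-gene sets per sample and their overlap statistics.

    A gene is called expressed in a sample when its sense exonic read count
    is at least *threshold*.  Reports the expressed fraction per sample,
    the fraction of ever-expressed genes shared by all samples
    (``|intersection| / |union|``), and pairwise Jaccard indices.
    """
    samples = sorted(counts_per_sample)
    if not samples:
        raise ValueError("no samples given")
    universe = set(counts_per_sample[samples[0]])
    for s in samples[1:]:
        if set(counts_per_sample[s]) != universe:
            raise ValueError(f"sample {s}: gene universe differs across samples")
    sets = {
        s: {g for g, c in counts_per_sample[s].items() if c >= threshold}
        for s in samples
    }
    union = set().union(*sets.values())
    inter = set(universe)
    for s in samples:
        inter &= sets[s]
    jaccard = {}
    for a, b in combinations(samples, 2):
        u = sets[a] | sets[b]
        jaccard[(a, b)] = len(sets[a] & sets[b]) / len(u) if u else float("nan")
    return {
        "sets": sets,
        "universe_size": len(universe),
        "expressed_fraction": {s: len(sets[s]) / len(universe) for s in samples},
        "shared_fraction": len(inter) / len(union) if union else float("nan"),
        "pairwise_jaccard": jaccard,
    }


def antisense_gene_flags(
    reads: Sequence[AlignedRead],
    genes: Sequence[GeneModel],
    threshold: int = 1,
) -> dict:
    """Genes with exonic antisense transcription (count >= *threshold*)."""
    anti = gene_read_counts(reads, genes, antisense=True)
    flagged = {g for g, c in anti.items() if c >= threshold}
    return {
        "flagged": flagged,
        "flagged_fraction": len(flagged) / len(genes) if genes else float("nan"),
        "antisense_counts": anti,
    }


def density_table(
    counts: pd.DataFrame,
    partition: RegionPartition,
) -> pd.DataFrame:
    """Relative tag densities and antisense fractions per region type.

    *counts* is a count table as produced by
    :func:`strandex.read_assignment.count_by_region` (rows = categories,
    columns = sense/antisense/na).  The strand totals M(s) are the sense
    (resp. antisense) reads assigned to annotated region types, excluding
    the ``other`` category, so D stays a within-annotation density.
    Region types with zero total length are omitted with a warning.
    Columns ``D_sense_norm``/``D_antisense_norm`` rescale each density
    column to its maximum for cross-type comparison.
    """
    m_sense = int(counts.loc[list(REGION_TYPES), "sense"].sum())
    m_anti = int(counts.loc[list(REGION_TYPES), "antisense"].sum())
    rows = []
    for t in REGION_TYPES:
        length = partition.total_length.get(t, 0)
        if length <= 0:
            logger.warning("region type %s has zero total length; omitted", t)
            continue
        n_s = int(counts.loc[t, "sense"])
        n_a = int(counts.loc[t, "antisense"])
        d_s = n_s / (length * m_sense) if m_sense > 0 else float("nan")
        d_a = n_a / (length * m_anti) if m_anti > 0 else float("nan")
        r = n_a / (n_s + n_a) if (n_s + n_a) > 0 else float("nan")
        rows.append((t, n_s, n_a, length, d_s, d_a, r))
    df = pd.DataFrame(
        rows,
        columns=[
            "region_type", "N_sense", "N_antisense", "L",
            "D_sense", "D_antisense", "r_antisense",
        ],
    ).set_index("region_type")
    for col in ("D_sense", "D_antisense"):
        mx = df[col].max()
        df[col + "_norm"] = df[col] / mx if mx and mx > 0 else float("nan")
    return df


def pairwise_sample_correlation(
    rpkm_per_sample: Mapping[str, Mapping[str, float] | pd.Series],
    min_genes: int = 2,
) -> pd.DataFrame:
    """Spearman rho matrix of log10(RPKM) between samples.

    For each sample pair, genes with zero RPKM in either sample are dropped
    (count logged) before ranking; pairs left with fewer than *min_genes*
    genes get NaN.  The matrix is symmetric with unit diagonal.
    """
    samples = sorted(rpkm_per_sample)
    series = {s: pd.Series(rpkm_per_sample[s], dtype=float) for s in samples}
    mat = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    for a, b in combinations(samples, 2):
        x, y = series[a].align(series[b], join="inner")
        keep = (x > 0) & (y > 0)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("pair (%s, %s): dropped %d zero-RPKM genes", a, b, dropped)
        if keep.sum() < min_genes:
            logger.warning("pair (%s, %s): <%d genes left; rho=NaN", a, b, min_genes)
            rho = float("nan")
        else:
            rho = float(
                stats.spearmanr(np.log10(x[keep]), np.log10(y[keep])).statistic
            )
        mat.loc[a, b] = mat.loc[b, a] = rho
    return mat
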