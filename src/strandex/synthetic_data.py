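"""Synthetic annotated genome, stranded reads, planted TARs and probes.

The generator emulates the structure of a strand-specific short-read
transcriptome experiment on a toy genome with full ground truth:

* a multi-gene annotation with introns, UTR/CDS structure and a few
  deliberately adjacent gene pairs (to exercise promoter/terminator
  trimming), plus some non-coding RNA intervals;
* per-sample stranded 50-bp reads drawn per region type with configurable
  antisense fractions (defaults: exons 1%, promoters 12%, terminators
  16%, introns 50%);
* sparse intergenic transcribed intervals ("planted TARs") disjoint from
  every gene span, promoter and terminator, read at configurable depth;
* a two-condition design (conditions A and B cycled over samples) with
  per-gene log2 fold changes, and a matched microarray probe table whose
  probe values are the true fold change plus Gaussian noise.

Reads are placed entirely within the chosen region interval, so the
entirely-within counting statistic is exactly recoverable; an optional
stress fraction of boundary-straddling reads exercises the (other, na)
path.  A single random stream, seeded once, drives the whole fixture, so
one integer reproduces every output byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    GenomicInterval,
    RegionPartition,
    build_region_partition,
)
from .read_assignment import AlignedRead

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "simulate",
    "simulate_annotation",
    "simulate_reads",
    "simulate_probes",
    "write_bed12",
    "write_bed6",
    "write_reads_bed",
    "SimulationError",
]

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """All knobs of the synthetic experiment, with study-scale defaults."""

    seed: int = 0
    chrom: str = "chr1"
    chrom_length: int = 10_000_000
    n_genes: int = 100
    n_ncrnas: int = 5

    # gene structure: exonic length drawn log-normally, split into exon
    # pieces; intron lengths log-normal
    exonic_length_log_mean: float = math.log(2000.0)
    exonic_length_log_sd: float = 1.2
    exon_piece_log_mean: float = math.log(250.0)
    exon_piece_log_sd: float = 0.6
    intron_length_log_mean: float = math.log(1500.0)
    intron_length_log_sd: float = 1.0
    min_exon_len: int = 60
    min_intron_len: int = 60
    max_exonic_len: int = 30_000
    max_intron_len: int = 20_000
    utr5_fraction: float = 0.10
    utr3_fraction: float = 0.20

    # gene spacing
    promoter_len: int = 1000
    terminator_len: int = 1000
    adjacent_fraction: float = 0.02  # gene pairs closer than one flank length
    adjacent_gap: tuple[int, int] = (200, 999)

    # expression
    expressed_fraction: float = 0.7
    expression_gamma_shape: float = 0.6
    expression_gamma_scale: float = 30.0
    log2fc_sd: float = 1.0

    # reads
    n_samples: int = 3
    n_reads: int = 100_000  # gene-derived reads per sample
    read_length: int = 50
    region_weights: dict = field(
        default_factory=lambda: {
            "exon": 0.55, "intron": 0.33, "promoter": 0.06, "terminator": 0.06,
        }
    )
    antisense_fraction: dict = field(
        default_factory=lambda: {
            "exon": 0.01, "intron": 0.50, "promoter": 0.12, "terminator": 0.16,
        }
    )
    boundary_read_fraction: float = 0.0  # stress: exon/intron junction reads

    # planted intergenic TARs
    n_tars: int = 50
    tar_length_range: tuple[int, int] = (120, 400)
    tar_min_depth: int = 3  # per sample; matches the cluster min-read filter
    tar_depth_mean: float = 10.0  # per sample

    # microarray probes
    probes_per_gene_mean: float = 3.0
    probe_noise_sd: float = 1.0

    def validate(self) -> None:
        for t, f in self.antisense_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise SimulationError(f"antisense_fraction[{t}]={f} outside [0,1]")
        if not 0.0 <= self.expressed_fraction <= 1.0:
            raise SimulationError("expressed_fraction outside [0,1]")
        if self.n_genes < 0 or self.n_reads < 0 or self.n_tars < 0:
            raise SimulationError("counts must be >= 0")
        if self.read_length <= 0:
            raise SimulationError("read_length must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    genes: list[GeneModel] = field(default_factory=list)
    ncrnas: list[GenomicInterval] = field(default_factory=list)
    expression: dict[str, float] = field(default_factory=dict)  # 0 => silent
    log2fc: dict[str, float] = field(default_factory=dict)  # A vs B
    condition_of_sample: dict[str, str] = field(default_factory=dict)
    tars: list[GenomicInterval] = field(default_factory=list)
    tar_depths: dict[str, list[int]] = field(default_factory=dict)  # sample -> per-TAR
    #: per sample: one (category, strand_relation, owner) label per read
    read_labels: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)


@dataclass
class SimResult:
    config: SimConfig
    truth: GroundTruth
    reads_by_sample: dict[str, list[AlignedRead]]
    probes: pd.DataFrame
    partition: RegionPartition


# ---------------------------------------------------------------------------
# annotation


def _draw_gene_structure(cfg: SimConfig, rng: np.random.Generator):
    """Exon/intron length lists for one gene."""
    exonic = int(
        np.clip(rng.lognormal(cfg.exonic_length_log_mean, cfg.exonic_length_log_sd),
                4 * cfg.min_exon_len, cfg.max_exonic_len)
    )
    exon_lens: list[int] = []
    remaining = exonic
    while remaining > 0:
        size = int(
            np.clip(rng.lognormal(cfg.exon_piece_log_mean, cfg.exon_piece_log_sd),
                    cfg.min_exon_len, cfg.max_exonic_len)
        )
        if remaining - size < cfg.min_exon_len:
            size = remaining
        exon_lens.append(size)
        remaining -= size
    intron_lens = [
        int(np.clip(rng.lognormal(cfg.intron_length_log_mean, cfg.intron_length_log_sd),
                    cfg.min_intron_len, cfg.max_intron_len))
        for _ in range(len(exon_lens) - 1)
    ]
    return exon_lens, intron_lens


def _cds_span_from_utrs(
    cfg: SimConfig, exons: list[GenomicInterval], strand: str
) -> GenomicInterval:
    """CDS genomic span leaving utr5/utr3 fractions of exonic bp at the ends."""
    exonic = sum(e.length for e in exons)
    utr5 = int(cfg.utr5_fraction * exonic)
    utr3 = int(cfg.utr3_fraction * exonic)
    if utr5 + utr3 >= exonic - 30:  # keep a real CDS
        utr5 = utr3 = max(0, (exonic - 60) // 4)
    left_trim = utr5 if strand == "+" else utr3
    right_trim = utr3 if strand == "+" else utr5

    def advance(lengths_left: int) -> int:
        """Genomic position after consuming exonic bp from the left."""
        for e in exons:
            if lengths_left < e.length:
                return e.start + lengths_left
            lengths_left -= e.length
        return exons[-1].end

    cds_start = advance(left_trim)
    # consume from the right symmetrically
    rev_left = sum(e.length for e in exons) - right_trim
    cds_end = advance(rev_left)
    chrom = exons[0].chrom
    if cds_end <= cds_start:
        cds_start, cds_end = exons[0].start, exons[-1].end
    return GenomicInterval(chrom, cds_start, cds_end, strand)


def simulate_annotation(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], list[GenomicInterval], GroundTruth]:
    """Simulate the toy genome annotation and per-gene expression truth.

    Gene spans never overlap; consecutive genes are separated by at least
    ``2 * (promoter_len + terminator_len)`` bp of intergenic space except
    for a configurable fraction of deliberately adjacent pairs (gap drawn
    from ``adjacent_gap``) that exercise flank trimming.  ncRNA intervals
    and planted TAR intervals are placed in the remaining intergenic
    space, clear of every gene span, promoter and terminator.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    flank = cfg.promoter_len + cfg.terminator_len
    min_gap, max_gap = 2 * flank, 4 * flank
    truth = GroundTruth()
    cursor = flank + 100
    free_segments: list[tuple[int, int]] = []
    for i in range(cfg.n_genes):
        if i > 0:
            if rng.random() < cfg.adjacent_fraction:
                gap = int(rng.integers(cfg.adjacent_gap[0], cfg.adjacent_gap[1] + 1))
            else:
                gap = int(rng.integers(min_gap, max_gap + 1))
                # the middle of a wide gap is clear of both genes' flanks
                free_segments.append((cursor + flank, cursor + gap - flank))
            cursor += gap
        strand = "+" if rng.random() < 0.5 else "-"
        exon_lens, intron_lens = _draw_gene_structure(cfg, rng)
        exons = []
        pos = cursor
        chrom = cfg.chrom
        for j, el in enumerate(exon_lens):
            exons.append(GenomicInterval(chrom, pos, pos + el, strand))
            pos += el
            if j < len(intron_lens):
                pos += intron_lens[j]
        span = GenomicInterval(chrom, cursor, pos, strand)
        gid = f"G{i:04d}"
        gene = GeneModel(
            gene_id=gid,
            span=span,
            exons=exons,
            cds_span=_cds_span_from_utrs(cfg, exons, strand),
        )
        truth.genes.append(gene)
        cursor = pos
        # expression truth
        expressed = rng.random() < cfg.expressed_fraction
        level = (
            float(rng.gamma(cfg.expression_gamma_shape, cfg.expression_gamma_scale))
            if expressed
            else 0.0
        )
        if expressed and level <= 0:
            level = 1e-3
        truth.expression[gid] = level
        truth.log2fc[gid] = float(rng.normal(0.0, cfg.log2fc_sd))
    required = cursor + flank + 100
    if required > cfg.chrom_length:
        raise SimulationError(
            f"chrom_length={cfg.chrom_length} too small for n_genes={cfg.n_genes}; "
            f"need at least {required} bp"
        )
    free_segments.append((cursor + flank, cfg.chrom_length))

    def place(length: int, margin: int = 100) -> GenomicInterval | None:
        eligible = [
            idx for idx, (s, e) in enumerate(free_segments)
            if e - s >= length + 2 * margin
        ]
        if not eligible:
            return None
        idx = int(eligible[rng.integers(len(eligible))])
        s, e = free_segments[idx]
        start = int(rng.integers(s + margin, e - margin - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(cfg.chrom, start, start + length, strand)
        # split the segment so later placements cannot touch this interval
        free_segments[idx] = (s, start - margin)
        free_segments.append((start + length + margin, e))
        return iv

    for _ in range(cfg.n_ncrnas):
        iv = place(int(rng.integers(200, 2001)))
        if iv is None:
            logger.warning("no intergenic room left for an ncRNA; skipped")
            continue
        truth.ncrnas.append(iv)
    for _ in range(cfg.n_tars):
        iv = place(int(rng.integers(cfg.tar_length_range[0], cfg.tar_length_range[1] + 1)))
        if iv is None:
            logger.warning("no intergenic room left for a planted TAR; skipped")
            continue
        truth.tars.append(iv)
    return truth.genes, truth.ncrnas, truth


# ---------------------------------------------------------------------------
# reads


def _placement_index(
    cfg: SimConfig, genes: Sequence[GeneModel], partition: RegionPartition
) -> dict[str, dict]:
    """Per gene: available region types, weights, and placeable intervals.

    For the ``exon`` type the gene's exon intervals are used directly (a
    read lands within one exon); intron/promoter/terminator use the
    (trimmed) partition intervals owned by the gene.  Flank base pairs
    shared with another gene's promoter or terminator are excluded from
    placement: a read there is contained in two genes' flanks at once, so
    its ground-truth owner — and hence its true strand relation — would be
    ill-defined.  Intervals shorter than the read length are skipped
    (logged per gene); types with no placeable interval are dropped from
    that gene's weights.
    """
    from .annotation import subtract_intervals

    rl = cfg.read_length
    per_gene: dict[str, dict[str, list[GenomicInterval]]] = {
        g.gene_id: {"exon": [e for e in g.exons if e.length >= rl],
                    "intron": [], "promoter": [], "terminator": []}
        for g in genes
    }
    flanks: list[tuple[str, str, GenomicInterval]] = []  # (owner, type, interval)
    for r in partition.regions:
        if r.region_type == "intron":
            if r.interval.length >= rl:
                per_gene[r.owner_gene]["intron"].append(r.interval)
        elif r.region_type in ("promoter", "terminator"):
            flanks.append((r.owner_gene, r.region_type, r.interval))
    for owner, rtype, iv in flanks:
        others = [
            o_iv for o_owner, _, o_iv in flanks
            if o_owner != owner and o_iv.overlaps(iv)
        ]
        for piece in subtract_intervals(iv, others):
            if piece.length >= rl:
                per_gene[owner][rtype].append(piece)
            else:
                logger.debug(
                    "gene %s: %s piece too short after removing shared flank "
                    "bp; skipped", owner, rtype,
                )
    index = {}
    for g in genes:
        entry = {}
        for t, w in cfg.region_weights.items():
            ivs = per_gene[g.gene_id][t]
            if not ivs:
                if w > 0:
                    logger.debug(
                        "gene %s: no placeable %s interval; type skipped",
                        g.gene_id, t,
                    )
                continue
            placeable = np.array([iv.length - rl + 1 for iv in ivs], dtype=float)
            entry[t] = (ivs, np.cumsum(placeable), placeable.sum())
        index[g.gene_id] = {"intervals": entry, "strand": g.strand}
    return index


def simulate_reads(
    cfg: SimConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    partition: RegionPartition | None = None,
) -> dict[str, list[AlignedRead]]:
    """Draw per-sample stranded reads with ground-truth labels.

    Per gene-derived read: a region type is drawn from the configured
    region weights, a gene with a placeable interval of that type is drawn
    proportionally to its condition-specific expression times its exonic
    length in kb (expression is a per-kilobase density, so expected read
    counts grow with gene length at fixed expression — the origin of the
    length bias in fold-change precision), the strand is
    flipped to antisense with the type's configured probability, and the
    read is placed uniformly, entirely within one interval of that type
    (so category frequencies are exactly multinomial in the configured
    weights).  Planted TARs additionally receive ``tar_min_depth +
    Poisson`` reads per sample, uniform within the TAR interval, on the
    TAR strand.  Labels for every read are recorded in
    ``truth.read_labels``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if partition is None:
        partition = build_region_partition(
            truth.genes, cfg.promoter_len, cfg.terminator_len
        )
    index = _placement_index(cfg, truth.genes, partition)
    gene_ids = [g.gene_id for g in truth.genes]
    rl = cfg.read_length
    reads_by_sample: dict[str, list[AlignedRead]] = {}
    for s in range(cfg.n_samples):
        sid = f"s{s + 1}"
        cond = "A" if s % 2 == 0 else "B"
        truth.condition_of_sample[sid] = cond
        sign = 1.0 if cond == "A" else -1.0
        exonic_kb = {g.gene_id: g.exonic_length / 1000.0 for g in truth.genes}
        weights = {
            g: truth.expression[g]
            * exonic_kb[g]
            * 2.0 ** (sign * truth.log2fc[g] / 2.0)
            for g in gene_ids
        }
        # per region type: expressed genes with a placeable interval,
        # weighted by condition-specific expression
        type_names = [t for t, w in cfg.region_weights.items() if w > 0]
        gene_pool: dict[str, tuple[list[str], np.ndarray]] = {}
        for t in type_names:
            eligible = [
                g for g in gene_ids if t in index[g]["intervals"] and weights[g] > 0
            ]
            if not eligible:
                continue
            w = np.array([weights[g] for g in eligible])
            gene_pool[t] = (eligible, np.cumsum(w / w.sum()))
        reads: list[AlignedRead] = []
        labels: list[tuple[str, str, str]] = []
        if gene_pool and cfg.n_reads > 0:
            avail = [t for t in type_names if t in gene_pool]
            tw = np.array([cfg.region_weights[t] for t in avail])
            if len(avail) < len(type_names):
                logger.warning(
                    "no placeable gene for types %s; weights renormalized",
                    sorted(set(type_names) - set(avail)),
                )
            type_draws = rng.choice(len(avail), size=cfg.n_reads, p=tw / tw.sum())
            u_gene = rng.random(cfg.n_reads)
            u_anti = rng.random(cfg.n_reads)
            for i in range(cfg.n_reads):
                t = avail[int(type_draws[i])]
                eligible, cum_w = gene_pool[t]
                g = eligible[int(np.searchsorted(cum_w, u_gene[i], side="right"))]
                entry = index[g]
                ivs, cum, total = entry["intervals"][t]
                off = rng.integers(int(total))
                j = int(np.searchsorted(cum, off, side="right"))
                iv = ivs[j]
                start = iv.start + int(off - (cum[j - 1] if j > 0 else 0))
                anti = u_anti[i] < cfg.antisense_fraction[t]
                strand = entry["strand"]
                if anti:
                    strand = "-" if strand == "+" else "+"
                reads.append(
                    AlignedRead(
                        GenomicInterval(cfg.chrom, start, start + rl, strand), sid
                    )
                )
                labels.append((t, "antisense" if anti else "sense", g))
        # boundary-straddling stress reads
        n_boundary = int(round(cfg.boundary_read_fraction * cfg.n_reads))
        multi = [g for g in truth.genes if len(g.exons) > 1]
        for _ in range(n_boundary if multi else 0):
            g = multi[int(rng.integers(len(multi)))]
            e = g.exons[int(rng.integers(len(g.exons) - 1))]
            start = e.end - rl // 2
            reads.append(
                AlignedRead(GenomicInterval(cfg.chrom, start, start + rl, g.strand), sid)
            )
            labels.append(("boundary", "na", g.gene_id))
        # planted TAR reads
        depths = []
        for ti, tar in enumerate(truth.tars):
            depth = cfg.tar_min_depth + int(
                rng.poisson(max(cfg.tar_depth_mean - cfg.tar_min_depth, 0.0))
            )
            depths.append(depth)
            hi = tar.end - rl
            for _ in range(depth):
                start = int(rng.integers(tar.start, hi + 1))
                reads.append(
                    AlignedRead(
                        GenomicInterval(cfg.chrom, start, start + rl, tar.strand), sid
                    )
                )
                labels.append(("tar", "na", f"TAR{ti:04d}"))
        truth.tar_depths[sid] = depths
        truth.read_labels[sid] = labels
        reads_by_sample[sid] = reads
    return reads_by_sample


# ---------------------------------------------------------------------------
# probes


def simulate_probes(
    cfg: SimConfig, truth: GroundTruth, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Two-color probe table: per gene, k probes of true log2FC + noise."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rows = []
    pid = 0
    for g in truth.genes:
        k = 1 + int(rng.poisson(max(cfg.probes_per_gene_mean - 1.0, 0.0)))
        for _ in range(k):
            m = truth.log2fc[g.gene_id] + float(rng.normal(0.0, cfg.probe_noise_sd))
            rows.append((f"P{pid:06d}", g.gene_id, m))
            pid += 1
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", "log2_ratio"])


def simulate(cfg: SimConfig) -> SimResult:
    """Run the full generator from one seed: annotation, reads, probes."""
    rng = np.random.default_rng(cfg.seed)
    genes, ncrnas, truth = simulate_annotation(cfg, rng)
    partition = build_region_partition(genes, cfg.promoter_len, cfg.terminator_len)
    reads = simulate_reads(cfg, truth, rng, partition)
    probes = simulate_probes(cfg, truth, rng)
    return SimResult(cfg, truth, reads, probes, partition)


# ---------------------------------------------------------------------------
# writers


def write_bed12(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            cds = g.cds_span or g.span
            sizes = ",".join(str(e.length) for e in g.exons) + ","
            starts = ",".join(str(e.start - g.span.start) for e in g.exons) + ","
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.chrom, g.span.start, g.span.end, g.gene_id, 0, g.strand,
                        cds.start, cds.end, 0, len(g.exons), sizes, starts,
                    )
                )
                + "\n"
            )


def write_bed6(
    intervals: Sequence[GenomicInterval],
    path: str | os.PathLike,
    names: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


def write_reads_bed(reads: Sequence[AlignedRead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.sample_id}\t0\t{iv.strand}\n"
            )


def write_truth_json(truth: GroundTruth, path: str | os.PathLike) -> None:
    payload = {
        "expression": truth.expression,
        "log2fc": truth.log2fc,
        "condition_of_sample": truth.condition_of_sample,
        "tars": [
            {"chrom": t.chrom, "start": t.start, "end": t.end, "strand": t.strand}
            for t in truth.tars
        ],
        "tar_depths": truth.tar_depths,
        "n_genes": len(truth.genes),
        "n_ncrnas": len(truth.ncrnas),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
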