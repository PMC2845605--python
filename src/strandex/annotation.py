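"""Gene annotation parsing and strand-aware region partitioning.

A gene annotation (BED12 or GTF) is decomposed into typed genomic regions:
5'UTR, CDS, 3'UTR and intron inside the gene body, plus a promoter (1 kb
immediately upstream of the stranded 5' end) and a terminator (1 kb
immediately downstream of the stranded 3' end).  Promoters and terminators
are trimmed of any base pairs overlapping a neighbouring protein-coding
gene span, possibly splitting them.  The resulting :class:`RegionPartition`
is the substrate for strand-relation read classification and relative tag
density statistics.

Coordinates are 0-based half-open (BED convention) everywhere; GTF input is
converted on read.
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Region",
    "RegionPartition",
    "REGION_TYPES",
    "load_gene_models",
    "derive_introns",
    "build_region_partition",
    "subtract_intervals",
    "AnnotationError",
]

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."

#: Region types of the partition, in classification priority order.
REGION_TYPES = ("cds", "utr5", "utr3", "intron", "promoter", "terminator")

DEFAULT_PROMOTER_LEN = 1000
DEFAULT_TERMINATOR_LEN = 1000


class AnnotationError(ValueError):
    """Malformed annotation record or violated gene-model invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open stranded genomic interval ``[start, end)``.

    Parameters
    ----------
    chrom
        Chromosome name (exact-match semantics; no alias resolution).
    start, end
        0-based half-open coordinates with ``0 <= start < end``.
    strand
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in (PLUS, MINUS, UNSTRANDED):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """Whether *other* lies entirely within this interval (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Whether the intervals share at least one base pair (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A single-transcript gene model.

    ``exons`` must be sorted, non-overlapping, and tile the span together
    with the introns (first exon starts at ``span.start``, last ends at
    ``span.end``).  ``cds_span`` is the genomic extent of the coding
    sequence; genes without one are treated as non-coding for the UTR/CDS
    split (their exons are typed ``cds`` for counting and flagged).
    """

    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval]
    cds_span: GenomicInterval | None = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.span.strand not in (PLUS, MINUS):
            raise AnnotationError(f"gene {self.gene_id}: span must be stranded")
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: no exons")
        exs = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exs, exs[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"gene {self.gene_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        for e in exs:
            if not self.span.contains(e):
                raise AnnotationError(
                    f"gene {self.gene_id}: exon [{e.start},{e.end}) outside "
                    f"span [{self.span.start},{self.span.end})"
                )
        if exs[0].start != self.span.start or exs[-1].end != self.span.end:
            raise AnnotationError(
                f"gene {self.gene_id}: exons do not reach the span boundaries"
            )
        self.exons = exs
        if self.cds_span is not None and not self.span.contains(self.cds_span):
            raise AnnotationError(f"gene {self.gene_id}: CDS outside span")

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass(frozen=True)
class Region:
    """One typed interval of the partition, attributed to its owner gene."""

    interval: GenomicInterval
    region_type: str
    owner_gene: str
    gene_strand: str


@dataclass
class RegionPartition:
    """Typed, gene-attributed region set with per-type total lengths."""

    regions: list[Region]
    total_length: dict[str, int]
    promoter_len: int = DEFAULT_PROMOTER_LEN
    terminator_len: int = DEFAULT_TERMINATOR_LEN
    #: genes that had no annotated CDS (their exons were typed ``cds``)
    noncoding_cds_genes: frozenset[str] = frozenset()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                r.interval.chrom,
                r.interval.start,
                r.interval.end,
                f"{r.region_type}|{r.owner_gene}",
                0,
                r.gene_strand,
            )
            for r in self.regions
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        )

    def write_bed(self, path: str | os.PathLike) -> None:
        """Write the partition as BED6 (name = ``regiontype|gene_id``)."""
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)

    def write_total_lengths(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(
            sorted(self.total_length.items()), columns=["region_type", "total_bp"]
        )
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# parsing


def _parse_bed12_line(line: str, lineno: int) -> GeneModel:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise AnnotationError(f"line {lineno}: expected 12 BED columns, got {len(fields)}")
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        name = fields[3]
        strand = fields[5]
        thick_start, thick_end = int(fields[6]), int(fields[7])
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: {exc}") from exc
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise AnnotationError(f"line {lineno}: blockCount does not match block lists")
    exons = [
        GenomicInterval(chrom, start + off, start + off + size, strand)
        for off, size in zip(starts, sizes)
    ]
    cds = None
    if thick_end > thick_start:
        cds = GenomicInterval(chrom, thick_start, thick_end, strand)
    try:
        return GeneModel(
            gene_id=name,
            span=GenomicInterval(chrom, start, end, strand),
            exons=exons,
            cds_span=cds,
        )
    except AnnotationError as exc:
        raise AnnotationError(f"line {lineno}: {exc}") from exc


def _load_gtf(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="merge",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, dict[str, list]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise AnnotationError(
                f"{path}: {feat.featuretype} feature without gene_id attribute"
            )
        entry = by_gene.setdefault(gid, {"exon": [], "CDS": [], "strand": feat.strand})
        # gffutils keeps GFF 1-based inclusive coords; convert to 0-based half-open
        entry[feat.featuretype].append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        )
    genes = []
    for gid, entry in by_gene.items():
        exons = sorted(entry["exon"], key=lambda e: e.start)
        if not exons:
            raise AnnotationError(f"gene {gid}: GTF record has no exon features")
        span = GenomicInterval(
            exons[0].chrom, exons[0].start, exons[-1].end, entry["strand"]
        )
        cds = None
        if entry["CDS"]:
            cdss = sorted(entry["CDS"], key=lambda c: c.start)
            cds = GenomicInterval(span.chrom, cdss[0].start, cdss[-1].end, span.strand)
        genes.append(GeneModel(gene_id=gid, span=span, exons=exons, cds_span=cds))
    return genes


def load_gene_models(path: str | os.PathLike, dialect: str = "bed12") -> list[GeneModel]:
    """Load one :class:`GeneModel` per gene from a BED12 or GTF file.

    BED12 blocks become exons and the thickStart/thickEnd pair the CDS span;
    GTF exon/CDS features are grouped by ``gene_id`` and 1-based inclusive
    coordinates converted to 0-based half-open.  One transcript per gene is
    assumed.
    """
    if dialect == "bed12":
        genes = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                genes.append(_parse_bed12_line(line, lineno))
        return genes
    if dialect == "gtf":
        return _load_gtf(str(path))
    raise ValueError(f"unknown annotation dialect {dialect!r}")


# ---------------------------------------------------------------------------
# region derivation


def derive_introns(gene: GeneModel) -> list[GenomicInterval]:
    """Gaps between consecutive exons, on the gene's strand.

    Abutting exons (zero gap) yield no intron; single-exon genes yield an
    empty list.
    """
    introns = []
    for a, b in zip(gene.exons, gene.exons[1:]):
        if b.start > a.end:
            introns.append(GenomicInterval(gene.chrom, a.end, b.start, gene.strand))
    return introns


def subtract_intervals(
    interval: GenomicInterval, others: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Remove every base pair of *others* from *interval* (strand-agnostic).

    Returns the surviving pieces in coordinate order; may split the input.
    """
    pieces = [(interval.start, interval.end)]
    for o in others:
        if o.chrom != interval.chrom:
            continue
        nxt = []
        for s, e in pieces:
            if o.end <= s or o.start >= e:
                nxt.append((s, e))
                continue
            if o.start > s:
                nxt.append((s, o.start))
            if o.end < e:
                nxt.append((o.end, e))
        pieces = nxt
        if not pieces:
            break
    return [
        GenomicInterval(interval.chrom, s, e, interval.strand) for s, e in pieces
    ]


def _utr_cds_split(gene: GeneModel) -> list[tuple[GenomicInterval, str]]:
    """Split a gene's exons into (interval, type) pieces: utr5/cds/utr3.

    Exonic base pairs strictly before the CDS span are the 5'-side UTR on
    the plus strand (3'-side on the minus strand) and symmetrically after.
    Genes without a CDS contribute whole exons typed ``cds``.
    """
    if gene.cds_span is None:
        return [(e, "cds") for e in gene.exons]
    cs, ce = gene.cds_span.start, gene.cds_span.end
    upstream_type = "utr5" if gene.strand == PLUS else "utr3"
    downstream_type = "utr3" if gene.strand == PLUS else "utr5"
    out: list[tuple[GenomicInterval, str]] = []
    for e in gene.exons:
        if e.end <= cs:
            out.append((e, upstream_type))
            continue
        if e.start >= ce:
            out.append((e, downstream_type))
            continue
        if e.start < cs:
            out.append(
                (GenomicInterval(e.chrom, e.start, cs, e.strand), upstream_type)
            )
        lo, hi = max(e.start, cs), min(e.end, ce)
        if hi > lo:
            out.append((GenomicInterval(e.chrom, lo, hi, e.strand), "cds"))
        if e.end > ce:
            out.append(
                (GenomicInterval(e.chrom, ce, e.end, e.strand), downstream_type)
            )
    return out


def _flank_intervals(
    gene: GeneModel, promoter_len: int, terminator_len: int
) -> list[tuple[GenomicInterval, str]]:
    """Untrimmed promoter/terminator intervals, clipped at coordinate 0."""
    out = []
    if gene.strand == PLUS:
        pstart, pend = gene.span.start - promoter_len, gene.span.start
        tstart, tend = gene.span.end, gene.span.end + terminator_len
    else:
        pstart, pend = gene.span.end, gene.span.end + promoter_len
        tstart, tend = gene.span.start - terminator_len, gene.span.start
    for (s, e), rtype in (((pstart, pend), "promoter"), ((tstart, tend), "terminator")):
        s = max(s, 0)
        if e > s:
            out.append((GenomicInterval(gene.chrom, s, e, gene.strand), rtype))
    return out


class _SpanIndex:
    """Sorted per-chromosome gene-span lookup for flank trimming."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._by_chrom: dict[str, tuple[list[int], list[GenomicInterval]]] = {}
        for chrom in {g.chrom for g in genes}:
            spans = sorted(
                (g.span for g in genes if g.chrom == chrom), key=lambda s: s.start
            )
            self._by_chrom[chrom] = ([s.start for s in spans], spans)

    def overlapping(self, iv: GenomicInterval) -> list[GenomicInterval]:
        if iv.chrom not in self._by_chrom:
            return []
        starts, spans = self._by_chrom[iv.chrom]
        hits = []
        # spans never overlap each other by more than typical gene scale;
        # scan a window around the query (linear scan is fine at toy scale)
        i = bisect_right(starts, iv.end)
        for s in spans[:i]:
            if s.end > iv.start:
                hits.append(s)
        return hits


def build_region_partition(
    genes: Sequence[GeneModel],
    promoter_len: int = DEFAULT_PROMOTER_LEN,
    terminator_len: int = DEFAULT_TERMINATOR_LEN,
) -> RegionPartition:
    """Construct the typed region partition for a set of gene models.

    Per gene: UTR/CDS pieces from the exon–CDS split, introns from the exon
    complement, a promoter of ``promoter_len`` bp upstream of the stranded
    5' end and a terminator of ``terminator_len`` bp downstream of the 3'
    end.  Flanks are clipped at coordinate 0 and trimmed of any overlap
    with a protein-coding gene span (strand-agnostic; may split the flank).
    Deterministic and order-independent: regions are sorted canonically.
    """
    if promoter_len < 0 or terminator_len < 0:
        raise ValueError("promoter/terminator lengths must be >= 0")
    coding_index = _SpanIndex([g for g in genes if g.biotype == "protein_coding"])
    regions: list[Region] = []
    noncds = set()
    for gene in genes:
        if gene.cds_span is None:
            noncds.add(gene.gene_id)
        for iv, rtype in _utr_cds_split(gene):
            regions.append(Region(iv, rtype, gene.gene_id, gene.strand))
        for iv in derive_introns(gene):
            regions.append(Region(iv, "intron", gene.gene_id, gene.strand))
        for iv, rtype in _flank_intervals(gene, promoter_len, terminator_len):
            for piece in subtract_intervals(iv, coding_index.overlapping(iv)):
                regions.append(Region(piece, rtype, gene.gene_id, gene.strand))
    regions.sort(
        key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end,
                       r.region_type, r.owner_gene)
    )
    totals = {t: 0 for t in REGION_TYPES}
    for r in regions:
        totals[r.region_type] += r.interval.length
    return RegionPartition(
        regions=regions,
        total_length=totals,
        promoter_len=promoter_len,
        terminator_len=terminator_len,
        noncoding_cds_genes=frozenset(noncds),
    )
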