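"""Strand-aware read classification and count tables.

Each aligned read is assigned to exactly one (region type, strand relation)
category.  A read counts toward a region only when it maps *entirely
within* that region's interval; among all regions fully containing the
read the winner is chosen by the fixed priority

    cds > utr5 > utr3 > intron > promoter > terminator,

with cross-gene ties broken by lexicographically smallest gene id.  The
strand relation is *sense* when the read strand equals the owner gene's
strand, *antisense* otherwise.  Reads contained in no region — including
reads straddling an internal region boundary of a gene — fall to
``(other, na)``; no junction-aware rescue is attempted, because the
counting statistic is defined by the strict containment rule.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .annotation import (
    MINUS,
    PLUS,
    GenomicInterval,
    Region,
    RegionPartition,
    REGION_TYPES,
)

__all__ = [
    "AlignedRead",
    "ReadAssignment",
    "RegionIndex",
    "load_reads",
    "classify_read",
    "count_by_region",
    "ReadError",
]

CATEGORIES = REGION_TYPES + ("other",)
STRAND_RELATIONS = ("sense", "antisense", "na")

_PRIORITY = {t: i for i, t in enumerate(REGION_TYPES)}


class ReadError(ValueError):
    """Malformed read record."""


@dataclass(frozen=True)
class AlignedRead:
    """One uniquely mapped stranded read."""

    interval: GenomicInterval
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if self.interval.strand not in (PLUS, MINUS):
            raise ReadError(
                f"read {self.interval.chrom}:{self.interval.start}-"
                f"{self.interval.end} is unstranded; the analysis is "
                "strand-specific"
            )


@dataclass(frozen=True)
class ReadAssignment:
    """Category, strand relation, and owner gene of one classified read."""

    category: str
    strand_relation: str
    owner_gene: str | None = None


def load_reads(path: str | os.PathLike, sample_id: str | None = None) -> list[AlignedRead]:
    """Load aligned reads from a BED6 file.

    The strand column must be ``+`` or ``-``.  The BED name column is used
    as the sample id when present (overridable via *sample_id*).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    if df["strand"].isna().any():
        raise ReadError(f"{path}: missing strand column (BED6 required)")
    reads = []
    for row in df.itertuples(index=False):
        if row.strand not in (PLUS, MINUS):
            raise ReadError(
                f"{path}: unstranded read {row.chrom}:{row.start}-{row.end} "
                f"(strand {row.strand!r})"
            )
        if sample_id is not None:
            sid = sample_id
        elif isinstance(row.name, str) and row.name:
            sid = row.name
        else:
            sid = "sample"
        reads.append(
            AlignedRead(
                GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                sample_id=str(sid),
            )
        )
    return reads


class RegionIndex:
    """Per-chromosome interval index over a :class:`RegionPartition`.

    Built once and reused across reads; classification itself stays a pure
    function of the partition content.
    """

    def __init__(self, partition: RegionPartition):
        self.partition = partition
        self._trees: dict[str, IntervalTree] = {}
        for region in partition.regions:
            iv = region.interval
            tree = self._trees.setdefault(iv.chrom, IntervalTree())
            tree.addi(iv.start, iv.end, region)

    def containing(self, interval: GenomicInterval) -> list[Region]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = tree.overlap(interval.start, interval.end)
        return [
            h.data
            for h in hits
            if h.begin <= interval.start and interval.end <= h.end
        ]


def classify_read(
    read: AlignedRead, partition: RegionPartition | RegionIndex
) -> ReadAssignment:
    """Assign a read to its (category, strand relation, owner gene)."""
    index = partition if isinstance(partition, RegionIndex) else RegionIndex(partition)
    candidates = index.containing(read.interval)
    if not candidates:
        return ReadAssignment("other", "na", None)
    winner = min(candidates, key=lambda r: (_PRIORITY[r.region_type], r.owner_gene))
    relation = "sense" if read.interval.strand == winner.gene_strand else "antisense"
    return ReadAssignment(winner.region_type, relation, winner.owner_gene)


def count_by_region(
    reads: list[AlignedRead],
    partition: RegionPartition | RegionIndex,
    per_sample: bool = False,
) -> pd.DataFrame | dict[str, pd.DataFrame]:
    """Count reads per (region type, strand relation).

    Returns a DataFrame indexed by category (region types plus ``other``)
    with columns ``sense``, ``antisense``, ``na``; the grand total equals
    the number of input reads.  With ``per_sample=True`` returns a dict
    mapping sample id to its table, plus a ``"pooled"`` entry.
    """
    from collections import Counter

    index = partition if isinstance(partition, RegionIndex) else RegionIndex(partition)
    pooled: Counter = Counter()
    by_sample: dict[str, Counter] = {}
    for read in reads:
        a = classify_read(read, index)
        key = (a.category, a.strand_relation)
        pooled[key] += 1
        if per_sample:
            by_sample.setdefault(read.sample_id, Counter())[key] += 1

    def to_frame(counter: Counter) -> pd.DataFrame:
        df = pd.DataFrame(
            0, index=list(CATEGORIES), columns=list(STRAND_RELATIONS), dtype=int
        )
        for (cat, rel), n in counter.items():
            df.loc[cat, rel] = n
        return df

    if per_sample:
        tables = {sid: to_frame(c) for sid, c in sorted(by_sample.items())}
        tables["pooled"] = to_frame(pooled)
        return tables
    return to_frame(pooled)
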