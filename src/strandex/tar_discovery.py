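"""Novel transcriptionally active region (TAR) discovery.

Reads are clustered per chromosome and strand by single-linkage chaining:
a read joins the current cluster when the gap to the cluster end
(``read.start - cluster.end``) is at most ``g`` base pairs (default 15);
overlapping or abutting reads always join.  Clusters supported by fewer
than ``k`` reads (default 3) are discarded.  Per-sample clusters are then
merged across samples wherever same-strand intervals overlap by at least
one base pair, and any merged cluster overlapping an annotated gene span
or non-coding RNA interval (strand-agnostic, >= 1 bp) is removed entirely.
The survivors are the novel TARs.

The alternative order suggested by pooling all samples' reads before
clustering is available via ``mode="pool"`` for sensitivity analysis.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GenomicInterval
from .expression import compute_rpkm
from .read_assignment import AlignedRead

__all__ = [
    "TarCluster",
    "cluster_reads",
    "merge_clusters_across_samples",
    "subtract_annotated",
    "summarize_tars",
    "discover_tars",
    "DEFAULT_MAX_GAP",
    "DEFAULT_MIN_READS",
]

DEFAULT_MAX_GAP = 15
DEFAULT_MIN_READS = 3


@dataclass
class TarCluster:
    """A read cluster: interval, per-sample support, and the (g, k) params."""

    interval: GenomicInterval
    reads_per_sample: dict[str, int]
    max_gap: int = DEFAULT_MAX_GAP
    min_reads: int = DEFAULT_MIN_READS

    @property
    def total_reads(self) -> int:
        return sum(self.reads_per_sample.values())

    @property
    def length(self) -> int:
        return self.interval.length


def cluster_reads(
    reads: Sequence[AlignedRead],
    max_gap: int = DEFAULT_MAX_GAP,
    min_reads: int = DEFAULT_MIN_READS,
    stranded: bool = True,
) -> list[TarCluster]:
    """Single-linkage read clustering per chromosome (and strand).

    Consecutive reads (sorted by start) join one cluster iff the gap
    ``next.start - cluster.end`` is at most *max_gap*; a negative or zero
    gap (overlap or abutment) always joins.  Clusters with fewer than
    *min_reads* reads are discarded.  Output is sorted by coordinate.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    groups: dict[tuple, list[AlignedRead]] = {}
    for r in reads:
        key = (r.interval.chrom, r.interval.strand if stranded else ".")
        groups.setdefault(key, []).append(r)
    clusters: list[TarCluster] = []
    for (chrom, strand), members in groups.items():
        members.sort(key=lambda r: (r.interval.start, r.interval.end))
        cur: list[AlignedRead] = []
        cur_end = -1

        def flush() -> None:
            if len(cur) >= min_reads:
                start = min(r.interval.start for r in cur)
                end = max(r.interval.end for r in cur)
                per_sample: dict[str, int] = {}
                for r in cur:
                    per_sample[r.sample_id] = per_sample.get(r.sample_id, 0) + 1
                clusters.append(
                    TarCluster(
                        GenomicInterval(chrom, start, end, strand),
                        per_sample,
                        max_gap=max_gap,
                        min_reads=min_reads,
                    )
                )

        for r in members:
            if cur and r.interval.start - cur_end > max_gap:
                flush()
                cur = []
                cur_end = -1
            cur.append(r)
            cur_end = max(cur_end, r.interval.end)
        if cur:
            flush()
    clusters.sort(key=lambda c: (c.interval.chrom, c.interval.start,
                                 c.interval.end, c.interval.strand))
    return clusters


def merge_clusters_across_samples(
    cluster_sets: Iterable[Sequence[TarCluster]],
) -> list[TarCluster]:
    """Union same-strand clusters from different samples that overlap >= 1 bp.

    Overlap is transitive: chains A∩B, B∩C merge into one cluster even when
    A and C are disjoint.  Per-sample read counts are preserved and summed.
    All input sets must have been built with identical (g, k) parameters.
    Idempotent: applying the merge to its own output returns it unchanged.
    """
    pool: list[TarCluster] = [c for cs in cluster_sets for c in cs]
    if not pool:
        return []
    params = {(c.max_gap, c.min_reads) for c in pool}
    if len(params) > 1:
        raise ValueError(f"mismatched clustering parameters across sets: {params}")
    max_gap, min_reads = params.pop()
    groups: dict[tuple, list[TarCluster]] = {}
    for c in pool:
        groups.setdefault((c.interval.chrom, c.interval.strand), []).append(c)
    merged: list[TarCluster] = []
    for (chrom, strand), members in groups.items():
        members.sort(key=lambda c: (c.interval.start, c.interval.end))
        cur_start, cur_end = members[0].interval.start, members[0].interval.end
        cur_counts = dict(members[0].reads_per_sample)
        for c in members[1:]:
            if c.interval.start < cur_end:  # >= 1 bp overlap
                cur_end = max(cur_end, c.interval.end)
                for sid, n in c.reads_per_sample.items():
                    cur_counts[sid] = cur_counts.get(sid, 0) + n
            else:
                merged.append(
                    TarCluster(GenomicInterval(chrom, cur_start, cur_end, strand),
                               cur_counts, max_gap, min_reads)
                )
                cur_start, cur_end = c.interval.start, c.interval.end
                cur_counts = dict(c.reads_per_sample)
        merged.append(
            TarCluster(GenomicInterval(chrom, cur_start, cur_end, strand),
                       cur_counts, max_gap, min_reads)
        )
    merged.sort(key=lambda c: (c.interval.chrom, c.interval.start,
                               c.interval.end, c.interval.strand))
    return merged


def subtract_annotated(
    clusters: Sequence[TarCluster],
    gene_spans: Sequence[GenomicInterval],
    ncrna: Sequence[GenomicInterval] = (),
) -> list[TarCluster]:
    """Remove clusters overlapping any gene span or ncRNA interval.

    Overlap of >= 1 bp, strand-agnostic, removes the whole cluster (no
    trimming); the survivors are the novel TARs.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in list(gene_spans) + list(ncrna):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    survivors = []
    for c in clusters:
        tree = trees.get(c.interval.chrom)
        if tree is None or not tree.overlap(c.interval.start, c.interval.end):
            survivors.append(c)
    return survivors


def summarize_tars(
    tars: Sequence[TarCluster],
    m_total: int,
    length_bins: Sequence[int] = (0, 100, 200, 500, 1000, 2000, 5000),
    read_threshold: int = 10,
) -> dict:
    """Length and read-support summary of the novel TARs.

    Reports TAR counts per length bin, counts longer than 500 and 1000 bp,
    the count supported by at least *read_threshold* reads, and per-TAR
    RPKM with the cluster length as the length term and *m_total* as the
    sequencing depth.
    """
    lengths = np.array([t.length for t in tars], dtype=int)
    totals = np.array([t.total_reads for t in tars], dtype=int)
    edges = list(length_bins) + [np.inf]
    hist, _ = np.histogram(lengths, bins=edges)
    table = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "n_tars": hist.astype(int),
        }
    )
    rpkms = [
        compute_rpkm(t.total_reads, t.length, m_total) if m_total > 0 else float("nan")
        for t in tars
    ]
    return {
        "n_tars": len(tars),
        "length_histogram": table,
        "n_longer_500": int((lengths > 500).sum()) if len(tars) else 0,
        "n_longer_1000": int((lengths > 1000).sum()) if len(tars) else 0,
        "n_at_least_reads": int((totals >= read_threshold).sum()) if len(tars) else 0,
        "read_threshold": read_threshold,
        "rpkm": rpkms,
    }


def discover_tars(
    reads_by_sample: Mapping[str, Sequence[AlignedRead]],
    gene_spans: Sequence[GenomicInterval],
    ncrna: Sequence[GenomicInterval] = (),
    max_gap: int = DEFAULT_MAX_GAP,
    min_reads: int = DEFAULT_MIN_READS,
    mode: str = "per_sample",
) -> list[TarCluster]:
    """End-to-end TAR discovery: cluster, merge across samples, subtract.

    ``mode="per_sample"`` clusters each sample separately (the min-read
    filter applies per sample) and merges the resulting clusters;
    ``mode="pool"`` pools all reads before a single clustering pass.
    """
    if mode == "per_sample":
        sets = [
            cluster_reads(reads, max_gap, min_reads)
            for _, reads in sorted(reads_by_sample.items())
        ]
        merged = merge_clusters_across_samples(sets)
    elif mode == "pool":
        pooled = [r for _, reads in sorted(reads_by_sample.items()) for r in reads]
        merged = cluster_reads(pooled, max_gap, min_reads)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return subtract_annotated(merged, gene_spans, ncrna)


def write_tars_bed(tars: Sequence[TarCluster], path: str | os.PathLike) -> None:
    """Write novel TARs as BED6 (name = TAR id, score = total reads)."""
    rows = [
        (t.interval.chrom, t.interval.start, t.interval.end,
         f"TAR{i + 1:05d}", t.total_reads, t.interval.strand)
        for i, t in enumerate(tars)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_params_sidecar(path: str | os.PathLike, **params) -> None:
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True)
        fh.write("\n")
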