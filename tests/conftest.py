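import pytest

from strandex import (
    GeneModel,
    GenomicInterval,
    SimConfig,
    build_region_partition,
    simulate,
)


@pytest.fixture
def two_exon_gene():
    """Plus-strand gene [1000, 1500) with exons [1000,1100) and [1300,1500),
    CDS [1050, 1400)."""
    return GeneModel(
        gene_id="GA",
        span=GenomicInterval("chr1", 1000, 1500, "+"),
        exons=[
            GenomicInterval("chr1", 1000, 1100, "+"),
            GenomicInterval("chr1", 1300, 1500, "+"),
        ],
        cds_span=GenomicInterval("chr1", 1050, 1400, "+"),
    )


@pytest.fixture
def isolated_plus_gene():
    """Single-exon plus-strand gene [5000, 8000), fully coding."""
    return GeneModel(
        gene_id="GP",
        span=GenomicInterval("chr1", 5000, 8000, "+"),
        exons=[GenomicInterval("chr1", 5000, 8000, "+")],
        cds_span=GenomicInterval("chr1", 5000, 8000, "+"),
    )


@pytest.fixture
def isolated_minus_gene():
    return GeneModel(
        gene_id="GM",
        span=GenomicInterval("chr1", 5000, 8000, "-"),
        exons=[GenomicInterval("chr1", 5000, 8000, "-")],
        cds_span=GenomicInterval("chr1", 5000, 8000, "-"),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated experiment, shared across tests."""
    cfg = SimConfig(seed=7, n_genes=40, n_reads=8000, n_tars=25, n_ncrnas=3)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_partition(small_sim):
    return small_sim.partition


def brute_force_classify(read, partition):
    """Independent per-read classifier: scan all regions for containment,
    choose by priority then gene id."""
    priority = {"cds": 0, "utr5": 1, "utr3": 2, "intron": 3,
                "promoter": 4, "terminator": 5}
    best = None
    for region in partition.regions:
        iv = region.interval
        if (
            iv.chrom == read.interval.chrom
            and iv.start <= read.interval.start
            and read.interval.end <= iv.end
        ):
            key = (priority[region.region_type], region.owner_gene)
            if best is None or key < best[0]:
                best = (key, region)
    if best is None:
        return ("other", "na", None)
    region = best[1]
    rel = "sense" if read.interval.strand == region.gene_strand else "antisense"
    return (region.region_type, rel, region.owner_gene)


def brute_force_clusters(reads, max_gap, min_reads):
    """Connected components with an edge iff same chrom+strand and
    gap <= max_gap, then size filtering.  Returns a set of
    (chrom, start, end, strand, n_reads) tuples."""
    n = len(reads)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = reads[i].interval, reads[j].interval
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap <= max_gap:
                union(i, j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(reads[i])
    out = set()
    for members in comps.values():
        if len(members) >= min_reads:
            out.add(
                (
                    members[0].interval.chrom,
                    min(r.interval.start for r in members),
                    max(r.interval.end for r in members),
                    members[0].interval.strand,
                    len(members),
                )
            )
    return out
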