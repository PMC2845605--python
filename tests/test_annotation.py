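import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strandex import (
    AnnotationError,
    GeneModel,
    GenomicInterval,
    build_region_partition,
    derive_introns,
    load_gene_models,
    subtract_intervals,
)


class TestGenomicInterval:
    def test_rejects_empty_and_inverted(self):
        with pytest.raises(AnnotationError):
            GenomicInterval("chr1", 100, 100, "+")
        with pytest.raises(AnnotationError):
            GenomicInterval("chr1", 200, 100, "+")
        with pytest.raises(AnnotationError):
            GenomicInterval("chr1", -5, 100, "+")

    def test_length_containment_overlap(self):
        a = GenomicInterval("chr1", 10, 60, "+")
        b = GenomicInterval("chr1", 20, 40, "-")
        assert a.length == 50
        assert a.contains(b) and not b.contains(a)
        assert a.overlaps(b)
        assert not a.overlaps(GenomicInterval("chr2", 20, 40, "+"))
        assert not a.overlaps(GenomicInterval("chr1", 60, 80, "+"))  # abutting


class TestLoadGeneModels:
    def test_bed12_blocks_become_exons(self, tmp_path):
        line = (
            "chr1\t1000\t1500\tGA\t0\t+\t1000\t1500\t0\t2\t100,200,\t0,300,\n"
        )
        p = tmp_path / "genes.bed"
        p.write_text(line)
        (gene,) = load_gene_models(p, "bed12")
        assert gene.span == GenomicInterval("chr1", 1000, 1500, "+")
        assert gene.exons == [
            GenomicInterval("chr1", 1000, 1100, "+"),
            GenomicInterval("chr1", 1300, 1500, "+"),
        ]
        assert gene.cds_span == GenomicInterval("chr1", 1000, 1500, "+")

    def test_single_exon_gene_is_degenerate(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t400\tG1\t0\t-\t100\t400\t0\t1\t300,\t0,\n")
        (gene,) = load_gene_models(p, "bed12")
        assert derive_introns(gene) == []
        assert gene.exonic_length == gene.span.length == 300

    def test_gtf_one_based_inclusive_converted(self, tmp_path):
        # 1-based inclusive exon 1001..1100 must become [1000, 1100)
        gtf = (
            'chr1\tsrc\texon\t1001\t1100\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
            'chr1\tsrc\tCDS\t1021\t1080\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
        )
        p = tmp_path / "genes.gtf"
        p.write_text(gtf)
        (gene,) = load_gene_models(p, "gtf")
        assert gene.exons == [GenomicInterval("chr1", 1000, 1100, "+")]
        assert gene.cds_span == GenomicInterval("chr1", 1020, 1080, "+")

    def test_malformed_bed_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t400\tG1\t0\t+\n")  # only 6 columns
        with pytest.raises(AnnotationError, match="line 1"):
            load_gene_models(p, "bed12")

    def test_exon_outside_span_rejected(self):
        with pytest.raises(AnnotationError):
            GeneModel(
                "G1",
                span=GenomicInterval("chr1", 100, 200, "+"),
                exons=[GenomicInterval("chr1", 100, 250, "+")],
            )


class TestDeriveIntrons:
    def test_gap_complement(self):
        g = GeneModel(
            "G",
            span=GenomicInterval("chr1", 0, 300, "+"),
            exons=[
                GenomicInterval("chr1", 0, 100, "+"),
                GenomicInterval("chr1", 200, 300, "+"),
            ],
        )
        assert derive_introns(g) == [GenomicInterval("chr1", 100, 200, "+")]

    def test_abutting_exons_yield_no_intron(self):
        g = GeneModel(
            "G",
            span=GenomicInterval("chr1", 0, 250, "+"),
            exons=[
                GenomicInterval("chr1", 0, 100, "+"),
                GenomicInterval("chr1", 100, 150, "+"),
                GenomicInterval("chr1", 200, 250, "+"),
            ],
        )
        assert derive_introns(g) == [GenomicInterval("chr1", 150, 200, "+")]

    def test_overlapping_exons_rejected(self):
        with pytest.raises(AnnotationError, match="overlap"):
            GeneModel(
                "G",
                span=GenomicInterval("chr1", 0, 300, "+"),
                exons=[
                    GenomicInterval("chr1", 0, 120, "+"),
                    GenomicInterval("chr1", 100, 300, "+"),
                ],
            )


class TestSubtractIntervals:
    def test_splits_around_hole(self):
        iv = GenomicInterval("chr1", 0, 100, "+")
        out = subtract_intervals(iv, [GenomicInterval("chr1", 40, 60, "-")])
        assert [(o.start, o.end) for o in out] == [(0, 40), (60, 100)]

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.tuples(st.integers(0, 200), st.integers(1, 50)), max_size=5
        )
    )
    def test_matches_basewise_complement(self, holes):
        iv = GenomicInterval("chr1", 0, 200, "+")
        ivs = [GenomicInterval("chr1", s, s + l, ".") for s, l in holes]
        out = subtract_intervals(iv, ivs)
        covered = set()
        for o in out:
            assert iv.start <= o.start < o.end <= iv.end
            covered |= set(range(o.start, o.end))
        expected = set(range(0, 200))
        for s, l in holes:
            expected -= set(range(s, s + l))
        assert covered == expected


class TestRegionPartition:
    def test_flanks_follow_strand(self, isolated_plus_gene, isolated_minus_gene):
        for gene, prom, term in [
            (isolated_plus_gene, (4000, 5000), (8000, 9000)),
            (isolated_minus_gene, (8000, 9000), (4000, 5000)),
        ]:
            part = build_region_partition([gene], 1000, 1000)
            by_type = {
                r.region_type: (r.interval.start, r.interval.end)
                for r in part.regions
            }
            assert by_type["promoter"] == prom
            assert by_type["terminator"] == term

    def test_neighbor_trims_terminator(self, isolated_plus_gene):
        neighbor = GeneModel(
            "GB",
            span=GenomicInterval("chr1", 8600, 10000, "+"),
            exons=[GenomicInterval("chr1", 8600, 10000, "+")],
            cds_span=GenomicInterval("chr1", 8600, 10000, "+"),
        )
        part = build_region_partition([isolated_plus_gene, neighbor], 1000, 1000)
        terms = [
            (r.interval.start, r.interval.end)
            for r in part.regions
            if r.region_type == "terminator" and r.owner_gene == "GP"
        ]
        assert terms == [(8000, 8600)]

    def test_promoter_clipped_at_chromosome_start(self):
        g = GeneModel(
            "G0",
            span=GenomicInterval("chr1", 300, 900, "+"),
            exons=[GenomicInterval("chr1", 300, 900, "+")],
            cds_span=GenomicInterval("chr1", 300, 900, "+"),
        )
        part = build_region_partition([g], 1000, 1000)
        (prom,) = [r for r in part.regions if r.region_type == "promoter"]
        assert (prom.interval.start, prom.interval.end) == (0, 300)

    def test_utr_cds_split_is_strand_aware(self, two_exon_gene):
        part = build_region_partition([two_exon_gene])
        pieces = {
            (r.region_type, r.interval.start, r.interval.end)
            for r in part.regions
            if r.region_type in ("utr5", "cds", "utr3")
        }
        assert pieces == {
            ("utr5", 1000, 1050),
            ("cds", 1050, 1100),
            ("cds", 1300, 1400),
            ("utr3", 1400, 1500),
        }

    def test_gene_without_cds_typed_cds_and_flagged(self):
        g = GeneModel(
            "GN",
            span=GenomicInterval("chr1", 100, 400, "+"),
            exons=[GenomicInterval("chr1", 100, 400, "+")],
        )
        part = build_region_partition([g])
        assert "GN" in part.noncoding_cds_genes
        types = {r.region_type for r in part.regions if r.owner_gene == "GN"}
        assert "cds" in types and "utr5" not in types

    def test_total_lengths_sum_regions(self, small_partition):
        for t, total in small_partition.total_length.items():
            assert total == sum(
                r.interval.length
                for r in small_partition.regions
                if r.region_type == t
            )

    def test_partition_completeness_per_gene(self, small_sim):
        """utr5+cds+utr3+intron intervals of each gene tile its span."""
        part = small_sim.partition
        body = {}
        for r in part.regions:
            if r.region_type in ("utr5", "cds", "utr3", "intron"):
                body.setdefault(r.owner_gene, []).append(r.interval)
        for gene in small_sim.truth.genes:
            ivs = sorted(body[gene.gene_id], key=lambda i: i.start)
            assert ivs[0].start == gene.span.start
            assert ivs[-1].end == gene.span.end
            for a, b in zip(ivs, ivs[1:]):
                assert a.end == b.start  # no gap, no overlap
            assert sum(i.length for i in ivs) == gene.span.length

    def test_flanks_never_overlap_gene_spans(self, small_sim):
        part = small_sim.partition
        spans = [g.span for g in small_sim.truth.genes]
        for r in part.regions:
            if r.region_type in ("promoter", "terminator"):
                assert r.interval.length <= 1000
                for span in spans:
                    assert not r.interval.overlaps(span)

    def test_order_independent(self, small_sim):
        genes = small_sim.truth.genes
        base = build_region_partition(genes)
        for perm in (genes[::-1], genes[1:] + genes[:1]):
            other = build_region_partition(perm)
            assert other.regions == base.regions
            assert other.total_length == base.total_length

    def test_empty_gene_list(self):
        part = build_region_partition([])
        assert part.regions == []
        assert all(v == 0 for v in part.total_length.values())
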