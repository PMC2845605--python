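# Methods

This note documents the models and procedures implemented in `strandex`,
the conventions and numerical choices behind them, what the synthetic
generator does and does not emulate, and the known limitations.

## Coordinates and gene models

All interval arithmetic is 0-based half-open (BED convention); GTF input
(1-based inclusive) is converted on read. One gene model per gene is
assumed — the package does not collapse isoforms; upstream annotation
preparation must pick one transcript per gene. Exons must tile the gene
span together with the introns (no gaps at the span boundaries); this is
validated at load time. Chromosome names are matched exactly.

## Region partition

Per gene: exonic base pairs strictly 5′ of the CDS span are 5′UTR
(strand-aware), strictly 3′ are 3′UTR, the rest CDS; introns are the
gaps between consecutive exons. Genes without an annotated CDS have
their exons typed `cds` for counting and are flagged
(`RegionPartition.noncoding_cds_genes`) — the UTR/CDS split presumes a
coding gene, and no convention exists for non-coding models.

Promoters and terminators default to 1000 bp immediately upstream of the
stranded 5′ end and downstream of the 3′ end. They are clipped at
coordinate 0 and trimmed of any overlap with a *protein-coding gene
span* (not just its exons), strand-agnostically, possibly splitting the
flank. Span-level, strand-agnostic trimming is the conservative choice:
a flank base pair inside any neighbouring gene body cannot be attributed
to intergenic flanking transcription. No right-boundary clipping is
applied because chromosome lengths are not required as input.

## Read classification

The counting rule is strict containment: a read contributes to a region
type only when it maps entirely within a single interval of that type.
Reads that straddle an internal boundary (e.g. an exon/intron junction)
are counted as `(other, na)` — no junction-aware rescue is attempted,
because rescuing would change the statistic being computed. When several
regions fully contain a read, the priority cds > utr5 > utr3 > intron >
promoter > terminator decides, with cross-gene ties broken by
lexicographically smallest gene id; the tie-break exists purely for
determinism and fires only on overlapping annotations. Spliced
alignments are out of scope: input intervals are treated as contiguous,
appropriate for short ungapped alignments.

Two normalisations are reported per region type t and strand relation s:

- relative tag density D(t,s) = N(t,s) / (L(t)·M(s)), where M(s) counts
  the strand-s reads assigned to annotated region types, *excluding*
  `other`. Including `other` would make D depend on how much intergenic
  signal a sample happens to carry; excluding it keeps D a
  within-annotation density. A normalised-to-maximum column is also
  written, since the absolute scale of D is arbitrary.
- antisense fraction r(t) = N(t,antisense) / (N(t,sense)+N(t,antisense)),
  reported as NA when the denominator is zero. r is invariant under
  global depth scaling.

## Expression

RPKM uses the gene's *exonic* length (not the span) and the sample's
total read count on both strands as the depth term. The per-gene count C
is the number of reads entirely within any exon on the gene's strand;
intronic and antisense reads are excluded from C (both choices are
configurable at the counting layer by calling `gene_read_counts`
directly). "Expressed" means C ≥ θ with θ = 1 by default; θ is exposed
because any fixed threshold is arbitrary at varying depth. In
cross-sample Spearman correlations of log10 RPKM, genes with zero RPKM
in either sample of a pair are dropped (with a logged count) rather than
pseudocounted: a rank statistic gains nothing from an arbitrary offset,
and zeros would otherwise form a large tied mass.

## Novel TAR discovery

Per sample, reads are clustered by single-linkage chaining per
chromosome and strand: a read joins the open cluster iff
`read.start − cluster.end ≤ g` (g = 15 bp), so overlap and abutment
always join and reads exactly g apart join — merge tools differ by ±1
on this boundary, so the convention is stated explicitly. Clusters with
fewer than k = 3 reads are discarded *per sample, before merging*.
Per-sample clusters are then merged across samples wherever same-strand
intervals overlap by ≥ 1 bp (transitively), summing per-sample read
support. Finally, any cluster overlapping an annotated gene span or
ncRNA interval by ≥ 1 bp — strand-agnostic — is removed whole: the
subtraction names clusters, not base pairs, and antisense transcription
over gene bodies is the density module's subject, not a novel TAR.

The alternative order — pool all samples' reads, then cluster once — is
available via `mode="pool"` for sensitivity analysis; the per-sample
order is the default. Pooling can only grow or chain clusters, so
pooled-mode clusters contain every per-sample cluster, but a grown
cluster may newly touch a gene and be subtracted.

Clustering is strand-aware by default because the library is
strand-specific; unstranded clustering is available via a flag.

## Cross-platform comparison

RNA-seq fold change f = log2(rpkm_A/rpkm_B) is defined only for genes
with nonzero RPKM in both conditions; excluded genes are excluded from
all three probe-aggregation methods identically, keeping n equal across
methods. Probe aggregation: mean, median, or best probe — the probe
minimising |m − f|, ties toward the smaller value. The best-probe rule
uses the RNA-seq value as its own reference and therefore inflates the
correlation by construction; every report carries this warning.

Gene length for binning is the exonic length, consistent with the RPKM
length term. Bins are (lo, lo+2000] with an open-ended top bin; bins
with fewer than 10 genes report NA. Headline subsets are genes < 2 kb
and > 10 kb. The mechanism for the length trend is sampling noise: at
fixed expression, expected counts scale with length, so Var(f) shrinks
roughly as 1/length while probe noise is length-independent.

## Synthetic data generator

The generator emulates the *structure* of a stranded short-read
transcriptome experiment, with full ground truth:

- **Annotation**: genes placed left to right on one toy chromosome,
  spans separated by 2–4× the combined flank length so promoters and
  terminators rarely trim, plus a small fraction (default 2%, roughly
  the rarity of sub-kilobase gene spacing in mammalian genomes) of
  deliberately adjacent pairs (gap 200–999 bp) that exercise flank
  trimming and splitting. Exonic length per gene is log-normal
  (median 2 kb, log-sd 1.2 — wide enough to populate both the <2 kb and
  >10 kb headline bins), split into ~250 bp exons; introns are
  log-normal around 1.5 kb.
- **Expression**: 70% of genes expressed; per-gene level ~
  Gamma(0.6, 30) (heavy-tailed, as transcriptomes are); per-gene log2
  fold change ~ Normal(0, 1) between two conditions, samples cycling
  A, B, A, … (three samples by default: two biological replicates of A
  plus one contrast).
- **Reads** (50 bp, 100 000 per sample by default): region type drawn
  from fixed weights (exon .55, intron .33, promoter .06,
  terminator .06), gene drawn ∝ expression × exonic kb, strand flipped
  to antisense with per-type probability (defaults: exon 0.01, promoter
  0.12, terminator 0.16, intron 0.50), position uniform entirely within
  one interval of the type. Two placement restrictions keep ground
  truth well-defined: reads never straddle region boundaries (a
  separate stress flag emits junction reads to exercise the `other`
  path), and flank reads are never placed on base pairs shared by two
  genes' flanks, where the true owner — and hence the true strand
  relation — would be ambiguous.
- **Planted TARs**: intergenic intervals (120–400 bp) disjoint from all
  gene spans, promoters, terminators and ncRNAs, each read in every
  sample at depth ≥ the cluster minimum (3 + Poisson, mean 10).
- **Probes**: per gene, 1 + Poisson(2) probes; probe value = true log2
  fold change + Normal(0, 1). The 1.0 log2-unit noise is comparable to
  the fold-change spread, as is typical of two-color ratio data.

One `numpy` Generator seeded once drives the whole fixture, so a single
integer reproduces every output byte-for-byte.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: sequence content and
alignment artefacts (mappability, duplicates, errors), spliced reads,
isoform structure, overlapping gene models, fragment-length selection,
expression correlation between neighbouring genes, and probe-specific
microarray biases (GC, cross-hybridisation). Recovery results here show
the *pipeline* is correct under its own model, not that the statistics
are unbiased on real libraries.

## Numerical and testing choices

Degenerate inputs: zero-length intervals are rejected at construction;
empty gene lists yield empty partitions; region types with zero total
length are omitted from density tables with a warning; Spearman on a
zero-variance vector is NA. Determinism everywhere: partitions and
cluster lists are canonically sorted, so results are independent of
input order.

Test problem sizes are chosen to make binomial error bands narrow at
desk scale: antisense-fraction recovery uses one 100k-read sample
(each estimate within 3 binomial SD of its configured truth); TAR
recovery plants 200 TARs; the length-bias property averages 20
replicates of a 300-gene, 30k-read, two-condition experiment. The
acceptance script runs the 3×100k default experiment plus one
length-bias replicate and reports all headline quantities as computed.

## Known limitations

- One transcript per gene; no isoform-aware UTR/CDS typing.
- Ungapped reads only; junction reads are deliberately uncounted.
- The expressed-gene threshold is depth-dependent; no model-based
  present/absent call is attempted.
- TAR boundaries are read-cluster extents; no coverage-profile
  segmentation or boundary refinement.
- The best-probe aggregation is reported for completeness but is
  circular by definition; mean/median are the honest comparisons.
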