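# strandex

Downstream analysis of strand-specific short-read RNA-seq, focused on two
questions that only stranded libraries can answer: **how much antisense
transcription does each class of genomic region carry**, and **what is
transcribed outside the annotated gene set**. The package also quantifies
gene expression (RPKM), compares RNA-seq fold changes against two-color
microarray probes, and ships a fully ground-truthed synthetic-data
generator so every stage is testable without any external download.

It is written for genomicists analysing stranded read alignments (BED)
against a gene annotation (BED12 or GTF), either through the Python API
or the `strandex` command line.

## What it computes

**Region partition.** Each gene model is decomposed into 5′UTR, CDS,
3′UTR and intron intervals, plus a promoter (1 kb upstream of the
stranded 5′ end) and a terminator (1 kb downstream of the 3′ end).
Flanks are trimmed of any base pairs overlapping a neighbouring
protein-coding gene span.

**Read classification.** A read counts toward a region type *t* only if
it maps entirely within one of its intervals; among containing regions
the priority is cds > utr5 > utr3 > intron > promoter > terminator, and
the strand relation is *sense* when the read strand matches the owner
gene. Reads contained in no region (including boundary-straddling reads)
are `other`. From the counts N(t, s):

- relative tag density  D(t, s) = N(t, s) / (L(t) · M(s)), with L(t) the
  summed length of type-t regions and M(s) the total strand-s reads
  assigned to the annotation;
- antisense fraction  r(t) = N(t, antisense) / (N(t, sense) + N(t, antisense)).

**Expression.** RPKM = C / ((L_g/1000) · (M/10⁶)) with C the sense
exonic read count, L_g the exonic length and M the sample depth;
expressed-gene sets (C ≥ θ, default 1) and their cross-sample overlap;
Spearman correlation of log10 RPKM between samples.

**Novel TARs.** Reads are clustered per chromosome and strand
(single-linkage, gap ≤ 15 bp, ≥ 3 reads per cluster), clusters are
merged across samples where they overlap on the same strand, and any
cluster touching an annotated gene span or ncRNA is removed. Survivors
are novel transcriptionally active regions, summarised by length and
read support.

**Array comparison.** Per-gene RNA-seq log2 fold change
f = log2(rpkm_A/rpkm_B) against microarray probe log2 ratios aggregated
per gene by mean, median, or best probe (closest to f — note this last
rule inflates correlation by construction); Spearman ρ overall and in
2000-bp gene-length bins. Because read counts grow with gene length at
fixed expression, f is more precise for long genes and ρ rises with
length.

## Worked example

Everything below runs offline from one seed:

```python
import strandex as sx

cfg = sx.SimConfig(seed=11, n_genes=40, n_reads=20000, n_tars=20)
res = sx.simulate(cfg)

reads = [r for rs in res.reads_by_sample.values() for r in rs]
counts = sx.count_by_region(reads, res.partition)
dens = sx.density_table(counts, res.partition)
print(dens[["N_sense", "N_antisense", "r_antisense"]].round(4))

tars = sx.discover_tars(res.reads_by_sample,
                        [g.span for g in res.truth.genes],
                        res.truth.ncrnas)
rec = sum(any(p.overlaps(t.interval) for t in tars) for p in res.truth.tars)
print("novel TARs:", len(tars), "planted recovered:", rec, "/", len(res.truth.tars))
```

prints

```
             N_sense  N_antisense  r_antisense
region_type
cds            22398          220       0.0097
utr5            2922           26       0.0088
utr3            6444           82       0.0126
intron          9944         9884       0.4985
promoter        3166          443       0.1227
terminator      3029          538       0.1508
novel TARs: 92 planted recovered: 20 / 20
```

The generator was configured with antisense fractions of 1% in exons,
12% in promoters, 16% in terminators and 50% in introns; the recovered
`r_antisense` column reads those fractions back from the classified
counts (exonic types ~1%, promoter 12.3%, terminator 15.1%, intron
49.9%). All 20 planted intergenic transcribed regions come back as
novel TARs; the additional TARs are clusters of promoter/terminator
reads, which lie outside gene spans and therefore survive subtraction.

The same analyses are available as subcommands —
`strandex simulate | partition | classify | express | tars |
compare-array | all` — each writing TSV/BED/JSON outputs plus a
`run_metadata.json` echoing every parameter.

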