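# backsplice

Discovery of circular RNAs (circRNAs) from the unmapped reads of RNA-seq
alignments, with candidate filtering, gene-model annotation, and cohort-level
statistics.

## The problem

CircRNAs are covalently closed transcripts formed when a downstream splice
donor joins back to an upstream splice acceptor (a *back-splice*, or
head-to-tail junction). The junction sequence does not exist in the linear
genome, so reads that span it fail ordinary alignment and end up in the
unmapped fraction of a BAM file — which is exactly where this package looks
for them.

For each unmapped read, `backsplice`:

1. splits the read into terminal 20-mer **anchors** and realigns both anchors
   exactly against the reference genome (k-mer index, both strands);
2. keeps anchor pairs that map in reversed ("3′ to 5′") genomic order — the
   signature of a back-splice — with uniquely-mapping anchors and an implied
   span ≤ 100 kb;
3. extends both anchors toward the read interior to the exact breakpoint,
   requiring a zero-mismatch full-read match and the canonical splice
   dinucleotides: `AG` immediately upstream of the circle start and `GT`
   immediately downstream of the circle end (`AC`/`CT` in plus-strand genome
   letters for minus-strand circles);
4. quantifies supporting reads per junction, then applies three filters —
   **expression** (≥ 5 junction-spanning reads by default), **genomic size**
   (head-to-tail inclusive span ≥ 6 bases), and **uniqueness** (the 50-base
   flank at each junction boundary must occur at exactly one genomic
   location);
5. annotates each surviving circle against gene models (*intra-gene* /
   *inter-gene* / *unannotated*; junction ends on exact exon boundaries,
   strictly within exons, or *other*) and writes a TSV report plus a FASTA of
   50-base fused-junction sequences centered on the fusion point.

Cohort utilities count **unique** circRNAs (a coordinate counted once across
samples), compute per-sample ratios and ≥10 %-of-samples recurrence, call
**tumor-specific** circles under an interval-containment rule, normalize
counts per million unmapped reads, score samples with an 11-gene
proliferation panel (BIRC5, CCNB1, CDC20, CEP55, MKI67, NDC80, NUF2, PTTG1,
RRM2, TYMS, UBE2C; mean z-score across the cohort), and run Pearson
correlation plus paired/Welch t tests.

A deterministic simulator generates genomes with planted circRNAs, junction
reads, gene models, and cohorts with a configurable count–proliferation
correlation, so the entire workflow is testable without any downloads.

## Worked example

```
backsplice simulate --out fx --seed 7 --linear-reads 200
# fixture with 10 circle(s) and 351 read(s) written to fx

backsplice detect fx/reads.sam --genome fx/genome.fa --gtf fx/genes.gtf --out out
# processed 1 sample(s) into out

head -4 out/reads.circs.tsv
# chrom  start  end    strand  n_supporting_reads  genomic_size  gene_class  gene_names  boundary_class
# chr1   4220   7113   -       17                  2894          intra_gene  GENE004A    exon_exon_boundary
# chr1   18448  19777  -       10                  1330          unannotated             other
# chr1   22788  26402  -       12                  3615          intra_gene  GENE000A    exon_exon_boundary
```

Each row is one detected circRNA: its 1-based inclusive genomic interval and
strand, the number of distinct reads spanning its back-splice junction, its
head-to-tail genomic span, and its gene/exon context. The rows match the
planted truth table `fx/truth.tsv` exactly, including support counts.
`out/reads.junctions.fa` holds the 50-base fused-junction sequence of each
circle (fusion between bases 25 and 26), and `out/run_config.json` records
the exact parameters for reproducibility.

Cohort analysis consumes per-sample reports plus a label TSV
(`sample_id  group  pair_id`) and an optional genes × samples expression
TSV:

```
backsplice cohort out/*.circs.tsv --labels labels.tsv --expression expr.tsv --out cohout
```

writing a per-group summary (totals, unique counts, ratios, recurrence,
tumor-specific counts), a tumor-specific coordinate list, and a
`statistics.json` with the paired/Welch tests and the proliferation
correlation.

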