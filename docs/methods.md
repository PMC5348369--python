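# Methods

## Detection model

A back-splice read is modeled as the concatenation of two genomic segments
from the same chromosome and strand: a suffix of the circle ending at its 3′
(donor-side) boundary `e`, followed by a prefix starting at its 5′
(acceptor-side) boundary `s`, with `s < e` in genomic coordinates. Intervals
are 1-based and inclusive throughout; conversion to 0-based half-open happens
only at SAM and string-slicing boundaries.

Detection proceeds read by read over the unmapped fraction of an alignment
file:

1. **Anchors.** The first and last `anchor_len` bases (default 20) of the
   read are realigned exactly (0 mismatches) against both strands of the
   genome via a precomputed k-mer index. k-mers containing `N` are not
   indexed and anchors containing `N` never align, so `N` matches nothing.
   Reads shorter than `2 × anchor_len` are skipped and counted.
2. **Seeding.** A read seeds a candidate only if both anchors map uniquely
   (exactly one hit each), to the same chromosome and strand, in reversed
   genomic order (read-5′ anchor strictly downstream of the read-3′ anchor on
   `+`, mirrored on `-`), with an implied span ≤ `max_span` (default
   100,000 bases — large circles with genomic spans in the tens of kb are
   real, so the cap is generous but bounds the search). Collinear pairs are
   linear-transcript evidence and are rejected.
3. **Breakpoint refinement.** Breakpoint offsets `b` (read coordinates,
   `anchor_len ≤ b ≤ read_len − anchor_len`) are scanned in increasing
   order; an offset qualifies if the first `b` read bases match the genome
   ending at `e`, the rest match starting at `s`, with zero mismatches
   across the full read, and the splice signals hold: `AG` at `s−2..s−1` and
   `GT` at `e+1..e+2` on `+` (equivalently `AC`/`CT` in plus-strand letters
   on `-`, i.e. the reverse complement of the transcribed-strand AG/GT).
   The smallest qualifying `b` wins; this tie-break matters only for
   junctions with a micro-homology of ≥ 4 bases carrying a spurious `GTAG`
   copy, where any fixed convention is equally defensible. A minus-strand
   read is handled by reverse-complementing it, which turns it into a
   plus-strand back-splice read over the same interval with anchor roles
   swapped. Candidates without a signal-consistent breakpoint are dropped
   before quantification, so every reported candidate has canonical signals.
4. **Quantification.** Candidates are merged on (chrom, start, end, strand)
   and support is the number of distinct read identifiers, so a fragment
   whose two mates both span the junction counts once. Mates are otherwise
   processed as independent reads.

Exact matching everywhere (anchors and extension) is a deliberate choice:
it makes desk-scale results deterministic and lets every step be verified
against brute-force oracles (full scans, exhaustive breakpoint
enumeration). The cost is sensitivity on error-containing reads, which a
production aligner-backed variant would recover.

## Filters

* **Expression**: support ≥ `min_reads`, default 5.
* **Genomic size**: inclusive span `end − start + 1` ≥ `min_size`, default 6.
  The inclusive convention matches the 1-based inclusive coordinates; with an
  exclusive distance the two interpretations differ only for 5–6-base spans.
* **Uniqueness**: the head flank (`flank_len` bases from `start`, default 50)
  and tail flank (ending at `end`), truncated at chromosome edges, must each
  occur exactly once genome-wide, counting exact matches on both strands.
  Flank length 50 exceeds the anchor length and matches the junction-FASTA
  scale. An `external_blat` mode shells out to BLAT for near-match
  sensitivity on real genomes; the default internal mode keeps the package
  dependency-free and exactly testable against a naive substring scan.

Each filter is a per-candidate predicate, so the three filters commute and
may be applied in any order.

## Annotation

Gene context collects genes whose span overlaps the circle start plus genes
overlapping the end: one gene containing both ends → `intra_gene`; two or
more genes → `inter_gene`; no genic hit → `unannotated`. A junction with
exactly one genic end is left `unannotated` (and logged) rather than forced
into a genic class. Boundary status is exact-coordinate: start equals an
annotated exon start **and** end equals an exon end (possibly different
exons) → `exon_exon_boundary`; both ends strictly inside exons →
`within_exon`; anything else → `other` (the two named categories do not
cover intronic/intergenic ends, so an explicit remainder class is needed).
Overlap is strand-agnostic because unstranded library preparations do not
reveal the transcribed strand of a junction. Gene-level spans are used; no
transcript-isoform resolution is attempted.

## Outputs

The report TSV carries chrom, start, end, strand, supporting reads, genomic
size, and both annotation classes; it round-trips through `read_report`.
The junction FASTA gives each circle a `total_len`-base sequence (default
50) split symmetrically: the last 25 circle bases then the first 25, so the
fusion sits between positions 25 and 26 — a symmetric split centers the
junction for downstream probe/primer design. Circles smaller than 25 bases
contribute `min(span, 25)` bases per side with no wrap-around (wrap-around
would duplicate sequence; the truncation is logged). Minus-strand sequences
are reverse-complemented into transcript orientation.

## Cohort analyses

* **Unique counting** deduplicates (chrom, start, end) across samples;
  strand is ignored in cross-sample identity. Ratios to sample counts are
  reported unrounded.
* **Recurrence** keeps coordinates with `count / n_samples ≥ fraction`
  (inclusive at the boundary), default fraction 0.10.
* **Tumor-specific calling**: a tumor circle identical to or fully contained
  within a normal circle on the same chromosome is *common* (circles from
  the same genomic region are assumed functionally related); all others are
  tumor-specific. Containment (not mere overlap) is the minimal reading of
  "smaller circles within the same region" and is brute-force verifiable.
  The implementation sorts normal intervals by start and uses a prefix
  maximum of ends, O((n+m) log m), and is tested against the O(n·m) scan.
* **Normalization** is circles per million unmapped reads; the scale
  constant is configurable.
* **Proliferation score**: mean across the 11 panel genes of the per-gene
  z-score (centered/scaled across cohort samples, population SD;
  zero-variance genes contribute 0 with a warning). This is a deliberately
  simple scalar proxy for published risk-of-relapse proliferation summaries
  whose gene coefficients are not reproduced here; it preserves the
  structure of the analysis (one proliferation scalar per sample).
* **Tests**: paired t on per-pair differences (identical vectors → (0, 1);
  constant nonzero differences are degenerate and raise) and Welch t for
  unpaired groups, both two-sided via scipy.

## Synthetic data

The generator emulates the detection substrate, not transcriptome realism:

* **Genome**: i.i.d. bases at a requested GC (default 0.41, human-like),
  deterministic under seed.
* **Planted circles**: default study conditions are 10 circles on a
  2 × 100 kb genome, spans 60–5,000 bases, 5–20 supporting reads each,
  equal strand mix. Splice dinucleotides are written at the boundaries, and
  the bases at `start` and `end` are chosen so the junction cannot slide
  (the base at `start` never equals the base just past `end`, and vice
  versa), making planted-recovery exact. All junction flanks are verified
  unique genome-wide; a deliberate duplication of one circle's head flank
  can be requested to exercise the uniqueness filter. Each circle gets a
  gene-model context cycling through the four annotation categories so
  annotation is checked end to end.
* **Reads**: 50-nt, error-free by default (an error-rate option exists but
  the exact-match core is the tested configuration). The fusion offset is
  uniform over interior positions ≥ 20 bases from both ends so both anchors
  always map. Linear decoy reads are plain genomic substrings (half reverse-
  complemented) that detection must reject. Note that with 50-nt reads this
  geometry requires a circle's span to exceed the read length; smaller
  circles would produce multi-wrap reads, which are out of scope.
* **Cohorts**: per-sample proliferation scores are standard-normal draws,
  empirically standardized; the 11-gene expression matrix is a positive
  linear transform of the score per gene, so the mean z-score reproduces the
  drawn scores exactly. Counts are `round(mean_g + b·score + ε)` with
  `b = r·σ` and residual SD `σ·√(1−r²)`, giving the target within-group
  Pearson correlation (default −0.22). Group means default to 18 (tumor)
  and 25 (normal-adjacent) circles with σ = 8, and unmapped library sizes
  are drawn from 5–22 million reads — values chosen to resemble reported
  breast-tissue cohorts. Rounding and clipping at zero perturb the realized
  correlation slightly; the acceptance band (±0.10 at n = 500) absorbs
  this. What passing these tests does **not** show: robustness to
  sequencing errors, expression-level structure, isoforms, GC bias, or
  repeat-rich real genomes.

## Problem sizes and calibration

Test and acceptance runs use the fixture sizes above (hundreds of reads on
200 kb genomes; 1,000-replicate null calibration of the paired t at 10
pairs; power checks at 30 pairs where the design effect of 7 circles against
a paired-difference SD of ≈ 11.3 gives > 90 % theoretical power). These
sizes keep every oracle (full substring scans, exhaustive breakpoint
enumeration, O(n·m) containment) affordable while leaving the statistics
with comfortable margins.

## Known limitations

* Exact-match detection cannot recover junctions from reads with sequencing
  errors or SNVs; anchors in repeats multi-map and are discarded rather than
  rescued.
* Circles spanning less than a read length are undetectable by this read
  geometry (multi-wrap reads are not modeled).
* Inter-chromosomal (fusion) junctions, linear splice discovery, and
  isoform-aware exon numbering are out of scope.
* The internal uniqueness filter is exact-match; truly repetitive genomes
  need the BLAT mode.
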