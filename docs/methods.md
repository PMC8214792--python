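# Methods

This note documents the models, conventions and numerical choices behind
riboflow, and what the synthetic-data generators do and do not emulate.

## Coordinate model

All internal coordinates are 0-based half-open; GTF/GFF3 input (1-based
inclusive) is converted once at the I/O boundary. Transcript coordinates run
5'→3' along the mature transcript. On the '−' strand, exon blocks are stored
in decreasing genomic order so block order always equals transcript order,
and a read's `pos5` is the genomic coordinate of its biological 5' end (the
larger coordinate; a length-L read occupies [pos5−L+1, pos5]). Spliced
alignments and alignments with indels are reduced to (5' end, aligned
length): every algorithm downstream anchors on 5' ends, and soft-clipped
bases are excluded so the anchor is the aligned 5' terminus.

Consequence: P-site shifting (`shift_to_psites`) moves the 5' end by the
per-length offset **genomically** ('+': pos5+o, '−': pos5−o). For footprints
whose 5'-to-P-site span crosses an exon junction this is approximate — the
true P-site is o *transcript* nucleotides downstream. The affected fraction
is small (reads within o nt upstream of a junction) and shows up as a slight
frame-0 dilution on heavily spliced transcripts. The calibration tests
therefore use unspliced transcripts, so they measure offset recovery rather
than this known approximation; coordinate-mapping tests use multi-exon
transcripts throughout.

## Read-length selection

For each read length, 5'-end counts over the first 150 CDS nucleotides of
the top 10% of CDSs (ranked by overlapping read weight, ties broken by
transcript id) are summed. The mean-centered vector's DFT magnitudes over
k = 1..⌊N/2⌋ are examined: the length passes iff the profile holds ≥ 1000
reads and the argmax bin is the bin whose period N/k is closest to 3 (for
N = 150 that is k = 50 exactly). The binned argmax (rather than a continuous
period estimate) was chosen for determinism. The test is invariant to
uniform scaling of the profile except through the read-count gate.

## P-site offsets

The TIS profile spans positions −30..+29 (inclusive; 60 bins) around the
start codon; transcripts whose leader is shorter than 30 nt or whose window
would truncate are excluded entirely rather than zero-padded, so the profile
is a sum of fully observed windows. The change-point score at candidate c is
the mean of the w = 5 positions from c minus the mean of the w positions
before c, for c ∈ [−25, 0]; the offset is −c at the maximum. Ties prefer the
offset closest to 12 — the canonical distance from a footprint 5' end to the
P-site in an initiating ribosome — then the smaller offset; both the window
and the tie target are configurable, and offsets can be overridden manually
per length. Profiles with no reads fall back to offset 12 with the event
recorded. The window −30..+29 with w = 5 covers mammalian-type offsets
(≈ 11–14 nt) with margin on both sides.

## CAGE TSS reassignment

The promoter-proximal search window defaults to 1000 nt genomically upstream
and 500 nt downstream of the annotated TSS. Downstream movement is capped so
the new TSS stays inside the (contiguous) first exon and leaves a leader of
at least 1 nt — a TSS at or past the start codon would invalidate the
transcript model. With `respect_gene_boundaries`, window positions
overlapping another gene's annotated span are excluded. The new TSS is the
position of maximal CAGE weight; ties break toward the annotated TSS, then
upstream. Peaks below `min_count` leave the transcript unchanged, so raising
`min_count` can only reduce the number of reassignments. Transcripts of the
same gene are reassigned independently (isoform-specific TSSs are the
motivating case). The CDS never moves genomically; its transcript offset
shifts with the leader length.

## ORF search conventions

The reported interval always includes the stop codon; `min_length` counts it
(minimum useful value 6 = start + stop). ORFs lacking a downstream in-frame
stop are not reported. Per (frame, stop), `longest_only` keeps the 5'-most
start. Circular search runs on the doubled sequence; wrap-spanning ORFs
(width ≤ L) are reported once with the start position in [0, L). The default
near-cognate set is ATG plus its nine single-substitution variants that are
not stop codons. Sequence codons containing N match nothing. uORF candidates
require the start codon fully inside the leader (start + 3 ≤ cds_start);
ORFs whose stop falls inside the CDS are flagged `overlaps_cds` and can be
excluded.

## Metrics

Every ratio metric adds a pseudocount of 1 read to numerator and denominator
counts before FPKM conversion (FPKM = count·10⁹/(len·total)), making all
scores finite and monotone in the counts. The counting rule is: width-1
records (P-sites, CAGE tags) count toward a region iff their position lies
in it; longer reads count on ≥ 1 nt overlap. ORFscore uses P-site counts per
codon frame over the ORF, signed negative when the maximal frame is not the
ORF's own. FLOSS is the half-L1 distance between the ORF's footprint-length
distribution and the distribution over annotated CDSs. Positional entropy is
Shannon entropy of the coverage distribution divided by log2 of the region
length (single-position regions return 0 by convention; empty regions are
missing). The Kozak similarity scores the −4..−1 context against a bundled
default position-weight table reflecting the vertebrate consensus
(purine at −3, pyrimidines elsewhere); any PWM with rows summing to 1 can be
supplied instead.

## Metagene transformations

Seven transformations are implemented: sum, mean and median act as
cross-transcript aggregators on binned raw coverage; zscore
((x − mean)/sample sd, constant vectors map to zero), position_norm
(x/region total) and transcript_norm (x/transcript total, so the vector sums
to 1) act per transcript before summation; mrna_norm divides by the
transcript's RNA-seq FPKM. Scaled-region profiles bin leader/CDS/trailer by
means within near-equal chunks; transcripts missing a region or shorter than
the bin count are skipped and counted. Optional outlier damping caps
per-position counts at a quantile of the transcript's nonzero coverage
(default 0.99 when enabled). Anchored heatmaps exclude truncated windows;
the TSS anchor extends upstream into the contiguous genomic flank (CAGE and
scanning signal live there), while TIS/TTS windows stay within the
transcript; the TTS anchor is the first base of the stop codon.

## Differential translation

Counts are modeled per gene as NB with a log link on
assay + condition + assay:condition, with log size-factor offsets
(median-of-ratios computed jointly across assays so offsets are comparable
between RFP and RNA). The dispersion is estimated gene-wise by method of
moments on normalized counts — the summed excess variance over the four
(assay, condition) groups divided by the summed squared group means — and
then floored at the across-gene median of these raw estimates (and at 1e-8,
capped at 10). The floor is the classic "maximum-sharing" rule: with 2–3
replicates the per-gene moment estimate is noisy and its downward errors
(including negative excess variance, which would imply Poisson standard
errors) inflate Wald statistics; flooring at the central dispersion restores
near-nominal type-I error (~0.05 measured at the null study conditions)
while never shrinking a high-dispersion gene downward. No trend fitting or
empirical-Bayes shrinkage of fold changes is applied. Wald p-values are
two-sided normal; BH adjustment runs separately for the ΔTE, RFP and RNA
families, and classification thresholds the adjusted q-values: ΔTE and RFP
significant with RNA not → translational regulation; ΔTE and RNA significant
with RFP not significant or oppositely signed → buffering; RFP and RNA
significant, same sign, ΔTE not → mRNA abundance; otherwise not significant.
Genes with all-zero counts are excluded and reported.

## Synthetic data

The generators define the study conditions and are pure functions of
(parameters, seed), each driven by a single numpy `default_rng` stream.

* `make_genome`: random-sequence chromosome; one transcript per gene with
  leader/CDS/trailer split over 1..k exons on either strand, 1000 nt
  intergenic gaps; the CDS is forced to ATG…stop with internal in-frame
  stops scrubbed. Optionally plants one clean uORF per selected leader,
  recorded in the ground truth.
* `simulate_riboseq`: read-length and frame proportions are apportioned
  deterministically (largest remainder), so generated enrichment fractions
  are exact rather than sampled; transcripts are drawn proportional to
  log-normal expression (realistic rank spread, which the top-10% selection
  step depends on), codons uniformly, and the 5' end is placed at
  P-site − offset[length]. Contaminants are placed uniformly on supplied
  non-mRNA intervals.
* `simulate_ssu`/`simulate_rnaseq`: 5'-end densities uniform within regions,
  with a configurable leader-to-body enrichment factor for SSU.
* `simulate_cage`: width-1 tags at the true TSS (annotated TSS ± a known
  displacement), with optional geometric jitter.
* `simulate_counts`: NB draws for the 2-assay × 2-condition × n-replicate
  design; condition effects act on RNA and RFP means, interaction effects on
  RFP only; dispersion 0 gives Poisson.

Not emulated: sequencing error, fragment-length biases, positional ramp
effects, nucleotide composition biases, multi-isoform genes and overlapping
genes. Passing tests therefore demonstrate correctness of the algorithms
under clean signal at realistic depths, not robustness to every artifact of
real libraries.

## Problem sizes

Test and acceptance datasets use 12–50 genes, read depths of 10⁴–5·10⁴, and
count matrices of 400–2000 genes with 3 replicates per arm; the delta-TE
null calibration pools three 2000-gene simulations. These sizes give the
recovery checks tight expected behavior (binomial noise well below the
asserted margins) while keeping the full suite fast on a single CPU.

## Known limitations

* Genomic-arithmetic P-site shifting near exon junctions (above).
* Gene-level counting uses one representative transcript per gene (the
  longest CDS-bearing one); multi-isoform aggregation is out of scope.
* The uORF classifier itself is external by design: the package produces
  the labeled feature matrix (CDS positives, 3'UTR negatives).
* The collapsed-read file (.crt) is a versioned parquet table; it is a
  portable columnar schema, not byte-compatible with any R serialization.
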