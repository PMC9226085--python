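# Methods

This note documents the models, conventions, defaults and known limits of
`circedit`. It is written for someone who wants to judge what the package
computes and what passing its tests does — and does not — demonstrate.

## Coordinates and formats

All in-memory coordinates are 0-based half-open; GTF and VCF are converted
at the file boundary and nowhere else. SAM is the alignment interchange
format (text, human-readable fixtures); BED6 carries repeats with the
RepeatMasker family name in the name column, and an element is an Alu
exactly when its family name starts with "Alu". Editing summaries are
BED6+2 (name `gene|segment`, score = site count, extra columns segment
length and mean editing ratio); rows exist only for segments with at least
one site.

## Editing caller

The caller works per sample on a pileup restricted to bases with quality
>= 25 from reads with mapping quality >= 20, ignoring indel-consumed
bases and, by default, bases within 5 nt of a read end (a guard against
alignment-edge artifacts; configurable to 0). A column is a candidate when

* depth >= 5,
* exactly one non-reference base has >= 3 reads, and
* the remaining non-reference bases sum to <= 5% of depth.

These thresholds are package defaults in the range commonly used by
dedicated editing callers; they are not sourced from any particular study
and are all exposed in `EditingConfig`. SNP exclusion removes every
candidate at a known-VCF position, then — when matched DNA is available —
every candidate whose DNA alternative-allele fraction exceeds 10% at DNA
depth >= 10 (a heterozygote sits near 50%, an editing site near 0%). A
BLAT-style realignment filter is deliberately not implemented: on the
synthetic genomes, anchor uniqueness plus the DNA check covers the same
failure mode, and the caller is not meant for repeat-rich real genomes
without additional filtering.

Substitutions are typed on the genomic + strand (12 classes); A>G and T>C
are flagged A-to-I, covering edited adenosines on both strands. Sites are
called per sample and only aggregated afterwards — there is no joint
multi-sample calling.

## Back-splice detection

Candidate reads (those not mapped linearly) are split into 20-nt terminal
anchors. Each anchor is scored against every position of both genome
strands by exact Hamming match count (the genomes here are small enough
for an exhaustive scan); an anchor is unique when it has a single
full-length match, and its margin is best-minus-second-best match count.
A read whose anchors are unique, on one chromosome, and in reversed
genomic order is resolved by extending both anchors until the read is
explained by two genomic segments. Within the remaining ambiguity window
the breakpoint pair showing a canonical splice signal is preferred —
GT after the donor and AG before the acceptor for a + strand circle, or
the reverse-complement signal CT/AC for a - strand circle — and remaining
ties break to the leftmost donor. The signal, not the anchors' mapping
strand, decides the reported circle strand, because in an unstranded
library a back-splice read and its reverse complement carry the same
evidence; this also makes detection exactly symmetric under
reverse-complementing the genome and reads.

Junction coordinates are reported genomically: `acceptor_pos` is the left
breakpoint and `donor_pos` the right one regardless of strand, so for a
minus-strand circle the transcript-sense donor is at the left coordinate.

Filters (recorded, not silently dropped): >= 2 unique supporting reads
(identical read sequences collapse to one), anchor margin >= 2, span
< 100,000 nt. Verification searches the raw reads for an 80-bp probe built
from 40 nt on each side of the joint, allowing 2 edits; probes are
truncated symmetrically near contig ends and flagged. The 40/40 split and
the 2-edit tolerance are the package's neutral reading of an "80 bp
back-spliced sequence" probe; both are configurable.

Breakpoint resolution is exact: a sequencing error anywhere in a candidate
read prevents its two-segment explanation, so at the default 0.1% error
rate roughly 10% of junction reads are not counted. This thins counts
proportionally across samples and does not bias group comparisons;
exactness guarantees are therefore stated (and tested) on error-free
reads.

## Annotation

Gene segmentation derives UTR labels from an optional CDS span (exonic
positions outside it, sided by gene strand); genes without CDS have only
exon/intron labels. Where transcripts or genes overlap, labels resolve by
the precedence exon > UTR > intron, ties to the smaller gene start. The
flanking introns of a BSS are defined structurally — the intron adjacent
to the exon carrying each breakpoint, in host-gene orientation — rather
than by intron numbering, which is convention-dependent. A breakpoint at a
terminal exon yields a missing flank, excluded from flank-split views.
Circle origin classes: exonic (both breakpoints on exon boundaries of one
same-strand transcript), intronic (span inside one intron), exon_intron
(other overlap), antisense (only opposite-strand overlap), intergenic.

Alu-pair orientation is computed in genomic coordinates over all
(upstream-intron Alu, downstream-intron Alu) pairs: +/- is convergent,
-/+ divergent, equal strands same-orientation; convergent + divergent are
the inverted, circularization-competent pairs. The counts are symmetric
under mirroring the locus, so a host-strand-relative view would be
identical.

## Statistics

Group comparisons follow a normality-gated tree: if every group passes
the normality test at alpha = 0.05, Student's t (two groups) or one-way
ANOVA with Tukey's post-hoc (more); otherwise Mann-Whitney U (unpaired),
Wilcoxon signed-rank (paired), or Kruskal-Wallis (more than two groups).
Correlation switches between Pearson and Spearman the same way. The gate
is Shapiro-Wilk by default: it is defined from n = 3, whereas the
D'Agostino-Pearson test (selectable via `normality="dagostino"`) requires
n >= 8 and is unusable at the cohort sizes this package targets. Groups
smaller than 3 skip the gate and fall to the nonparametric branch with a
warning; constant data yields p = NaN rather than a fabricated value.

Differential circRNA analysis runs per feature on BSS-spanning reads per
million linearly mapped reads, calling p < 0.05 significant without
multiple-testing correction — the convention of a volcano plot with a raw
p = 0.05 line; Benjamini-Hochberg is available but off by default, a
fidelity-first choice documented here rather than hidden. Fold change is
case mean over control mean, reported as +inf and flagged when the
control mean is zero. Host independence marks a circRNA whose host mRNA
(FPKM from linear read counts over the gene span) shows p >= 0.05 while
the circle itself is significant.

## Synthetic data generator

The generator emulates a two-group total-RNA cohort at desk scale.
Defaults, chosen once as the package's study conditions:

* 4 genes (alternating strands, one lncRNA without CDS), 5 exons of
  200 nt, introns of 700 nt starting GT and ending AG in gene sense,
  150-nt UTR flanks folded into the terminal exons, 300-nt intergenic
  spacers — a ~18-kb genome.
* Two Alu-like elements per gene (introns 1 and last, + and - strand),
  built from a fixed 300-nt adenosine-rich consensus with 5% per-copy
  divergence, reverse-complemented for minus placements.
* 12 editing sites per Alu at adenosines of the element's sense strand
  (genomically A>G on +, T>C on - elements), control rates uniform on
  [0.10, 0.50] — spanning the caller's detection threshold the way real
  editing ratios do, which is what lets a rate reduction move *counts* —
  multiplied by 0.5 in the HF group.
* 2 heterozygous SNPs per gene (carried at 50% in RNA and DNA reads),
  written to the known-variant VCF.
* One circRNA per gene over internal exons, with BSS-spanning reads per
  sample Poisson around 5 (control) vs 20 (HF) — a 4x increase; exact
  counts on demand for exactness tests. Back-splice reads take distinct
  offsets across the joint, and the first read of each junction in each
  sample spans the joint centrally so that the 80-bp verification probe
  (40 nt each side) is observable in the raw reads by construction even at
  the lowest planted read counts.
* 4 + 4 samples, 100-nt reads, 50x RNA coverage uniform over the
  contiguous pre-mRNA (total-RNA libraries see intronic coverage, and
  contiguous pre-mRNA needs no spliced CIGARs), 30x DNA coverage, 0.1%
  uniform sequencing error, constant base quality 37.

The generator records the *realized* per-sample edited/total tallies and
junction read counts after all mutations, so exactness tests compare
against what the reads actually carry rather than against binomial
expectations. Back-splice reads are emitted only to the unmapped FASTQ,
never into the linear SAM.

What the generator does not model — and therefore what passing tests do
not show about real data: quality-score error profiles, coverage bias and
fragment-length effects, spliced alignments, paired ends, stranded
libraries, hyper-editing clusters, C-to-U editing, genuinely repetitive
genome background beyond the planted Alu copies, and alignment artifacts
of a real aligner (alignments are simulated as correct by construction).

## Numerical and design choices

* Determinism: every stochastic step draws from
  `numpy.random.default_rng([seed, stage, sample])`; same-seed runs are
  byte-identical, and report files are stamped with the seed and a hash of
  the scientific configuration.
* Breakpoint ties: splice signal first (GT-AG, then CT-AC), then leftmost
  donor — required for exact-coordinate tests.
* Repeat-context ties: Alu before other repeats, then smallest element
  start.
* Editing exactness is defined with edge trimming off, making caller
  counts identical to generator tallies instead of merely close.
* Clone quantification (`circedit.trace`) uses local affine-gap alignment
  (match +1, mismatch -1, gap open -2, extend -1), both strands tried,
  ties to the leftmost start; clones are rejected below 70% identity over
  the aligned columns or below 50% clone coverage (a short high-identity
  island is not a matching clone). The editing percent counts only
  reference-A columns read as G, over non-gap reference-A columns; other
  mismatches are reported separately. Per-clone and pooled values are both
  reported, since either convention is defensible.

## Problem sizes

Tests and the acceptance script run on the generator's default desk-scale
cohorts (~18-kb genome, ~70k reads per cohort), with 3 seeds for
robustness checks, 10 seeds for direction recovery, 200 label
permutations for calibration, and 1000 random instances per brute-force
oracle comparison. These sizes give the binomial/permutation estimates
quoted by the acceptance checks comfortable margins while keeping a full
run in minutes on one CPU.

## Known limitations

The detector reports one junction per (chrom, strand, breakpoint pair)
and does not reconstruct circle-internal structure, rolling-circle
junctions, or intronic-lariat circles. The caller has no hyper-editing
mode. The statistics module implements the two-group design the package
targets; the >2-group branches (ANOVA/Tukey, Kruskal-Wallis) are exposed
and tested but not exercised by the pipeline driver. FPKM is computed
from read counts over the gene span, which is adequate for the synthetic
contiguous pre-mRNA but not a general transcript quantifier.
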