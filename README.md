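# circedit

Desk-scale analysis linking loss of A-to-I RNA editing in intronic Alu
elements to circular-RNA formation.

## The problem

ADAR enzymes deaminate adenosine to inosine (A-to-I) in double-stranded RNA.
Because inosine is read as guanosine by sequencers and the splicing
machinery, editing appears as A>G mismatches between RNA reads and the
genome (or T>C on the opposite genomic strand). The main substrate is
double-stranded RNA formed by pairs of inverted Alu elements in introns —
the same structures that promote back-splicing, the head-to-tail joining of
a downstream exon's 3' end to an upstream exon's 5' start that produces
circular RNAs (circRNAs). When editing of the Alus flanking a back-splice
site (BSS) is lost, those Alus pair more stably and circRNA production
rises. Detecting this coupled pattern — editing down, circRNA up — in a
two-group RNA-seq cohort requires four analysis stages that this package
implements end to end:

1. **Editing-site calling** (`circedit.editing`): base-quality and
   mapping-quality filtered pileups; a position is a candidate when exactly
   one non-reference base has >= 3 supporting reads at depth >= 5 and all
   other non-reference bases stay below 5% of the depth (sequencing-error
   guard). Known SNPs (VCF) are removed, and positions whose matched DNA
   reads carry the same alternative allele (> 10% at depth >= 10) are
   removed as private SNPs. The editing ratio is edited reads / total
   reads; A>G and T>C substitutions are flagged as A-to-I.
2. **Back-splice detection** (`circedit.circ`): reads that fail to map
   linearly are split into 20-nt terminal anchors; anchors aligned uniquely
   to one chromosome in reversed genomic order define a candidate junction,
   extended until the read is explained by two genomic segments, with the
   GT-AG splice signal (CT-AC on the forward strand for minus-strand
   circles) selecting the breakpoint pair. Junctions need >= 2 unique
   supporting reads, confident anchors, and a span < 100 kb, and are
   verified by searching the raw reads for an 80-bp probe spanning the
   back-spliced joint.
3. **Annotation** (`circedit.annotation`): genes segmented into
   5'UTR/exon/intron/3'UTR; repeat context (Alu / other repeat /
   nonrepetitive); the introns flanking a BSS; circRNA genomic origin
   classes.
4. **Integration** (`circedit.integration`): normality-gated group
   statistics (Shapiro-Wilk gate; Student's t or ANOVA+Tukey when normal,
   Mann-Whitney U / Wilcoxon / Kruskal-Wallis otherwise; Pearson vs
   Spearman for correlation), differential circRNA analysis on
   BSS-spanning reads per million mapped reads, editing-event counts in
   BSS-flanking introns, host-gene independence, and convergent /
   divergent / same-orientation counting of Alu pairs across the two
   flanking introns.

Because the kind of patient cohort such a study uses is not publicly
available, the package ships a first-class synthetic-data generator
(`circedit.synthetic`) that plants editing sites, heterozygous SNPs and
back-splice junctions into a miniature genome with known per-group rates
and records everything in a truth manifest — the oracle against which the
whole pipeline is tested.

## Worked example

Run the full pipeline on the default synthetic cohort (4 control vs 4 "HF"
samples, editing rates halved and circRNA reads quadrupled in HF):

```bash
circedit run --out demo/ --seed 1
```

or in Python:

```python
from circedit.pipeline import RunConfig, run_pipeline
from circedit.synthetic import SimulationConfig

res = run_pipeline(RunConfig(outdir="demo", simulation=SimulationConfig(seed=1)))
print(res["report"]["editing"]["per_group_totals"])
print(res["report"]["circ"])
print(res["report"]["differential"])
```

With seed 1 this prints:

```
editing per-group totals: {'control': 381, 'HF': 328}
by substitution: {'A>G': 355, 'C>A': 1, 'T>C': 353}
circ: {'n_detected': 4, 'n_passing': 4, 'origin_fractions': {'exonic': 1.0}, 'n_verified': 4}
differential: {'n_significant': 4, 'n_up': 4, 'n_down': 0}
```

Reading these numbers: 709 editing events were called across the eight
samples, all intronic and essentially all typed A>G or T>C (the A-to-I
fingerprint on the two strands; the single C>A call is one sequencing-error
artifact that slipped past the noise guard). Events drop from 381 in the
control group to 328 in HF — the planted editing loss. All four planted
circRNAs are detected at exact breakpoints, verified, classified exonic,
and all four are significantly increased in HF despite unchanged host-gene
expression (`host_independence: {'host_independent': 4}`). The
flanking-intron comparison shows the joint pattern for each circle, e.g.:

```
circ chr1:10150-12150(+): flank editing 24.0 (control) -> 20.0 (HF),
direction down, Mann-Whitney p = 0.020
```

together with one convergent (inverted, circularization-competent) Alu
pair across its flanking introns.

`demo/` then contains per-sample editing-site TSVs and per-segment BED
summaries, the junction table, the BSS quantification matrix, the
volcano-ready differential table, flank-overlap and Alu-orientation
tables, and `report.json` / `report.md` stamped with the seed and config
hash. Reruns with the same seed are byte-identical.

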