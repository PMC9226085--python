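"""Gene segmentation, repeat context and back-splice flanking introns.

A gene body is partitioned into 5'UTR / exon / intron / 3'UTR segments; the
UTR labels are derived from an optional CDS span (positions inside an exon
but outside the CDS).  Positions outside every gene are intergenic.  When
transcripts or genes overlap, labels are resolved with the precedence
exon > UTR > intron.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from intervaltree import IntervalTree

from circedit.io_formats import GenomicInterval


class Segment(str, Enum):
    FIVE_PRIME_UTR = "five_prime_utr"
    EXON = "exon"
    INTRON = "intron"
    THREE_PRIME_UTR = "three_prime_utr"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: label precedence when overlapping transcripts/genes disagree
_SEGMENT_RANK = {
    Segment.EXON: 0,
    Segment.FIVE_PRIME_UTR: 1,
    Segment.THREE_PRIME_UTR: 1,
    Segment.INTRON: 2,
}


class RepeatClass(str, Enum):
    ALU = "alu"
    NON_ALU_REPEAT = "non_alu_repeat"
    NONREPETITIVE = "nonrepetitive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class RepeatElement:
    """A repeat interval with RepeatMasker-style family name."""

    interval: GenomicInterval
    family: str

    @property
    def is_alu(self) -> bool:
        return self.family.startswith("Alu")


@dataclass
class GeneModel:
    """A gene with one or more transcripts (sorted exon interval lists)."""

    gene_id: str
    biotype: str
    interval: GenomicInterval
    transcripts: dict[str, list[GenomicInterval]]
    cds_span: Optional[GenomicInterval] = None

    def introns(self, transcript_id: Optional[str] = None) -> list[GenomicInterval]:
        """Introns of one transcript (default: the first), sorted by start."""
        tid = transcript_id or next(iter(self.transcripts))
        exons = self.transcripts[tid]
        return [
            GenomicInterval(self.interval.chrom, a.end, b.start, self.interval.strand)
            for a, b in zip(exons, exons[1:])
            if a.end < b.start
        ]

    def exon_boundaries(self, transcript_id: Optional[str] = None) -> tuple[set[int], set[int]]:
        """(set of exon starts, set of exon ends) of one transcript."""
        tid = transcript_id or next(iter(self.transcripts))
        exons = self.transcripts[tid]
        return {e.start for e in exons}, {e.end for e in exons}


@dataclass(frozen=True)
class CircOrigin:
    origin_class: str  # exonic | exon_intron | intronic | intergenic | antisense
    host_gene: Optional[str]


class GenomeAnnotation:
    """Indexed gene models + repeats for fast positional queries."""

    def __init__(self, genes: Sequence[GeneModel], repeats: Sequence[RepeatElement] = ()):
        self.genes = list(genes)
        self.repeats = list(repeats)
        self._gene_trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            tree = self._gene_trees.setdefault(g.interval.chrom, IntervalTree())
            tree[g.interval.start : g.interval.end] = g
        self._repeat_trees: dict[str, IntervalTree] = {}
        for el in self.repeats:
            tree = self._repeat_trees.setdefault(el.interval.chrom, IntervalTree())
            tree[el.interval.start : el.interval.end] = el

    # -- gene segmentation --------------------------------------------------

    def _transcript_label(
        self, gene: GeneModel, exons: list[GenomicInterval], pos: int
    ) -> Optional[Segment]:
        first, last = exons[0].start, exons[-1].end
        if not (first <= pos < last):
            return None
        for e in exons:
            if e.start <= pos < e.end:
                cds = gene.cds_span
                if cds is not None:
                    if pos < cds.start:
                        return (
                            Segment.FIVE_PRIME_UTR
                            if gene.interval.strand != "-"
                            else Segment.THREE_PRIME_UTR
                        )
                    if pos >= cds.end:
                        return (
                            Segment.THREE_PRIME_UTR
                            if gene.interval.strand != "-"
                            else Segment.FIVE_PRIME_UTR
                        )
                return Segment.EXON
        return Segment.INTRON

    def segment_of(self, chrom: str, pos: int) -> tuple[Segment, Optional[str]]:
        """Segment label at a position, plus the gene id (None if intergenic).

        Overlapping transcripts/genes are resolved with the precedence
        exon > UTR > intron; ties at equal rank go to the gene with the
        smallest start (deterministic).
        """
        tree = self._gene_trees.get(chrom)
        best: Optional[tuple[int, int, Segment, str]] = None
        if tree is not None:
            for hit in tree[pos]:
                gene: GeneModel = hit.data
                for exons in gene.transcripts.values():
                    label = self._transcript_label(gene, exons, pos)
                    if label is None:
                        continue
                    key = (_SEGMENT_RANK[label], gene.interval.start, label, gene.gene_id)
                    if best is None or key[:2] < best[:2]:
                        best = key
        if best is None:
            return Segment.INTERGENIC, None
        return best[2], best[3]

    # -- repeat context -----------------------------------------------------

    def repeat_context(self, chrom: str, pos: int) -> tuple[RepeatClass, Optional[RepeatElement]]:
        """Repeat class at a position: alu > non-Alu repeat > nonrepetitive.

        Ties within a class are broken by the smallest element start.
        """
        tree = self._repeat_trees.get(chrom)
        if tree is None:
            return RepeatClass.NONREPETITIVE, None
        hits = sorted(
            (h.data for h in tree[pos]),
            key=lambda el: (not el.is_alu, el.interval.start),
        )
        if not hits:
            return RepeatClass.NONREPETITIVE, None
        el = hits[0]
        return (RepeatClass.ALU if el.is_alu else RepeatClass.NON_ALU_REPEAT), el

    # -- back-splice junction annotation -------------------------------------

    def _host_candidates(self, chrom: str, acceptor: int, donor: int) -> list[GeneModel]:
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (h.data for h in tree.overlap(acceptor, donor)),
            key=lambda g: g.interval.start,
        )

    def flanking_introns(
        self, junction
    ) -> tuple[Optional[GenomicInterval], Optional[GenomicInterval]]:
        """Introns flanking a back-splice site, in host-gene orientation.

        Returns ``(upstream, downstream)``: the intron immediately 5' of the
        junction's upstream exon and the intron immediately 3' of its
        downstream exon, each ``None`` when the breakpoint lies at a
        terminal exon.  The junction's breakpoints must coincide exactly
        with exon boundaries of one host transcript.
        """
        chrom, acceptor, donor = junction.chrom, junction.acceptor_pos, junction.donor_pos
        for gene in self._host_candidates(chrom, acceptor, donor):
            for tid, exons in gene.transcripts.items():
                starts = {e.start: i for i, e in enumerate(exons)}
                ends = {e.end: i for i, e in enumerate(exons)}
                if acceptor not in starts or donor not in ends:
                    continue
                introns = gene.introns(tid)
                i_left = starts[acceptor]   # exon whose genomic start is the left breakpoint
                i_right = ends[donor]       # exon whose genomic end is the right breakpoint
                left_intron = introns[i_left - 1] if i_left > 0 else None
                right_intron = introns[i_right] if i_right < len(introns) else None
                if gene.interval.strand == "-":
                    # transcript-upstream is genomically right of the circle
                    return right_intron, left_intron
                return left_intron, right_intron
        raise AnnotationError(
            f"junction {chrom}:{acceptor}-{donor} does not match exon boundaries of any gene"
        )

    def annotate_circ_origin(self, junction) -> CircOrigin:
        """Classify the genomic origin of a circRNA candidate.

        exonic when both breakpoints sit on exon boundaries of one
        same-strand transcript; intronic when the span lies inside a single
        intron; exon_intron for any other overlap of the host's
        exon/intron structure; antisense when the only overlapping gene is
        on the opposite strand; intergenic when no gene overlaps.
        """
        chrom, acceptor, donor = junction.chrom, junction.acceptor_pos, junction.donor_pos
        candidates = self._host_candidates(chrom, acceptor, donor)
        if not candidates:
            return CircOrigin("intergenic", None)
        same = [g for g in candidates if g.interval.strand in (junction.strand, ".")]
        if not same:
            return CircOrigin("antisense", candidates[0].gene_id)
        for gene in same:
            for tid, exons in gene.transcripts.items():
                starts, ends = {e.start for e in exons}, {e.end for e in exons}
                if acceptor in starts and donor in ends:
                    return CircOrigin("exonic", gene.gene_id)
        for gene in same:
            for tid in gene.transcripts:
                for intron in gene.introns(tid):
                    if intron.start <= acceptor and donor <= intron.end:
                        return CircOrigin("intronic", gene.gene_id)
        return CircOrigin("exon_intron", same[0].gene_id)


class AnnotationError(ValueError):
    """A junction or position could not be reconciled with the gene models."""


# -- module-level convenience wrappers over GenomeAnnotation ------------------

def segment_of(chrom: str, pos: int, genes: Sequence[GeneModel]):
    return GenomeAnnotation(genes).segment_of(chrom, pos)


def repeat_context(chrom: str, pos: int, repeats: Sequence[RepeatElement]):
    return GenomeAnnotation([], repeats).repeat_context(chrom, pos)


def flanking_introns(junction, genes: Sequence[GeneModel]):
    return GenomeAnnotation(genes).flanking_introns(junction)


def annotate_circ_origin(junction, genes: Sequence[GeneModel]):
    return GenomeAnnotation(genes).annotate_circ_origin(junction)
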