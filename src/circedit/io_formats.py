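"""Readers/writers for the standard formats the pipeline touches.

Coordinate convention: everything in memory is 0-based half-open
(``[start, end)``).  GTF and VCF are 1-based on disk; the conversion happens
here and only here, so no other module ever shifts a coordinate.
"""

from __future__ import annotations

import array
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam
from Bio import SeqIO

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A file violated the expectations of its declared format."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N-safe)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval. ``start`` 0-based inclusive, ``end`` exclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class VariantRecord:
    """A known (or DNA-checked) single-nucleotide variant, 0-based."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    source_tag: str = "known_vcf"  # or "dna_check"

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base must differ")
        for b in (self.ref_base, self.alt_base):
            if b not in "ACGT":
                raise ValueError(f"invalid base {b!r}")


@dataclass
class AlignedRead:
    """One alignment record; unmapped reads carry ``interval=None``."""

    read_id: str
    interval: Optional[GenomicInterval]
    query_sequence: str
    base_qualities: list[int]
    cigar: list[tuple[str, int]] = field(default_factory=list)
    mapping_quality: int = 0
    is_linear_mapped: bool = True

    def __post_init__(self):
        if self.base_qualities and len(self.base_qualities) != len(self.query_sequence):
            raise ValueError("quality list length must equal sequence length")
        if self.is_linear_mapped and self.interval is not None:
            ref_len = sum(n for op, n in self.cigar if op in "MDN=X")
            if ref_len != len(self.interval):
                raise ValueError(
                    f"CIGAR reference length {ref_len} != interval length {len(self.interval)}"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into ``{name: SEQUENCE}``.

    Sequences are upper-cased; names are taken up to the first whitespace.
    Duplicate names and empty files are format errors.
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"duplicate FASTA record name {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise FormatError(f"no FASTA records found in {path}")
    return genome


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | os.PathLike):
    """Parse a GTF of gene/transcript/exon (+ optional CDS) features.

    Returns a list of :class:`circedit.annotation.GeneModel` with coordinates
    converted from GTF's 1-based inclusive to internal 0-based half-open.
    Exons are grouped per transcript and sorted by start on load.
    """
    import gffutils
    from circedit.annotation import GeneModel

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gid = g.attributes["gene_id"][0]
        biotype = (g.attributes.get("gene_biotype") or g.attributes.get("biotype") or ["other"])[0]
        gene_iv = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand)
        transcripts: dict[str, list[GenomicInterval]] = {}
        cds_span: Optional[GenomicInterval] = None
        for t in db.children(g, featuretype="transcript"):
            tid = t.attributes["transcript_id"][0]
            exons = sorted(
                (
                    GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
                    for e in db.children(t, featuretype="exon")
                ),
                key=lambda iv: iv.start,
            )
            for e in exons:
                if e.start < gene_iv.start or e.end > gene_iv.end:
                    raise FormatError(
                        f"exon [{e.start},{e.end}) outside gene {gid} span"
                    )
            transcripts[tid] = exons
        cds_feats = list(db.children(g, featuretype="CDS"))
        if cds_feats:
            cds_span = GenomicInterval(
                g.seqid,
                min(c.start - 1 for c in cds_feats),
                max(c.end for c in cds_feats),
                g.strand,
            )
        genes.append(
            GeneModel(
                gene_id=gid,
                biotype=biotype,
                interval=gene_iv,
                transcripts=transcripts,
                cds_span=cds_span,
            )
        )
    return genes


def write_gtf(genes, path: str | os.PathLike, source: str = "circedit") -> None:
    """Write GeneModels back to GTF (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                "\t".join(
                    [
                        g.interval.chrom,
                        source,
                        "gene",
                        str(g.interval.start + 1),
                        str(g.interval.end),
                        ".",
                        g.interval.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for tid, exons in g.transcripts.items():
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}"; gene_biotype "{g.biotype}";'
                fh.write(
                    "\t".join(
                        [
                            g.interval.chrom,
                            source,
                            "transcript",
                            str(min(e.start for e in exons) + 1),
                            str(max(e.end for e in exons)),
                            ".",
                            g.interval.strand,
                            ".",
                            tattrs,
                        ]
                    )
                    + "\n"
                )
                for e in exons:
                    fh.write(
                        "\t".join(
                            [
                                e.chrom,
                                source,
                                "exon",
                                str(e.start + 1),
                                str(e.end),
                                ".",
                                e.strand,
                                ".",
                                tattrs,
                            ]
                        )
                        + "\n"
                    )
                if g.cds_span is not None:
                    fh.write(
                        "\t".join(
                            [
                                g.interval.chrom,
                                source,
                                "CDS",
                                str(g.cds_span.start + 1),
                                str(g.cds_span.end),
                                ".",
                                g.interval.strand,
                                "0",
                                tattrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike):
    """Read a BED6 repeat annotation into RepeatElements.

    The name column is the repeat family (RepeatMasker style, e.g. AluSx3);
    ``is_alu`` is true when it starts with "Alu".
    """
    from circedit.annotation import RepeatElement

    elements = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 requires 6 columns (strand)")
            chrom, start, end, name, _score, strand = cols[:6]
            start, end = int(start), int(end)
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            elements.append(
                RepeatElement(
                    interval=GenomicInterval(chrom, start, end, strand),
                    family=name,
                )
            )
    return elements


def write_bed(elements, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for el in elements:
            iv = el.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{el.family}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# editing summary BED (BED6+2)
# ---------------------------------------------------------------------------

def write_editing_bed(summaries, path: str | os.PathLike) -> None:
    """Write per-(gene, segment) editing summaries as BED6+2.

    One row per (gene, segment) with name ``gene|segment``, score = number of
    editing sites, and two extra columns: segment length and mean editing
    ratio.  Segments with zero sites are omitted (summaries only exist for
    n_sites >= 1).
    """
    with open(path, "w") as fh:
        for s in summaries:
            iv = s.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.gene_id}|{s.segment}\t"
                f"{s.n_sites}\t{iv.strand}\t{s.segment_length}\t{s.mean_editing_ratio:.6g}\n"
            )


def read_editing_bed(path: str | os.PathLike):
    """Round-trip reader for :func:`write_editing_bed` output."""
    from circedit.editing import SegmentEditingSummary

    rows = []
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                raise FormatError("editing summary BED requires 8 columns")
            chrom, start, end, name, score, strand, seg_len, ratio = cols[:8]
            gene_id, segment = name.split("|", 1)
            rows.append(
                SegmentEditingSummary(
                    gene_id=gene_id,
                    segment=segment,
                    interval=GenomicInterval(chrom, int(start), int(end), strand),
                    n_sites=int(score),
                    segment_length=int(seg_len),
                    mean_editing_ratio=float(ratio),
                )
            )
    return rows


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike) -> list[VariantRecord]:
    """Read SNVs from a VCF (plain text or bgzipped); positions become 0-based."""
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1 and alt in "ACGT":
                    records.append(
                        VariantRecord(rec.chrom, rec.pos - 1, rec.ref, alt, "known_vcf")
                    )
    return records


def write_vcf(
    variants: Iterable[VariantRecord],
    contigs: dict[str, int],
    path: str | os.PathLike,
) -> None:
    """Write SNVs as VCF 4.2 (1-based on disk)."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos, stop=v.pos + 1, alleles=(v.ref_base, v.alt_base)
            )
            out.write(rec)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_CIGAR_OPS = "MIDNSHP=XB"


def read_alignments(path: str | os.PathLike) -> Iterator[AlignedRead]:
    """Stream AlignedReads from a SAM file.

    Unmapped reads are yielded with ``is_linear_mapped=False`` and no
    interval.  A reference name missing from the header is a format error
    (raised by the underlying parser).
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                yield AlignedRead(
                    read_id=rec.query_name,
                    interval=None,
                    query_sequence=rec.query_sequence or "",
                    base_qualities=list(rec.query_qualities or []),
                    cigar=[],
                    mapping_quality=rec.mapping_quality,
                    is_linear_mapped=False,
                )
                continue
            cigar = [(_CIGAR_OPS[op], n) for op, n in rec.cigartuples]
            ref_len = sum(n for op, n in cigar if op in "MDN=X")
            yield AlignedRead(
                read_id=rec.query_name,
                interval=GenomicInterval(
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_start + ref_len,
                    "-" if rec.is_reverse else "+",
                ),
                query_sequence=rec.query_sequence or "",
                base_qualities=list(rec.query_qualities or []),
                cigar=cigar,
                mapping_quality=rec.mapping_quality,
                is_linear_mapped=True,
            )


def write_alignments(
    reads: Iterable[AlignedRead],
    contigs: dict[str, int],
    path: str | os.PathLike,
) -> None:
    """Write AlignedReads as plain-text SAM."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.read_id
            seg.query_sequence = r.query_sequence
            seg.query_qualities = array.array("B", r.base_qualities)
            seg.mapping_quality = r.mapping_quality
            if r.interval is None or not r.is_linear_mapped:
                seg.is_unmapped = True
            else:
                seg.reference_id = out.header.get_tid(r.interval.chrom)
                seg.reference_start = r.interval.start
                seg.cigarstring = "".join(f"{n}{op}" for op, n in r.cigar)
                seg.is_reverse = r.interval.strand == "-"
            out.write(seg)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Yield ``(read_id, sequence)`` from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike, quality: int = 37) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")
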