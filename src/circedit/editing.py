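"""RNA editing-site calling from pileups, with SNP exclusion.

The caller follows the classic RNA-editing detection recipe: build a
base-quality- and mapping-quality-filtered pileup, nominate positions where
exactly one non-reference base is well supported (a sequencing-error guard
rejects columns with several alternative bases), then remove known SNPs from
a VCF and, when matched DNA is available, positions whose DNA reads also
carry the alternative allele.  A>G and T>C substitutions are the genomic
fingerprints of A-to-I editing (inosine is read as guanosine; T>C is the
same event on the opposite strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from circedit.annotation import GenomeAnnotation, RepeatClass, Segment
from circedit.io_formats import AlignedRead, GenomicInterval, VariantRecord

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_BASE = "ACGT"

SUBSTITUTION_TYPES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)


@dataclass
class EditingConfig:
    """Thresholds of the caller; RNAEditor-class defaults, all overridable."""

    min_base_quality: int = 25
    min_mapping_quality: int = 20
    min_depth: int = 5
    min_alt_reads: int = 3
    max_noise: float = 0.05
    max_dna_alt_fraction: float = 0.1
    min_dna_depth: int = 10
    edge_trim: int = 5  # bases this close to a read end are not counted


@dataclass(frozen=True)
class PileupColumn:
    chrom: str
    pos: int
    ref_base: str
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


class Pileup:
    """Per-chromosome (4, L) base-count matrices."""

    def __init__(self, counts: dict[str, np.ndarray], genome: dict[str, str]):
        self.counts = counts
        self.genome = genome

    def column(self, chrom: str, pos: int) -> PileupColumn:
        col = self.counts[chrom][:, pos]
        return PileupColumn(
            chrom,
            pos,
            self.genome[chrom][pos],
            {b: int(col[i]) for b, i in _BASE_INDEX.items()},
        )

    def depth(self, chrom: str) -> np.ndarray:
        return self.counts[chrom].sum(axis=0)

    def iter_columns(self) -> Iterator[PileupColumn]:
        for chrom, mat in self.counts.items():
            for pos in np.flatnonzero(mat.sum(axis=0) > 0):
                yield self.column(chrom, int(pos))


def _aligned_pairs(read: AlignedRead) -> tuple[np.ndarray, np.ndarray]:
    """(query positions, reference positions) consumed by match ops."""
    qpos, rpos = [], []
    q = 0
    r = read.interval.start
    for op, n in read.cigar:
        if op in "M=X":
            qpos.append(np.arange(q, q + n))
            rpos.append(np.arange(r, r + n))
            q += n
            r += n
        elif op in "IS":
            q += n
        elif op in "DN":
            r += n
        # H/P consume nothing
    if not qpos:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(qpos), np.concatenate(rpos)


def pileup(
    reads: Iterable[AlignedRead],
    genome: dict[str, str],
    config: EditingConfig | None = None,
) -> Pileup:
    """Tally base counts per reference position.

    Bases below ``min_base_quality``, reads below ``min_mapping_quality``
    and bases within ``edge_trim`` of either read end are excluded;
    insertions and deletions contribute nothing.
    """
    cfg = config or EditingConfig()
    counts = {
        chrom: np.zeros((4, len(seq)), dtype=np.int32) for chrom, seq in genome.items()
    }
    base_lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        base_lut[ord(b)] = i
        base_lut[ord(b.lower())] = i
    for read in reads:
        if not read.is_linear_mapped or read.interval is None:
            continue
        if read.mapping_quality < cfg.min_mapping_quality:
            continue
        chrom = read.interval.chrom
        if chrom not in counts:
            raise ValueError(f"read mapped to unknown reference {chrom!r}")
        qpos, rpos = _aligned_pairs(read)
        if len(qpos) == 0:
            continue
        seq = np.frombuffer(read.query_sequence.encode(), dtype=np.uint8)
        quals = np.asarray(read.base_qualities, dtype=np.int16)
        n = len(seq)
        keep = quals[qpos] >= cfg.min_base_quality
        if cfg.edge_trim > 0:
            keep &= (qpos >= cfg.edge_trim) & (qpos < n - cfg.edge_trim)
        b = base_lut[seq[qpos[keep]]]
        r = rpos[keep]
        valid = b >= 0
        np.add.at(counts[chrom], (b[valid], r[valid]), 1)
    return Pileup(counts, genome)


@dataclass
class EditingSite:
    """One candidate/called edited position in one sample."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    edited_reads: int
    total_reads: int
    substitution_type: str = ""
    is_AtoI: bool = False
    segment: Optional[Segment] = None
    gene_id: Optional[str] = None
    repeat_class: Optional[RepeatClass] = None
    repeat_family: Optional[str] = None
    sample_id: Optional[str] = None
    removed_by: Optional[str] = None  # known_vcf | dna_check, set on exclusion

    def __post_init__(self):
        if not self.substitution_type:
            self.substitution_type, self.is_AtoI = type_substitution(
                self.ref_base, self.alt_base
            )

    @property
    def editing_ratio(self) -> float:
        return self.edited_reads / self.total_reads


def type_substitution(ref_base: str, alt_base: str) -> tuple[str, bool]:
    """Genomic substitution class (12 types) and the A-to-I flag.

    A>G and T>C mismatches are both indicative of A-to-I editing (the T>C
    readout is an edited adenosine on the opposite strand); the reported
    class stays genomic.
    """
    sub = f"{ref_base}>{alt_base}"
    if sub not in SUBSTITUTION_TYPES:
        raise ValueError(f"invalid substitution {sub}")
    return sub, sub in ("A>G", "T>C")


def call_candidates(
    pile: Pileup,
    config: EditingConfig | None = None,
    sample_id: Optional[str] = None,
) -> list[EditingSite]:
    """Nominate candidate editing sites from a pileup.

    A position is a candidate when exactly one non-reference base reaches
    ``min_alt_reads``, depth reaches ``min_depth``, and the remaining
    non-reference bases together stay below ``max_noise`` of the depth.
    """
    cfg = config or EditingConfig()
    out: list[EditingSite] = []
    for chrom, mat in pile.counts.items():
        seq = np.frombuffer(pile.genome[chrom].encode(), dtype=np.uint8)
        ref_idx = np.full(len(seq), -1, dtype=np.int8)
        for b, i in _BASE_INDEX.items():
            ref_idx[seq == ord(b)] = i
        depth = mat.sum(axis=0)
        known = ref_idx >= 0
        nonref = mat.copy()
        cols = np.arange(mat.shape[1])
        safe_ref = np.where(known, ref_idx, 0)
        nonref[safe_ref, cols] = 0
        n_strong = (nonref >= cfg.min_alt_reads).sum(axis=0)
        top_idx = nonref.argmax(axis=0)
        top = nonref.max(axis=0)
        noise = nonref.sum(axis=0) - top
        ok = (
            known
            & (depth >= cfg.min_depth)
            & (n_strong == 1)
            & (noise <= cfg.max_noise * depth)
        )
        for pos in np.flatnonzero(ok):
            out.append(
                EditingSite(
                    chrom=chrom,
                    pos=int(pos),
                    ref_base=_IDX_BASE[ref_idx[pos]],
                    alt_base=_IDX_BASE[top_idx[pos]],
                    edited_reads=int(top[pos]),
                    total_reads=int(depth[pos]),
                    sample_id=sample_id,
                )
            )
    return out


def exclude_snps(
    candidates: Sequence[EditingSite],
    known_variants: Sequence[VariantRecord] = (),
    dna_pileup: Optional[Pileup] = None,
    config: EditingConfig | None = None,
    with_removed: bool = False,
):
    """Remove SNPs from candidate sites.

    Any candidate at a known-VCF position is removed.  When a matched DNA
    pileup is provided, candidates whose DNA alternative-allele fraction
    exceeds ``max_dna_alt_fraction`` at DNA depth >= ``min_dna_depth`` are
    removed and tagged ``dna_check``; the survivors are editing sites.
    """
    cfg = config or EditingConfig()
    vcf_pos = {(v.chrom, v.pos) for v in known_variants}
    kept: list[EditingSite] = []
    removed: list[EditingSite] = []
    for site in candidates:
        if (site.chrom, site.pos) in vcf_pos:
            removed.append(replace_removed(site, "known_vcf"))
            continue
        if dna_pileup is not None and site.chrom in dna_pileup.counts:
            col = dna_pileup.counts[site.chrom][:, site.pos]
            depth = int(col.sum())
            alt = int(col[_BASE_INDEX[site.alt_base]])
            if depth >= cfg.min_dna_depth and alt / depth > cfg.max_dna_alt_fraction:
                removed.append(replace_removed(site, "dna_check"))
                continue
        kept.append(site)
    if with_removed:
        return kept, removed
    return kept


def replace_removed(site: EditingSite, reason: str) -> EditingSite:
    return replace(site, removed_by=reason)


def annotate_sites(
    sites: Sequence[EditingSite], annotation: GenomeAnnotation
) -> list[EditingSite]:
    """Attach segment, gene and repeat context to called sites (in place)."""
    for s in sites:
        s.segment, s.gene_id = annotation.segment_of(s.chrom, s.pos)
        s.repeat_class, el = annotation.repeat_context(s.chrom, s.pos)
        s.repeat_family = el.family if el is not None else None
    return list(sites)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class SegmentEditingSummary:
    gene_id: str
    segment: str
    interval: GenomicInterval
    n_sites: int
    segment_length: int
    mean_editing_ratio: float


def _segment_lengths(gene, utr_aware: bool = True) -> dict[str, tuple[int, GenomicInterval]]:
    """Total length and bounding interval per segment of one gene."""
    chrom = gene.interval.chrom
    strand = gene.interval.strand
    exons = next(iter(gene.transcripts.values()))
    introns = gene.introns()
    out: dict[str, tuple[int, GenomicInterval]] = {}
    exon_len = sum(len(e) for e in exons)
    utr5 = utr3 = 0
    if gene.cds_span is not None:
        for e in exons:
            left = max(0, min(e.end, gene.cds_span.start) - e.start)
            right = max(0, e.end - max(e.start, gene.cds_span.end))
            if strand == "-":
                utr3 += left
                utr5 += right
            else:
                utr5 += left
                utr3 += right
        exon_len -= utr5 + utr3
    bounding = GenomicInterval(chrom, gene.interval.start, gene.interval.end, strand)
    out[Segment.EXON.value] = (exon_len, bounding)
    if introns:
        out[Segment.INTRON.value] = (sum(len(i) for i in introns), bounding)
    if utr5:
        out[Segment.FIVE_PRIME_UTR.value] = (utr5, bounding)
    if utr3:
        out[Segment.THREE_PRIME_UTR.value] = (utr3, bounding)
    return out


def summarize_segments(sites: Sequence[EditingSite], genes) -> list[SegmentEditingSummary]:
    """Per-(gene, segment) editing summary: site count, length, mean ratio.

    Only (gene, segment) pairs with at least one site are emitted.
    """
    by_gene = {g.gene_id: g for g in genes}
    groups: dict[tuple[str, str], list[EditingSite]] = {}
    for s in sites:
        if s.gene_id is None or s.segment in (None, Segment.INTERGENIC):
            continue
        groups.setdefault((s.gene_id, Segment(s.segment).value), []).append(s)
    out = []
    for (gid, seg), members in sorted(groups.items()):
        gene = by_gene[gid]
        lengths = _segment_lengths(gene)
        seg_len, bounding = lengths.get(seg, (0, gene.interval))
        out.append(
            SegmentEditingSummary(
                gene_id=gid,
                segment=seg,
                interval=bounding,
                n_sites=len(members),
                segment_length=seg_len,
                mean_editing_ratio=float(np.mean([m.editing_ratio for m in members])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# per-position profiles and per-gene event means
# ---------------------------------------------------------------------------

def per_position_profile(
    element,
    pileups_by_group: dict[str, Sequence[Pileup]],
    genome: dict[str, str],
) -> dict[str, np.ndarray]:
    """Per-adenosine A-to-I ratio along an Alu element, averaged per group.

    Positions are the adenosines of the element's sense strand (for '-'
    elements these are genomic Ts, and edited reads carry C); the returned
    vectors are indexed along the element 5'->3' in its own orientation.
    Samples with zero coverage at a position are ignored in the average; a
    position covered by no sample yields NaN.
    """
    iv = element.interval
    seq = genome[iv.chrom]
    if iv.strand == "-":
        targets = [p for p in range(iv.start, iv.end) if seq[p] == "T"]
        targets = targets[::-1]  # element-local 5'->3'
        alt_idx, ref_idx = _BASE_INDEX["C"], _BASE_INDEX["T"]
    else:
        targets = [p for p in range(iv.start, iv.end) if seq[p] == "A"]
        alt_idx, ref_idx = _BASE_INDEX["G"], _BASE_INDEX["A"]
    profiles: dict[str, np.ndarray] = {}
    for group, piles in pileups_by_group.items():
        ratios = np.full((len(piles), len(targets)), np.nan)
        for si, pile in enumerate(piles):
            mat = pile.counts[iv.chrom]
            for ti, p in enumerate(targets):
                depth = int(mat[:, p].sum())
                if depth > 0:
                    ratios[si, ti] = mat[alt_idx, p] / depth
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            profiles[group] = np.nanmean(ratios, axis=0)
    return profiles


def mean_events_per_gene(
    sites_by_sample: dict[str, Sequence[EditingSite]],
    groups: dict[str, str],
    control: str = "control",
    case: str = "HF",
    alpha: float = 0.05,
):
    """Mean editing-event counts per gene per group, with direction and p.

    Genes with zero sites in every sample are excluded; the remaining genes
    are partitioned into "reduced" / "increased" by comparing the case group
    mean against the control group mean, with significance from the
    normality-gated test tree.
    """
    import pandas as pd

    from circedit.integration import run_group_test

    rows = []
    gene_ids = sorted(
        {s.gene_id for sites in sites_by_sample.values() for s in sites if s.gene_id}
    )
    group_names = [control, case]
    for gid in gene_ids:
        counts = {
            sid: sum(1 for s in sites if s.gene_id == gid)
            for sid, sites in sites_by_sample.items()
        }
        values = {
            g: np.array([c for sid, c in counts.items() if groups[sid] == g], dtype=float)
            for g in group_names
        }
        means = {g: float(v.mean()) if len(v) else float("nan") for g, v in values.items()}
        test_name, p = run_group_test([values[g] for g in group_names])
        direction = "reduced" if means[case] < means[control] else "increased"
        rows.append(
            {
                "gene_id": gid,
                **{f"mean_{g}": means[g] for g in group_names},
                "direction": direction,
                "test": test_name,
                "p_value": p,
                "significant": bool(p < alpha) if not np.isnan(p) else False,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------

def sites_to_frame(sites: Sequence[EditingSite]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref_base,
                "alt": s.alt_base,
                "edited_reads": s.edited_reads,
                "total_reads": s.total_reads,
                "editing_ratio": s.editing_ratio,
                "substitution_type": s.substitution_type,
                "is_AtoI": s.is_AtoI,
                "segment": str(s.segment) if s.segment else "",
                "gene_id": s.gene_id or "",
                "repeat_class": str(s.repeat_class) if s.repeat_class else "",
                "repeat_family": s.repeat_family or "",
                "sample_id": s.sample_id or "",
            }
            for s in sites
        ]
    )
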