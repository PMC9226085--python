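"""Back-splice junction (circRNA) detection from non-linearly-mapped reads.

Reads that fail to map linearly are split into two terminal anchors (20 nt
by default).  Each anchor is aligned exhaustively against both strands of
the genome; a read whose anchors map uniquely, on one chromosome and strand
but in *reversed* genomic order (the head anchor downstream of the tail
anchor) is a back-splice candidate.  The anchors are extended inward until
the full read is explained by two genomic segments; within the remaining
breakpoint-ambiguity window the pair placing GT immediately after the donor
and AG immediately before the acceptor is preferred, falling back to the
leftmost consistent pair.  Junctions are then filtered (>= 2 unique
supporting reads, anchor uniqueness margin, span < 100 kb) and verified by
searching the raw reads for an 80-bp probe spanning the back-spliced joint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from circedit.io_formats import GenomicInterval, revcomp

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class CircConfig:
    anchor_len: int = 20
    min_reads: int = 2            # unique supporting reads per junction
    min_anchor_margin: int = 2    # best-minus-second-best anchor match count
    max_span: int = 100_000       # junction length filter, exclusive bound
    probe_len: int = 80           # verification probe, split probe_len/2 each side
    probe_max_mismatch: int = 2


@dataclass(frozen=True)
class AnchorHit:
    read_id: str
    side: str                    # head | tail
    interval: Optional[GenomicInterval]
    is_unique: bool
    score_margin: int            # best minus second-best match count


@dataclass
class BackspliceJunction:
    """A circRNA candidate; coordinates are genomic and strand-agnostic:
    ``acceptor_pos`` is the left breakpoint (5' BSS on the + strand) and
    ``donor_pos`` the right breakpoint, 0-based half-open."""

    chrom: str
    strand: str
    acceptor_pos: int
    donor_pos: int
    supporting_read_ids: set[str] = field(default_factory=set)
    supporting_sequences: set[str] = field(default_factory=set)
    splice_signal: str = "other"  # GT-AG | other
    anchor_margin: int = 0
    verified: bool = False
    probe_truncated: bool = False
    filter_status: set[str] = field(default_factory=set)

    @property
    def span(self) -> int:
        return self.donor_pos - self.acceptor_pos

    @property
    def n_unique_reads(self) -> int:
        return len(self.supporting_sequences)

    @property
    def passed(self) -> bool:
        return not self.filter_status

    def key(self) -> tuple:
        return (self.chrom, self.strand, self.acceptor_pos, self.donor_pos)


class GenomeIndex:
    """Exhaustive Hamming-scan anchor aligner over a small genome."""

    def __init__(self, genome: dict[str, str]):
        self.genome = genome
        self._arrays = {
            chrom: np.frombuffer(seq.encode(), dtype=np.uint8)
            for chrom, seq in genome.items()
        }

    def _match_counts(self, anchor: str, chrom_arr: np.ndarray) -> np.ndarray:
        k = len(anchor)
        n = len(chrom_arr) - k + 1
        if n <= 0:
            return np.zeros(0, dtype=np.int16)
        counts = np.zeros(n, dtype=np.int16)
        a = np.frombuffer(anchor.encode(), dtype=np.uint8)
        for j in range(k):
            counts += chrom_arr[j : j + n] == a[j]
        return counts

    def align(self, read_id: str, side: str, anchor: str) -> AnchorHit:
        """Best locus of an anchor on either strand, with uniqueness margin.

        All loci are scored by exact match count; ``is_unique`` requires a
        single full-length best locus, and ``score_margin`` is best minus
        second-best over every other locus on both strands.
        """
        k = len(anchor)
        best: list[tuple[int, str, int, str]] = []  # (score, chrom, pos, strand)
        second = 0
        n_best = 0
        rc = revcomp(anchor)
        for chrom, arr in self._arrays.items():
            for strand, query in (("+", anchor), ("-", rc)):
                counts = self._match_counts(query, arr)
                if len(counts) == 0:
                    continue
                top = int(counts.max())
                n_top = int((counts == top).sum())
                runner = int(counts[counts < top].max()) if n_top < len(counts) else 0
                if not best or top > best[0][0]:
                    if best:
                        second = max(second, best[0][0])
                    pos = int(np.flatnonzero(counts == top)[0])
                    best = [(top, chrom, pos, strand)]
                    n_best = n_top
                    second = max(second, runner)
                elif top == best[0][0]:
                    n_best += n_top
                    second = max(second, top)
                else:
                    second = max(second, top)
        if not best:
            return AnchorHit(read_id, side, None, False, 0)
        score, chrom, pos, strand = best[0]
        unique = score == k and n_best == 1
        margin = score - second if n_best == 1 else 0
        interval = GenomicInterval(chrom, pos, pos + k, strand)
        return AnchorHit(read_id, side, interval, unique, margin)


def split_anchors(seq: str, anchor_len: int = 20) -> Optional[tuple[str, str]]:
    """First and last ``anchor_len`` bases of a read; None when too short."""
    if len(seq) < 2 * anchor_len:
        return None
    return seq[:anchor_len], seq[-anchor_len:]


def _extend(read: str, genome_seq: str, head_pos: int, tail_end: int, anchor_len: int):
    """Maximal inward extensions of both anchors against the genome.

    Returns ``(e_head, e_tail)``: the longest prefix of the read matching
    the genome from ``head_pos`` and the longest suffix matching up to
    ``tail_end``.
    """
    L = len(read)
    e_head = 0
    while e_head < L and head_pos + e_head < len(genome_seq) and read[e_head] == genome_seq[head_pos + e_head]:
        e_head += 1
    e_tail = 0
    while e_tail < L and tail_end - 1 - e_tail >= 0 and read[L - 1 - e_tail] == genome_seq[tail_end - 1 - e_tail]:
        e_tail += 1
    return e_head, e_tail


def detect_junction(
    head: AnchorHit,
    tail: AnchorHit,
    read: str,
    genome: dict[str, str],
    config: CircConfig | None = None,
) -> Optional[BackspliceJunction]:
    """Resolve one read's anchors into a back-splice junction, or None.

    Requires unique anchors on a single chromosome and strand in
    head-to-tail order (head anchor genomically downstream of the tail
    anchor on the + strand).  The breakpoint pair is chosen to place GT
    after the donor and AG before the acceptor; if no GT-AG placement
    exists in the ambiguity window, the leftmost consistent pair is used
    with ``splice_signal="other"``.
    """
    cfg = config or CircConfig()
    if head.interval is None or tail.interval is None:
        return None
    if not (head.is_unique and tail.is_unique):
        return None
    hiv, tiv = head.interval, tail.interval
    if hiv.chrom != tiv.chrom or hiv.strand != tiv.strand:
        return None
    strand = hiv.strand
    if strand == "-":
        # work in the + frame of the reverse-complemented read: its head
        # anchor is the revcomp of this read's tail anchor and vice versa
        rc = revcomp(read)
        head_f = AnchorHit(head.read_id, "head", GenomicInterval(tiv.chrom, tiv.start, tiv.end, "+"), True, tail.score_margin)
        tail_f = AnchorHit(tail.read_id, "tail", GenomicInterval(hiv.chrom, hiv.start, hiv.end, "+"), True, head.score_margin)
        j = _resolve_breakpoints(head_f, tail_f, rc, genome, cfg, fallback_strand="-")
        if j is not None:
            j.supporting_read_ids = {head.read_id}
            j.supporting_sequences = {read}
        return j
    return _resolve_breakpoints(head, tail, read, genome, cfg, fallback_strand="+")


def _resolve_breakpoints(
    head: AnchorHit,
    tail: AnchorHit,
    read: str,
    genome: dict[str, str],
    cfg: CircConfig,
    fallback_strand: str,
) -> Optional[BackspliceJunction]:
    """Pick the breakpoint pair; the splice signal decides the circle strand.

    For an unstranded library the anchors' mapping strand says nothing
    about the circle's transcriptional strand; the genomic dinucleotides
    do: GT after the donor with AG before the acceptor marks a + strand
    junction, the reverse complement CT/AC marks a - strand one.  GT-AG is
    preferred over CT-AC, both over no signal; remaining ties break to the
    leftmost donor.  Without any signal the anchor strand is kept.
    """
    hiv, tiv = head.interval, tail.interval
    if hiv.start <= tiv.start:
        return None  # linear order: not a back-splice
    seq = genome[hiv.chrom]
    L = len(read)
    a = cfg.anchor_len
    head_pos = hiv.start
    tail_end = tiv.end
    e_head, e_tail = _extend(read, seq, head_pos, tail_end, a)
    if e_head + e_tail < L:
        return None  # read not fully explained by two segments
    s_lo, s_hi = L - e_tail, e_head  # valid split offsets within the read
    candidates = []
    for s in range(s_lo, s_hi + 1):
        donor = head_pos + s
        acceptor = tail_end - (L - s)
        if acceptor >= donor:
            continue
        if seq[donor : donor + 2] == "GT" and seq[acceptor - 2 : acceptor] == "AG":
            rank = 0  # + strand signal
        elif seq[donor : donor + 2] == "CT" and seq[acceptor - 2 : acceptor] == "AC":
            rank = 1  # - strand signal
        else:
            rank = 2
        candidates.append((rank, donor, acceptor, s))
    if not candidates:
        return None
    candidates.sort()
    rank, donor, acceptor, _s = candidates[0]
    strand = {0: "+", 1: "-", 2: fallback_strand}[rank]
    return BackspliceJunction(
        chrom=hiv.chrom,
        strand=strand,
        acceptor_pos=acceptor,
        donor_pos=donor,
        supporting_read_ids={head.read_id},
        supporting_sequences={read},
        splice_signal="GT-AG" if rank < 2 else "other",
        anchor_margin=min(head.score_margin, tail.score_margin),
    )


def detect_junctions(
    reads: Iterable[tuple[str, str]],
    genome: dict[str, str],
    config: CircConfig | None = None,
    index: GenomeIndex | None = None,
) -> tuple[list[BackspliceJunction], dict[str, int]]:
    """Detect and aggregate junctions over a stream of (read_id, seq).

    Identical read sequences supporting the same junction collapse to one
    "unique read".  Returns the junction list and a counter dictionary of
    skipped/discarded read categories.
    """
    cfg = config or CircConfig()
    idx = index or GenomeIndex(genome)
    stats = {"short": 0, "no_anchor_hit": 0, "non_unique_anchor": 0, "discordant": 0, "linear_or_unresolved": 0, "junction_reads": 0}
    pool: dict[tuple, BackspliceJunction] = {}
    for read_id, seq in reads:
        anchors = split_anchors(seq, cfg.anchor_len)
        if anchors is None:
            stats["short"] += 1
            continue
        head = idx.align(read_id, "head", anchors[0])
        tail = idx.align(read_id, "tail", anchors[1])
        if head.interval is None or tail.interval is None:
            stats["no_anchor_hit"] += 1
            continue
        if not (head.is_unique and tail.is_unique):
            stats["non_unique_anchor"] += 1
            continue
        if head.interval.chrom != tail.interval.chrom or head.interval.strand != tail.interval.strand:
            stats["discordant"] += 1
            continue
        j = detect_junction(head, tail, seq, genome, cfg)
        if j is None:
            stats["linear_or_unresolved"] += 1
            continue
        stats["junction_reads"] += 1
        key = j.key()
        if key in pool:
            pool[key].supporting_read_ids.update(j.supporting_read_ids)
            pool[key].supporting_sequences.update(j.supporting_sequences)
            pool[key].anchor_margin = max(pool[key].anchor_margin, j.anchor_margin)
        else:
            pool[key] = j
    return sorted(pool.values(), key=lambda j: j.key()), stats


def filter_junctions(
    junctions: Sequence[BackspliceJunction], config: CircConfig | None = None
) -> list[BackspliceJunction]:
    """Apply the unique-read / anchor-quality / span filters.

    Failures are recorded in ``filter_status`` rather than dropped, so that
    reporting can show why each candidate fell out.
    """
    cfg = config or CircConfig()
    for j in junctions:
        j.filter_status = set()
        if j.n_unique_reads < cfg.min_reads:
            j.filter_status.add("min_reads")
        if j.anchor_margin < cfg.min_anchor_margin:
            j.filter_status.add("anchor_quality")
        if j.span >= cfg.max_span:
            j.filter_status.add("max_span")
    return list(junctions)


def backsplice_probe(
    junction: BackspliceJunction, genome: dict[str, str], probe_len: int = 80
) -> tuple[str, bool]:
    """The back-spliced verification probe and a truncation flag.

    The probe is the last ``probe_len/2`` nt before the donor breakpoint
    followed by the first ``probe_len/2`` nt from the acceptor breakpoint
    (head-to-tail order); when a breakpoint sits closer than half a probe to
    a contig end, both halves are truncated symmetrically and the flag set.
    """
    seq = genome[junction.chrom]
    half = probe_len // 2
    left_avail = min(half, junction.donor_pos)
    right_avail = min(half, len(seq) - junction.acceptor_pos)
    use = min(left_avail, right_avail)
    probe = (
        seq[junction.donor_pos - use : junction.donor_pos]
        + seq[junction.acceptor_pos : junction.acceptor_pos + use]
    )
    return probe, use < half


def verify_junction(
    junction: BackspliceJunction,
    raw_reads: Iterable[str],
    genome: dict[str, str],
    config: CircConfig | None = None,
) -> bool:
    """Search the raw reads for the 80-bp back-spliced probe.

    Verified when at least one raw read contains the probe (either
    orientation) within ``probe_max_mismatch`` edits.
    """
    cfg = config or CircConfig()
    probe, truncated = backsplice_probe(junction, genome, cfg.probe_len)
    junction.probe_truncated = truncated
    probes = (probe, revcomp(probe))
    for seq in raw_reads:
        for p in probes:
            res = edlib.align(p, seq, mode="HW", task="distance", k=cfg.probe_max_mismatch)
            if res["editDistance"] != -1:
                junction.verified = True
                return True
    junction.verified = False
    return False


def detect_in_samples(
    fastq_reads_by_sample: dict[str, list[tuple[str, str]]],
    genome: dict[str, str],
    config: CircConfig | None = None,
):
    """Detect junctions per sample and merge into a cohort-level table.

    Returns ``(junctions, per_sample_counts)`` where the counts map
    ``junction key -> {sample: n unique supporting reads}``.  Filtering uses
    the pooled unique-read support.
    """
    cfg = config or CircConfig()
    idx = GenomeIndex(genome)
    merged: dict[tuple, BackspliceJunction] = {}
    per_sample: dict[tuple, dict[str, int]] = {}
    for sample_id, reads in fastq_reads_by_sample.items():
        junctions, _stats = detect_junctions(reads, genome, cfg, index=idx)
        for j in junctions:
            key = j.key()
            if key in merged:
                merged[key].supporting_read_ids.update(j.supporting_read_ids)
                merged[key].supporting_sequences.update(j.supporting_sequences)
                merged[key].anchor_margin = max(merged[key].anchor_margin, j.anchor_margin)
            else:
                merged[key] = j
            per_sample.setdefault(key, {})[sample_id] = j.n_unique_reads
    junctions = filter_junctions(sorted(merged.values(), key=lambda j: j.key()), cfg)
    return junctions, per_sample


def quantify_bss(
    junctions: Sequence[BackspliceJunction],
    per_sample_counts: dict[tuple, dict[str, int]],
    linear_mapped_by_sample: dict[str, int],
):
    """Per-sample BSS-spanning read counts with per-million normalization.

    Counts are unique supporting reads per (junction, sample); the
    normalized value is reads per million linearly mapped reads of that
    sample.
    """
    import pandas as pd

    rows = []
    for j in junctions:
        counts = per_sample_counts.get(j.key(), {})
        for sample_id, total in linear_mapped_by_sample.items():
            n = counts.get(sample_id, 0)
            rows.append(
                {
                    "circ_id": f"{j.chrom}:{j.acceptor_pos}-{j.donor_pos}({j.strand})",
                    "chrom": j.chrom,
                    "acceptor_pos": j.acceptor_pos,
                    "donor_pos": j.donor_pos,
                    "strand": j.strand,
                    "sample_id": sample_id,
                    "bss_reads": n,
                    "bss_reads_per_million": 1e6 * n / total if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def junctions_to_frame(junctions: Sequence[BackspliceJunction], annotation=None):
    """Junction table (TSV-ready); optionally annotated with host/origin."""
    import pandas as pd

    rows = []
    for j in junctions:
        row = {
            "chrom": j.chrom,
            "acceptor_pos": j.acceptor_pos,
            "donor_pos": j.donor_pos,
            "strand": j.strand,
            "span": j.span,
            "n_unique_reads": j.n_unique_reads,
            "splice_signal": j.splice_signal,
            "anchor_margin": j.anchor_margin,
            "verified": j.verified,
            "filters": ",".join(sorted(j.filter_status)) or "PASS",
        }
        if annotation is not None:
            origin = annotation.annotate_circ_origin(j)
            row["host_gene"] = origin.host_gene or ""
            row["origin_class"] = origin.origin_class
        rows.append(row)
    return pd.DataFrame(rows)
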