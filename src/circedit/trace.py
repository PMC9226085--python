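"""A-to-I quantification from Sanger-clone sequences.

Each clone is aligned to a supplied reference region with an affine-gap
local alignment (both strands are tried, best kept); the editing percentage
is the fraction of reference adenosine columns read as G within the aligned
span, matching the mini-gene / RIP readout "A-to-I (G) events over total
adenosine content".  Non-A>G mismatches are reported separately and never
enter the percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from circedit.io_formats import read_fasta, revcomp

GAP = "-"


@dataclass
class CloneAlignment:
    clone_id: str
    ref_aligned: str
    clone_aligned: str
    ref_start: int
    ref_end: int
    strand: str               # strand of the clone relative to the reference
    score: float
    identity: float
    n_adenosines_reference: int
    n_A_read_as_G: int
    n_other_mismatches: int

    def __post_init__(self):
        if len(self.ref_aligned) != len(self.clone_aligned):
            raise ValueError("aligned strings must have equal length")
        if self.n_A_read_as_G > self.n_adenosines_reference:
            raise ValueError("edited columns cannot exceed reference adenosines")


class AlignmentRejected(ValueError):
    """Clone did not reach the identity threshold against the reference."""


def _aligner(match: float = 1.0, mismatch: float = -1.0, gap_open: float = -2.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def align_clone(
    clone_seq: str,
    reference_seq: str,
    clone_id: str = "clone",
    min_identity: float = 0.7,
    min_coverage: float = 0.5,
    min_length: int = 50,
) -> CloneAlignment:
    """Local alignment of one clone to the reference region.

    Scoring: match +1, mismatch -1, gap open -2, gap extend -1; both
    orientations are tried and the better one kept; ties between co-optimal
    alignments break to the leftmost start.  A clone is rejected as
    non-matching when the alignment identity over its columns falls below
    ``min_identity`` or when fewer than ``min_coverage`` of the clone's
    bases take part in the local alignment (a short high-identity island in
    an otherwise unrelated sequence is not a matching clone).
    """
    clone_seq = clone_seq.upper()
    reference_seq = reference_seq.upper()
    if len(clone_seq) < min_length:
        raise AlignmentRejected(f"clone shorter than {min_length} nt")
    aligner = _aligner()
    best = None
    for strand, query in (("+", clone_seq), ("-", revcomp(clone_seq))):
        alns = aligner.align(reference_seq, query)
        if len(alns) == 0:
            continue
        aln = alns[0]  # Biopython orders co-optimal alignments deterministically
        if best is None or aln.score > best[1].score:
            best = (strand, aln)
    if best is None:
        raise AlignmentRejected("no alignment found")
    strand, aln = best
    ref_start, ref_end = int(aln.coordinates[0][0]), int(aln.coordinates[0][-1])
    ref_a, clone_a = _aligned_strings(aln)
    columns = len(ref_a)
    matches = sum(1 for r, c in zip(ref_a, clone_a) if r == c and r != GAP)
    identity = matches / columns if columns else 0.0
    if identity < min_identity:
        raise AlignmentRejected(f"identity {identity:.2f} below {min_identity}")
    aligned_clone_bases = sum(1 for c in clone_a if c != GAP)
    coverage = aligned_clone_bases / len(clone_seq)
    if coverage < min_coverage:
        raise AlignmentRejected(
            f"alignment covers only {coverage:.0%} of the clone (min {min_coverage:.0%})"
        )
    n_ref_A = sum(1 for r, c in zip(ref_a, clone_a) if r == "A" and c != GAP)
    n_AG = sum(1 for r, c in zip(ref_a, clone_a) if r == "A" and c == "G")
    n_other = sum(
        1
        for r, c in zip(ref_a, clone_a)
        if r != GAP and c != GAP and r != c and not (r == "A" and c == "G")
    )
    return CloneAlignment(
        clone_id=clone_id,
        ref_aligned=ref_a,
        clone_aligned=clone_a,
        ref_start=ref_start,
        ref_end=ref_end,
        strand=strand,
        score=float(aln.score),
        identity=identity,
        n_adenosines_reference=n_ref_A,
        n_A_read_as_G=n_AG,
        n_other_mismatches=n_other,
    )


def _aligned_strings(aln) -> tuple[str, str]:
    """Gapped target/query strings restricted to the aligned local span."""
    ref_parts, clone_parts = [], []
    coords = aln.coordinates
    target, query = aln.target, aln.query
    for i in range(coords.shape[1] - 1):
        t0, t1 = int(coords[0, i]), int(coords[0, i + 1])
        q0, q1 = int(coords[1, i]), int(coords[1, i + 1])
        if t1 > t0 and q1 > q0:
            ref_parts.append(str(target[t0:t1]))
            clone_parts.append(str(query[q0:q1]))
        elif t1 > t0:
            ref_parts.append(str(target[t0:t1]))
            clone_parts.append(GAP * (t1 - t0))
        else:
            ref_parts.append(GAP * (q1 - q0))
            clone_parts.append(str(query[q0:q1]))
    return "".join(ref_parts), "".join(clone_parts)


def editing_percent(alignment: CloneAlignment) -> float:
    """Percent of reference adenosine columns read as G.

    Gap columns at reference adenosines are excluded from the denominator;
    zero adenosines in the aligned span is undefined.
    """
    if alignment.n_adenosines_reference == 0:
        raise ValueError("no adenosines in aligned span: editing percent undefined")
    return 100.0 * alignment.n_A_read_as_G / alignment.n_adenosines_reference


def quantify_clones(
    clones: dict[str, str] | str,
    reference: str,
    min_identity: float = 0.7,
) -> pd.DataFrame:
    """Per-clone (plus pooled) A-to-I quantification table.

    ``clones`` is a {id: sequence} mapping or a FASTA path; ``reference``
    a sequence or FASTA path (first record).  Rejected clones appear with
    status "rejected"; the pooled row aggregates edited and adenosine
    counts over accepted clones.
    """
    if isinstance(clones, str):
        clones = read_fasta(clones)
    if isinstance(reference, str) and ("/" in reference or reference.endswith((".fa", ".fasta"))):
        reference = next(iter(read_fasta(reference).values()))
    rows = []
    tot_A = tot_G = 0
    for cid, seq in clones.items():
        try:
            aln = align_clone(seq, reference, clone_id=cid, min_identity=min_identity)
        except AlignmentRejected as exc:
            rows.append(
                {"clone_id": cid, "status": "rejected", "identity": np.nan,
                 "n_A": 0, "n_A_to_G": 0, "n_other_mismatches": 0, "percent_A_to_I": np.nan,
                 "note": str(exc)}
            )
            continue
        tot_A += aln.n_adenosines_reference
        tot_G += aln.n_A_read_as_G
        rows.append(
            {
                "clone_id": cid,
                "status": "ok",
                "identity": aln.identity,
                "n_A": aln.n_adenosines_reference,
                "n_A_to_G": aln.n_A_read_as_G,
                "n_other_mismatches": aln.n_other_mismatches,
                "percent_A_to_I": editing_percent(aln),
                "note": "",
            }
        )
    rows.append(
        {
            "clone_id": "POOLED",
            "status": "ok" if tot_A else "empty",
            "identity": np.nan,
            "n_A": tot_A,
            "n_A_to_G": tot_G,
            "n_other_mismatches": sum(r["n_other_mismatches"] for r in rows),
            "percent_A_to_I": 100.0 * tot_G / tot_A if tot_A else np.nan,
            "note": "pooled over accepted clones",
        }
    )
    return pd.DataFrame(rows)
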