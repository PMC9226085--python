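"""Back-splice detection: anchors, breakpoints, filters, verification."""

import numpy as np
import pytest

from circedit import circ as circmod
from circedit.circ import (
    BackspliceJunction,
    CircConfig,
    GenomeIndex,
    backsplice_probe,
    detect_junctions,
    filter_junctions,
    split_anchors,
    verify_junction,
)
from circedit.io_formats import revcomp
from circedit.synthetic import CircPlan, SimulationConfig, build_genome, simulate_rna_reads


@pytest.fixture(scope="module")
def circ_data():
    """Error-free single-sample dataset with exact junction read counts."""
    cfg = SimulationConfig(
        seed=13, seq_error_rate=0.0, n_samples_per_group=1, circ_reads_exact=True,
        circ_plan=[CircPlan(g, 1, 3, {"control": 4.0, "HF": 4.0}) for g in range(4)],
    )
    genome, genes, repeats, _v, manifest = build_genome(cfg)
    linear, fastq = simulate_rna_reads(genome, genes, manifest, cfg, "control_1")
    return cfg, genome, genes, manifest, linear, fastq


class TestSplitAnchors:
    def test_hundred_nt_read(self):
        seq = "".join("ACGT"[i % 4] for i in range(100))
        head, tail = split_anchors(seq, 20)
        assert head == seq[:20] and tail == seq[80:]

    def test_short_read_skipped(self):
        assert split_anchors("A" * 39, 20) is None
        assert split_anchors("A" * 40, 20) is not None


class TestAlignAnchor:
    GENOME = {
        "chr1": "ATGCATTACGGATCCGATTACAGGCATCGATCGGCTAGCTAACGTTACGGATACCGGTTAACCGGTTAA"
        "CCTTGGAACCTTGGAATTCCGGAATTCCGGAGGATCCTTAAGGCCTTAAGGCCAATTGGCCAATTGGCC"
    }

    def test_unique_hit(self):
        idx = GenomeIndex(self.GENOME)
        anchor = self.GENOME["chr1"][10:30]
        hit = idx.align("r", "head", anchor)
        assert hit.is_unique and hit.interval.start == 10 and hit.interval.strand == "+"
        assert hit.score_margin >= 1

    def test_duplicated_anchor_not_unique(self):
        motif = "ACGTACGTTGCAGGTTCCAA"
        genome = {"c": "T" * 30 + motif + "G" * 30 + motif + "A" * 30}
        hit = GenomeIndex(genome).align("r", "head", motif)
        assert not hit.is_unique and hit.score_margin == 0

    def test_reverse_strand_found_via_revcomp(self):
        idx = GenomeIndex(self.GENOME)
        anchor = revcomp(self.GENOME["chr1"][40:60])
        hit = idx.align("r", "tail", anchor)
        assert hit.is_unique and hit.interval.strand == "-"
        assert (hit.interval.start, hit.interval.end) == (40, 60)


class TestDetectJunctions:
    def test_planted_breakpoints_exact(self, circ_data):
        _cfg, genome, _genes, manifest, _linear, fastq = circ_data
        junctions, stats = detect_junctions(fastq, genome)
        got = {(j.chrom, j.acceptor_pos, j.donor_pos, j.strand) for j in junctions}
        want = {
            (j.chrom, j.acceptor_pos, j.donor_pos, j.strand) for j in manifest.junctions
        }
        assert got == want
        assert stats["junction_reads"] == len(fastq)
        assert all(j.splice_signal == "GT-AG" for j in junctions)
        assert all(j.n_unique_reads == 4 for j in junctions)

    def test_linear_read_yields_nothing(self, circ_data):
        _cfg, genome, genes, *_rest = circ_data
        exon = genes[0].transcripts[f"{genes[0].gene_id}.t1"][1]
        linear_like = [("lin", genome["chr1"][exon.start : exon.start + 100])]
        junctions, stats = detect_junctions(linear_like, genome)
        assert junctions == [] and stats["linear_or_unresolved"] == 1

    def test_repeat_read_discarded_as_non_unique(self, circ_data):
        _cfg, genome, _genes, manifest, *_rest = circ_data
        # a read from inside an Alu copy: its anchors occur near-identically
        # in every other copy, so the margin collapses and the read is dropped
        site = manifest.editing_sites[0]
        alu_read = [("alu", genome["chr1"][site.pos - 50 : site.pos + 50])]
        junctions, stats = detect_junctions(alu_read, genome)
        assert junctions == []
        assert stats["non_unique_anchor"] + stats["linear_or_unresolved"] == 1

    def test_strand_symmetry_under_genome_mirror(self, circ_data):
        """Reverse-complementing genome and reads mirrors every junction."""
        _cfg, genome, _genes, manifest, _linear, fastq = circ_data
        L = len(genome["chr1"])
        mirrored_genome = {"chr1": revcomp(genome["chr1"])}
        mirrored_reads = [(rid, revcomp(seq)) for rid, seq in fastq]
        junctions, _ = detect_junctions(mirrored_reads, mirrored_genome)
        got = {(j.acceptor_pos, j.donor_pos, j.strand) for j in junctions}
        want = {
            (L - j.donor_pos, L - j.acceptor_pos, "-" if j.strand == "+" else "+")
            for j in manifest.junctions
        }
        assert got == want

    def test_breakpoint_ambiguity_resolved_by_gt_ag(self):
        """With a shared homology at both breakpoints, every consistent
        breakpoint pair is enumerable; the detector must pick the GT-AG one."""
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        rand = lambda n: "".join(rng.choice(bases, n))
        homology = "CATG"
        exon_a = rand(60) + homology          # acceptor exon head region
        exon_d = rand(60) + homology          # donor exon tail region
        # layout: ... AG | exon_a ... exon_d | GT ...
        genome_seq = rand(100) + "AG" + exon_a + rand(40) + exon_d + "GT" + rand(100)
        genome = {"c": genome_seq}
        acceptor = 102                        # after the AG
        donor = 102 + len(exon_a) + 40 + len(exon_d)  # before the GT
        read = genome_seq[donor - 50 : donor] + genome_seq[acceptor : acceptor + 50]
        junctions, _ = detect_junctions([("r", read)], genome)
        assert len(junctions) == 1
        j = junctions[0]
        # oracle: enumerate all consistent splits by brute force
        consistent = []
        for s in range(0, 101):
            d, a = donor - 50 + s, acceptor + s - 50
            if read[:s] == genome_seq[d - s : d] and read[s:] == genome_seq[a : a + 100 - s]:
                consistent.append((d, a))
        assert len(consistent) > 1, "fixture must be ambiguous"
        gtag = [
            (d, a)
            for d, a in consistent
            if genome_seq[d : d + 2] == "GT" and genome_seq[a - 2 : a] == "AG"
        ]
        assert (j.donor_pos, j.acceptor_pos) == gtag[0] == (donor, acceptor)

    def test_duplicate_read_sequences_collapse(self, circ_data):
        _cfg, genome, _genes, manifest, _linear, fastq = circ_data
        doubled = fastq + [(rid + "_dup", seq) for rid, seq in fastq]
        junctions, _ = detect_junctions(doubled, genome)
        assert all(j.n_unique_reads == 4 for j in junctions)


class TestFilters:
    def _junction(self, n_reads=3, span=2000, margin=10):
        j = BackspliceJunction(
            chrom="c", strand="+", acceptor_pos=100, donor_pos=100 + span,
            supporting_sequences={f"s{i}" for i in range(n_reads)},
            supporting_read_ids={f"r{i}" for i in range(n_reads)},
            anchor_margin=margin,
        )
        return j

    @pytest.mark.parametrize(
        "kw,expected",
        [
            (dict(n_reads=1), {"min_reads"}),
            (dict(span=120_000), {"max_span"}),
            (dict(margin=1), {"anchor_quality"}),
            (dict(), set()),
            (dict(n_reads=1, span=120_000), {"min_reads", "max_span"}),
        ],
    )
    def test_filter_status(self, kw, expected):
        (j,) = filter_junctions([self._junction(**kw)])
        assert j.filter_status == expected
        assert j.passed == (not expected)


class TestVerification:
    def test_planted_junctions_verified(self, circ_data):
        _cfg, genome, _genes, manifest, _linear, fastq = circ_data
        junctions, _ = detect_junctions(fastq, genome)
        raw = [s for _, s in fastq]
        assert all(verify_junction(j, raw, genome) for j in junctions)

    def test_absent_junction_not_verified(self, circ_data):
        _cfg, genome, _genes, _manifest, _linear, fastq = circ_data
        fake = BackspliceJunction(chrom="chr1", strand="+", acceptor_pos=7, donor_pos=150)
        raw = [s for _, s in fastq]
        assert not verify_junction(fake, raw, genome)

    def test_probe_tolerates_two_mismatches(self, circ_data):
        _cfg, genome, _genes, manifest, _linear, fastq = circ_data
        junctions, _ = detect_junctions(fastq, genome)
        j = junctions[0]
        probe, _ = backsplice_probe(j, genome)
        read = probe[:30] + ("A" if probe[30] != "A" else "C") + probe[31:]
        read = read[:60] + ("G" if read[60] != "G" else "T") + read[61:]
        assert verify_junction(j, [read], genome)
        read3 = "".join(
            ("A" if c != "A" else "C") if i in (10, 40, 70) else c
            for i, c in enumerate(probe)
        )
        assert not verify_junction(j, [read3], genome, CircConfig(probe_max_mismatch=2))

    def test_probe_truncated_near_contig_edges(self, circ_data):
        _cfg, genome, *_ = circ_data
        # donor only 15 nt from the contig start: both halves shrink to 15
        j = BackspliceJunction(chrom="chr1", strand="+", acceptor_pos=5, donor_pos=15)
        probe, truncated = backsplice_probe(j, genome)
        assert truncated and len(probe) == 30
        L = len(genome["chr1"])
        j2 = BackspliceJunction(chrom="chr1", strand="+", acceptor_pos=L - 10, donor_pos=L - 5)
        probe2, truncated2 = backsplice_probe(j2, genome)
        assert truncated2 and len(probe2) == 20  # 10 per side


class TestQuantification:
    def test_counts_match_manifest_on_error_free_reads(self, circ_data):
        _cfg, genome, _genes, manifest, _linear, fastq = circ_data
        junctions, per_sample = circmod.detect_in_samples({"control_1": fastq}, genome)
        quant = circmod.quantify_bss(junctions, per_sample, {"control_1": 1000})
        for pj in manifest.junctions:
            cid = f"{pj.chrom}:{pj.acceptor_pos}-{pj.donor_pos}({pj.strand})"
            row = quant[(quant["circ_id"] == cid) & (quant["sample_id"] == "control_1")]
            assert int(row["bss_reads"].iloc[0]) == pj.reads["control_1"]

    def test_per_million_normalization(self, pipeline_result):
        quant = pipeline_result["quant"]
        linear = pipeline_result["linear_counts"]
        row = quant.iloc[0]
        expected = 1e6 * row["bss_reads"] / linear[row["sample_id"]]
        assert row["bss_reads_per_million"] == pytest.approx(expected)

    def test_absent_sample_counts_zero(self, circ_data):
        _cfg, genome, _genes, manifest, _linear, fastq = circ_data
        junctions, per_sample = circmod.detect_in_samples({"control_1": fastq}, genome)
        quant = circmod.quantify_bss(junctions, per_sample, {"control_1": 1000, "ghost": 1000})
        ghost = quant[quant["sample_id"] == "ghost"]
        assert (ghost["bss_reads"] == 0).all()
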