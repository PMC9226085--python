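"""Pileup, candidate calling, SNP exclusion, typing and summaries."""

import numpy as np
import pytest
from scipy import stats as sps

from circedit import editing as editmod
from circedit.annotation import GenomeAnnotation, Segment
from circedit.editing import (
    EditingConfig,
    EditingSite,
    Pileup,
    call_candidates,
    exclude_snps,
    mean_events_per_gene,
    per_position_profile,
    pileup,
    summarize_segments,
    type_substitution,
)
from circedit.io_formats import AlignedRead, GenomicInterval, VariantRecord
from circedit.synthetic import SimulationConfig, build_genome, simulate_rna_reads


def _read(rid, start, seq, cigar=None, mapq=60, quals=None):
    cigar = cigar or [("M", len(seq))]
    ref_len = sum(n for op, n in cigar if op in "MDN=X")
    return AlignedRead(
        rid,
        GenomicInterval("chr1", start, start + ref_len, "+"),
        seq,
        quals or [37] * len(seq),
        cigar,
        mapping_quality=mapq,
    )


class TestPileup:
    GENOME = {"chr1": "AACCGGTTAACCGGTTAACC"}

    def test_matches_brute_force_tally(self):
        """Counts equal a naive per-read, per-base tally on a mixed-CIGAR fixture."""
        reads = [
            _read("a", 0, "AACCGGTTAA"),
            _read("b", 2, "CCGGTTAACC"),
            _read("c", 4, "GGTAAACC", cigar=[("M", 6), ("D", 2), ("M", 2)]),  # del
            _read("d", 4, "GGXXTTAACC", cigar=[("M", 2), ("I", 2), ("M", 6)]),  # ins
            _read("e", 6, "TTTTAACC", cigar=[("S", 2), ("M", 6)]),  # clip
        ]
        cfg = EditingConfig(min_base_quality=0, edge_trim=0)
        pile = pileup(reads, self.GENOME, cfg)
        # naive oracle
        expected = {}
        for r in reads:
            q = 0
            ref = r.interval.start
            for op, n in r.cigar:
                if op in "M=X":
                    for i in range(n):
                        expected.setdefault(ref + i, {}).setdefault(
                            r.query_sequence[q + i], 0
                        )
                        expected[ref + i][r.query_sequence[q + i]] += 1
                    q += n
                    ref += n
                elif op in "IS":
                    q += n
                elif op in "DN":
                    ref += n
        for pos, bases in expected.items():
            col = pile.column("chr1", pos)
            for b, n in bases.items():
                assert col.counts[b] == n, (pos, b)
        total = int(pile.counts["chr1"].sum())
        assert total == sum(n for bases in expected.values() for n in bases.values())

    def test_low_mapping_quality_read_excluded(self):
        reads = [_read("ok", 0, "AACC"), _read("bad", 0, "AACC", mapq=5)]
        pile = pileup(reads, self.GENOME, EditingConfig(edge_trim=0))
        assert pile.column("chr1", 0).counts["A"] == 1

    def test_low_base_quality_excluded(self):
        reads = [_read("r", 0, "AACC", quals=[10, 37, 37, 37])]
        pile = pileup(reads, self.GENOME, EditingConfig(edge_trim=0))
        assert pile.column("chr1", 0).depth == 0
        assert pile.column("chr1", 1).depth == 1

    def test_edge_trim_drops_read_ends(self):
        reads = [_read("r", 0, "AACCGGTTAA")]
        pile = pileup(reads, self.GENOME, EditingConfig(edge_trim=2))
        assert pile.column("chr1", 0).depth == 0
        assert pile.column("chr1", 2).depth == 1
        assert pile.column("chr1", 9).depth == 0

    def test_unknown_reference_rejected(self):
        reads = [
            AlignedRead("r", GenomicInterval("chrX", 0, 4, "+"), "AAAA", [37] * 4, [("M", 4)], 60)
        ]
        with pytest.raises(ValueError):
            pileup(reads, self.GENOME)

    def test_depth_equals_sum_of_base_counts(self):
        reads = [_read("a", 0, "AACCGGTTAA"), _read("b", 0, "TACCGGTTAA")]
        pile = pileup(reads, self.GENOME, EditingConfig(edge_trim=0))
        col = pile.column("chr1", 0)
        assert col.depth == sum(col.counts.values()) == 2


def _pile_from_counts(ref: str, counts: dict[str, int]) -> Pileup:
    genome = {"chr1": ref}
    mat = np.zeros((4, len(ref)), dtype=np.int32)
    for base, n in counts.items():
        mat["ACGT".index(base), 0] = n
    return Pileup({"chr1": mat}, genome)


class TestCallCandidates:
    @pytest.mark.parametrize(
        "counts,expected_ratio",
        [
            ({"A": 15, "G": 5}, 0.25),     # clean candidate
            ({"A": 18, "G": 2}, None),     # below min_alt_reads
            ({"A": 11, "G": 5, "C": 4}, None),  # two alt bases: noise guard
            ({"A": 3, "G": 3}, None),      # rejected? depth 6 >= 5, noise 0 -> candidate
        ],
    )
    def test_rule_enumeration(self, counts, expected_ratio):
        pile = _pile_from_counts("A", counts)
        sites = call_candidates(pile, EditingConfig())
        if expected_ratio is None and counts != {"A": 3, "G": 3}:
            assert sites == []
        elif counts == {"A": 3, "G": 3}:
            # exactly one strong alt, zero noise, depth 6: a valid candidate
            assert len(sites) == 1 and sites[0].editing_ratio == 0.5
        else:
            assert len(sites) == 1
            assert sites[0].editing_ratio == pytest.approx(expected_ratio)
            assert sites[0].alt_base == "G"

    def test_min_depth_enforced(self):
        pile = _pile_from_counts("A", {"A": 1, "G": 3})
        assert call_candidates(pile, EditingConfig(min_depth=5)) == []
        assert len(call_candidates(pile, EditingConfig(min_depth=4))) == 1

    def test_two_strong_alts_rejected_even_if_balanced(self):
        pile = _pile_from_counts("A", {"A": 20, "G": 5, "T": 5})
        assert call_candidates(pile, EditingConfig()) == []


class TestExcludeSnps:
    def _cand(self, pos=100, alt="G"):
        return EditingSite("chr1", pos, "A", alt, 10, 20, sample_id="s")

    def test_known_vcf_position_removed(self):
        known = [VariantRecord("chr1", 100, "A", "G")]
        kept, removed = exclude_snps([self._cand()], known, with_removed=True)
        assert kept == [] and removed[0].removed_by == "known_vcf"

    def test_dna_alt_fraction_removes_and_tags(self):
        genome = {"chr1": "A" * 200}
        mat = np.zeros((4, 200), dtype=np.int32)
        mat[0, 100] = 15  # A
        mat[2, 100] = 15  # G at 50%
        dna = Pileup({"chr1": mat}, genome)
        kept, removed = exclude_snps([self._cand()], [], dna, with_removed=True)
        assert kept == [] and removed[0].removed_by == "dna_check"

    def test_clean_dna_retains_candidate(self):
        genome = {"chr1": "A" * 200}
        mat = np.zeros((4, 200), dtype=np.int32)
        mat[0, 100] = 30  # ref only
        dna = Pileup({"chr1": mat}, genome)
        kept = exclude_snps([self._cand()], [], dna)
        assert len(kept) == 1

    def test_shallow_dna_is_not_evidence(self):
        genome = {"chr1": "A" * 200}
        mat = np.zeros((4, 200), dtype=np.int32)
        mat[0, 100] = 3
        mat[2, 100] = 3  # 50% alt but depth 6 < 10
        dna = Pileup({"chr1": mat}, genome)
        assert len(exclude_snps([self._cand()], [], dna)) == 1


class TestTypeSubstitution:
    @pytest.mark.parametrize(
        "ref,alt,sub,atoi",
        [
            ("A", "G", "A>G", True),
            ("T", "C", "T>C", True),
            ("C", "T", "C>T", False),
            ("G", "A", "G>A", False),
            ("A", "C", "A>C", False),
        ],
    )
    def test_classes(self, ref, alt, sub, atoi):
        assert type_substitution(ref, alt) == (sub, atoi)

    def test_identity_rejected(self):
        with pytest.raises(ValueError):
            type_substitution("A", "A")


class TestSummaries:
    def test_mean_and_count(self, built):
        _g, genes, *_ = built
        gene = genes[0]
        intron = gene.introns()[0]
        sites = [
            EditingSite("chr1", intron.start + i, "A", "G", e, 10,
                        gene_id=gene.gene_id, segment=Segment.INTRON)
            for i, e in enumerate((2, 3, 4))
        ]
        rows = summarize_segments(sites, genes)
        assert len(rows) == 1
        row = rows[0]
        assert row.n_sites == 3
        assert row.mean_editing_ratio == pytest.approx(0.3)
        assert row.segment == "intron"
        assert row.segment_length == sum(len(i) for i in gene.introns())

    def test_conservation_of_total_site_count(self, pipeline_result):
        genes = pipeline_result["genes"]
        for sid, sites in pipeline_result["sites_by_sample"].items():
            rows = summarize_segments(sites, genes)
            assert sum(r.n_sites for r in rows) == len(sites)

    def test_no_exon_row_for_intron_only_sites(self, built):
        _g, genes, *_ = built
        gene = genes[0]
        intron = gene.introns()[0]
        sites = [
            EditingSite("chr1", intron.start + 1, "A", "G", 5, 10,
                        gene_id=gene.gene_id, segment=Segment.INTRON)
        ]
        rows = summarize_segments(sites, genes)
        assert all(r.segment != "exon" for r in rows)


@pytest.fixture(scope="module")
def profiled():
    cfg = SimulationConfig(seed=21, n_genes=2, coverage=150,
                           n_samples_per_group=2, seq_error_rate=0.0)
    genome, genes, repeats, _v, manifest = build_genome(cfg)
    piles = {}
    for s in manifest.samples:
        linear, _ = simulate_rna_reads(genome, genes, manifest, cfg, s["sample_id"])
        piles[s["sample_id"]] = pileup(linear, genome, EditingConfig(edge_trim=0))
    return cfg, genome, repeats, manifest, piles


class TestPerPositionProfile:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_planted_rates_recovered_per_position(self, profiled, strand):
        cfg, genome, repeats, manifest, piles = profiled
        el = next(r for r in repeats if r.is_alu and r.interval.strand == strand)
        by_group = {
            "control": [piles[s["sample_id"]] for s in manifest.samples if s["group"] == "control"],
        }
        prof = per_position_profile(el, by_group, genome)["control"]
        iv = el.interval
        seq = genome["chr1"]
        if strand == "+":
            targets = [p for p in range(iv.start, iv.end) if seq[p] == "A"]
        else:
            targets = [p for p in range(iv.start, iv.end) if seq[p] == "T"][::-1]
        assert len(prof) == len(targets)
        planted = {
            s.pos: s.rates["control"]
            for s in manifest.editing_sites
            if iv.contains(s.chrom, s.pos)
        }
        assert planted, "element should carry planted sites"
        for idx, pos in enumerate(targets):
            rate = planted.get(pos, 0.0)
            n = 300  # ~2 samples x 150x
            lo, hi = sps.binom.interval(0.9999, n, rate) if rate > 0 else (0, 0)
            assert lo / n - 0.05 <= prof[idx] <= hi / n + 0.05, (pos, rate, prof[idx])

    def test_unedited_positions_near_zero(self, profiled):
        cfg, genome, repeats, manifest, piles = profiled
        el = next(r for r in repeats if r.is_alu)
        by_group = {"control": [next(iter(piles.values()))]}
        prof = per_position_profile(el, by_group, genome)["control"]
        planted_pos = {
            s.pos for s in manifest.editing_sites if el.interval.contains(s.chrom, s.pos)
        }
        iv = el.interval
        seq = genome["chr1"]
        base = "A" if iv.strand == "+" else "T"
        targets = [p for p in range(iv.start, iv.end) if seq[p] == base]
        if iv.strand == "-":
            targets = targets[::-1]
        for idx, pos in enumerate(targets):
            if pos not in planted_pos and np.isfinite(prof[idx]):
                assert prof[idx] == 0.0  # error-free run


class TestMeanEventsPerGene:
    def test_direction_and_exclusion(self, pipeline_result):
        df = mean_events_per_gene(
            pipeline_result["sites_by_sample"], pipeline_result["groups"]
        )
        # every gene carries planted editing halved in HF: all must be "reduced"
        assert set(df["direction"]) == {"reduced"}
        # a gene with no sites anywhere must not appear
        empty = mean_events_per_gene(
            {sid: [] for sid in pipeline_result["groups"]}, pipeline_result["groups"]
        )
        assert len(empty) == 0


class TestEditingSiteInvariants:
    def test_ratio_bounds_on_pipeline_output(self, pipeline_result):
        for sites in pipeline_result["sites_by_sample"].values():
            for s in sites:
                assert 0.0 <= s.editing_ratio <= 1.0
                assert s.edited_reads <= s.total_reads
                assert s.is_AtoI == (s.substitution_type in ("A>G", "T>C"))
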