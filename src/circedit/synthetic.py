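"""Miniature genome / RNA-seq / DNA-seq simulator with a truth manifest.

The generator emulates the study design of a total-RNA sequencing cohort of
two groups ("control" vs "HF"): genes with alternating exons and introns and
UTR flanks, ~300-nt adenosine-rich Alu-like elements inserted into chosen
introns on chosen strands, per-site A-to-I editing rates that are reduced in
the HF group, planted heterozygous SNPs, uniform pre-mRNA read coverage with
independent sequencing errors, matched DNA reads (never edited), and
back-splice-spanning reads for planted circRNAs that are emitted only to the
unmapped-read FASTQ.  Every planted quantity is recorded in a
machine-readable :class:`TruthManifest`, including the *realized* per-sample
edited/total read tallies and junction read counts, so downstream stages can
be tested for exact recovery.

All outputs are deterministic under the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from circedit import io_formats
from circedit.annotation import GeneModel, RepeatElement
from circedit.io_formats import AlignedRead, GenomicInterval, VariantRecord, revcomp

# ~300-nt Alu-like consensus: two GC-rich arms, an A-rich linker and a poly-A
# tail, giving the adenosine-rich sense strand that A-to-I editing targets.
ALU_CONSENSUS = (
    "GGCCGGGCGCGGTGGCTCACGCCTGTAATCCCAGCACTTTGGGAGGCCGAGGCGGGCGGATCACGAGGTC"
    "AGGAGATCGAGACCATCCCGGCTAAAACGGTGAAACCCCGTCTCTACTAAAAATACAAAAAATTAGCCGG"
    "GCGTGGTGGAAAAATACAAAAAACGGGCGCCTGTAGTCCCAGCTACTCGGGAGGCTGAGGCAGGAGAATG"
    "GCGTGAACCCGGGAGGCGGAGCTTGCAGTGAGCCGAGATCGCGCCACTGCACTCCAGCCTGGGCGACAAA"
    "AAAAAAAAAAAAAAAAAAA"
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_BASE = "ACGT"


def seq_to_arr(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    out = np.empty(arr.shape, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def arr_to_seq(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


class ConfigError(ValueError):
    pass


@dataclass
class AluPlacement:
    gene: int            # gene index
    intron: int          # intron index in transcript order (0-based)
    strand: str          # genomic strand of the inserted element
    family: str = "AluSx3"


@dataclass
class CircPlan:
    gene: int
    acceptor_exon: int   # transcript-order exon index forming the 5' BSS
    donor_exon: int      # transcript-order exon index forming the 3' BSS
    mean_reads: dict[str, float] = field(default_factory=lambda: {"control": 5.0, "HF": 20.0})


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the desk-scale conditions.

    The group design defaults to 4 control + 4 "HF" samples, a 0.5x
    multiplicative reduction of every planted editing rate in the HF group,
    and a 4x increase of back-splice read counts — the direction of the
    editing-down / circRNA-up pattern the pipeline is meant to recover.
    """

    seed: int = 0
    n_genes: int = 4
    exons_per_gene: int = 5
    exon_len: int = 200
    intron_len: int = 700
    utr_len: int = 150
    intergenic_len: int = 300
    alu_placements: Optional[list[AluPlacement]] = None  # None -> auto (2 per gene, +/-)
    other_repeats: bool = True          # plant one non-Alu (L1) element for context tests
    alu_divergence: float = 0.05
    sites_per_alu: int = 12
    editing_rate_range: tuple[float, float] = (0.1, 0.5)
    hf_editing_multiplier: float = 0.5
    snps_per_gene: int = 2
    circ_plan: Optional[list[CircPlan]] = None  # None -> auto (1 circle per gene)
    circ_reads_exact: bool = False      # exact planned counts instead of Poisson draws
    coverage: float = 50.0
    dna_coverage: float = 30.0
    read_len: int = 100
    seq_error_rate: float = 0.001
    n_samples_per_group: int = 4
    group_names: tuple[str, str] = ("control", "HF")
    base_quality: int = 37

    def __post_init__(self):
        if not 0.0 <= self.seq_error_rate <= 1.0:
            raise ConfigError("seq_error_rate must be in [0,1]")
        if not 0.0 <= self.alu_divergence <= 1.0:
            raise ConfigError("alu_divergence must be in [0,1]")
        lo, hi = self.editing_rate_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("editing_rate_range must be within [0,1]")
        if self.read_len < 2 * 20:
            raise ConfigError("read_len must be at least twice the anchor length (20)")

    @property
    def samples(self) -> list[tuple[str, str]]:
        """(sample_id, group) pairs, controls first."""
        out = []
        for group in self.group_names:
            for i in range(1, self.n_samples_per_group + 1):
                out.append((f"{group}_{i}", group))
        return out

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "alu_placements" in raw and raw["alu_placements"] is not None:
            raw["alu_placements"] = [AluPlacement(**p) for p in raw["alu_placements"]]
        if "circ_plan" in raw and raw["circ_plan"] is not None:
            raw["circ_plan"] = [CircPlan(**p) for p in raw["circ_plan"]]
        if "editing_rate_range" in raw:
            raw["editing_rate_range"] = tuple(raw["editing_rate_range"])
        if "group_names" in raw:
            raw["group_names"] = tuple(raw["group_names"])
        return cls(**raw)


@dataclass
class PlantedSite:
    """A planted A-to-I editing site, recorded genomically.

    ``strand`` is the sense strand of the host Alu: '+' sites appear as A>G
    on the genome, '-' sites as T>C.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    strand: str
    gene_id: str
    family: str
    rates: dict[str, float]
    realized: dict[str, dict[str, int]] = field(default_factory=dict)  # sample -> {edited,total}


@dataclass
class PlantedJunction:
    circ_id: str
    chrom: str
    strand: str
    acceptor_pos: int    # genomic left breakpoint (5' BSS on + strand)
    donor_pos: int       # genomic right breakpoint (3' BSS on + strand)
    gene_id: str
    mean_reads: dict[str, float]
    reads: dict[str, int] = field(default_factory=dict)           # realized per sample
    upstream_intron: Optional[tuple[int, int]] = None             # host-gene orientation
    downstream_intron: Optional[tuple[int, int]] = None


@dataclass
class TruthManifest:
    """Everything the generator planted; the oracle for all downstream tests."""

    samples: list[dict]                      # {sample_id, group, individual}
    editing_sites: list[PlantedSite]
    snps: list[dict]                         # {chrom,pos,ref,alt}
    junctions: list[PlantedJunction]
    genome_length: int = 0

    def groups(self) -> dict[str, str]:
        return {s["sample_id"]: s["group"] for s in self.samples}

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "samples": self.samples,
            "editing_sites": [dataclasses.asdict(s) for s in self.editing_sites],
            "snps": self.snps,
            "junctions": [dataclasses.asdict(j) for j in self.junctions],
            "genome_length": self.genome_length,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TruthManifest":
        with open(path) as fh:
            raw = json.load(fh)
        sites = [PlantedSite(**s) for s in raw["editing_sites"]]
        juncs = []
        for j in raw["junctions"]:
            for k in ("upstream_intron", "downstream_intron"):
                if j.get(k) is not None:
                    j[k] = tuple(j[k])
            juncs.append(PlantedJunction(**j))
        return cls(
            samples=raw["samples"],
            editing_sites=sites,
            snps=raw["snps"],
            junctions=juncs,
            genome_length=raw.get("genome_length", 0),
        )


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

CHROM = "chr1"


def _gene_sense_layout(cfg: SimulationConfig) -> tuple[list[tuple[int, int]], int]:
    """Exon spans in gene-sense coordinates; UTRs fold into terminal exons."""
    n, ex, inlen, utr = cfg.exons_per_gene, cfg.exon_len, cfg.intron_len, cfg.utr_len
    exons = []
    pos = 0
    for k in range(n):
        length = ex + (utr if k == 0 else 0) + (utr if k == n - 1 else 0)
        exons.append((pos, pos + length))
        pos += length
        if k < n - 1:
            pos += inlen
    return exons, pos


def build_genome(cfg: SimulationConfig):
    """Build the synthetic genome and all static annotation.

    Returns ``(genome: {chrom: seq}, genes, repeats, variants, manifest)``.
    Alu-like elements are a fixed consensus with per-copy random divergence,
    reverse-complemented for '-' placements; every intron starts with GT and
    ends with AG in gene-sense orientation; outputs are deterministic under
    ``cfg.seed``.
    """
    rng = np.random.default_rng([cfg.seed, 11])
    exon_layout, gene_len = _gene_sense_layout(cfg)
    n_introns = cfg.exons_per_gene - 1

    chrom_parts: list[np.ndarray] = []
    genes: list[GeneModel] = []
    pos = 0

    def rand_seq(n: int) -> np.ndarray:
        return rng.integers(0, 4, n, dtype=np.uint8)

    for gi in range(cfg.n_genes):
        pos += cfg.intergenic_len
        gstart = pos
        strand = "+" if gi % 2 == 0 else "-"
        biotype = "protein_coding" if gi % 4 != 3 else "lncRNA"
        sense = rand_seq(gene_len)
        # splice signals: intron starts GT, ends AG (gene sense)
        for (s, e), (s2, _) in zip(exon_layout, exon_layout[1:]):
            sense[e] = _BASE_INDEX["G"]
            sense[e + 1] = _BASE_INDEX["T"]
            sense[s2 - 2] = _BASE_INDEX["A"]
            sense[s2 - 1] = _BASE_INDEX["G"]
        block = sense if strand == "+" else seq_to_arr(revcomp(arr_to_seq(sense)))
        chrom_parts.append(block)

        if strand == "+":
            exons = [
                GenomicInterval(CHROM, gstart + s, gstart + e, strand)
                for s, e in exon_layout
            ]
        else:
            exons = [
                GenomicInterval(CHROM, gstart + gene_len - e, gstart + gene_len - s, strand)
                for s, e in reversed(exon_layout)
            ]
        gid = f"G{gi + 1}"
        cds = None
        if biotype == "protein_coding":
            cds = GenomicInterval(
                CHROM, gstart + cfg.utr_len, gstart + gene_len - cfg.utr_len, strand
            )
        genes.append(
            GeneModel(
                gene_id=gid,
                biotype=biotype,
                interval=GenomicInterval(CHROM, gstart, gstart + gene_len, strand),
                transcripts={f"{gid}.t1": exons},
                cds_span=cds,
            )
        )
        pos = gstart + gene_len
    pos += cfg.intergenic_len  # trailing spacer
    genome_len = pos
    # fill spacers with random sequence, then overwrite the gene spans
    rng_spacer = np.random.default_rng([cfg.seed, 12])
    arr = rng_spacer.integers(0, 4, genome_len, dtype=np.uint8)
    for g, block in zip(genes, chrom_parts):
        arr[g.interval.start : g.interval.end] = block

    # --- Alu / repeat insertion (genomic space) ---
    placements = cfg.alu_placements
    if placements is None:
        families = ["AluSx3", "AluSz", "AluY"]
        placements = []
        for gi in range(cfg.n_genes):
            placements.append(AluPlacement(gi, 0, "+", families[gi % 3]))
            placements.append(AluPlacement(gi, n_introns - 1, "-", families[(gi + 1) % 3]))

    repeats: list[RepeatElement] = []
    alu_len = len(ALU_CONSENSUS)
    consensus_arr = seq_to_arr(ALU_CONSENSUS)
    for pl in placements:
        gene = genes[pl.gene]
        introns = gene.introns()  # genomic order
        tr_idx = pl.intron if gene.interval.strand == "+" else n_introns - 1 - pl.intron
        intron = introns[tr_idx]
        if alu_len + 20 > len(intron):
            raise ConfigError(
                f"Alu placement exceeds intron length ({alu_len + 20} > {len(intron)})"
            )
        copy = consensus_arr.copy()
        div = rng.random(alu_len) < cfg.alu_divergence
        copy[div] = (copy[div] + rng.integers(1, 4, int(div.sum()))) % 4
        if pl.strand == "-":
            copy = seq_to_arr(revcomp(arr_to_seq(copy)))
        start = intron.start + (len(intron) - alu_len) // 2
        arr[start : start + alu_len] = copy
        repeats.append(
            RepeatElement(
                interval=GenomicInterval(CHROM, start, start + alu_len, pl.strand),
                family=pl.family,
            )
        )
    if cfg.other_repeats and genes:
        # one non-Alu element in the first intron's 5' half, clear of the Alu
        g0 = genes[0]
        intron = g0.introns()[0]
        l1_len = 120
        start = intron.start + 5
        arr[start : start + l1_len] = rng.integers(0, 4, l1_len, dtype=np.uint8)
        repeats.append(
            RepeatElement(GenomicInterval(CHROM, start, start + l1_len, "+"), "L1MA4")
        )

    # --- editing plan ---
    editing_sites: list[PlantedSite] = []
    occupied: set[int] = set()
    for pl, rep in zip(placements, repeats[: len(placements)]):
        gene = genes[pl.gene]
        iv = rep.interval
        target = _BASE_INDEX["A"] if pl.strand == "+" else _BASE_INDEX["T"]
        cand = np.flatnonzero(arr[iv.start : iv.end] == target) + iv.start
        cand = cand[(cand >= iv.start + 3) & (cand < iv.end - 3)]
        k = min(cfg.sites_per_alu, len(cand))
        chosen = np.sort(rng.choice(cand, size=k, replace=False))
        lo, hi = cfg.editing_rate_range
        for p in chosen:
            ctl = float(rng.uniform(lo, hi))
            rates = {
                cfg.group_names[0]: ctl,
                cfg.group_names[1]: min(1.0, ctl * cfg.hf_editing_multiplier),
            }
            ref, alt = ("A", "G") if pl.strand == "+" else ("T", "C")
            editing_sites.append(
                PlantedSite(CHROM, int(p), ref, alt, pl.strand, gene.gene_id, pl.family, rates)
            )
            occupied.add(int(p))

    # --- SNP plan (heterozygous, anywhere in the gene body) ---
    snps: list[dict] = []
    variants: list[VariantRecord] = []
    for gene in genes:
        placed = 0
        while placed < cfg.snps_per_gene:
            p = int(rng.integers(gene.interval.start, gene.interval.end))
            if p in occupied:
                continue
            ref = _IDX_BASE[arr[p]]
            alt = _IDX_BASE[(arr[p] + rng.integers(1, 4)) % 4]
            snps.append({"chrom": CHROM, "pos": p, "ref": ref, "alt": alt})
            variants.append(VariantRecord(CHROM, p, ref, alt, "known_vcf"))
            occupied.add(p)
            placed += 1

    # --- circRNA plan ---
    plan = cfg.circ_plan
    if plan is None:
        plan = [
            CircPlan(gi, 1, cfg.exons_per_gene - 2)
            for gi in range(cfg.n_genes)
        ]
    junctions: list[PlantedJunction] = []
    for ci, cp in enumerate(plan):
        gene = genes[cp.gene]
        exons = gene.transcripts[f"{gene.gene_id}.t1"]
        # transcripts store exons sorted by genomic start; map transcript
        # order -> genomic order through the gene strand
        if gene.interval.strand == "-":
            tr_exons = list(reversed(exons))
        else:
            tr_exons = exons
        acc_ex, don_ex = tr_exons[cp.acceptor_exon], tr_exons[cp.donor_exon]
        lo = min(acc_ex.start, don_ex.start)
        hi = max(acc_ex.end, don_ex.end)
        introns = gene.introns()
        left_i = next((iv for iv in reversed(introns) if iv.end <= lo), None)
        right_i = next((iv for iv in introns if iv.start >= hi), None)
        if gene.interval.strand == "-":
            up, down = right_i, left_i
        else:
            up, down = left_i, right_i
        junctions.append(
            PlantedJunction(
                circ_id=f"circ_{gene.gene_id}",
                chrom=CHROM,
                strand=gene.interval.strand,
                acceptor_pos=lo,
                donor_pos=hi,
                gene_id=gene.gene_id,
                mean_reads=dict(cp.mean_reads),
                upstream_intron=(up.start, up.end) if up else None,
                downstream_intron=(down.start, down.end) if down else None,
            )
        )

    samples = [
        {"sample_id": sid, "group": grp, "individual": sid}
        for sid, grp in cfg.samples
    ]
    manifest = TruthManifest(
        samples=samples,
        editing_sites=editing_sites,
        snps=snps,
        junctions=junctions,
        genome_length=genome_len,
    )
    genome = {CHROM: arr_to_seq(arr)}
    return genome, genes, repeats, variants, manifest


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _apply_errors(mat: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    mask = rng.random(mat.shape) < rate
    n = int(mask.sum())
    if n:
        mat[mask] = (mat[mask] + rng.integers(1, 4, n, dtype=np.uint8)) % 4


def _rows_to_reads(
    mat: np.ndarray, starts: np.ndarray, sample_id: str, tag: str, cfg: SimulationConfig
) -> list[AlignedRead]:
    L = mat.shape[1]
    quals = [cfg.base_quality] * L
    cigar = [("M", L)]
    order = np.argsort(starts, kind="stable")
    reads = []
    for rank, i in enumerate(order):
        reads.append(
            AlignedRead(
                read_id=f"{sample_id}.{tag}{rank}",
                interval=GenomicInterval(CHROM, int(starts[i]), int(starts[i]) + L, "+"),
                query_sequence=arr_to_seq(mat[i]),
                base_qualities=quals,
                cigar=cigar,
                mapping_quality=60,
            )
        )
    return reads


def simulate_rna_reads(
    genome: dict[str, str],
    genes: list[GeneModel],
    manifest: TruthManifest,
    cfg: SimulationConfig,
    sample_id: str,
) -> tuple[list[AlignedRead], list[tuple[str, str]]]:
    """Simulate one sample's RNA reads.

    Linear reads are drawn uniformly over each gene's contiguous pre-mRNA and
    returned as mapped records (pure-match CIGAR); back-splice reads spanning
    each planted circRNA head-to-tail joint are returned separately as
    unmapped FASTQ records and never appear among the linear reads.  Realized
    per-site edited/total tallies and per-junction read counts are recorded
    into the manifest.
    """
    groups = manifest.groups()
    if sample_id not in groups:
        raise ValueError(f"unknown sample {sample_id!r}")
    group = groups[sample_id]
    sample_index = [s["sample_id"] for s in manifest.samples].index(sample_id)
    rng = np.random.default_rng([cfg.seed, 100, sample_index])
    arr = seq_to_arr(genome[CHROM])
    L = cfg.read_len

    all_mats, all_starts = [], []
    for gene in genes:
        glen = len(gene.interval)
        n_reads = math.ceil(cfg.coverage * glen / L)
        starts = rng.integers(gene.interval.start, gene.interval.end - L + 1, n_reads)
        mat = arr[starts[:, None] + np.arange(L)[None, :]].copy()
        all_mats.append(mat)
        all_starts.append(starts)
    mat = np.concatenate(all_mats) if all_mats else np.empty((0, L), dtype=np.uint8)
    starts = np.concatenate(all_starts) if all_starts else np.empty(0, dtype=np.int64)

    def covering(pos: int) -> np.ndarray:
        return np.flatnonzero((starts <= pos) & (starts + L > pos))

    for site in manifest.editing_sites:
        rows = covering(site.pos)
        if len(rows):
            hit = rng.random(len(rows)) < site.rates[group]
            mat[rows[hit], site.pos - starts[rows[hit]]] = _BASE_INDEX[site.alt]
    for snp in manifest.snps:
        rows = covering(snp["pos"])
        if len(rows):
            hit = rng.random(len(rows)) < 0.5
            mat[rows[hit], snp["pos"] - starts[rows[hit]]] = _BASE_INDEX[snp["alt"]]
    _apply_errors(mat, cfg.seq_error_rate, rng)

    # realized tallies after all mutations: what the reads actually carry
    for site in manifest.editing_sites:
        rows = covering(site.pos)
        cols = site.pos - starts[rows]
        edited = int((mat[rows, cols] == _BASE_INDEX[site.alt]).sum())
        site.realized[sample_id] = {"edited": edited, "total": int(len(rows))}

    linear = _rows_to_reads(mat, starts, sample_id, "r", cfg)

    # back-splice reads -> unmapped FASTQ only
    fastq: list[tuple[str, str]] = []
    h_lo, h_hi = 25, L - 25
    gene_strand = {g.gene_id: g.interval.strand for g in genes}
    for j in manifest.junctions:
        mean = j.mean_reads[group]
        if cfg.circ_reads_exact:
            k = int(round(mean))
        else:
            k = int(rng.poisson(mean))
        k = min(k, h_hi - h_lo + 1)
        j.reads[sample_id] = k
        if k == 0:
            continue
        # the first read spans the joint centrally so the back-spliced
        # sequence (40 nt each side) is always observable in the raw reads;
        # the rest draw distinct offsets
        center = L // 2
        rest = np.arange(h_lo, h_hi + 1)
        rest = rest[rest != center]
        offsets = [center] + [int(o) for o in rng.choice(rest, size=k - 1, replace=False)]
        for bi, h in enumerate(sorted(offsets)):
            joint = arr_to_seq(
                np.concatenate(
                    [arr[j.donor_pos - h : j.donor_pos], arr[j.acceptor_pos : j.acceptor_pos + L - h]]
                )
            )
            if gene_strand.get(j.gene_id, j.strand) == "-":
                joint = revcomp(joint)
            jarr = seq_to_arr(joint)[None, :].copy()
            _apply_errors(jarr, cfg.seq_error_rate, rng)
            fastq.append((f"{sample_id}.bs.{j.circ_id}.{bi}", arr_to_seq(jarr[0])))
    return linear, fastq


def simulate_dna_reads(
    genome: dict[str, str],
    manifest: TruthManifest,
    cfg: SimulationConfig,
    individual: str,
) -> list[AlignedRead]:
    """Uniform whole-genome DNA reads for one individual.

    Heterozygous SNP alleles appear at rate 0.5; planted editing never does
    (DNA is not edited), so RNA-vs-DNA comparison can exclude true SNPs.
    """
    individuals = [s["individual"] for s in manifest.samples]
    if individual not in individuals:
        raise ValueError(f"unknown individual {individual!r}")
    rng = np.random.default_rng([cfg.seed, 200, individuals.index(individual)])
    arr = seq_to_arr(genome[CHROM])
    L = cfg.read_len
    n_reads = math.ceil(cfg.dna_coverage * len(arr) / L)
    starts = rng.integers(0, len(arr) - L + 1, n_reads)
    mat = arr[starts[:, None] + np.arange(L)[None, :]].copy()
    for snp in manifest.snps:
        rows = np.flatnonzero((starts <= snp["pos"]) & (starts + L > snp["pos"]))
        if len(rows):
            hit = rng.random(len(rows)) < 0.5
            mat[rows[hit], snp["pos"] - starts[rows[hit]]] = _BASE_INDEX[snp["alt"]]
    _apply_errors(mat, cfg.seq_error_rate, rng)
    return _rows_to_reads(mat, starts, individual, "d", cfg)


# ---------------------------------------------------------------------------
# cohort driver
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimulationConfig, outdir: str | os.PathLike) -> dict:
    """Generate the full dataset on disk and return a path dictionary.

    Writes genome.fa, genes.gtf, repeats.bed, snps.vcf, samples.tsv,
    per-sample ``rna_<sample>.sam`` / ``unmapped_<sample>.fastq``,
    per-individual ``dna_<individual>.sam`` and ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, repeats, variants, manifest = build_genome(cfg)
    contigs = {CHROM: manifest.genome_length}

    io_formats.write_fasta(genome, outdir / "genome.fa")
    io_formats.write_gtf(genes, outdir / "genes.gtf")
    io_formats.write_bed(repeats, outdir / "repeats.bed")
    io_formats.write_vcf(variants, contigs, outdir / "snps.vcf")

    paths = {
        "genome": str(outdir / "genome.fa"),
        "gtf": str(outdir / "genes.gtf"),
        "repeats": str(outdir / "repeats.bed"),
        "vcf": str(outdir / "snps.vcf"),
        "manifest": str(outdir / "manifest.json"),
        "samples": str(outdir / "samples.tsv"),
        "rna": {},
        "fastq": {},
        "dna": {},
    }
    with open(outdir / "samples.tsv", "w") as fh:
        fh.write("sample_id\tgroup\tindividual\n")
        for s in manifest.samples:
            fh.write(f"{s['sample_id']}\t{s['group']}\t{s['individual']}\n")

    for s in manifest.samples:
        sid = s["sample_id"]
        linear, fastq = simulate_rna_reads(genome, genes, manifest, cfg, sid)
        rna_path = outdir / f"rna_{sid}.sam"
        fq_path = outdir / f"unmapped_{sid}.fastq"
        io_formats.write_alignments(linear, contigs, rna_path)
        io_formats.write_fastq(fastq, fq_path, quality=cfg.base_quality)
        paths["rna"][sid] = str(rna_path)
        paths["fastq"][sid] = str(fq_path)
        dna = simulate_dna_reads(genome, manifest, cfg, s["individual"])
        dna_path = outdir / f"dna_{s['individual']}.sam"
        io_formats.write_alignments(dna, contigs, dna_path)
        paths["dna"][s["individual"]] = str(dna_path)

    manifest.to_json(outdir / "manifest.json")
    return {"paths": paths, "manifest": manifest, "genome": genome, "genes": genes, "repeats": repeats, "variants": variants}
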