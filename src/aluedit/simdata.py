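"""Synthetic reference, ground truth, and aligned-read simulation.

The generator builds a toy genome with gene-embedded Alu intervals, plants
A-to-I editing sites (adenosines within Alu elements, edited at
condition-dependent frequencies with a per-donor multiplicative scalar) and
heterozygous germline SNPs, and emits already-aligned single-end reads with
sequencing errors, pre-flagged PCR duplicates, secondary (multimapped)
records, and junction-spanning alignments. Everything downstream of
alignment is therefore testable offline against known truth.

Reads are emitted aligned by construction — alignment itself is out of
scope — so alignment coordinates are exact and the only noise sources are
the planted biology (editing, SNPs) and the per-base error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import CapacityError
from .readprep import AlignedRead, AlignedReadSet, encode_bases, write_sam

__all__ = [
    "GeneModel",
    "ReferenceBundle",
    "SimTruth",
    "SimParams",
    "make_reference",
    "plant_truth",
    "simulate_sample",
]

_BASES = "ACGT"
_COMPLEMENT_ALT = {"A": "G", "T": "C"}  # canonical edited base per reference base


@dataclass(frozen=True)
class GeneModel:
    """A gene: strand plus sorted, non-overlapping exon intervals
    (0-based half-open). The gene body spans first exon start to last exon
    end, introns included."""

    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = -1
        for s, e in self.exons:
            if not (prev_end <= s < e):
                raise ValueError(f"gene {self.gene_id}: exons must be sorted and non-overlapping")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class ReferenceBundle:
    """Toy (or real) genome plus Alu, gene, and SNP-mask annotations on
    shared coordinates.

    ``alu_intervals`` are (contig, start, end, strand, name) tuples, 0-based
    half-open; ``snp_mask`` holds (contig, pos0) positions of known variants
    excluded from editing calls. :func:`plant_truth` fills the mask from the
    planted SNPs, emulating a dbSNP-style database.
    """

    contigs: dict[str, str]
    alu_intervals: list[tuple[str, int, int, str, str]]
    genes: list[GeneModel]
    snp_mask: set[tuple[str, int]] = field(default_factory=set)

    def validate(self) -> None:
        for name, seq in self.contigs.items():
            if set(seq) - set("ACGTN"):
                raise ValueError(f"contig {name}: sequence contains non-ACGTN characters")
        for contig, start, end, strand, _ in self.alu_intervals:
            if not (0 <= start < end <= len(self.contigs[contig])):
                raise ValueError(f"Alu interval ({contig}, {start}, {end}) outside contig")
            if strand not in "+-":
                raise ValueError("Alu strand must be + or -")

    # ---- file writers (lossless round-trip with the readers below) ----

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_alu_bed(self, path: str | Path) -> None:
        """BED6, 0-based half-open."""
        with open(path, "w") as fh:
            for contig, start, end, strand, name in self.alu_intervals:
                fh.write(f"{contig}\t{start}\t{end}\t{name}\t0\t{strand}\n")

    def write_genes_gtf(self, path: str | Path, source: str = "aluedit_sim") -> None:
        """GTF, 1-based inclusive coordinates."""
        with open(path, "w") as fh:
            for gene in self.genes:
                attrs = f'gene_id "{gene.gene_id}";'
                fh.write(
                    f"{gene.contig}\t{source}\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )
                for i, (s, e) in enumerate(gene.exons, start=1):
                    fh.write(
                        f"{gene.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                        f'{attrs} exon_number "{i}";\n'
                    )

    def write_snp_vcf(self, path: str | Path, truth: "SimTruth | None" = None) -> None:
        """VCF v4.2 (1-based POS) of the known-SNP mask. If ``truth`` is
        given, REF/ALT/AF come from the planted SNPs; otherwise ALT is '.'"""
        alt_by_pos = {}
        if truth is not None:
            alt_by_pos = {
                (c, p): (alt, af) for c, p, alt, af in truth.snp_sites
            }
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction">\n')
            for name, seq in self.contigs.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for contig, pos0 in sorted(self.snp_mask):
                ref = self.contigs[contig][pos0]
                alt, af = alt_by_pos.get((contig, pos0), (".", None))
                info = f"AF={af:g}" if af is not None else "."
                fh.write(f"{contig}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")


@dataclass
class SimTruth:
    """Planted ground truth: editing sites with per-condition frequencies,
    heterozygous SNPs, and per-donor editing scalars."""

    edit_sites: list[tuple[str, int, str, dict[str, float]]]
    snp_sites: list[tuple[str, int, str, float]]
    donor_effects: dict[str, float] = field(default_factory=dict)

    def edit_positions(self) -> set[tuple[str, int]]:
        return {(c, p) for c, p, _, _ in self.edit_sites}

    def snp_positions(self) -> set[tuple[str, int]]:
        return {(c, p) for c, p, _, _ in self.snp_sites}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tcontig\tpos0\tref_or_alt\tdetail\n")
            for c, p, ref, freqs in self.edit_sites:
                detail = ",".join(f"{k}={v:g}" for k, v in sorted(freqs.items()))
                fh.write(f"edit\t{c}\t{p}\t{ref}\t{detail}\n")
            for c, p, alt, af in self.snp_sites:
                fh.write(f"snp\t{c}\t{p}\t{alt}\taf={af:g}\n")


@dataclass(frozen=True)
class SimParams:
    """Knobs of the read simulator.

    depth is the mean per-position coverage; rates are per-read (dup,
    multimap, junction) or per-base (error, low_baseq) probabilities. Base
    qualities are drawn uniformly from 30-40 with a ``low_baseq_rate``
    fraction in 10-24 so the base-quality filter has work to do. A fixed
    seed makes the output bit-for-bit reproducible.
    """

    depth: float = 50.0
    read_len: int = 100
    error_rate: float = 0.001
    dup_rate: float = 0.05
    multimap_rate: float = 0.05
    junction_rate: float = 0.1
    low_baseq_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "dup_rate", "multimap_rate", "junction_rate", "low_baseq_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.read_len < 1:
            raise ValueError("read_len must be positive")


def make_reference(
    n_genes: int,
    alu_per_gene: int = 2,
    alu_len: int = 300,
    seed: int = 0,
    *,
    gene_len: int = 5000,
    intergenic: int = 300,
    exons_per_gene: int = 3,
    contig_name: str = "chrS",
) -> ReferenceBundle:
    """Build a deterministic toy genome: ``n_genes`` genes laid end to end on
    one contig, each containing ``alu_per_gene`` Alu intervals of length
    ``alu_len`` fully inside the gene body.

    The sequence is uniform random ACGT, so roughly half of all Alu positions
    are adenosines/thymidines eligible to host editing sites or SNPs.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    if alu_per_gene < 1:
        raise ValueError(f"alu_per_gene must be >= 1, got {alu_per_gene}")
    if alu_len < 30:
        raise ValueError(f"alu_len must be >= 30, got {alu_len}")
    if gene_len < exons_per_gene * 200 or gene_len < alu_per_gene * (alu_len + 50):
        raise ValueError("gene_len too small to host the requested exons and Alu intervals")

    rng = np.random.default_rng(seed)
    total_len = intergenic + n_genes * (gene_len + intergenic)
    seq_codes = rng.integers(0, 4, size=total_len, dtype=np.uint8)
    seq = "".join(_BASES[c] for c in seq_codes)

    genes: list[GeneModel] = []
    alu_intervals: list[tuple[str, int, int, str, str]] = []
    exon_len = 200
    for g in range(n_genes):
        gstart = intergenic + g * (gene_len + intergenic)
        gend = gstart + gene_len
        # exons: first and last anchor the gene body; the rest evenly spaced
        anchors = np.linspace(gstart, gend - exon_len, exons_per_gene).astype(int)
        exons = tuple((int(a), int(a) + exon_len) for a in anchors)
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"G{g + 1:03d}"
        genes.append(GeneModel(gene_id=gene_id, contig=contig_name, strand=strand, exons=exons))
        # non-overlapping Alu placements inside the gene body
        slot = gene_len // alu_per_gene
        for a in range(alu_per_gene):
            lo = gstart + a * slot
            hi = gstart + (a + 1) * slot - alu_len
            start = int(rng.integers(lo, hi + 1))
            astrand = "+" if rng.random() < 0.5 else "-"
            alu_intervals.append(
                (contig_name, start, start + alu_len, astrand, f"AluY.{gene_id}.{a + 1}")
            )

    bundle = ReferenceBundle(
        contigs={contig_name: seq}, alu_intervals=alu_intervals, genes=genes
    )
    bundle.validate()
    return bundle


def plant_truth(
    ref: ReferenceBundle,
    n_edit_sites: int,
    freq_by_condition: Mapping[str, float],
    n_snps: int = 0,
    donor_scalars: Mapping[str, float] | None = None,
    seed: int = 0,
    allele_fraction: float = 0.5,
) -> SimTruth:
    """Plant editing sites and SNPs at distinct Alu A/T positions.

    Editing sites and SNPs are sampled without replacement from the A/T
    positions inside Alu intervals, so they are disjoint by construction —
    which is exactly what the SNP mask must enforce downstream. The planted
    SNP positions are installed into ``ref.snp_mask`` (the simulated
    known-variant database).
    """
    for cond, f in freq_by_condition.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"editing frequency for {cond!r} must lie in [0, 1], got {f}")
    if n_edit_sites < 0 or n_snps < 0:
        raise ValueError("site counts must be non-negative")

    rng = np.random.default_rng(seed)
    eligible: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    for contig, start, end, _, _ in ref.alu_intervals:
        seq = ref.contigs[contig]
        for pos in range(start, end):
            if seq[pos] in "AT" and (contig, pos) not in seen:
                eligible.append((contig, pos))
                seen.add((contig, pos))
    needed = n_edit_sites + n_snps
    if needed > len(eligible):
        raise CapacityError(
            f"requested {needed} sites but only {len(eligible)} Alu A/T positions available"
        )

    idx = rng.choice(len(eligible), size=needed, replace=False)
    chosen = [eligible[i] for i in idx]
    edit_sites = []
    for contig, pos in chosen[:n_edit_sites]:
        ref_base = ref.contigs[contig][pos]
        edit_sites.append((contig, pos, ref_base, dict(freq_by_condition)))
    snp_sites = []
    for contig, pos in chosen[n_edit_sites:]:
        ref_base = ref.contigs[contig][pos]
        alt = str(rng.choice([b for b in _BASES if b != ref_base]))
        snp_sites.append((contig, pos, alt, allele_fraction))

    truth = SimTruth(
        edit_sites=edit_sites,
        snp_sites=snp_sites,
        donor_effects=dict(donor_scalars or {}),
    )
    ref.snp_mask = truth.snp_positions()
    return truth


def simulate_sample(
    ref: ReferenceBundle,
    truth: SimTruth,
    condition: str,
    donor: str,
    params: SimParams,
    sam_path: str | Path | None = None,
) -> AlignedReadSet:
    """Simulate one sample's aligned reads.

    At every editing site each overlapping read carries the canonical edited
    base (G over reference A, C over reference T) with probability
    ``freq[condition] * donor_scalar``, so the edited-read count at a site of
    coverage c is Binomial(c, f*s) before errors. SNP positions carry the
    designated alt allele at the planted allele fraction. Sequencing errors
    substitute a uniformly chosen different base per base. Duplicates are
    exact flagged copies of primary reads; a ``multimap_rate`` fraction of
    reads is flagged secondary with MAPQ 1; a ``junction_rate`` fraction
    spans a simulated intron (N CIGAR gap of 50-500 bp).

    Returns the read set (coordinate-sorted) and, if ``sam_path`` is given,
    writes the identical records as SAM. ``mapped_reads`` counts primary,
    non-duplicate records.
    """
    if truth.edit_sites and any(condition not in f for _, _, _, f in truth.edit_sites):
        raise ValueError(f"condition {condition!r} missing from edit-site frequency maps")
    if truth.donor_effects:
        if donor not in truth.donor_effects:
            raise ValueError(f"unknown donor {donor!r}")
        donor_scalar = truth.donor_effects[donor]
    else:
        donor_scalar = 1.0

    rng = np.random.default_rng(params.seed)
    all_reads: list[AlignedRead] = []
    read_serial = 0

    for contig, seq in ref.contigs.items():
        L = len(seq)
        codes = encode_bases(seq)
        n_reads = int(round(params.depth * L / params.read_len))
        if n_reads == 0:
            continue
        rl = params.read_len

        # per-genome-position substitution channels (edit + SNP, disjoint)
        alt_code = np.zeros(L, dtype=np.uint8)
        alt_p = np.zeros(L, dtype=np.float64)
        for c, pos, ref_base, freqs in truth.edit_sites:
            if c != contig:
                continue
            p = min(max(freqs[condition] * donor_scalar, 0.0), 1.0)
            alt_p[pos] = p
            alt_code[pos] = _BASES.index(_COMPLEMENT_ALT[ref_base])
        for c, pos, alt, af in truth.snp_sites:
            if c != contig:
                continue
            alt_p[pos] = af
            alt_code[pos] = _BASES.index(alt)

        can_junction = rl >= 21 and L > rl + 500
        is_junc = (
            (rng.random(n_reads) < params.junction_rate)
            if can_junction
            else np.zeros(n_reads, dtype=bool)
        )
        k = np.where(is_junc, rng.integers(10, rl - 10, size=n_reads), rl)
        intron = np.where(is_junc, rng.integers(50, 501, size=n_reads), 0)
        span = rl + intron
        starts = np.floor(rng.random(n_reads) * (L - span + 1)).astype(np.int64)

        offsets = np.arange(rl, dtype=np.int64)
        pos = starts[:, None] + offsets[None, :] + intron[:, None] * (offsets[None, :] >= k[:, None])
        bases = codes[pos]

        sub_mask = rng.random((n_reads, rl)) < alt_p[pos]
        bases = np.where(sub_mask, alt_code[pos], bases)
        if params.error_rate > 0:
            err_mask = rng.random((n_reads, rl)) < params.error_rate
            shift = rng.integers(1, 4, size=(n_reads, rl), dtype=np.uint8)
            bases = np.where(err_mask, (bases + shift) % 4, bases)

        quals = rng.integers(30, 41, size=(n_reads, rl)).astype(np.int16)
        if params.low_baseq_rate > 0:
            low_mask = rng.random((n_reads, rl)) < params.low_baseq_rate
            lowq = rng.integers(10, 25, size=(n_reads, rl)).astype(np.int16)
            quals = np.where(low_mask, lowq, quals)

        reverse = rng.random(n_reads) < 0.5
        secondary = rng.random(n_reads) < params.multimap_rate
        dup_of = np.flatnonzero((~secondary) & (rng.random(n_reads) < params.dup_rate))

        base_chars = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in range(n_reads):
            read_serial += 1
            name = f"r{read_serial:07d}"
            seq_i = base_chars[bases[i]].tobytes().decode("ascii")
            if is_junc[i]:
                cigar = [("M", int(k[i])), ("N", int(intron[i])), ("M", rl - int(k[i]))]
            else:
                cigar = [("M", rl)]
            all_reads.append(
                AlignedRead(
                    name=name,
                    contig=contig,
                    pos0=int(starts[i]),
                    cigar=cigar,
                    seq=seq_i,
                    base_quals=quals[i],
                    mapq=1 if secondary[i] else 60,
                    secondary=bool(secondary[i]),
                    reverse=bool(reverse[i]),
                )
            )
        contig_offset = len(all_reads) - n_reads
        for i in dup_of:
            src = all_reads[contig_offset + int(i)]
            all_reads.append(
                AlignedRead(
                    name=src.name + ".dup",
                    contig=src.contig,
                    pos0=src.pos0,
                    cigar=list(src.cigar),
                    seq=src.seq,
                    base_quals=src.base_quals.copy(),
                    mapq=src.mapq,
                    secondary=False,
                    duplicate=True,
                    reverse=src.reverse,
                )
            )

    all_reads.sort(key=lambda r: (r.contig, r.pos0, r.name))
    mapped = sum(1 for r in all_reads if not r.secondary and not r.duplicate)
    readset = AlignedReadSet(
        reads=all_reads, mapped_reads=mapped, sample_id=f"{condition}_{donor}"
    )
    if sam_path is not None:
        write_sam(readset, sam_path, ref.contigs)
    return readset
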