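"""Alu-restricted pileups, A-to-I editing-site calls, and the Alu Editing
Index (AEI).

A-to-I editing is read out as A→G mismatches (or T→C on the antisense
representation) between reads and the reference. Classification is
reference-base-driven: a reference A column with G reads is an A→G event, a
reference T column with C reads is the same event observed on the opposite
strand; no read-strand inference is attempted. The AEI is the percentage of
A→G plus T→C mismatched bases among all informative bases — matches (A·A,
T·T) plus those mismatches — over every Alu A/T column, called site or not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .errors import UndefinedIndexError
from .readprep import (
    AlignedReadSet,
    AlignedSegment,
    FilterParams,
    filter_alignments,
    mask_read_start,
    split_junction_segments,
)

__all__ = [
    "PileupColumn",
    "EditingSite",
    "AEIComponents",
    "SampleEditome",
    "CallParams",
    "build_pileup",
    "accumulate_aei_components",
    "compute_aei",
    "call_editing_sites",
    "write_sites_vcf",
    "read_sites_vcf",
    "quantify_sample",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_EDITED_BASE = {"A": "G", "T": "C"}


@dataclass(frozen=True)
class PileupColumn:
    """Per-position base counts from filtered reads at one Alu position."""

    contig: str
    pos0: int
    ref_base: str
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class EditingSite:
    """A called A-to-I editing site in one sample."""

    contig: str
    pos0: int
    ref_base: str
    edited_base: str
    edited_count: int
    depth: int
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if (self.ref_base, self.edited_base) not in (("A", "G"), ("T", "C")):
            raise ValueError(
                f"({self.ref_base}->{self.edited_base}) is not a canonical A-to-I signature"
            )
        if not 0 < self.edited_count <= self.depth:
            raise ValueError("edited_count must satisfy 0 < edited_count <= depth")

    @property
    def freq(self) -> float:
        return self.edited_count / self.depth


@dataclass(frozen=True)
class AEIComponents:
    """The four AEI tallies: A→G and T→C mismatch bases, A·A and T·T match
    bases, summed over Alu columns. Additive under sample merging."""

    ag_mismatch: int = 0
    tc_mismatch: int = 0
    aa_match: int = 0
    tt_match: int = 0

    def __add__(self, other: "AEIComponents") -> "AEIComponents":
        return AEIComponents(
            self.ag_mismatch + other.ag_mismatch,
            self.tc_mismatch + other.tc_mismatch,
            self.aa_match + other.aa_match,
            self.tt_match + other.tt_match,
        )


@dataclass(frozen=True)
class CallParams:
    """Editing-site evidence thresholds.

    min_baseq mirrors the pileup's base-quality filter; min_coverage and
    min_edited_reads set the per-site evidence floor; columns whose
    non-canonical mismatch fraction exceeds ``max_other_mismatch_frac`` are
    treated as mapping artifacts and skipped.
    """

    min_coverage: int = 5
    min_edited_reads: int = 2
    min_baseq: int = 25
    max_other_mismatch_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.min_edited_reads > self.min_coverage:
            raise ValueError("min_edited_reads must not exceed min_coverage")


@dataclass
class SampleEditome:
    """One sample's called sites, AEI and mapped-read count."""

    sample_id: str
    condition: str | None
    donor: str | None
    sites: list[EditingSite]
    mapped_reads: int
    aei: float
    components: AEIComponents | None = None
    pileup: list[PileupColumn] | None = None


def build_pileup(
    segments: Iterable[AlignedSegment],
    alu_intervals: Iterable[tuple],
    reference: Mapping[str, str],
    min_baseq: int = 25,
) -> list[PileupColumn]:
    """Count bases per Alu position from filtered, split, masked segments.

    Bases below ``min_baseq`` (including start-masked bases, which carry a
    negative sentinel quality) are excluded. Positions outside Alu intervals
    are ignored; covered Alu positions whose reference base is N are skipped
    with a log message. Columns are sorted by (contig, pos0).
    """
    counts_by_contig: dict[str, np.ndarray] = {}
    alu_mask: dict[str, np.ndarray] = {}
    for iv in alu_intervals:
        contig, start, end = iv[0], int(iv[1]), int(iv[2])
        if contig not in alu_mask:
            alu_mask[contig] = np.zeros(len(reference[contig]), dtype=bool)
        alu_mask[contig][start:end] = True

    effective_min = max(int(min_baseq), 0)
    for seg in segments:
        mask = alu_mask.get(seg.contig)
        if mask is None:
            continue
        keep = (seg.quals >= effective_min) & (seg.bases < 4) & mask[seg.ref_pos]
        if not keep.any():
            continue
        if seg.contig not in counts_by_contig:
            counts_by_contig[seg.contig] = np.zeros(
                (4, len(reference[seg.contig])), dtype=np.int64
            )
        np.add.at(counts_by_contig[seg.contig], (seg.bases[keep], seg.ref_pos[keep]), 1)

    columns: list[PileupColumn] = []
    for contig in sorted(counts_by_contig):
        counts = counts_by_contig[contig]
        seq = reference[contig]
        covered = np.flatnonzero(counts.sum(axis=0) > 0)
        for pos in covered:
            ref_base = seq[pos]
            if ref_base == "N":
                logger.info("skipping column %s:%d with reference base N", contig, pos)
                continue
            columns.append(
                PileupColumn(
                    contig=contig,
                    pos0=int(pos),
                    ref_base=ref_base,
                    counts={b: int(counts[i, pos]) for i, b in enumerate(_BASES)},
                )
            )
    return columns


def accumulate_aei_components(pileup: Iterable[PileupColumn]) -> AEIComponents:
    """Sum the four AEI tallies over all Alu columns with reference A or T.

    Non-canonical mismatches (A→C, A→T, T→A, T→G) do not enter the index.
    """
    ag = tc = aa = tt = 0
    for col in pileup:
        if col.ref_base == "A":
            aa += col.counts["A"]
            ag += col.counts["G"]
        elif col.ref_base == "T":
            tt += col.counts["T"]
            tc += col.counts["C"]
    return AEIComponents(ag_mismatch=ag, tc_mismatch=tc, aa_match=aa, tt_match=tt)


def compute_aei(components: AEIComponents) -> float:
    """Alu Editing Index: 100 × (A→G + T→C) / (A·A + T·T + A→G + T→C).

    Raises :class:`UndefinedIndexError` when no informative base exists —
    an undefined index is not a zero index.
    """
    mism = components.ag_mismatch + components.tc_mismatch
    total = mism + components.aa_match + components.tt_match
    if total == 0:
        raise UndefinedIndexError("AEI undefined: no informative A/T bases in Alu regions")
    return 100.0 * mism / total


def call_editing_sites(
    pileup: Iterable[PileupColumn],
    snp_mask: set[tuple[str, int]],
    params: CallParams = CallParams(),
    sample_id: str | None = None,
) -> list[EditingSite]:
    """Call candidate A-to-I sites from a pileup.

    A site is emitted iff the reference base is A or T, the canonical edited
    base (G for A, C for T) is supported by at least ``min_edited_reads``,
    depth is at least ``min_coverage``, the position is not in the known-SNP
    mask, and the non-canonical mismatch fraction does not exceed
    ``max_other_mismatch_frac``.
    """
    sites: list[EditingSite] = []
    for col in pileup:
        edited_base = _EDITED_BASE.get(col.ref_base)
        if edited_base is None:
            continue
        depth = col.depth
        if depth < params.min_coverage:
            continue
        edited = col.counts[edited_base]
        if edited < params.min_edited_reads:
            continue
        if (col.contig, col.pos0) in snp_mask:
            continue
        other = depth - col.counts[col.ref_base] - edited
        if other > params.max_other_mismatch_frac * depth:
            continue
        sites.append(
            EditingSite(
                contig=col.contig,
                pos0=col.pos0,
                ref_base=col.ref_base,
                edited_base=edited_base,
                edited_count=edited,
                depth=depth,
                sample_id=sample_id,
            )
        )
    return sites


def write_sites_vcf(
    sites: Sequence[EditingSite],
    path: str | Path,
    contigs: Mapping[str, int] | Mapping[str, str],
    sample_id: str | None = None,
) -> None:
    """Write called sites as VCF v4.2 (POS is 1-based).

    INFO carries DP (pileup depth), EC (edited-read count) and EF
    (editing frequency). Round-trips through :func:`read_sites_vcf`.
    """
    header = pysam.VariantHeader()
    header.add_meta("source", "aluedit")
    if sample_id is None and sites:
        sample_id = sites[0].sample_id
    if sample_id is not None:
        header.add_meta("sample_id", sample_id)
    for name, val in contigs.items():
        header.contigs.add(name, length=val if isinstance(val, int) else len(val))
    header.info.add("DP", 1, "Integer", "Pileup depth at the site")
    header.info.add("EC", 1, "Integer", "Edited (mismatch) read count")
    header.info.add("EF", 1, "Float", "Editing frequency EC/DP")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sorted(sites, key=lambda s: (s.contig, s.pos0)):
            rec = out.new_record(
                contig=site.contig,
                start=site.pos0,
                stop=site.pos0 + 1,
                alleles=(site.ref_base, site.edited_base),
            )
            rec.info["DP"] = site.depth
            rec.info["EC"] = site.edited_count
            rec.info["EF"] = site.freq
            out.write(rec)


def read_sites_vcf(path: str | Path) -> list[EditingSite]:
    """Read a sites VCF written by :func:`write_sites_vcf` back into
    :class:`EditingSite` objects (frequency recomputed exactly as EC/DP)."""
    sites: list[EditingSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_id = None
        for rec_line in str(vcf.header).splitlines():
            if rec_line.startswith("##sample_id="):
                sample_id = rec_line.split("=", 1)[1]
        for rec in vcf:
            sites.append(
                EditingSite(
                    contig=rec.contig,
                    pos0=rec.start,
                    ref_base=rec.ref,
                    edited_base=rec.alts[0],
                    edited_count=int(rec.info["EC"]),
                    depth=int(rec.info["DP"]),
                    sample_id=sample_id,
                )
            )
    return sites


def read_snp_mask_vcf(path: str | Path) -> set[tuple[str, int]]:
    """Load a known-SNP VCF into the internal 0-based position mask."""
    mask: set[tuple[str, int]] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            mask.add((rec.contig, rec.start))
    return mask


def quantify_sample(
    reads: AlignedReadSet,
    reference: Mapping[str, str],
    alu_intervals: Iterable[tuple],
    snp_mask: set[tuple[str, int]],
    sample_id: str | None = None,
    condition: str | None = None,
    donor: str | None = None,
    filter_params: FilterParams = FilterParams(),
    call_params: CallParams = CallParams(),
    keep_pileup: bool = False,
) -> SampleEditome:
    """Run the full per-sample pipeline: filter reads, split junctions, mask
    read starts, build the Alu pileup, accumulate the AEI, and call sites."""
    alu_list = list(alu_intervals)
    filtered = filter_alignments(reads, filter_params)
    segments: list[AlignedSegment] = []
    for read in filtered:
        segments.extend(split_junction_segments(mask_read_start(read, filter_params.softclip_n)))
    pileup = build_pileup(segments, alu_list, reference, min_baseq=filter_params.min_baseq)
    components = accumulate_aei_components(pileup)
    aei = compute_aei(components)
    sid = sample_id or reads.sample_id or "sample"
    sites = call_editing_sites(pileup, snp_mask, call_params, sample_id=sid)
    return SampleEditome(
        sample_id=sid,
        condition=condition,
        donor=donor,
        sites=sites,
        mapped_reads=reads.mapped_reads,
        aei=aei,
        components=components,
        pileup=pileup if keep_pileup else None,
    )
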