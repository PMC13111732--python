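"""Alignment loading and the pre-pileup filtering cascade.

The editing pipeline consumes coordinate-sorted alignments and applies, in
order: removal of multimapped reads (secondary/supplementary flag or low
MAPQ), PCR-duplicate removal, splitting of junction-spanning reads at N
CIGAR operations, and masking of the first bases of each read in sequencing
orientation (random-hexamer priming artifacts). All coordinates are 0-based
half-open internally; conversions happen only at file boundaries.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam

from .errors import FormatError

__all__ = [
    "AlignedRead",
    "AlignedReadSet",
    "AlignedSegment",
    "FilterParams",
    "load_alignments",
    "write_sam",
    "filter_alignments",
    "split_junction_segments",
    "mask_read_start",
    "restrict_to_alu",
    "contributing_base_count",
]

# Base encoding used throughout: A=0, C=1, G=2, T=3, anything else=4.
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase

_CODE_BASE = "ACGTN"

#: Sentinel base quality marking a query base excluded from all pileups.
MASKED_QUAL = -1

_QUERY_OPS = frozenset("MIS")
_REF_OPS = frozenset("MDN")
_CIGAR_OP_FROM_PYSAM = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S", 5: "H", 7: "M", 8: "M"}


def encode_bases(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3,N/other=4)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(eq=False)
class AlignedRead:
    """One alignment record with the fields the filtering cascade needs.

    ``base_quals`` is an int16 array; the sentinel :data:`MASKED_QUAL` (-1)
    marks bases removed by :func:`mask_read_start` so they are skipped by
    every downstream pileup regardless of the base-quality threshold.
    """

    name: str
    contig: str
    pos0: int
    cigar: list[tuple[str, int]]
    seq: str
    base_quals: np.ndarray
    mapq: int
    secondary: bool = False
    duplicate: bool = False
    reverse: bool = False

    def __post_init__(self) -> None:
        self.base_quals = np.asarray(self.base_quals, dtype=np.int16)
        qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
        if qlen != len(self.seq) or len(self.seq) != len(self.base_quals):
            raise FormatError(
                f"read {self.name!r}: CIGAR query length {qlen}, sequence "
                f"length {len(self.seq)}, quality length {len(self.base_quals)} disagree"
            )
        if not 0 <= self.mapq <= 255:
            raise FormatError(f"read {self.name!r}: MAPQ {self.mapq} outside [0, 255]")

    @property
    def ref_end(self) -> int:
        """One past the rightmost reference position consumed by the alignment."""
        return self.pos0 + sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)

    def mean_base_quality(self) -> float:
        q = self.base_quals[self.base_quals >= 0]
        return float(q.mean()) if q.size else 0.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlignedRead):
            return NotImplemented
        return (
            self.name == other.name
            and self.contig == other.contig
            and self.pos0 == other.pos0
            and self.cigar == other.cigar
            and self.seq == other.seq
            and np.array_equal(self.base_quals, other.base_quals)
            and self.mapq == other.mapq
            and self.secondary == other.secondary
            and self.duplicate == other.duplicate
            and self.reverse == other.reverse
        )


@dataclass(eq=False)
class AlignedReadSet:
    """A collection of alignments plus the sample's mapped-read count.

    ``mapped_reads`` counts primary, non-duplicate, mapped records as seen at
    load (or simulation) time; it is the depth denominator for normalising
    editing-event counts and is deliberately *not* recomputed by
    :func:`filter_alignments`.
    """

    reads: list[AlignedRead]
    mapped_reads: int
    sample_id: str | None = None

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[AlignedRead]:
        return iter(self.reads)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlignedReadSet):
            return NotImplemented
        return (
            self.mapped_reads == other.mapped_reads
            and len(self.reads) == len(other.reads)
            and all(a == b for a, b in zip(self.reads, other.reads))
        )


@dataclass(eq=False)
class AlignedSegment:
    """A junction-free piece of one read: contiguous in reference space.

    ``ref_pos``, ``bases`` (uint8 codes) and ``quals`` are parallel arrays
    over the segment's aligned (M) bases, sorted by reference position.
    """

    read_name: str
    contig: str
    ref_start: int
    ref_end: int
    query_start: int
    ref_pos: np.ndarray
    bases: np.ndarray
    quals: np.ndarray

    def triples(self) -> list[tuple[int, str, int]]:
        """Per-base (ref_pos0, base, qual) triples, e.g. for hand inspection."""
        return [
            (int(p), _CODE_BASE[b], int(q))
            for p, b, q in zip(self.ref_pos, self.bases, self.quals)
        ]


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the pre-pileup filtering cascade.

    Defaults follow the pipeline's published settings: MAPQ >= 20,
    base quality >= 25, first 5 bases of each read masked.
    """

    min_mapq: int = 20
    min_baseq: int = 25
    softclip_n: int = 5
    drop_secondary: bool = True
    dedup: bool = True

    def __post_init__(self) -> None:
        if min(self.min_mapq, self.min_baseq, self.softclip_n) < 0:
            raise ValueError("filter thresholds must be non-negative")


def load_alignments(path: str | Path) -> AlignedReadSet:
    """Read a SAM/BAM file into an :class:`AlignedReadSet`.

    Unmapped records are skipped (they can contribute to no pileup).
    ``mapped_reads`` is the number of mapped, primary, non-duplicate records.

    Raises
    ------
    FormatError
        If the file lacks @SQ headers or a record is malformed (e.g. quality
        string length disagreeing with the sequence length).
    """
    path = Path(path)
    reads: list[AlignedRead] = []
    mapped = 0
    try:
        fh = pysam.AlignmentFile(str(path), "r", check_sq=True)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    with fh:
        try:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                if rec.cigartuples is None or rec.query_sequence is None:
                    raise FormatError(f"{path}: record {rec.query_name!r} lacks CIGAR or sequence")
                cigar = []
                for opcode, n in rec.cigartuples:
                    try:
                        cigar.append((_CIGAR_OP_FROM_PYSAM[opcode], n))
                    except KeyError:
                        raise FormatError(
                            f"{path}: record {rec.query_name!r} has unsupported CIGAR op {opcode}"
                        ) from None
                quals = rec.query_qualities
                if quals is None:
                    raise FormatError(f"{path}: record {rec.query_name!r} lacks base qualities")
                read = AlignedRead(
                    name=rec.query_name,
                    contig=rec.reference_name,
                    pos0=rec.reference_start,
                    cigar=cigar,
                    seq=rec.query_sequence,
                    base_quals=np.asarray(quals, dtype=np.int16),
                    mapq=rec.mapping_quality,
                    secondary=rec.is_secondary or rec.is_supplementary,
                    duplicate=rec.is_duplicate,
                    reverse=rec.is_reverse,
                )
                reads.append(read)
                if not read.secondary and not read.duplicate:
                    mapped += 1
        except (ValueError, OSError) as exc:  # htslib parse errors
            raise FormatError(f"{path}: {exc}") from exc
    return AlignedReadSet(reads=reads, mapped_reads=mapped, sample_id=path.stem)


def write_sam(readset: AlignedReadSet, path: str | Path, contigs: Mapping[str, int] | Mapping[str, str]) -> None:
    """Write the read set as coordinate-sorted SAM.

    ``contigs`` maps contig name to length (int) or to sequence (str).
    """
    lengths = {
        name: (val if isinstance(val, int) else len(val)) for name, val in contigs.items()
    }
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": ln} for name, ln in lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in readset:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.name
            rec.reference_name = read.contig
            rec.reference_start = read.pos0
            rec.mapping_quality = read.mapq
            rec.cigarstring = read.cigar_string
            rec.query_sequence = read.seq
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(min(max(q, 0), 93) + 33) for q in read.base_quals)
            )
            rec.flag = (
                (0x10 if read.reverse else 0)
                | (0x100 if read.secondary else 0)
                | (0x400 if read.duplicate else 0)
            )
            out.write(rec)


def _as_readset(reads: AlignedReadSet | Sequence[AlignedRead]) -> AlignedReadSet:
    if isinstance(reads, AlignedReadSet):
        return reads
    reads = list(reads)
    mapped = sum(1 for r in reads if not r.secondary and not r.duplicate)
    return AlignedReadSet(reads=reads, mapped_reads=mapped)


def filter_alignments(
    reads: AlignedReadSet | Sequence[AlignedRead], params: FilterParams = FilterParams()
) -> AlignedReadSet:
    """Remove multimapped reads and PCR duplicates.

    Multimapped means the secondary/supplementary flag is set *or* MAPQ falls
    below ``params.min_mapq`` (spliced aligners report multimappers with low
    MAPQ). Duplicate removal drops flagged records and additionally collapses
    unflagged groups sharing (contig, pos0, CIGAR, strand) to one
    representative: the read with the highest mean base quality, ties broken
    by name. Output order is the stable input order; the operation is
    idempotent.
    """
    readset = _as_readset(reads)
    kept = [
        r
        for r in readset.reads
        if not (params.drop_secondary and r.secondary) and r.mapq >= params.min_mapq
    ]
    if params.dedup:
        kept = [r for r in kept if not r.duplicate]
        best: dict[tuple, tuple[tuple, int]] = {}
        for i, r in enumerate(kept):
            key = (r.contig, r.pos0, r.cigar_string, r.reverse)
            rank = (-r.mean_base_quality(), r.name)
            if key not in best or rank < best[key][0]:
                best[key] = (rank, i)
        keep_idx = sorted(i for _, i in best.values())
        kept = [kept[i] for i in keep_idx]
    return AlignedReadSet(
        reads=kept, mapped_reads=readset.mapped_reads, sample_id=readset.sample_id
    )


def split_junction_segments(read: AlignedRead) -> list[AlignedSegment]:
    """Split a read at N (intron) CIGAR operations into reference-contiguous
    segments, mirroring the splitting of junction-spanning reads into
    supplementary alignments.

    Soft/hard clips and insertions consume query only and contribute no
    aligned base; deletions advance the reference within a segment. A CIGAR
    whose first or last reference-consuming operation is N is rejected.
    """
    ops = [op for op, _ in read.cigar if op in _REF_OPS or op == "N"]
    if ops and (ops[0] == "N" or ops[-1] == "N"):
        raise FormatError(f"read {read.name!r}: CIGAR {read.cigar_string} has leading/trailing N")

    seq_codes = encode_bases(read.seq)
    segments: list[AlignedSegment] = []
    runs: list[tuple[int, int, int]] = []  # (ref_start, query_start, length)
    rpos, qpos = read.pos0, 0
    seg_end = rpos

    def _close() -> None:
        nonlocal runs
        if not runs:
            return
        ref_pos = np.concatenate([np.arange(r, r + n, dtype=np.int64) for r, _, n in runs])
        qidx = np.concatenate([np.arange(q, q + n, dtype=np.int64) for _, q, n in runs])
        segments.append(
            AlignedSegment(
                read_name=read.name,
                contig=read.contig,
                ref_start=runs[0][0],
                ref_end=seg_end,
                query_start=runs[0][1],
                ref_pos=ref_pos,
                bases=seq_codes[qidx],
                quals=read.base_quals[qidx],
            )
        )
        runs = []

    for op, n in read.cigar:
        if op in ("S", "I"):
            qpos += n
        elif op == "H":
            continue
        elif op == "M":
            runs.append((rpos, qpos, n))
            rpos += n
            qpos += n
            seg_end = rpos
        elif op == "D":
            rpos += n
            if runs:
                seg_end = rpos
        elif op == "N":
            _close()
            rpos += n
        else:  # pragma: no cover - constructor already rejects unknown ops
            raise FormatError(f"read {read.name!r}: unsupported CIGAR op {op!r}")
    _close()
    return segments


def mask_read_start(read: AlignedRead, n: int) -> AlignedRead:
    """Mask the first ``n`` query bases in sequencing orientation.

    For forward reads these are the first ``n`` bases of SEQ; for
    reverse-strand reads the sequencer's first bases sit at the 3' end of the
    stored alignment, so the last ``n`` bases are masked. Masked bases keep
    their position in the read (length unchanged) but carry the sentinel
    quality :data:`MASKED_QUAL` and contribute to no pileup. ``n`` larger
    than the read saturates without error.
    """
    if n < 0:
        raise ValueError(f"mask length must be non-negative, got {n}")
    if n == 0:
        return read
    quals = read.base_quals.copy()
    k = min(n, len(quals))
    if read.reverse:
        if k:
            quals[len(quals) - k :] = MASKED_QUAL
    else:
        quals[:k] = MASKED_QUAL
    return replace(read, base_quals=quals)


def contributing_base_count(read: AlignedRead) -> int:
    """Number of aligned bases of the read that can enter a pileup
    (M-aligned and not start-masked; base-quality filtering happens later)."""
    return sum(int((seg.quals >= 0).sum()) for seg in split_junction_segments(read))


def _merged_intervals_by_contig(
    intervals: Iterable[tuple],
) -> dict[str, tuple[list[int], list[int]]]:
    """Merge possibly-overlapping (contig, start, end, ...) intervals into
    per-contig sorted disjoint (starts, ends) lists for bisect lookup."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        contig, start, end = iv[0], int(iv[1]), int(iv[2])
        by_contig.setdefault(contig, []).append((start, end))
    merged: dict[str, tuple[list[int], list[int]]] = {}
    for contig, ivs in by_contig.items():
        ivs.sort()
        starts: list[int] = []
        ends: list[int] = []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[contig] = (starts, ends)
    return merged


def restrict_to_alu(
    reads: AlignedReadSet | Sequence[AlignedRead], alu_intervals: Iterable[tuple]
) -> AlignedReadSet:
    """Keep only reads whose alignment span overlaps at least one Alu
    interval (0-based half-open). Mapped-read count metadata is preserved."""
    readset = _as_readset(reads)
    merged = _merged_intervals_by_contig(alu_intervals)
    kept = []
    for r in readset.reads:
        entry = merged.get(r.contig)
        if entry is None:
            continue
        starts, ends = entry
        i = bisect.bisect_right(starts, r.ref_end - 1) - 1
        if i >= 0 and ends[i] > r.pos0:
            kept.append(r)
    return AlignedReadSet(
        reads=kept, mapped_reads=readset.mapped_reads, sample_id=readset.sample_id
    )
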