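"""Gene-level aggregation of editing events.

An "editing event" is one called site observed in one sample; a site is
assigned to every gene whose genomic body (first to last exon, introns
included — editing is predominantly intronic/3'-UTR) contains it. Event
counts are depth-normalised to events per million mapped reads, and genes
accumulating more than a threshold number of events across all samples form
the highly-edited set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .editome import SampleEditome
from .errors import InconsistencyError
from .simdata import GeneModel

__all__ = [
    "GeneEditingTable",
    "HighlyEditedSet",
    "assign_sites_to_genes",
    "normalize_events",
    "select_highly_edited",
    "read_genes_gtf",
]

#: Normalisation scale: events per million mapped reads.
PER_MILLION = 1_000_000.0


@dataclass
class GeneEditingTable:
    """Genes × samples editing-event matrix.

    ``raw`` holds integer event counts; ``norm`` (filled by
    :func:`normalize_events`) holds events per million mapped reads.
    ``samples`` is a per-sample frame indexed by sample_id with columns
    condition, donor, mapped_reads. ``dropped_sites`` counts sites on
    contigs absent from the gene models; ``multi_assigned_sites`` counts
    site×sample events credited to more than one gene.
    """

    raw: pd.DataFrame
    samples: pd.DataFrame
    norm: pd.DataFrame | None = None
    dropped_sites: dict[str, int] = field(default_factory=dict)
    multi_assigned_sites: int = 0
    unique_sites: int = 0

    def write_tsv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.raw.to_csv(f"{prefix}.raw_events.tsv", sep="\t")
        if self.norm is not None:
            with open(f"{prefix}.norm_events.tsv", "w") as fh:
                fh.write("# events per million mapped reads\n")
                self.norm.to_csv(fh, sep="\t")
        self.samples.to_csv(f"{prefix}.samples.tsv", sep="\t")


@dataclass
class HighlyEditedSet:
    """Genes whose total event count across samples strictly exceeds the
    threshold (default: more than 50 events)."""

    gene_ids: set[str]
    threshold: int
    totals: dict[str, int]


def assign_sites_to_genes(
    editomes: Sequence[SampleEditome], genes: Sequence[GeneModel]
) -> GeneEditingTable:
    """Count each sample's called sites per gene body.

    A site inside k overlapping gene bodies increments all k genes. Sites on
    contigs with no gene model are dropped with a warning and tallied in
    ``dropped_sites``.
    """
    gene_ids = [g.gene_id for g in genes]
    sample_ids = [e.sample_id for e in editomes]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_ids across editomes")

    by_contig: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    for contig in {g.contig for g in genes}:
        idx = [i for i, g in enumerate(genes) if g.contig == contig]
        starts = np.array([genes[i].start for i in idx], dtype=np.int64)
        ends = np.array([genes[i].end for i in idx], dtype=np.int64)
        by_contig[contig] = (starts, ends, idx)

    raw = np.zeros((len(genes), len(editomes)), dtype=np.int64)
    dropped: dict[str, int] = {}
    multi = 0
    seen_positions: set[tuple[str, int]] = set()
    for s, editome in enumerate(editomes):
        n_dropped = 0
        for site in editome.sites:
            seen_positions.add((site.contig, site.pos0))
            entry = by_contig.get(site.contig)
            if entry is None:
                n_dropped += 1
                continue
            starts, ends, idx = entry
            hit = (starts <= site.pos0) & (site.pos0 < ends)
            nhit = int(hit.sum())
            if nhit == 0:
                continue
            if nhit > 1:
                multi += 1
            for j in np.flatnonzero(hit):
                raw[idx[j], s] += 1
        if n_dropped:
            dropped[editome.sample_id] = n_dropped
            warnings.warn(
                f"sample {editome.sample_id}: dropped {n_dropped} site(s) on contigs "
                "absent from the gene models",
                stacklevel=2,
            )

    samples = pd.DataFrame(
        {
            "condition": [e.condition for e in editomes],
            "donor": [e.donor for e in editomes],
            "mapped_reads": [e.mapped_reads for e in editomes],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    raw_df = pd.DataFrame(raw, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    return GeneEditingTable(
        raw=raw_df,
        samples=samples,
        dropped_sites=dropped,
        multi_assigned_sites=multi,
        unique_sites=len(seen_positions),
    )


def normalize_events(table: GeneEditingTable) -> GeneEditingTable:
    """Fill ``norm`` with events per million mapped reads; ``raw`` is left
    untouched. A sample with zero mapped reads but nonzero events is
    internally inconsistent and rejected."""
    mapped = table.samples["mapped_reads"].to_numpy(dtype=float)
    col_events = table.raw.to_numpy().sum(axis=0)
    bad = (mapped == 0) & (col_events > 0)
    if bad.any():
        names = list(table.raw.columns[bad])
        raise InconsistencyError(f"samples with events but zero mapped reads: {names}")
    denom = np.where(mapped > 0, mapped, 1.0)  # zero-read, zero-event samples -> 0.0
    norm = table.raw.to_numpy(dtype=float) * PER_MILLION / denom[None, :]
    table.norm = pd.DataFrame(norm, index=table.raw.index, columns=table.raw.columns)
    return table


def select_highly_edited(table: GeneEditingTable, threshold: int = 50) -> HighlyEditedSet:
    """Genes whose summed raw events across all samples strictly exceed
    ``threshold`` (a total of exactly ``threshold`` does not qualify)."""
    totals = table.raw.sum(axis=1)
    selected = set(totals.index[totals > threshold])
    return HighlyEditedSet(
        gene_ids=selected,
        threshold=threshold,
        totals={g: int(t) for g, t in totals.items()},
    )


def read_genes_gtf(path: str | Path) -> list[GeneModel]:
    """Load gene models (gene body + exons) from a GTF file (1-based
    inclusive coordinates, converted to 0-based half-open)."""
    import gffutils

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
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.features_of_type("exon")
            if f.attributes.get("gene_id", [None])[0] == g.attributes["gene_id"][0]
            and f.seqid == g.seqid
        )
        if not exons:
            exons = [(g.start - 1, g.end)]
        genes.append(
            GeneModel(
                gene_id=g.attributes["gene_id"][0],
                contig=g.seqid,
                strand=g.strand,
                exons=tuple(exons),
            )
        )
    return genes
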