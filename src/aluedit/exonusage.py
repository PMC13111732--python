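"""Bin-to-exon aggregation arithmetic for exon-usage analyses.

Upstream exon-usage callers quantify reads in non-overlapping bins per exon
and report per-bin normalised counts and log2 fold changes. This module
performs the two summarisation steps used downstream: a bin-length-weighted
mean of per-bin log2 fold changes per exon, and a simple sum of per-bin
normalised counts per exon. Differential testing of the bins themselves is
out of scope; any bin-level result table (including the test fixtures'
generated ones) can be consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = ["ExonBin", "aggregate_bin_lfc", "sum_bin_counts", "aggregate_exon_table"]


@dataclass(frozen=True)
class ExonBin:
    """One non-overlapping bin of an exon with per-sample normalised counts
    and an optional bin-level log2 fold change."""

    gene_id: str
    exon_id: str
    bin_id: str
    bin_length: int
    values: dict[str, float] = field(default_factory=dict)
    lfc: float | None = None

    def __post_init__(self) -> None:
        if self.bin_length <= 0:
            raise ValueError(f"bin {self.bin_id}: bin_length must be positive")


def _check_one_exon(bins: Sequence[ExonBin]) -> None:
    if not bins:
        raise ValueError("need at least one bin")
    exon_ids = {b.exon_id for b in bins}
    if len(exon_ids) != 1:
        raise ValueError(f"bins span multiple exons: {sorted(exon_ids)}")


def aggregate_bin_lfc(bins_of_exon: Sequence[ExonBin]) -> float:
    """Exon-level log2 fold change: mean of bin lfcs weighted by bin length,
    Σ(lfc_i · len_i) / Σ(len_i)."""
    _check_one_exon(bins_of_exon)
    if any(b.lfc is None for b in bins_of_exon):
        raise ValueError("every bin needs an lfc to aggregate")
    wsum = sum(b.lfc * b.bin_length for b in bins_of_exon)
    lsum = sum(b.bin_length for b in bins_of_exon)
    return wsum / lsum


def sum_bin_counts(bins_of_exon: Sequence[ExonBin], sample: str) -> float:
    """Exon-level normalised count for one sample: sum over its bins."""
    _check_one_exon(bins_of_exon)
    missing = [b.bin_id for b in bins_of_exon if sample not in b.values]
    if missing:
        raise ValueError(f"sample {sample!r} missing from bins {missing}")
    return float(sum(b.values[sample] for b in bins_of_exon))


def aggregate_exon_table(
    bins: pd.DataFrame, sample_columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Aggregate a bin-level table (columns: gene_id, exon_id, bin_id,
    bin_length, optional lfc, plus per-sample count columns) to exon level:
    length-weighted-mean lfc and summed counts per (gene_id, exon_id).
    """
    required = {"gene_id", "exon_id", "bin_id", "bin_length"}
    if not required.issubset(bins.columns):
        raise ValueError(f"bin table needs columns {sorted(required)}")
    if sample_columns is None:
        sample_columns = [
            c for c in bins.columns if c not in required and c != "lfc"
        ]
    rows = []
    for (gene_id, exon_id), grp in bins.groupby(["gene_id", "exon_id"], sort=True):
        row: dict[str, object] = {"gene_id": gene_id, "exon_id": exon_id}
        lengths = grp["bin_length"].to_numpy(dtype=float)
        if "lfc" in bins.columns and grp["lfc"].notna().all():
            row["lfc"] = float((grp["lfc"].to_numpy() * lengths).sum() / lengths.sum())
        for s in sample_columns:
            row[s] = float(grp[s].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def read_bin_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of bin-level results."""
    return pd.read_csv(path, sep="\t")


def write_exon_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
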