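"""Protein Stability Index (PSI) computation and motif databases.

PSI is the read-weighted mean bin index of a motif::

    PSI = sum_{i=1..4} R_i * i

where ``R_i`` is the fraction of the motif's reads in sorted bin i.  With B1
the least-stable and B4 the most-stable bin, PSI ranges from 1 (all reads in
B1) to 4 (all reads in B4).

Two interpretations of ``R_i`` are supported:

* ``raw`` (default): the literal fraction of the motif's reads in bin i.
* ``depth``: each bin count is first divided by that bin's total read depth
  (correcting for unequal sequencing of the bins) and the per-motif vector is
  then renormalised to sum 1.

Which of the two a given study used is often unstated; both are provided and
the choice is recorded in the database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .amplicon import BIN_IDS, BinCountTable

COUNT_COLS = [f"count_{b.lower()}" for b in BIN_IDS]
BIN_WEIGHTS = np.arange(1, 5, dtype=float)

MODES = ("raw", "depth")


def compute_psi(counts, mode: str = "raw", bin_totals=None):
    """PSI of a single 4-vector of bin counts.

    Returns ``(R, psi)`` where ``R`` is the length-4 read-fraction vector.
    All-zero counts are undefined and raise ``ValueError`` (callers exclude
    such motifs rather than propagating NaN).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (4,):
        raise ValueError("counts must be a 4-vector (B1..B4)")
    if counts.sum() == 0:
        raise ValueError("PSI is undefined for all-zero counts")
    if mode == "raw":
        weights = counts
    elif mode == "depth":
        if bin_totals is None:
            raise ValueError("depth mode requires bin_totals")
        bin_totals = np.asarray(bin_totals, dtype=float)
        if np.any(bin_totals <= 0):
            raise ValueError("depth mode requires positive bin totals")
        weights = counts / bin_totals
    else:
        raise ValueError(f"unknown mode {mode!r}")
    R = weights / weights.sum()
    return R, float(R @ BIN_WEIGHTS)


@dataclass
class MotifDatabase:
    """Per-genotype motif -> (bin counts, total, PSI) table.

    ``records`` columns: motif, count_b1..count_b4, total, psi; motifs are
    unique and lexicographically ordered; records below the applied minimum
    read count are absent.
    """

    genotype: str
    records: pd.DataFrame
    normalization_mode: str = "raw"
    min_reads_applied: int = 1
    bin_totals: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def motifs(self) -> pd.Series:
        return self.records["motif"]

    @property
    def psi(self) -> pd.Series:
        return self.records["psi"]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# genotype={self.genotype}\tmode={self.normalization_mode}"
                f"\tmin_reads={self.min_reads_applied}"
                f"\tbin_totals={','.join(str(t) for t in self.bin_totals)}\n"
            )
            self.records.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MotifDatabase":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(
                item.split("=", 1) for item in header.lstrip("# ").strip().split("\t")
            )
            records = pd.read_csv(fh, sep="\t")
        totals = meta.get("bin_totals", "")
        return cls(
            genotype=meta.get("genotype", "NA"),
            records=records,
            normalization_mode=meta.get("mode", "raw"),
            min_reads_applied=int(meta.get("min_reads", 1)),
            bin_totals=[int(t) for t in totals.split(",")] if totals else [],
        )


def build_database(
    table: BinCountTable, mode: str = "raw", min_reads: int = 1
) -> MotifDatabase:
    """Build a :class:`MotifDatabase` from a bin-count table.

    Motifs with total reads below ``min_reads`` are dropped; remaining
    records are ordered lexicographically by motif.  PSI is computed
    vectorised over all motifs in the requested mode.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    counts = table.counts[COUNT_COLS].to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    bin_totals = np.asarray(table.bin_totals, dtype=float)
    keep = totals >= max(min_reads, 1)
    records = table.counts.loc[keep, ["motif", *COUNT_COLS]].copy()
    kept = counts[keep]
    if mode == "raw":
        weights = kept
    else:
        if np.any(bin_totals <= 0):
            raise ValueError("depth mode requires positive totals in every bin")
        weights = kept / bin_totals
    R = weights / weights.sum(axis=1, keepdims=True)
    records["total"] = totals[keep].astype(int)
    records["psi"] = R @ BIN_WEIGHTS
    records = records.sort_values("motif", kind="mergesort").reset_index(drop=True)
    return MotifDatabase(
        genotype=table.genotype,
        records=records,
        normalization_mode=mode,
        min_reads_applied=min_reads,
        bin_totals=[int(t) for t in table.bin_totals],
    )


def database_from_counts_df(
    counts_df: pd.DataFrame,
    genotype: str = "NA",
    mode: str = "raw",
    min_reads: int = 1,
) -> MotifDatabase:
    """Convenience: build a database straight from a motif/count DataFrame
    (e.g. a simulator allocation), bypassing the read-level pipeline."""
    table = BinCountTable(
        genotype=genotype,
        counts=counts_df[["motif", *COUNT_COLS]].copy(),
        ledger={},
        raw_total=int(counts_df[COUNT_COLS].to_numpy().sum()),
    )
    return build_database(table, mode=mode, min_reads=min_reads)
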