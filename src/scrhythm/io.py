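"""Core data containers, file formats, and pipeline configuration.

Counts are stored genes x cells in scipy sparse matrices and exchanged on
disk as Matrix Market coordinate files (1-based on disk, 0-based in memory)
alongside plain TSV metadata. All result tables are TSV with a header and
full-precision floats.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger("scrhythm")

#: smallest positive float written in place of an exact-zero p-value
TINY_P = np.nextafter(0.0, 1.0)

CELL_COLUMNS = ["barcode", "sample", "timepoint_hours", "cell_type"]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.WARNING)


@dataclass
class CellCountMatrix:
    """Sparse gene x cell integer counts with per-cell annotations.

    Parameters
    ----------
    counts
        Sparse nonnegative-integer matrix, genes in rows, cells in columns.
    gene_ids
        Unique gene identifiers, one per row.
    cells
        One row per matrix column with at least the columns
        ``barcode``, ``sample``, ``timepoint_hours``, ``cell_type``.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cells) != n_cells:
            raise FormatError(
                f"{len(self.cells)} cell annotation rows for {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("gene ids are not unique")
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise FormatError(f"cell annotations missing columns: {missing}")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("negative count entries")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer count entries")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CellCountMatrix":
        """Return a new matrix restricted to the cells selected by ``mask``."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellCountMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            cells=self.cells.iloc[idx].reset_index(drop=True),
        )

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene id not found: {exc.args[0]}") from exc


@dataclass
class TimeSeries:
    """A scalar signal sampled at hour-valued times (e.g. 0, 4, ..., 20)."""

    times: np.ndarray
    values: np.ndarray
    replicate_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be sorted")


@dataclass
class PipelineConfig:
    """Thresholds and knobs shared across the analysis stages."""

    alpha: float = 0.05
    lfc_pseudobulk: float = 0.2
    lfc_aged: float = 0.58
    lfc_cell: float = 0.15
    min_pct: float = 0.05
    min_cells_per_timepoint: int = 250
    marker_min_pct: float = 0.25
    marker_lfc: float = 0.405
    kmeans_k: int | None = None
    period_lo: float = 20.0
    period_hi: float = 28.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("lfc_pseudobulk", "lfc_aged", "lfc_cell", "min_pct",
                     "marker_min_pct", "marker_lfc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.min_cells_per_timepoint < 0:
            raise ValueError("min_cells_per_timepoint must be nonnegative")
        if self.period_lo >= self.period_hi:
            raise ValueError("period_lo must be < period_hi")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_counts(
    mtx_path: str | Path,
    cells_tsv: str | Path,
    genes_tsv: str | Path,
) -> CellCountMatrix:
    """Read a genes x cells Matrix Market file plus TSV metadata.

    Raises :class:`FormatError` on dimension mismatch, duplicate gene ids,
    or negative / non-integer entries.
    """
    mat = scipy.io.mmread(str(mtx_path))
    cells = pd.read_csv(cells_tsv, sep="\t")
    genes = pd.read_csv(genes_tsv, sep="\t")
    if "gene_id" not in genes.columns:
        raise FormatError("genes.tsv must contain a gene_id column")
    return CellCountMatrix(
        counts=sp.csr_matrix(mat), gene_ids=genes["gene_id"].to_numpy(), cells=cells
    )


def write_counts(ccm: CellCountMatrix, out_dir: str | Path,
                 gene_table: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write matrix.mtx / cells.tsv / genes.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out / "matrix.mtx",
        "cells": out / "cells.tsv",
        "genes": out / "genes.tsv",
    }
    scipy.io.mmwrite(str(paths["mtx"]), ccm.counts.astype(np.int64), field="integer")
    ccm.cells.to_csv(paths["cells"], sep="\t", index=False)
    if gene_table is None:
        gene_table = pd.DataFrame({"gene_id": ccm.gene_ids})
    if list(gene_table["gene_id"]) != list(ccm.gene_ids):
        raise ValueError("gene_table rows must match matrix gene order")
    gene_table.to_csv(paths["genes"], sep="\t", index=False)
    return paths


def write_results(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as TSV with stable column order.

    Columns whose name contains ``pvalue`` or ``padj`` are floored at the
    smallest positive float so an exact zero never appears on disk.
    """
    if len(table.columns) == 0:
        raise ValueError("result table has no columns")
    out = table.copy()
    for col in out.columns:
        if "pvalue" in col or "padj" in col:
            vals = out[col].to_numpy(dtype=float, copy=True)
            vals[vals == 0.0] = TINY_P
            out[col] = vals
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_series(series: TimeSeries, path: str | Path) -> Path:
    df = pd.DataFrame({"time_hours": series.times, "value": series.values})
    if series.replicate_ids is not None:
        df["replicate"] = series.replicate_ids
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_series(path: str | Path) -> TimeSeries:
    df = pd.read_csv(path, sep="\t")
    if not {"time_hours", "value"} <= set(df.columns):
        raise FormatError("series TSV needs time_hours and value columns")
    order = np.argsort(df["time_hours"].to_numpy(), kind="stable")
    df = df.iloc[order]
    reps = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return TimeSeries(
        times=df["time_hours"].to_numpy(float),
        values=df["value"].to_numpy(float),
        replicate_ids=reps,
    )


def write_fasta(records: dict[str, str], path: str | Path) -> Path:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        seqio_write(recs, fh, "fasta")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
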