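"""Cell- and gene-level quality control for UMI count matrices.

Implements the three per-cell filters (library size, mitochondrial read
fraction, spike-in amplification linearity) and the two-part gene
detectability rule, plus per-cell detected-gene summaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UMICountMatrix",
    "QCThresholds",
    "CellFilterReport",
    "filter_cells",
    "detectable_genes",
    "genes_per_cell_summary",
]

#: Metadata columns required by :func:`filter_cells`.
REQUIRED_META = ("total_reads", "mito_fraction", "ercc_pearson")


@dataclass
class UMICountMatrix:
    """Genes x cells UMI counts for one donor at one time point.

    Parameters
    ----------
    counts
        2-D integer array, shape ``(n_genes, n_cells)``, non-negative.
    gene_ids, cell_ids
        Stable identifiers matching the rows / columns of ``counts``.
    donor, time_point
        Labels identifying the sample.
    cell_meta
        Optional per-cell QC metadata indexed by cell id with columns
        ``total_reads``, ``mito_fraction`` and ``ercc_pearson``.
    """

    counts: np.ndarray
    gene_ids: Sequence[str]
    cell_ids: Sequence[str]
    donor: str = "donor1"
    time_point: str = "t0"
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells array")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes and {len(self.cell_ids)} cells"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.cell_meta is not None:
            missing = set(self.cell_ids) - set(self.cell_meta.index)
            if missing:
                raise ValueError(f"cell_meta missing rows for cells: {sorted(missing)[:5]}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def select_cells(self, mask: np.ndarray) -> "UMICountMatrix":
        """Return a copy restricted to cells where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        kept = [c for c, m in zip(self.cell_ids, mask) if m]
        meta = self.cell_meta.loc[kept] if self.cell_meta is not None else None
        return UMICountMatrix(
            counts=self.counts[:, mask].copy(),
            gene_ids=list(self.gene_ids),
            cell_ids=kept,
            donor=self.donor,
            time_point=self.time_point,
            cell_meta=meta,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)


@dataclass(frozen=True)
class QCThresholds:
    """Filter cut-offs; defaults follow the study design.

    Cells are removed when ``total_reads < min_total_reads``, when
    ``mito_fraction > max_mito_fraction`` (strictly more), or when
    ``ercc_pearson <= min_ercc_pearson`` (only cells strictly above the
    correlation cut-off are retained). A gene is detectable when at least
    ``gene_min_cells_multi_umi`` cells carry more than a single UMI and the
    gene accumulates at least ``gene_min_total_reads`` reads in total.
    """

    min_total_reads: int = 80_000
    max_mito_fraction: float = 0.10
    min_ercc_pearson: float = 0.6
    gene_min_cells_multi_umi: int = 2
    gene_min_total_reads: int = 5


@dataclass
class CellFilterReport:
    """Removal report: one row per removed cell with its first failing rule."""

    removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["cell_id", "reason"])
    )

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def _first_failure(row: pd.Series, thr: QCThresholds) -> str | None:
    if row["total_reads"] < thr.min_total_reads:
        return "low_total_reads"
    if row["mito_fraction"] > thr.max_mito_fraction:
        return "high_mito_fraction"
    ercc = row["ercc_pearson"]
    if pd.isna(ercc) or not ercc > thr.min_ercc_pearson:
        return "low_ercc_pearson"
    return None


def filter_cells(
    matrix: UMICountMatrix, thresholds: QCThresholds | None = None
) -> tuple[UMICountMatrix, CellFilterReport]:
    """Remove cells failing any QC rule; the gene set is left unchanged.

    Returns the filtered matrix and a report listing each removed cell with
    the first criterion it failed (checked in order: total reads, mito
    fraction, spike-in correlation).

    Raises
    ------
    ValueError
        If ``cell_meta`` is absent or lacks one of the required columns;
        the error names the missing field.
    """
    thr = thresholds or QCThresholds()
    if matrix.cell_meta is None:
        raise ValueError("cell metadata required: missing fields "
                         + ", ".join(REQUIRED_META))
    for col in REQUIRED_META:
        if col not in matrix.cell_meta.columns:
            raise ValueError(f"cell metadata missing required field: {col}")

    meta = matrix.cell_meta.loc[matrix.cell_ids]
    reasons = [_first_failure(meta.loc[c], thr) for c in matrix.cell_ids]
    keep = np.array([r is None for r in reasons])
    report = CellFilterReport(
        removed=pd.DataFrame(
            {
                "cell_id": [c for c, r in zip(matrix.cell_ids, reasons) if r],
                "reason": [r for r in reasons if r],
            }
        )
    )
    return matrix.select_cells(keep), report


def detectable_genes(
    matrices: Iterable[UMICountMatrix],
    thresholds: QCThresholds | None = None,
) -> list[str]:
    """Genes detectable across a collection of matrices sharing a gene universe.

    A gene is detectable iff the number of cells (pooled over all matrices)
    with a UMI count of at least 2 reaches ``gene_min_cells_multi_umi`` AND
    its total count over all cells reaches ``gene_min_total_reads``.
    """
    thr = thresholds or QCThresholds()
    matrices = list(matrices)
    if not matrices:
        raise ValueError("at least one matrix required")
    universe = matrices[0].gene_ids
    for m in matrices[1:]:
        if m.gene_ids != universe:
            raise ValueError("matrices have inconsistent gene universes")
    multi = np.zeros(len(universe), dtype=np.int64)
    total = np.zeros(len(universe), dtype=np.int64)
    for m in matrices:
        multi += (m.counts >= 2).sum(axis=1)
        total += m.counts.sum(axis=1)
    ok = (multi >= thr.gene_min_cells_multi_umi) & (total >= thr.gene_min_total_reads)
    return [g for g, flag in zip(universe, ok) if flag]


def genes_per_cell_summary(matrix: UMICountMatrix) -> tuple[pd.Series, float, float]:
    """Per-cell number of detected genes (UMI >= 1) with mean and SD.

    SD is the sample standard deviation (ddof=1; 0.0 for a single cell).
    """
    if matrix.n_cells == 0 or matrix.n_genes == 0:
        raise ValueError("empty matrix")
    per_cell = pd.Series(
        (matrix.counts >= 1).sum(axis=0), index=matrix.cell_ids, name="n_detected"
    )
    mean = float(per_cell.mean())
    sd = float(per_cell.std(ddof=1)) if len(per_cell) > 1 else 0.0
    return per_cell, mean, sd
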