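"""Readers and writers for the plain-text formats used by the pipeline.

Count matrices travel either as dense TSV (genes x cells) or as sparse
matrix-market triplets with gene/barcode sidecar lists; peaks as BED3/BED6
(optionally with a trailing read-count column) or 10-column narrowPeak;
annotations, networks, cluster labels and QC metadata as delimited tables.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .qc import UMICountMatrix

__all__ = [
    "read_counts_tsv", "write_counts_tsv",
    "read_counts_mtx", "write_counts_mtx",
    "read_cell_metadata", "read_bed", "write_bed",
    "read_narrowpeak", "read_annotation", "write_annotation",
    "read_network", "write_network", "read_clusters", "read_config",
]


# --- count matrices --------------------------------------------------------

def read_counts_tsv(
    path: str | Path,
    meta_path: str | Path | None = None,
    donor: str = "donor1",
    time_point: str = "t0",
) -> UMICountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = read_cell_metadata(meta_path) if meta_path else None
    return UMICountMatrix(
        counts=df.to_numpy(),
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
        donor=donor,
        time_point=time_point,
        cell_meta=meta,
    )


def write_counts_tsv(matrix: UMICountMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_counts_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    meta_path: str | Path | None = None,
    donor: str = "donor1",
    time_point: str = "t0",
) -> UMICountMatrix:
    """Sparse triplet matrix (genes x cells) with row/column sidecars."""
    mat = spio.mmread(str(mtx_path))
    genes = Path(genes_path).read_text().split()
    cells = Path(barcodes_path).read_text().split()
    meta = read_cell_metadata(meta_path) if meta_path else None
    return UMICountMatrix(
        counts=np.asarray(mat.todense()) if sparse.issparse(mat) else np.asarray(mat),
        gene_ids=genes,
        cell_ids=cells,
        donor=donor,
        time_point=time_point,
        cell_meta=meta,
    )


def write_counts_mtx(matrix: UMICountMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.genes.txt`` / ``.barcodes.txt``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.coo_matrix(matrix.counts))
    prefix.with_suffix(".genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
    prefix.with_suffix(".barcodes.txt").write_text("\n".join(matrix.cell_ids) + "\n")
    if matrix.cell_meta is not None:
        matrix.cell_meta.to_csv(prefix.with_suffix(".meta.tsv"), sep="\t",
                                index_label="cell_id")


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    if "cell_id" not in meta.columns:
        raise ValueError("cell metadata table must have a cell_id column")
    return meta.set_index("cell_id")


# --- intervals -------------------------------------------------------------

_BED6 = ["chrom", "start", "end", "name", "score", "strand"]
_NARROWPEAK = _BED6 + ["signal_value", "p_value", "q_value", "summit"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3/BED6, optionally with a trailing read_count column (7 fields)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    if ncol == 3:
        df.columns = _BED6[:3]
    elif ncol == 4:
        # BED3 + read count (compact export)
        df.columns = _BED6[:3] + ["read_count"]
    elif ncol == 6:
        df.columns = _BED6
    elif ncol == 7:
        df.columns = _BED6 + ["read_count"]
    else:
        raise ValueError(f"unsupported BED column count: {ncol}")
    return df


def write_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    out = peaks.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in out.columns:
            out[col] = default
    cols = _BED6 + (["read_count"] if "read_count" in out.columns else [])
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 10:
        raise ValueError("narrowPeak files have exactly 10 columns")
    df.columns = _NARROWPEAK
    # signal value doubles as the read-count proxy when none is provided
    if "read_count" not in df.columns:
        df["read_count"] = df["signal_value"]
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    """BED-like feature table: chrom, start, end, category, gene_id."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "category"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    if "gene_id" not in df.columns:
        df["gene_id"] = ""
    df["gene_id"] = df["gene_id"].fillna("")
    return df


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


# --- networks, clusters, config -------------------------------------------

def read_network(path: str | Path) -> pd.DataFrame:
    """Three-column delimited edge table: tf, target, confidence."""
    df = pd.read_csv(path, sep="\t")
    if not {"tf", "target", "confidence"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["tf", "target", "confidence"])
    return df


def write_network(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_clusters(path: str | Path) -> pd.Series:
    """Two-column table (cell_id, cluster) -> labels keyed by cell id."""
    df = pd.read_csv(path, sep="\t")
    if not {"cell_id", "cluster"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "cluster"])
    return df.set_index("cell_id")["cluster"]


def read_config(path: str | Path) -> dict:
    """Structured key: value configuration (YAML subset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must map keys to values")
    return cfg
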