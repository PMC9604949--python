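"""Index for critical transitions from within-cluster correlation structure.

For each cell cluster the index is the ratio of the mean retained gene-gene
Pearson correlation to the mean retained cell-cell Pearson correlation,
where "retained" keeps only coefficients strictly above a threshold
(default 0.70, signed). A maximum of the index along a time course flags
proximity to a state transition.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import UMICountMatrix

__all__ = ["ClusterAssignment", "IcResult", "pairwise_pearson", "compute_ic"]


@dataclass
class ClusterAssignment:
    """cell_id -> small-integer cluster label, with a provenance note."""

    labels: pd.Series  # index: cell_id, values: cluster label
    provenance: str = "external"

    def clusters(self) -> list:
        return sorted(self.labels.unique().tolist())


@dataclass
class IcResult:
    cluster: object
    ic_value: float  # NaN when undefined
    mean_gene_gene_r: float
    mean_cell_cell_r: float
    n_gene_pairs_retained: int
    n_cell_pairs_retained: int
    n_cells: int
    threshold: float
    defined: bool


def pairwise_pearson(matrix: np.ndarray | UMICountMatrix, axis: str = "genes") -> np.ndarray:
    """All C(n, 2) pairwise Pearson coefficients along one axis.

    Parameters
    ----------
    matrix
        2-D array (genes x cells) or a :class:`UMICountMatrix`.
    axis
        ``"genes"`` correlates row vectors, ``"cells"`` column vectors.

    Returns
    -------
    ndarray
        Condensed upper-triangle vector ordered as (0,1), (0,2), ...,
        (n-2, n-1). Pairs involving a zero-variance vector are NaN and are
        excluded downstream.
    """
    X = matrix.counts if isinstance(matrix, UMICountMatrix) else np.asarray(matrix)
    if axis == "cells":
        X = X.T
    elif axis != "genes":
        raise ValueError("axis must be 'genes' or 'cells'")
    X = X.astype(float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 vectors to correlate")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    iu = np.triu_indices(n, k=1)
    return R[iu]


def _mean_retained(condensed: np.ndarray, threshold: float, use_abs: bool) -> tuple[float, int]:
    vals = np.abs(condensed) if use_abs else condensed
    keep = np.isfinite(vals) & (vals > threshold)
    n = int(keep.sum())
    if n == 0:
        return float("nan"), 0
    return float(condensed[keep].mean()), n


def compute_ic(
    matrix: UMICountMatrix | np.ndarray,
    clusters: ClusterAssignment | None = None,
    threshold: float = 0.70,
    use_abs: bool = False,
    log1p: bool = False,
) -> list[IcResult]:
    """Per-cluster transition index.

    Clusters with fewer than 2 cells or 2 genes, or with an empty retained
    correlation set on either axis, yield a flagged undefined result rather
    than being dropped. When ``clusters`` is None the whole matrix is
    treated as a single cluster labelled 0.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if isinstance(matrix, UMICountMatrix):
        counts = matrix.counts.astype(float)
        cell_ids = matrix.cell_ids
    else:
        counts = np.asarray(matrix, dtype=float)
        cell_ids = list(range(counts.shape[1]))
    if log1p:
        counts = np.log1p(counts)

    if clusters is None:
        clusters = ClusterAssignment(
            labels=pd.Series(0, index=pd.Index(cell_ids)), provenance="all-cells"
        )
    unknown = set(clusters.labels.index) - set(cell_ids)
    if unknown:
        raise ValueError(f"cluster labels reference unknown cells: {sorted(unknown)[:5]}")
    col_of = {c: j for j, c in enumerate(cell_ids)}

    results: list[IcResult] = []
    for cl in clusters.clusters():
        members = clusters.labels.index[clusters.labels == cl]
        cols = [col_of[c] for c in members]
        sub = counts[:, cols]
        if len(cols) < 2 or sub.shape[0] < 2:
            results.append(
                IcResult(cl, float("nan"), float("nan"), float("nan"),
                         0, 0, len(cols), threshold, False)
            )
            continue
        gg = pairwise_pearson(sub, axis="genes")
        cc = pairwise_pearson(sub, axis="cells")
        mg, ng = _mean_retained(gg, threshold, use_abs)
        mc, nc = _mean_retained(cc, threshold, use_abs)
        # a signed mean of 0 can only occur under use_abs; flag as undefined
        defined = ng > 0 and nc > 0 and mc != 0
        ic = mg / mc if defined else float("nan")
        results.append(
            IcResult(cl, ic, mg, mc, ng, nc, len(cols), threshold, defined)
        )
    return results


def ic_table(results: list[IcResult]) -> pd.DataFrame:
    """Results as a tidy table, one row per cluster."""
    return pd.DataFrame(
        {
            "cluster": [r.cluster for r in results],
            "ic": [r.ic_value for r in results],
            "mean_gene_gene_r": [r.mean_gene_gene_r for r in results],
            "mean_cell_cell_r": [r.mean_cell_cell_r for r in results],
            "n_gene_pairs_retained": [r.n_gene_pairs_retained for r in results],
            "n_cell_pairs_retained": [r.n_cell_pairs_retained for r in results],
            "n_cells": [r.n_cells for r in results],
            "threshold": [r.threshold for r in results],
            "defined": [r.defined for r in results],
        }
    )
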