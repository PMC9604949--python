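"""Cell-sharing statistics on binary single-cell accessibility matrices.

Sharing = the number of cells in which a peak is detected (column sum of a
binary cell x peak incidence matrix). Medians are reported overall and per
annotation category, and single-cell peaks are compared against a bulk peak
catalog for concordance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .peaks import _any_overlap, _merge, _validate

__all__ = ["CellPeakIncidence", "SharingSummary", "sharing_counts", "bulk_concordance"]


@dataclass
class CellPeakIncidence:
    """Binary cell x peak incidence with its interval catalog.

    ``incidence`` is dense or scipy-sparse, shape (n_cells, n_peaks), with
    0/1 entries; ``peaks`` carries chrom/start/end and optionally a
    ``category`` column (e.g. from annotation).
    """

    peaks: pd.DataFrame
    cell_ids: list[str]
    incidence: np.ndarray | sparse.spmatrix

    def __post_init__(self) -> None:
        _validate(self.peaks)
        shape = self.incidence.shape
        if shape != (len(self.cell_ids), len(self.peaks)):
            raise ValueError(
                f"incidence shape {shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.peaks)} peaks"
            )
        data = self.incidence.data if sparse.issparse(self.incidence) else self.incidence
        vals = np.unique(np.asarray(data))
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("incidence must be binary (0/1)")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class SharingSummary:
    per_peak: pd.Series  # cells sharing each peak
    medians: dict[str, float] = field(default_factory=dict)


def _median(x: np.ndarray) -> float:
    # np.median already uses the midpoint of the two central order statistics
    return float(np.median(x)) if len(x) else float("nan")


def sharing_counts(incidence: CellPeakIncidence) -> SharingSummary:
    """Cells sharing each peak, with medians overall and per category.

    Medians are reported for ``all`` peaks and, when the catalog carries a
    ``category`` column, for the ``promoter`` and ``intergenic`` subsets.
    """
    if len(incidence.peaks) == 0:
        raise ValueError("empty peak catalog")
    M = incidence.incidence
    counts = np.asarray(M.sum(axis=0)).ravel().astype(np.int64)
    per_peak = pd.Series(counts, index=incidence.peaks.index, name="n_cells_sharing")
    medians = {"all": _median(counts)}
    if "category" in incidence.peaks.columns:
        for cat in ("promoter", "intergenic"):
            sel = (incidence.peaks["category"] == cat).to_numpy()
            medians[cat] = _median(counts[sel])
    return SharingSummary(per_peak=per_peak, medians=medians)


def bulk_concordance(
    incidence: CellPeakIncidence, bulk: pd.DataFrame
) -> tuple[pd.DataFrame, float, dict[str, float]]:
    """Flag single-cell peaks by bulk support and measure bulk recovery.

    A single-cell peak is ``bulk_supported`` iff it overlaps a bulk peak by
    >= 1 bp. Recovery is the fraction of bulk peaks overlapped by at least
    one single-cell peak. Sharing medians are reported separately for
    supported and single-cell-only peaks.

    Raises
    ------
    ValueError
        When the two catalogs share no chromosome naming (full mismatch);
    """
    _validate(bulk, "bulk")
    sc = incidence.peaks
    if len(bulk) and len(sc):
        if not (set(sc["chrom"]) & set(bulk["chrom"])):
            raise ValueError(
                "chromosome mismatch between catalogs: "
                f"single-cell {sorted(set(sc['chrom']))[:5]} vs "
                f"bulk {sorted(set(bulk['chrom']))[:5]}"
            )
    supported = np.zeros(len(sc), dtype=bool)
    recovered = np.zeros(len(bulk), dtype=bool)
    for chrom in sorted(set(sc["chrom"]) | set(bulk["chrom"])):
        sc_mask = (sc["chrom"] == chrom).to_numpy()
        bk = bulk[bulk["chrom"] == chrom]
        b_s, b_e = _merge(bk["start"].to_numpy(), bk["end"].to_numpy(),
                          join_adjacent=False)
        if sc_mask.any():
            supported[sc_mask] = _any_overlap(
                sc.loc[sc_mask, "start"], sc.loc[sc_mask, "end"], b_s, b_e
            )
        sub = sc[sc_mask]
        s_s, s_e = _merge(sub["start"].to_numpy(), sub["end"].to_numpy(),
                          join_adjacent=False)
        bk_mask = (bulk["chrom"] == chrom).to_numpy()
        if bk_mask.any():
            recovered[bk_mask] = _any_overlap(
                bulk.loc[bk_mask, "start"], bulk.loc[bk_mask, "end"], s_s, s_e
            )
    recovery = float(recovered.mean()) if len(bulk) else float("nan")

    counts = np.asarray(incidence.incidence.sum(axis=0)).ravel().astype(np.int64)
    flags = pd.DataFrame(
        {
            "bulk_supported": supported,
            "n_cells_sharing": counts,
        },
        index=sc.index,
    )
    medians = {
        "bulk_supported": _median(counts[supported]),
        "single_cell_only": _median(counts[~supported]),
    }
    return flags, recovery, medians
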