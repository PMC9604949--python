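"""Interval algebra for bulk accessibility peaks.

Peaks are plain DataFrames with at least ``chrom``, ``start``, ``end``
(0-based, half-open) and usually ``read_count``. Operations: bp-wise
donor-reproducible intersection, multi-category genomic annotation with
intergenic-by-exclusion, per-promoter open/closed calls, four-way
open/closed configuration classification across an interval, presence
trajectories across a time course, and union-region log2 fold changes.

The overlap predicate everywhere is >= 1 bp.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONFIG_LABELS",
    "reproducible_peaks",
    "annotate_peaks",
    "promoter_open_calls",
    "classify_promoter_configs",
    "peak_trajectories",
    "union_region_fold_change",
]

PEAK_COLUMNS = ("chrom", "start", "end")
CONFIG_LABELS = ("open-open", "open-closed", "closed-open", "closed-closed")


def _validate(df: pd.DataFrame, name: str = "peaks") -> pd.DataFrame:
    for col in PEAK_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{name} table lacks required column {col!r}")
    if len(df) and not (df["start"] < df["end"]).all():
        raise ValueError(f"{name}: every interval must satisfy start < end")
    return df


def _merge(starts: np.ndarray, ends: np.ndarray, join_adjacent: bool = True):
    """Merge sorted-by-start intervals; adjacent ([a,b),[b,c)) optionally join."""
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [], []
    for s, e in zip(starts, ends):
        if out_s and (s < out_e[-1] or (join_adjacent and s == out_e[-1])):
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def _any_overlap(q_start, q_end, r_starts, r_ends) -> np.ndarray:
    """For each query, does it overlap (>=1 bp) any sorted disjoint region?"""
    q_start = np.asarray(q_start)
    q_end = np.asarray(q_end)
    if len(r_starts) == 0:
        return np.zeros(len(q_start), dtype=bool)
    hi = np.searchsorted(r_starts, q_end, side="left")  # regions starting before q end
    lo = np.searchsorted(r_ends, q_start, side="right")  # first region ending after q start
    return lo < hi


def _overlap_components(df: pd.DataFrame) -> np.ndarray:
    """Connected components (per chrom, >=1 bp overlap, transitive) of intervals.

    Returns an integer component id per row of ``df``; ids are assigned in
    (chrom, start) order so output is independent of input row order.
    """
    comp = np.empty(len(df), dtype=np.int64)
    next_id = 0
    for chrom in sorted(df["chrom"].unique()):
        idx = df.index[df["chrom"] == chrom]
        sub = df.loc[idx].sort_values(["start", "end"], kind="stable")
        cur_end = -1
        for row_pos, (s, e) in zip(sub.index, zip(sub["start"], sub["end"])):
            if s >= cur_end:  # no strict overlap with the open component
                next_id += 1
                cur_end = e
            else:
                cur_end = max(cur_end, e)
            comp[df.index.get_loc(row_pos)] = next_id - 1
    return comp


# ---------------------------------------------------------------------------
# Donor-reproducible intersection
# ---------------------------------------------------------------------------

def reproducible_peaks(peaksets: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """bp-wise intersection of peak coverage across all donors.

    Output regions are the maximal genomic segments covered by at least one
    peak in EVERY donor, with adjacent segments merged. Each region records
    the summed ``read_count`` of every donor peak overlapping it.
    """
    if len(peaksets) < 2:
        raise ValueError("at least 2 donor peak sets required")
    peaksets = [_validate(p) for p in peaksets]
    if any(len(p) == 0 for p in peaksets):
        warnings.warn("a donor has an empty peak set; intersection is empty",
                      stacklevel=2)
        return pd.DataFrame(columns=["chrom", "start", "end", "read_count"])

    n_donors = len(peaksets)
    chroms = sorted(set.intersection(*(set(p["chrom"]) for p in peaksets)))
    rows = []
    for chrom in chroms:
        merged = []
        for p in peaksets:
            sub = p[p["chrom"] == chrom]
            merged.append(_merge(sub["start"].to_numpy(), sub["end"].to_numpy()))
        # sweep: coverage count over donor-merged intervals
        pts = np.unique(np.concatenate([np.concatenate(m) for m in merged]))
        delta = np.zeros(len(pts), dtype=np.int64)
        for s_arr, e_arr in merged:
            delta[np.searchsorted(pts, s_arr)] += 1
            delta[np.searchsorted(pts, e_arr)] -= 1
        cov = np.cumsum(delta)
        seg_s, seg_e = [], []
        for i in range(len(pts) - 1):
            if cov[i] == n_donors:
                if seg_e and seg_e[-1] == pts[i]:
                    seg_e[-1] = pts[i + 1]
                else:
                    seg_s.append(pts[i])
                    seg_e.append(pts[i + 1])
        if not seg_s:
            continue
        seg_s = np.asarray(seg_s)
        seg_e = np.asarray(seg_e)
        # per-segment read counts via a difference array over the sorted,
        # disjoint segments (lo..hi = segments overlapping each peak)
        diff = np.zeros(len(seg_s) + 1, dtype=np.int64)
        for p in peaksets:
            sub = p[p["chrom"] == chrom]
            if "read_count" not in sub.columns:
                continue
            s_arr = sub["start"].to_numpy()
            e_arr = sub["end"].to_numpy()
            rc = sub["read_count"].to_numpy(dtype=np.int64)
            lo = np.searchsorted(seg_e, s_arr, side="right")
            hi = np.searchsorted(seg_s, e_arr, side="left")
            keep = lo < hi
            np.add.at(diff, lo[keep], rc[keep])
            np.subtract.at(diff, hi[keep], rc[keep])
        counts = np.cumsum(diff[:-1])
        for s, e, rc in zip(seg_s, seg_e, counts):
            rows.append((chrom, int(s), int(e), int(rc)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "read_count"])


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def annotate_peaks(
    peaks: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign every overlapped feature category to each peak.

    A peak receives every category it overlaps by >= 1 bp, so the
    per-category totals may sum to more than the peak count. A peak that
    overlaps nothing is ``intergenic``, a label exclusive of all others.

    Returns
    -------
    (flags, totals)
        ``flags``: one boolean column per category plus ``intergenic``,
        aligned with ``peaks``. ``totals``: per-category peak counts.

    Raises
    ------
    ValueError
        If peaks reference a chromosome absent from the annotation; the
        message lists the offending chromosomes.
    """
    peaks = _validate(peaks)
    _validate(annotation, "annotation")
    unknown = sorted(set(peaks["chrom"]) - set(annotation["chrom"]))
    if unknown:
        raise ValueError(f"peaks on chromosomes absent from annotation: {unknown}")

    categories = sorted(annotation["category"].unique())
    flags = pd.DataFrame(False, index=peaks.index, columns=categories)
    for cat in categories:
        for chrom in peaks["chrom"].unique():
            feats = annotation[(annotation["category"] == cat)
                               & (annotation["chrom"] == chrom)]
            if len(feats) == 0:
                continue
            # no merging across features needed for a boolean any-overlap
            r_s, r_e = _merge(feats["start"].to_numpy(), feats["end"].to_numpy(),
                              join_adjacent=False)
            mask = peaks["chrom"] == chrom
            flags.loc[mask, cat] = _any_overlap(
                peaks.loc[mask, "start"], peaks.loc[mask, "end"], r_s, r_e
            )
    flags["intergenic"] = ~flags[categories].any(axis=1)
    totals = flags.sum(axis=0)
    totals.name = "n_peaks"
    return flags, totals


# ---------------------------------------------------------------------------
# Promoter open/closed calls and configurations
# ---------------------------------------------------------------------------

def _promoter_table(annotation: pd.DataFrame) -> pd.DataFrame:
    prom = annotation[annotation["category"] == "promoter"].reset_index(drop=True)
    if len(prom) == 0:
        raise ValueError("annotation contains no promoter features")
    prom = prom.copy()
    if "promoter_id" not in prom.columns:
        prom["promoter_id"] = [
            f"{g or 'NA'}@{c}:{s}-{e}"
            for g, c, s, e in zip(prom.get("gene_id", ""), prom["chrom"],
                                  prom["start"], prom["end"])
        ]
    return prom


def promoter_open_calls(
    peaks_by_time: Mapping[str, pd.DataFrame], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Per-promoter, per-time open/closed booleans.

    A promoter is open at a time point iff at least one peak of that time
    point overlaps it by >= 1 bp. Returns the promoter catalog (promoter_id,
    gene_id, coordinates) with one boolean column ``open_<time>`` per time.
    """
    prom = _promoter_table(annotation)
    out = prom[["promoter_id", "gene_id", "chrom", "start", "end"]].copy()
    for t, pk in peaks_by_time.items():
        _validate(pk, f"peaks[{t}]")
        col = np.zeros(len(prom), dtype=bool)
        for chrom in prom["chrom"].unique():
            sub = pk[pk["chrom"] == chrom]
            r_s, r_e = _merge(sub["start"].to_numpy(), sub["end"].to_numpy(),
                              join_adjacent=False)
            mask = (prom["chrom"] == chrom).to_numpy()
            col[mask] = _any_overlap(
                prom.loc[mask, "start"], prom.loc[mask, "end"], r_s, r_e
            )
        out[f"open_{t}"] = col
    return out


def classify_promoter_configs(
    open_calls: pd.DataFrame, t1: str, t2: str
) -> pd.DataFrame:
    """Four-way open/closed configuration of each promoter over (t1, t2).

    The classes partition the promoter catalog: exactly one config per
    promoter per interval. A gene with several promoters may carry several
    (possibly different) configs.
    """
    for t in (t1, t2):
        if f"open_{t}" not in open_calls.columns:
            raise ValueError(f"open calls lack time point {t!r}")
    a = open_calls[f"open_{t1}"].to_numpy(dtype=bool)
    b = open_calls[f"open_{t2}"].to_numpy(dtype=bool)
    config = np.where(
        a, np.where(b, "open-open", "open-closed"),
        np.where(b, "closed-open", "closed-closed"),
    )
    out = open_calls[["promoter_id", "gene_id", "chrom", "start", "end"]].copy()
    out["interval"] = f"{t1}-{t2}"
    out["config"] = config
    return out


# ---------------------------------------------------------------------------
# Trajectories and fold changes
# ---------------------------------------------------------------------------

def peak_trajectories(
    peaks_by_time: Mapping[str, pd.DataFrame]
) -> tuple[pd.DataFrame, dict]:
    """Link peaks at the same genomic position across time points.

    Peaks from all time points are chained into connected components by
    >= 1 bp overlap (transitively). Each chain gets a presence bit-pattern
    over the ordered time points (``"1"`` where at least one peak of that
    time point belongs to the chain), and a per-time read-count trace with 0
    where absent. A chain is ``persistent`` when present at every time point.

    Returns the chain table and a summary dict with ``n_chains``,
    ``n_persistent`` and ``persistent_fraction``.
    """
    times = list(peaks_by_time)
    frames = []
    for t in times:
        pk = _validate(peaks_by_time[t], f"peaks[{t}]").copy()
        pk["_time"] = t
        frames.append(pk)
    allp = pd.concat(frames, ignore_index=True)
    if len(allp) == 0:
        return (
            pd.DataFrame(columns=["chrom", "start", "end", "pattern", "persistent"]),
            {"n_chains": 0, "n_persistent": 0, "persistent_fraction": float("nan")},
        )
    allp["_comp"] = _overlap_components(allp)

    rows = []
    for comp, grp in allp.groupby("_comp", sort=True):
        rec = {
            "chrom": grp["chrom"].iloc[0],
            "start": int(grp["start"].min()),
            "end": int(grp["end"].max()),
        }
        pattern = ""
        for t in times:
            sub = grp[grp["_time"] == t]
            present = len(sub) > 0
            pattern += "1" if present else "0"
            rec[f"count_{t}"] = (
                int(sub["read_count"].sum()) if "read_count" in sub.columns else 0
            ) if present else 0
        rec["pattern"] = pattern
        rec["persistent"] = pattern == "1" * len(times)
        rows.append(rec)
    table = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    n = len(table)
    n_pers = int(table["persistent"].sum())
    return table, {
        "n_chains": n,
        "n_persistent": n_pers,
        "persistent_fraction": n_pers / n if n else float("nan"),
    }


def union_region_fold_change(
    peaks_t1: pd.DataFrame,
    peaks_t2: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-region log2 fold change of library-normalized read counts.

    Comparison regions are interval unions of overlapping t1/t2 peaks
    (peaks private to one time point form their own region). Per region:
    ``log2((c2/N2 + p) / (c1/N1 + p))`` with N the total read count of each
    time point and ``p`` the pseudocount on the normalized scale. No
    significance test is computed.
    """
    p1 = _validate(peaks_t1).copy()
    p2 = _validate(peaks_t2).copy()
    for p, lab in ((p1, "t1"), (p2, "t2")):
        if "read_count" not in p.columns:
            raise ValueError(f"peaks_{lab} lack a read_count column")
    N1 = float(p1["read_count"].sum())
    N2 = float(p2["read_count"].sum())
    if N1 == 0 or N2 == 0:
        raise ValueError("zero library size")
    p1["_time"], p2["_time"] = "t1", "t2"
    allp = pd.concat([p1, p2], ignore_index=True)
    allp["_comp"] = _overlap_components(allp)
    rows = []
    for comp, grp in allp.groupby("_comp", sort=True):
        c1 = float(grp.loc[grp["_time"] == "t1", "read_count"].sum())
        c2 = float(grp.loc[grp["_time"] == "t2", "read_count"].sum())
        l2fc = float(np.log2((c2 / N2 + pseudocount) / (c1 / N1 + pseudocount)))
        rows.append(
            (grp["chrom"].iloc[0], int(grp["start"].min()), int(grp["end"].max()),
             c1, c2, l2fc)
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "count_t1", "count_t2", "log2fc"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
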