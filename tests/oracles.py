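"""Independent brute-force oracles used to validate the implementations.

These deliberately use the most naive formulation available (double loops,
bp-resolution boolean arrays, exact rational arithmetic) and share no code
with the package.
"""
from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


# --- correlation / transition index ---------------------------------------

def pearson_brute(x, y) -> float:
    """Two-pass covariance Pearson correlation; nan on zero variance."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / math.sqrt(sxx * syy)


def ic_brute(matrix: np.ndarray, threshold: float = 0.70, use_abs: bool = False):
    """Naive double-loop transition index of a genes x cells matrix.

    Returns (ic, mean_gg, mean_cc, n_gg, n_cc); ic is nan when either
    retained set is empty.
    """
    def retained_mean(vectors):
        kept = []
        for i in range(len(vectors)):
            for j in range(i + 1, len(vectors)):
                r = pearson_brute(vectors[i], vectors[j])
                val = abs(r) if use_abs else r
                if not math.isnan(r) and val > threshold:
                    kept.append(r)
        if not kept:
            return float("nan"), 0
        return sum(kept) / len(kept), len(kept)

    genes = [matrix[i, :] for i in range(matrix.shape[0])]
    cells = [matrix[:, j] for j in range(matrix.shape[1])]
    mg, ng = retained_mean(genes)
    mc, nc = retained_mean(cells)
    ic = mg / mc if ng > 0 and nc > 0 else float("nan")
    return ic, mg, mc, ng, nc


# --- Fisher exact ----------------------------------------------------------

def fisher_brute(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-sided p by full enumeration with rational arithmetic."""
    n = a + b + c + d
    r1, r2, c1 = a + b, c + d, a + c
    total = math.comb(n, c1)
    p_obs = Fraction(math.comb(r1, a) * math.comb(r2, c1 - a), total)
    acc = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_x = Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), total)
        if p_x <= p_obs:
            acc += p_x
    return acc


# --- bp-resolution interval oracles ---------------------------------------

def coverage(peaks, length: int) -> np.ndarray:
    """Boolean coverage array of half-open intervals on one chromosome."""
    cov = np.zeros(length, dtype=bool)
    for s, e in peaks:
        cov[s:e] = True
    return cov


def runs(cov: np.ndarray):
    """Maximal runs of True as (start, end) half-open pairs."""
    out = []
    in_run = False
    for i, v in enumerate(cov):
        if v and not in_run:
            start, in_run = i, True
        elif not v and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(cov)))
    return out


def intersect_brute(peaksets, length: int):
    """bp-wise intersection of donor coverages -> merged segments."""
    cov = np.ones(length, dtype=bool)
    for pk in peaksets:
        cov &= coverage(pk, length)
    return runs(cov)


def overlaps(a, b) -> bool:
    """>= 1 bp overlap of two half-open intervals."""
    return a[0] < b[1] and b[0] < a[1]


def annotate_brute(peaks, features):
    """All-pairs overlap scan.

    ``features``: list of (start, end, category). Returns a list of category
    sets (empty -> intergenic) plus the per-category totals dict including
    ``intergenic``.
    """
    cats = []
    for pk in peaks:
        hit = {c for (s, e, c) in features if overlaps(pk, (s, e))}
        cats.append(hit)
    totals: dict[str, int] = {}
    for hit in cats:
        for c in hit or {"intergenic"}:
            totals[c] = totals.get(c, 0) + 1
    return cats, totals


def open_calls_brute(promoters, peaks):
    """Per-promoter any-overlap against a peak list (quadratic)."""
    return [any(overlaps(pr, pk) for pk in peaks) for pr in promoters]


def chains_brute(peaks_by_time: dict, length: int):
    """Transitive >=1 bp overlap chaining via per-bp union-find.

    Returns a set of frozen chain descriptors: (start, end, pattern).
    """
    items = []  # (time_index, start, end)
    times = list(peaks_by_time)
    for ti, t in enumerate(times):
        for s, e in peaks_by_time[t]:
            items.append((ti, s, e))
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    by_pos: list[list[int]] = [[] for _ in range(length)]
    for idx, (_, s, e) in enumerate(items):
        for pos in range(s, e):
            by_pos[pos].append(idx)
    for members in by_pos:
        for k in range(1, len(members)):
            union(members[0], members[k])

    chains: dict[int, list[int]] = {}
    for idx in range(len(items)):
        chains.setdefault(find(idx), []).append(idx)
    out = set()
    for members in chains.values():
        start = min(items[i][1] for i in members)
        end = max(items[i][2] for i in members)
        present = {items[i][0] for i in members}
        pattern = "".join("1" if ti in present else "0" for ti in range(len(times)))
        out.add((start, end, pattern))
    return out
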