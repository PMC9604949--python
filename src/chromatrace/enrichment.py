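"""Combined expression / accessibility enrichment tables and exact tests.

Builds the 4-group (chromatin configuration x DE status) and 8-group
(configuration x TF-target class) count tables and tests each contrast with
a two-sided Fisher exact test (probability-mass rule).
"""
from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .peaks import CONFIG_LABELS

__all__ = [
    "EnrichmentResult",
    "fisher_two_sided",
    "config_by_de_table",
    "config_contrasts",
    "eight_group_table",
    "eight_group_contrasts",
    "tf_target_de_test",
]


@dataclass
class EnrichmentResult:
    """One tested 2x2 contrast."""

    labels: tuple[str, ...]
    table: np.ndarray  # 2x2 counts
    odds_ratio: float  # (a*d)/(b*c); inf / 0 on zero cells, nan if doubly zero
    p_value: float
    direction: str  # "over" | "under" | "none"
    flagged: bool = False  # odds ratio degenerate (zero cell)


def fisher_two_sided(table) -> EnrichmentResult:
    """Two-sided Fisher exact test by the probability-mass rule.

    p is the sum of hypergeometric probabilities, over all 2x2 tables with
    the observed margins, of tables whose probability does not exceed that
    of the observed table. Probabilities are compared as exact integer
    weights (``C(r1, x) * C(r2, c1 - x)``), so ties are resolved exactly
    with no floating-point tolerance; the returned p is correct to float
    rounding. The odds ratio is the sample (a*d)/(b*c).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c

    if n == 0:
        return EnrichmentResult(("",), t, float("nan"), 1.0, "none", True)

    r2 = c + d
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    w_obs = comb(r1, a) * comb(r2, c1 - a)
    acc = 0
    for x in range(lo, hi + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        if w <= w_obs:
            acc += w
    total = comb(n, c1)
    p = 1.0 if acc == total else acc / total

    if a * d > 0 and b * c > 0:
        odds = (a * d) / (b * c)
        flagged = False
    elif b * c > 0:
        odds, flagged = 0.0, True
    elif a * d > 0:
        odds, flagged = float("inf"), True
    else:
        odds, flagged = float("nan"), True
    if np.isnan(odds) or odds == 1.0:
        direction = "none"
    else:
        direction = "over" if odds > 1.0 else "under"
    return EnrichmentResult(("",), t, odds, p, direction, flagged)


# ---------------------------------------------------------------------------
# 4-group table: configuration x DE status
# ---------------------------------------------------------------------------

def _gene_config_pairs(promoter_configs: pd.DataFrame) -> pd.DataFrame:
    """Distinct (gene_id, config) pairs; multi-promoter genes may repeat."""
    pairs = promoter_configs[["gene_id", "config"]].dropna()
    pairs = pairs[pairs["gene_id"] != ""]
    return pairs.drop_duplicates()


def config_by_de_table(
    de_records: pd.DataFrame, promoter_configs: pd.DataFrame
) -> pd.DataFrame:
    """Counts of DE and non-DE genes per chromatin configuration.

    A gene contributes to every configuration class among its promoters, so
    column sums may exceed the number of genes. The universe is the genes of
    ``de_records`` that carry at least one configuration.
    """
    if len(de_records) == 0:
        raise ValueError("empty gene universe")
    de_status = de_records.set_index("gene_id")["de_flag"] != "none"
    pairs = _gene_config_pairs(promoter_configs)
    pairs = pairs[pairs["gene_id"].isin(de_status.index)]
    pairs = pairs.assign(de=pairs["gene_id"].map(de_status))
    table = (
        pairs.groupby(["config", "de"]).size().unstack(fill_value=0)
        .reindex(list(CONFIG_LABELS), fill_value=0)
    )
    out = pd.DataFrame(index=table.index)
    out["de"] = table.get(True, pd.Series(0, index=table.index))
    out["non_de"] = table.get(False, pd.Series(0, index=table.index))
    return out


def config_contrasts(table: pd.DataFrame) -> list[EnrichmentResult]:
    """One-vs-rest Fisher test of DE over-representation per configuration."""
    results = []
    for cfg in table.index:
        a = int(table.loc[cfg, "de"])
        c = int(table.loc[cfg, "non_de"])
        b = int(table["de"].sum() - a)
        d = int(table["non_de"].sum() - c)
        res = fisher_two_sided([[a, b], [c, d]])
        res.labels = (str(cfg), "de_vs_rest")
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# 8-group table: configuration x TF-target class
# ---------------------------------------------------------------------------

def eight_group_table(
    de_records: pd.DataFrame,
    tf_status: pd.DataFrame,
    promoter_configs: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    """Counts per {4 configs} x {de_tf, non_de_tf} over targeted genes.

    Untargeted genes are excluded from the table and returned separately.
    ``tf_status`` is the per-gene class table from
    :func:`chromatrace.de.classify_tf_status` (columns gene_id, tf_class).
    """
    cls = tf_status.set_index("gene_id")["tf_class"]
    universe = de_records["gene_id"]
    n_untargeted = int((cls.reindex(universe) == "untargeted").sum())
    targeted = cls[cls != "untargeted"]
    pairs = _gene_config_pairs(promoter_configs)
    pairs = pairs[pairs["gene_id"].isin(targeted.index)]
    pairs = pairs.assign(tf_class=pairs["gene_id"].map(targeted))
    table = (
        pairs.groupby(["config", "tf_class"]).size().unstack(fill_value=0)
        .reindex(list(CONFIG_LABELS), fill_value=0)
    )
    for col in ("de_tf", "non_de_tf"):
        if col not in table.columns:
            table[col] = 0
    return table[["de_tf", "non_de_tf"]], n_untargeted


def eight_group_contrasts(table: pd.DataFrame) -> list[EnrichmentResult]:
    """Per-configuration test: de_tf vs non_de_tf, in-config vs rest."""
    results = []
    for cfg in table.index:
        a = int(table.loc[cfg, "de_tf"])
        b = int(table.loc[cfg, "non_de_tf"])
        c = int(table["de_tf"].sum() - a)
        d = int(table["non_de_tf"].sum() - b)
        res = fisher_two_sided([[a, b], [c, d]])
        res.labels = (str(cfg), "de_tf_vs_non_de_tf")
        results.append(res)
    return results


def tf_target_de_test(
    de_records: pd.DataFrame, tf_status: pd.DataFrame
) -> EnrichmentResult:
    """Are DE genes over-represented among targets of DE TFs?

    2x2: rows = targeted by a DE TF vs targeted only by non-DE TFs,
    columns = DE vs non-DE. Untargeted genes are excluded.
    """
    merged = de_records.merge(tf_status, on="gene_id")
    merged = merged[merged["tf_class"] != "untargeted"]
    de = merged["de_flag"] != "none"
    is_de_tf = merged["tf_class"] == "de_tf"
    a = int((de & is_de_tf).sum())
    b = int((~de & is_de_tf).sum())
    c = int((de & ~is_de_tf).sum())
    d = int((~de & ~is_de_tf).sum())
    res = fisher_two_sided([[a, b], [c, d]])
    res.labels = ("de_tf_targeted", "de_vs_non_de")
    return res


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flatten a list of contrasts into a tidy table."""
    return pd.DataFrame(
        {
            "contrast": ["|".join(r.labels) for r in results],
            "a": [int(r.table[0, 0]) for r in results],
            "b": [int(r.table[0, 1]) for r in results],
            "c": [int(r.table[1, 0]) for r in results],
            "d": [int(r.table[1, 1]) for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.direction for r in results],
            "flagged": [r.flagged for r in results],
        }
    )
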