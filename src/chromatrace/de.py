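"""Z-score differential expression between consecutive time points.

For each gene, z = (mean_t2 - mean_t1) / sqrt(sd_t2^2 + sd_t1^2) over the
cells of one donor; donor z values are averaged (unweighted) and genes are
called up/down at an inclusive +/-2 threshold. TF-target classes are then
assigned from a confidence-filtered regulatory network.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import UMICountMatrix
from .simulate import TFTargetNetwork

__all__ = [
    "ZScoreRecord",
    "zscore",
    "call_de",
    "classify_tf_status",
    "DE_FLAGS",
    "TF_CLASSES",
]

DE_FLAGS = ("up", "down", "none")
TF_CLASSES = ("de_tf", "non_de_tf", "untargeted")

#: Sentinel magnitude used when both SDs are zero but the means differ:
#: threshold + 10 on the default threshold of 2.
SENTINEL = 12.0


@dataclass
class ZScoreRecord:
    gene_id: str
    z_by_donor: dict[str, float]
    mean_z: float
    de_flag: str
    interval: tuple[str, str]


def zscore(
    matrix_t1: UMICountMatrix,
    matrix_t2: UMICountMatrix,
    sentinel: float = SENTINEL,
) -> pd.Series:
    """Per-gene z for one donor between two time points.

    Standard deviations are sample SDs (ddof=1) over cells. When both SDs
    are zero: z = 0 if the means are equal, else +/- ``sentinel`` preserving
    the direction of change.
    """
    if matrix_t1.gene_ids != matrix_t2.gene_ids:
        raise ValueError("mismatched gene universes between time points")
    if matrix_t1.donor != matrix_t2.donor:
        raise ValueError("zscore compares two time points of the same donor")
    for m in (matrix_t1, matrix_t2):
        if m.n_cells < 2:
            raise ValueError("each matrix needs at least 2 cells")
    x1 = matrix_t1.counts.astype(float)
    x2 = matrix_t2.counts.astype(float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    s1, s2 = x1.std(axis=1, ddof=1), x2.std(axis=1, ddof=1)
    denom = np.sqrt(s1**2 + s2**2)
    diff = m2 - m1
    with np.errstate(invalid="ignore", divide="ignore"):
        z = diff / denom
    zero = denom == 0
    z[zero & (diff == 0)] = 0.0
    z[zero & (diff != 0)] = np.sign(diff[zero & (diff != 0)]) * sentinel
    return pd.Series(z, index=matrix_t1.gene_ids, name=matrix_t1.donor)


def call_de(
    z_by_donor: dict[str, pd.Series],
    threshold: float = 2.0,
    interval: tuple[str, str] = ("t1", "t2"),
) -> pd.DataFrame:
    """Average donor z-scores and flag DE genes at an inclusive threshold.

    Returns one row per gene of the shared universe with per-donor z
    columns, ``mean_z`` and ``de_flag`` in {up, down, none}; ``up`` iff
    mean_z >= +threshold, ``down`` iff mean_z <= -threshold.
    """
    if not z_by_donor:
        raise ValueError("at least one donor required")
    donors = sorted(z_by_donor)
    genes = z_by_donor[donors[0]].index
    for d in donors[1:]:
        genes = genes.intersection(z_by_donor[d].index)
    if len(genes) == 0:
        raise ValueError("no overlapping genes across donors")
    # keep the first donor's gene order for a stable output
    genes = [g for g in z_by_donor[donors[0]].index if g in set(genes)]

    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for d in donors:
        out[f"z_{d}"] = z_by_donor[d].loc[genes]
    out["mean_z"] = out[[f"z_{d}" for d in donors]].mean(axis=1)
    out["de_flag"] = "none"
    out.loc[out["mean_z"] >= threshold, "de_flag"] = "up"
    out.loc[out["mean_z"] <= -threshold, "de_flag"] = "down"
    out["interval"] = f"{interval[0]}-{interval[1]}"
    return out.reset_index()


def classify_tf_status(
    de_records: pd.DataFrame,
    network: TFTargetNetwork,
    min_confidence: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition genes by the DE status of the TFs targeting them.

    A gene is ``de_tf`` iff at least one surviving (confidence strictly
    > ``min_confidence``) incoming edge originates from a TF-coding gene
    flagged DE; ``non_de_tf`` iff it has surviving edges but none from a DE
    TF; ``untargeted`` otherwise. TFs absent from the DE universe trigger a
    warning and are treated as non-DE.

    Returns
    -------
    (gene_classes, tf_status)
        ``gene_classes``: gene_id, tf_class over the DE universe.
        ``tf_status``: tf, de (bool) for every TF with surviving edges.
    """
    de = de_records.set_index("gene_id")
    universe = list(de.index)
    edges = network.filtered(min_confidence)

    de_status = de["de_flag"] != "none"
    tfs = edges["tf"].unique()
    missing = [t for t in tfs if t not in de_status.index]
    if missing:
        warnings.warn(
            f"{len(missing)} TF id(s) absent from the gene universe; "
            "treated as non-DE",
            stacklevel=2,
        )
    tf_de = {t: bool(de_status.get(t, False)) for t in tfs}
    tf_status = pd.DataFrame(
        {"tf": list(tf_de), "de": [tf_de[t] for t in tf_de]}
    )

    targeted = edges.groupby("target")["tf"].agg(list)
    classes = []
    for g in universe:
        if g in targeted.index:
            if any(tf_de[t] for t in targeted[g]):
                classes.append("de_tf")
            else:
                classes.append("non_de_tf")
        else:
            classes.append("untargeted")
    gene_classes = pd.DataFrame({"gene_id": universe, "tf_class": classes})
    return gene_classes, tf_status
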