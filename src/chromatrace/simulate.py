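"""Synthetic-data generators with known ground truth.

Everything downstream of read-level processing is exercised on data produced
here: UMI count time courses from a two-state bursting model, peak sets with
scripted open/close schedules, feature annotations, scored TF->target
networks, binary single-cell accessibility matrices, and label-level draws
for enrichment calibration.

All generators are deterministic under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qc import UMICountMatrix

__all__ = [
    "CorrelatedBlock",
    "MeanShiftBlock",
    "ExpressionSimParams",
    "ExpressionSimResult",
    "simulate_expression",
    "PeakSimParams",
    "PeakSimResult",
    "simulate_peaksets",
    "build_annotation",
    "TFTargetNetwork",
    "simulate_tf_network",
    "simulate_scatac",
    "simulate_integration_labels",
    "nb_zero_probability",
]


# ---------------------------------------------------------------------------
# Expression: two-state bursting model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelatedBlock:
    """A gene block sharing a per-cell latent factor at designated times.

    The latent factor is ``exp(s_t * z_c)`` with ``z_c ~ N(0, 1)`` drawn once
    per cell and ``s_t`` the per-time strength; it multiplies the burst mean
    of every block gene, inducing controllable pairwise gene-gene
    correlation. Strength 0 disables the factor at that time point.
    """

    genes: tuple[int, ...]
    strength_per_time: tuple[float, ...]


@dataclass(frozen=True)
class MeanShiftBlock:
    """Deterministic per-time burst-mean multiplier for a gene block.

    Used to spike differential expression: e.g. a factor profile of
    ``(1, 4, 1, ...)`` quadruples the burst mean of the block genes at the
    second time point only.
    """

    genes: tuple[int, ...]
    factor_per_time: tuple[float, ...]


@dataclass
class ExpressionSimParams:
    """Parameters of the two-state expression simulator.

    Each gene in each cell is transcriptionally "on" with probability
    ``p_active`` (per gene class, per time point). "On" counts are drawn
    negative-binomial with the gene's burst mean and a common dispersion;
    "off" counts are zero except for a small leakage probability of a single
    stray UMI. Donor effects are independent multiplicative log-normal
    factors per gene.
    """

    n_genes: int = 200
    n_cells_per_time: int = 100
    time_points: tuple[str, ...] = ("5h", "24h", "48h", "72h", "96h")
    p_active_per_time: Sequence[float] | Mapping[str, Sequence[float]] = (
        0.15, 0.55, 0.75, 0.60, 0.45
    )
    gene_classes: Sequence[str] | None = None
    burst_mean: float = 5.0
    dispersion: float = 10.0
    mean_spread_sd: float = 0.5
    leakage: float = 0.01
    n_donors: int = 2
    donor_effect_sd: float = 0.1
    correlated_block: CorrelatedBlock | None = None
    mean_shift: MeanShiftBlock | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cells_per_time <= 0:
            raise ValueError("n_genes and n_cells_per_time must be positive")
        if self.n_donors <= 0:
            raise ValueError("n_donors must be positive")
        if len(set(self.time_points)) != len(self.time_points):
            raise ValueError("time point labels must be unique and ordered")
        if self.burst_mean <= 0 or self.dispersion <= 0:
            raise ValueError("burst_mean and dispersion must be > 0")
        if not 0 <= self.leakage <= 1:
            raise ValueError("leakage must be in [0, 1]")
        if self.donor_effect_sd < 0:
            raise ValueError("donor_effect_sd must be >= 0")

    def p_active_matrix(self) -> np.ndarray:
        """Per-gene x per-time activation probability matrix."""
        T = len(self.time_points)
        if isinstance(self.p_active_per_time, Mapping):
            if self.gene_classes is None:
                raise ValueError("gene_classes required with per-class p_active")
            rows = []
            for cls in self.gene_classes:
                prof = np.asarray(self.p_active_per_time[cls], dtype=float)
                if prof.shape != (T,):
                    raise ValueError("p_active profile length must match time points")
                rows.append(prof)
            mat = np.vstack(rows)
        else:
            prof = np.asarray(self.p_active_per_time, dtype=float)
            if prof.shape != (T,):
                raise ValueError("p_active profile length must match time points")
            mat = np.tile(prof, (self.n_genes, 1))
        if np.any((mat < 0) | (mat > 1)):
            raise ValueError("activation probabilities must lie in [0, 1]")
        return mat


@dataclass
class ExpressionSimResult:
    """Matrices keyed by ``(donor, time_point)`` plus ground truth.

    ``truth`` holds one row per gene: class label and the activation
    probability at every time point. ``on_states`` holds the latent per-cell
    on/off draw behind each matrix (genes x cells boolean).
    """

    matrices: dict[tuple[str, str], UMICountMatrix]
    truth: pd.DataFrame
    on_states: dict[tuple[str, str], np.ndarray]
    params: ExpressionSimParams


def nb_zero_probability(mean: float, dispersion: float) -> float:
    """P(X = 0) for a negative binomial with given mean and dispersion r."""
    r = dispersion
    return float((r / (r + mean)) ** r)


def simulate_expression(params: ExpressionSimParams) -> ExpressionSimResult:
    """Draw UMI count matrices for every donor x time point.

    Gene base means are log-normally spread around ``burst_mean`` (shared
    across donors and time points) so that cell state vectors correlate, as
    in real data where expression level spans orders of magnitude.
    """
    rng = np.random.default_rng(params.seed)
    G, C = params.n_genes, params.n_cells_per_time
    p_act = params.p_active_matrix()
    classes = (
        list(params.gene_classes)
        if params.gene_classes is not None
        else ["default"] * G
    )
    gene_ids = [f"G{i:05d}" for i in range(G)]

    # per-gene base mean and per-donor multiplicative effect
    base_mean = params.burst_mean * np.exp(
        rng.normal(0.0, params.mean_spread_sd, size=G) - params.mean_spread_sd**2 / 2
    )
    donors = [f"donor{d + 1}" for d in range(params.n_donors)]
    donor_factor = {
        d: np.exp(rng.normal(0.0, params.donor_effect_sd, size=G)) for d in donors
    }

    block = params.correlated_block
    if block is not None:
        if len(block.strength_per_time) != len(params.time_points):
            raise ValueError("correlated_block strengths must match time points")
        if max(block.genes, default=-1) >= G:
            raise ValueError("correlated_block gene index out of range")
    shift = params.mean_shift
    if shift is not None:
        if len(shift.factor_per_time) != len(params.time_points):
            raise ValueError("mean_shift factors must match time points")
        if max(shift.genes, default=-1) >= G:
            raise ValueError("mean_shift gene index out of range")

    matrices: dict[tuple[str, str], UMICountMatrix] = {}
    on_states: dict[tuple[str, str], np.ndarray] = {}
    r = params.dispersion
    for donor in donors:
        for ti, t in enumerate(params.time_points):
            on = rng.random((G, C)) < p_act[:, [ti]]
            mean = base_mean[:, None] * donor_factor[donor][:, None] * np.ones((G, C))
            if block is not None and block.strength_per_time[ti] > 0:
                z = rng.normal(0.0, 1.0, size=C)
                factor = np.exp(block.strength_per_time[ti] * z)
                mean[list(block.genes), :] *= factor[None, :]
            if shift is not None and shift.factor_per_time[ti] != 1.0:
                mean[list(shift.genes), :] *= shift.factor_per_time[ti]
            counts = np.zeros((G, C), dtype=np.int64)
            if on.any():
                m = mean[on]
                counts[on] = rng.negative_binomial(r, r / (r + m))
            off = ~on
            if params.leakage > 0 and off.any():
                leak = rng.random(int(off.sum())) < params.leakage
                counts[off] = leak.astype(np.int64)
            cell_ids = [f"{donor}_{t}_c{j:04d}" for j in range(C)]
            meta = pd.DataFrame(
                {
                    "total_reads": (counts.sum(axis=0) * 40 + 100_000).astype(int),
                    "mito_fraction": rng.uniform(0.01, 0.08, size=C),
                    "ercc_pearson": rng.uniform(0.8, 0.99, size=C),
                },
                index=cell_ids,
            )
            matrices[(donor, t)] = UMICountMatrix(
                counts=counts,
                gene_ids=gene_ids,
                cell_ids=cell_ids,
                donor=donor,
                time_point=t,
                cell_meta=meta,
            )
            on_states[(donor, t)] = on

    truth = pd.DataFrame({"gene_id": gene_ids, "gene_class": classes})
    for ti, t in enumerate(params.time_points):
        truth[f"p_active_{t}"] = p_act[:, ti]
    truth["base_mean"] = base_mean
    return ExpressionSimResult(matrices, truth, on_states, params)


# ---------------------------------------------------------------------------
# Bulk peaks: scripted open/close schedules
# ---------------------------------------------------------------------------

@dataclass
class PeakSimParams:
    """Parameters of the peak-set simulator.

    A catalog of disjoint promoter and intergenic sites is laid out on one
    synthetic chromosome. Each site is truly open at each time point with a
    scripted probability (scalar per time, or a per-site x per-time array);
    a truly open site is missed in a given donor with probability
    ``donor_dropout``.
    """

    genome_length: int = 1_000_000
    chrom: str = "chrS"
    n_promoters: int = 100
    n_intergenic_sites: int = 100
    promoter_width: int = 1_000
    intergenic_width: int = 500
    time_points: tuple[str, ...] = ("0h", "5h", "24h", "48h")
    open_probability_per_time: Sequence[float] | np.ndarray = (0.7, 0.9, 0.7, 0.5)
    readcount_mean_per_time: Sequence[float] = (50.0, 80.0, 60.0, 40.0)
    n_donors: int = 3
    donor_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_promoters < 0 or self.n_intergenic_sites < 0:
            raise ValueError("site counts must be non-negative")
        if not 0 <= self.donor_dropout <= 1:
            raise ValueError("donor_dropout must be in [0, 1]")
        n_sites = self.n_promoters + self.n_intergenic_sites
        span = n_sites * (max(self.promoter_width, self.intergenic_width) + 2)
        if span > self.genome_length:
            raise ValueError("genome too short for the requested site catalog")


@dataclass
class PeakSimResult:
    """Peak sets keyed by ``(donor, time_point)`` plus catalog and truth."""

    peaksets: dict[tuple[str, str], pd.DataFrame]
    catalog: pd.DataFrame  # site_id, chrom, start, end, category, gene_id
    truth: pd.DataFrame  # site_id x open_<time> booleans
    params: PeakSimParams


def _site_catalog(params: PeakSimParams, rng: np.random.Generator) -> pd.DataFrame:
    """Disjoint site catalog: promoters and intergenic sites interleaved."""
    n_sites = params.n_promoters + params.n_intergenic_sites
    slot = params.genome_length // max(n_sites, 1)
    width_max = max(params.promoter_width, params.intergenic_width)
    if slot <= width_max:
        raise ValueError("genome too short for the requested site catalog")
    kinds = ["promoter"] * params.n_promoters + ["intergenic"] * params.n_intergenic_sites
    order = rng.permutation(n_sites)
    rows = []
    prom_i = inter_i = 0
    for slot_i, idx in enumerate(order):
        kind = kinds[idx]
        width = params.promoter_width if kind == "promoter" else params.intergenic_width
        jitter = int(rng.integers(0, slot - width))
        start = slot_i * slot + jitter
        if kind == "promoter":
            site_id = f"prom{prom_i:05d}"
            gene_id = f"G{prom_i:05d}"
            prom_i += 1
        else:
            site_id = f"inter{inter_i:05d}"
            gene_id = ""
            inter_i += 1
        rows.append((site_id, params.chrom, start, start + width, kind, gene_id))
    return pd.DataFrame(
        rows, columns=["site_id", "chrom", "start", "end", "category", "gene_id"]
    )


def simulate_peaksets(params: PeakSimParams) -> PeakSimResult:
    """Emit per-donor, per-time peak sets from scripted open probabilities.

    Ground-truth open/closed labels are drawn once (shared by all donors)
    before dropout is applied, so the truth table reflects biology and the
    emitted peaks reflect per-donor detection.
    """
    rng = np.random.default_rng(params.seed)
    catalog = _site_catalog(params, rng)
    n_sites = len(catalog)
    T = len(params.time_points)
    p_open = np.asarray(params.open_probability_per_time, dtype=float)
    if p_open.ndim == 1:
        if p_open.shape != (T,):
            raise ValueError("open probability profile must match time points")
        p_open = np.tile(p_open, (n_sites, 1))
    elif p_open.shape != (n_sites, T):
        raise ValueError("open probability array must be (n_sites, n_times)")
    if np.any((p_open < 0) | (p_open > 1)):
        raise ValueError("open probabilities must lie in [0, 1]")

    open_truth = rng.random((n_sites, T)) < p_open
    truth = pd.DataFrame({"site_id": catalog["site_id"]})
    for ti, t in enumerate(params.time_points):
        truth[f"open_{t}"] = open_truth[:, ti]

    donors = [f"donor{d + 1}" for d in range(params.n_donors)]
    peaksets: dict[tuple[str, str], pd.DataFrame] = {}
    for donor in donors:
        for ti, t in enumerate(params.time_points):
            detected = open_truth[:, ti] & (
                rng.random(n_sites) >= params.donor_dropout
            )
            sub = catalog.loc[detected, ["chrom", "start", "end"]].reset_index(drop=True)
            reads = rng.poisson(params.readcount_mean_per_time[ti], size=len(sub)) + 1
            sub["name"] = catalog.loc[detected, "site_id"].values
            sub["score"] = 0
            sub["strand"] = "."
            sub["read_count"] = reads
            sub["donor"] = donor
            sub["time_point"] = t
            peaksets[(donor, t)] = sub
    return PeakSimResult(peaksets, catalog, truth, params)


def build_annotation(
    catalog: pd.DataFrame,
    n_extra_features: int = 0,
    genome_length: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature annotation table from a site catalog.

    Promoter sites become promoter features carrying their gene id;
    optionally adds random exon/intron/CpG/CTCF features placed anywhere on
    the chromosome (they may overlap sites, which is the interesting case
    for multi-category annotation).
    """
    ann = catalog.loc[
        catalog["category"] == "promoter",
        ["chrom", "start", "end", "category", "gene_id"],
    ].copy()
    if n_extra_features:
        rng = np.random.default_rng(seed)
        L = genome_length or int(catalog["end"].max() * 1.05)
        cats = rng.choice(["exon", "intron", "CpG", "CTCF"], size=n_extra_features)
        starts = rng.integers(0, max(L - 2_000, 1), size=n_extra_features)
        widths = rng.integers(200, 2_000, size=n_extra_features)
        extra = pd.DataFrame(
            {
                "chrom": catalog["chrom"].iloc[0],
                "start": starts,
                "end": starts + widths,
                "category": cats,
                "gene_id": "",
            }
        )
        ann = pd.concat([ann, extra], ignore_index=True)
    return ann.reset_index(drop=True)


# ---------------------------------------------------------------------------
# TF -> target network
# ---------------------------------------------------------------------------

@dataclass
class TFTargetNetwork:
    """Directed TF -> target edges with a confidence score in [0, 1].

    ``edges`` columns: ``tf``, ``target``, ``confidence`` and (for synthetic
    networks) a boolean ``coupled`` ground-truth flag marking targets whose
    expression shift copies their TF's shift.
    """

    edges: pd.DataFrame
    tf_universe: frozenset[str]

    def __post_init__(self) -> None:
        conf = self.edges["confidence"]
        if ((conf < 0) | (conf > 1)).any():
            raise ValueError("edge confidence must lie in [0, 1]")

    def filtered(self, min_confidence: float = 0.5) -> pd.DataFrame:
        """Edges surviving the strict confidence filter (> min_confidence)."""
        return self.edges[self.edges["confidence"] > min_confidence]


def simulate_tf_network(
    n_tfs: int,
    n_targets: int,
    gene_universe: Sequence[str],
    confidence_distribution: tuple = ("uniform", 0.0, 1.0),
    coupled_fraction: float = 0.0,
    edges_per_target: int = 1,
    seed: int = 0,
) -> TFTargetNetwork:
    """Random scored TF->target network over an existing gene universe.

    ``confidence_distribution`` is ``("constant", v)`` or
    ``("uniform", lo, hi)``. A ``coupled_fraction`` of targets is flagged as
    ground-truth coupled to their TF (used to validate enrichment calls).
    """
    if n_tfs <= 0 or n_targets <= 0:
        raise ValueError("n_tfs and n_targets must be positive")
    if n_tfs > len(gene_universe):
        raise ValueError("n_tfs exceeds the gene universe")
    rng = np.random.default_rng(seed)
    genes = list(gene_universe)
    tfs = genes[:n_tfs]
    pool = genes[n_tfs:] or genes
    targets = list(rng.choice(pool, size=min(n_targets, len(pool)), replace=False))

    rows = []
    for tgt in targets:
        chosen = rng.choice(tfs, size=min(edges_per_target, n_tfs), replace=False)
        for tf in np.atleast_1d(chosen):
            rows.append((tf, tgt))
    edges = pd.DataFrame(rows, columns=["tf", "target"])

    kind = confidence_distribution[0]
    if kind == "constant":
        edges["confidence"] = float(confidence_distribution[1])
    elif kind == "uniform":
        lo, hi = confidence_distribution[1], confidence_distribution[2]
        edges["confidence"] = rng.uniform(lo, hi, size=len(edges))
    else:
        raise ValueError(f"unknown confidence distribution: {kind!r}")

    coupled_targets = set(
        rng.choice(targets, size=int(round(coupled_fraction * len(targets))),
                   replace=False)
    ) if coupled_fraction > 0 else set()
    edges["coupled"] = edges["target"].isin(coupled_targets)
    return TFTargetNetwork(edges=edges, tf_universe=frozenset(tfs))


# ---------------------------------------------------------------------------
# Binary single-cell accessibility
# ---------------------------------------------------------------------------

def simulate_scatac(
    n_cells: int,
    peak_catalog: pd.DataFrame,
    sharing_profile: Sequence[float] | float,
    seed: int = 0,
) -> np.ndarray:
    """Binary cell x peak incidence with per-peak inclusion probabilities.

    ``sharing_profile`` is a scalar or one probability per catalog peak;
    expected cells-per-peak is ``n_cells * p``.
    """
    if len(peak_catalog) == 0:
        raise ValueError("empty peak catalog")
    p = np.broadcast_to(
        np.asarray(sharing_profile, dtype=float), (len(peak_catalog),)
    )
    if np.any((p < 0) | (p > 1)):
        raise ValueError("inclusion probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random((n_cells, len(peak_catalog))) < p[None, :]).astype(np.uint8)


# ---------------------------------------------------------------------------
# Label-level draws for enrichment calibration
# ---------------------------------------------------------------------------

CONFIGS = ("open-open", "open-closed", "closed-open", "closed-closed")


def simulate_integration_labels(
    n_genes: int = 2_000,
    p_de: float = 0.3,
    config_probs: Sequence[float] = (0.4, 0.2, 0.2, 0.2),
    p_targeted: float = 0.7,
    p_de_tf_given_targeted: float = 0.5,
    de_config_odds: float = 1.0,
    de_tf_odds: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-gene (DE, config, TF-class) labels, optionally coupled.

    With both odds at 1 the three labels are independent (null). With
    ``de_config_odds`` > 1, DE genes favour the open-open configuration by
    that odds multiplier; with ``de_tf_odds`` > 1, DE genes favour the
    DE-TF-targeted class. Returns columns ``gene_id``, ``de``, ``config``,
    ``tf_class`` (one of ``de_tf`` / ``non_de_tf`` / ``untargeted``).
    """
    rng = np.random.default_rng(seed)
    de = rng.random(n_genes) < p_de
    q = np.asarray(config_probs, dtype=float)
    q = q / q.sum()

    q_de = q.copy()
    q_de[0] *= de_config_odds
    q_de = q_de / q_de.sum()
    configs = np.empty(n_genes, dtype=object)
    configs[~de] = rng.choice(CONFIGS, size=int((~de).sum()), p=q)
    configs[de] = rng.choice(CONFIGS, size=int(de.sum()), p=q_de)

    targeted = rng.random(n_genes) < p_targeted
    p_base = p_de_tf_given_targeted
    odds_base = p_base / (1 - p_base)
    p_coupled = (odds_base * de_tf_odds) / (1 + odds_base * de_tf_odds)
    p_de_tf = np.where(de, p_coupled, p_base)
    de_tf = rng.random(n_genes) < p_de_tf
    tf_class = np.where(
        targeted, np.where(de_tf, "de_tf", "non_de_tf"), "untargeted"
    )
    return pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n_genes)],
            "de": de,
            "config": configs,
            "tf_class": tf_class,
        }
    )
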