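# chromatrace

Analysis toolkit for time courses of chromatin accessibility and stochastic
transcription activation. It reimplements, as a tested reusable pipeline,
the core computations of a combined scRNA-seq / bulk ATAC-seq / scATAC-seq
study design:

- **Quality control** (`chromatrace.qc`) — per-cell filters (total reads
  < 80,000; mitochondrial fraction > 10%; spike-in amplification Pearson
  correlation ≤ 0.6), the two-part gene detectability rule (≥ 2 cells with
  more than a single UMI and ≥ 5 reads in total), and genes-per-cell
  summaries.
- **Index for critical transitions** (`chromatrace.transition`) — per cell
  cluster, the ratio of the mean retained gene–gene to mean retained
  cell–cell Pearson correlation, keeping only coefficients strictly above
  0.70 (signed by default; `--use-abs` available).
- **Z-score differential expression** (`chromatrace.de`) —
  `z = (mean₂ − mean₁) / sqrt(sd₂² + sd₁²)` per gene and donor, unweighted
  donor averaging, inclusive ±2 calling, and TF-target classification from
  a confidence-scored network (strict > 0.5 edge filter).
- **Peak interval algebra** (`chromatrace.peaks`) — bp-wise
  donor-reproducible intersection, multi-category genomic annotation with
  intergenic-by-exclusion, per-promoter open/closed calls, four-way
  open/closed configuration classification across an interval, presence
  trajectories over a time course, and union-region log2 fold changes.
- **Enrichment** (`chromatrace.enrichment`) — the 4-group
  (configuration × DE) and 8-group (configuration × TF-target class)
  contingency tables with two-sided Fisher exact tests (probability-mass
  rule, exact integer arithmetic).
- **scATAC sharing** (`chromatrace.scatac`) — per-peak cells-sharing counts,
  medians per annotation category, and concordance with bulk peak sets.
- **Synthetic data** (`chromatrace.simulate`) — all pipeline inputs with
  known ground truth: UMI matrices from a two-state bursting model
  (negative-binomial "on" counts, configurable leakage, donor effects,
  correlated gene blocks, spiked mean shifts), peak sets with scripted
  open/close schedules and donor dropout, scored TF→target networks, binary
  cell × peak incidence matrices, and label-level draws for enrichment
  calibration.

All coordinates are 0-based half-open (BED convention); the overlap
predicate is ≥ 1 bp throughout.

## CLI

One `chromatrace` entry point with a subcommand per stage:

```sh
# synthetic inputs (MTX/BED/TSV + ground-truth tables)
chromatrace simulate expression --config cfg.yml --seed 1 --out sim/
chromatrace simulate peaks --seed 1 --out sim/

# QC with the default thresholds
chromatrace qc --counts counts.tsv --meta meta.tsv --out qc/

# per-cluster transition index
chromatrace ic --counts counts.tsv --clusters clusters.tsv --threshold 0.70 --out ic.tsv

# Z-score DE across donors + TF-target classes
chromatrace de --pair donor1:t1.tsv:t2.tsv --pair donor2:t1.tsv:t2.tsv \
    --network net.tsv --out-de de.tsv --out-tf tf.tsv

# interval operations
chromatrace peaks intersect d1.bed d2.bed d3.bed --out reproducible.bed
chromatrace peaks annotate --peaks reproducible.bed --annotation ann.tsv --out annot.tsv
chromatrace peaks configs --annotation ann.tsv --t1 5h:p5.bed --t2 24h:p24.bed --out configs.tsv
chromatrace peaks trajectories --time 0h:p0.bed --time 5h:p5.bed --out traj.tsv
chromatrace peaks foldchange --t1 p5.bed --t2 p24.bed --out fc.tsv

# integration + exact tests
chromatrace integrate --de de.tsv --tf-status tf.tsv --configs configs.tsv --out integ/

# single-cell sharing statistics
chromatrace scatac --incidence inc.mtx --peaks peaks.bed --barcodes bc.txt \
    --bulk bulk.bed --out sc/

# the whole synthetic workflow end to end
chromatrace pipeline --outdir run/ --seed 1
```

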