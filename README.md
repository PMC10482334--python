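# longomix

Analysis toolkit for longitudinal two-condition (test vs control)
multi-omics abundance tables, as produced by fed-batch culture studies
sampled over days with a few biological replicates. It provides, as a
tested reusable pipeline:

- **Synthetic data** (`longomix.synthetic`) — a generator for feature ×
  sample tables with a dominant smooth time trajectory (calibrated to a
  target variance share), log-normal replicate noise, a planted
  condition effect on chosen features, condition-exclusive features, and
  matching annotation evidence — all with ground truth for recovery tests.
- **Preprocessing** (`longomix.preprocess`) — feature-retention rules
  (retention-time window 0.8–9.0 min inclusive, max abundance strictly
  > 5,000), missing-value imputation, mean centering and pareto scaling.
- **OPLS-DA** (`longomix.opls`) — from-scratch orthogonal PLS
  discriminant analysis: predictive/orthogonal variance split (R2X),
  R2Y, stratified K-fold cross-validated Q2 (scaling refit per training
  fold), a label-permutation validity test (default 200 permutations,
  `p = (1 + #{Q2_perm ≥ Q2_obs}) / (n_perm + 1)`), and the
  loading-significance rule (|predictive loading| > SD of the loading
  vector).
- **Differential analysis** (`longomix.differential`) — trapezoidal
  abundance-over-time integrals (AUC) per condition, signed fold changes
  (down-regulation reported as −1/r; infinity sentinels for
  one-condition detections), maximum per-day fold change, and regulation
  calls (threshold 1.5 for metabolites, 1.1 for proteins, boundary
  inclusive, conjunct with OPLS significance).
- **Annotation** (`longomix.annotation`) — identification-confidence
  tiers 1/1*/2/3/4/5 from mass (±3.0 ppm), retention time (±0.3 min),
  MS/MS match flags and isotope fit (mSigma < 100), plus tier ×
  abundance-bin summaries.
- **Pipeline + CLI** (`longomix.pipeline`, `longomix.cli`) — YAML-driven
  orchestration with a reproducible run manifest.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(OPLS oracle equivalence against an independent OSC+PLS implementation,
variance conservation, PLS reduction limit, permutation-test
calibration, parameter recovery on the standard synthetic design,
structural variance mimicry, AUC quadrature oracle, and an exhaustive
tier-rule truth table).

## CLI

```sh
longomix simulate --config design.yaml --seed 1 --out data/
longomix preprocess --table data/abundances.tsv --meta data/samples.tsv \
    --features data/features.tsv --out filtered/
longomix opls --table filtered/filtered_abundances.tsv \
    --meta filtered/filtered_samples.tsv --scale pareto \
    --n-ortho auto --permutations 200 --seed 1 --out model/
longomix diff --table data/abundances.tsv --meta data/samples.tsv \
    --mode metabolite --significant model/significant_features.tsv \
    --out calls.tsv
longomix annotate --evidence ev.tsv --library lib.tsv --out annots.tsv
longomix run --config pipeline.yaml          # everything at once
```

A pipeline YAML mirrors `longomix.pipeline.PipelineConfig`, e.g.

```yaml
simulate:
  n_features: 2000
  n_discriminative: 50
  days: [3, 5, 7, 10, 12, 14, 17]
  seed: 1
mode: metabolite      # or protein (fold threshold 1.1)
scaling: pareto       # or center
n_ortho: auto
n_perm: 200
out_dir: results/run1
```

All tabular I/O is TSV with headers; each run writes scores, loadings,
the significant-feature list, differential calls (with annotation tiers
when evidence is supplied), model diagnostics, and a `manifest.json`
sufficient to reproduce the run byte-identically.

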