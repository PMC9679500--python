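# specstarch

A tested, reusable pipeline for calibrating near-infrared (NIR) reflectance
spectra (740–1070 nm, 1 nm grid) against fresh-root starch content in
multi-trial plant-breeding experiments. The package covers the full analysis
chain:

- **Synthetic data** (`specstarch.synthetic`) — multi-trial RCBD /
  alpha-lattice field designs, additive random-effects starch phenotypes and
  a band-mixture spectral forward model with known ground truth, so every
  downstream stage is testable without external data.
- **Spectra I/O** (`specstarch.spectra_io`) — CSV read/write with grid
  validation, scan averaging, wavelength trimming, root-starch-content
  utility, per-trial descriptive statistics.
- **Pretreatment** (`specstarch.pretreat`) — 13 variants: raw, SNV,
  finite-difference first/second derivatives, Savitzky–Golay smoothing and
  derivatives (windows 5/11), gap-segment derivative (window 11) and SNV
  combinations. Edge points are dropped, never padded.
- **Outlier QC** (`specstarch.qc`) — exploratory PCA and Mahalanobis-distance
  filtering in a retained principal-component space (threshold behaves like
  an SD rule).
- **Models** (`specstarch.models`) — first-party NIPALS PLSR (per-rank
  regression vectors, weights/loadings retained for importance analysis),
  radial-kernel SVM and random-forest delegates behind one fit/predict
  contract, 5-fold grouped hyperparameter selection by minimum RMSECV.
- **Evaluation** (`specstarch.evaluation`) — genotype-grouped 70/30 splits
  repeated 50×, the metric suite (R²p, R²cv, RMSEP, RMSECV, SEP, bias, RPD,
  RPIQ, CCC) and the CV2/CV1/CV0/CV00 genotype-by-environment validation
  schemes with programmatic plan verification.
- **Importance** (`specstarch.importance`) — VIP scores for PLSR,
  seeded permutation importance for any model, top-k wavelength reports.
- **Heritability** (`specstarch.heritability`) — profile-REML variance
  components for RCBD and alpha-lattice models, entry-mean broad-sense
  heritability, and a per-wavelength heritability scan.
- **Pipeline & CLI** (`specstarch.pipeline`, `specstarch.cli`) — config-driven
  orchestration with seeded, bit-reproducible runs and a manifest.

## CLI

```bash
specstarch simulate --config sim.yaml --out data/ --seed 7
specstarch summarize --reference data/reference.csv
specstarch qc --in data/spectra.csv --threshold 3 --report qc.json
specstarch pretreat --method SG.D2W11 --in data/spectra.csv --out treated.csv
specstarch train --spectra data/spectra.csv --reference data/reference.csv \
    --algo plsr --pretreat SG --out model.json
specstarch evaluate --spectra data/spectra.csv --reference data/reference.csv \
    --scheme CV1 --niter 50 --seed 7 --out metrics.csv
specstarch importance --spectra data/spectra.csv --reference data/reference.csv \
    --top 10 --out vip.csv
specstarch heritability --spectra data/spectra.csv --reference data/reference.csv \
    --out h2.csv
specstarch run --config pipeline.yaml --seed 7
```

A pipeline config is YAML/JSON mirroring `PipelineConfig`; defaults follow
the standard analysis settings (70% calibration fraction, 50 iterations,
Mahalanobis threshold 3, 5-fold tuning).

## Reproducibility

Every stochastic stage takes an explicit seed; a single top-level pipeline
seed deterministically spawns per-stage seeds, and identical configs produce
bit-identical CSV artifacts and a matching manifest hash.
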