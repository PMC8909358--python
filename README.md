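# spheroflux

Analysis toolkit for extracellular-flux (Seahorse-style) assays on
single-spheroid 3-D cultures:

- **flux_io** — per-well OCR/ECAR rate tables, plate layouts, background
  correction, injection-phase labelling
- **morphometry** — spheroid area, roundness (circularity 4πA/P²) and
  centroid from fluorescence z-stacks (max projection → Otsu → largest
  component), plus pre/post-assay displacement
- **calibration** — standard curves mapping spheroid area (or protein/DNA
  content) to viable-cell counts; size-class binning
- **qc** — within-phase OCR jump detection (movement artifacts),
  displacement flags, config-driven well exclusion
- **mito_stress** — the six Mito Stress respiration parameters per well
  (non-mitochondrial, basal, ATP-linked, proton leak, maximal, spare
  capacity) under per-well / per-1000-cells / per-1000-µm² bases
- **phenotyping** — CV summaries, min–max scaling, covariance PCA,
  average-linkage (UPGMA) clustering, Welch t-tests, bioenergetic
  OCR-vs-ECAR maps
- **synthetic_cohort** — a fully deterministic simulator of spheroid
  cohorts (cell counts, areas, images, four-phase kinetics, background
  wells, movement artifacts) with ground-truth tables

## CLI

```sh
# generate a synthetic dataset (CSV rates/layout/areas/calibration + YAML)
spheroflux simulate -o data/ --seed 1 --protocol single --n-wells 45

# run the full pipeline: QC -> calibration -> Mito Stress -> phenotyping
spheroflux analyze -c data/run_config.yaml -o run/

# segment spheroid TIFF stacks into a morphometry CSV
spheroflux morphometry well_*.tif --pixel-size-um 4.6 -o morpho.csv

# print the summary of a finished run
spheroflux report run/
```

`analyze` writes `params.csv`, `qc.csv`, `cv_summary.csv`,
`scaled_matrix.csv`, `pca_scores.csv` / `pca_loadings.csv` /
`pca_explained.csv`, `clusters.csv`, `dendrogram.newick`,
`bioenergetic_map.csv` and `summary.txt`. Runs are byte-identical given the
same config and seed. Exit codes: 0 ok, 1 validation error, 2 runtime
error.

Run configs are plain YAML; see the `run_config.yaml` emitted by
`simulate` for the schema (paths, schedule, background correction, QC
thresholds, normalization basis, size-class edges, analysis toggles).

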