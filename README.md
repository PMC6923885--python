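# gbmrad

MRI radiomics pipeline for predicting glioblastoma transcriptomic subtype
(classical, mesenchymal, proneural, neural) from co-registered structural
MRI (T1, T1-Gd, T2, T2-FLAIR) and ED/ET/NET sub-region segmentations.

The package provides:

- **`gbmrad.io_core`** — domain types (volumes, studies, segmentation masks,
  anatomy context, feature tables), NIfTI/CSV/JSON readers and writers.
- **`gbmrad.synthetic_cohort`** — a labeled synthetic cohort generator
  (nested-ellipsoid tumors in a shared brain mask) with auditable
  class-conditional effects on intensity, size, eccentricity, and placement,
  so every downstream stage is testable without any external data.
- **`gbmrad.preprocess`** — quantile-map histogram matching of each channel
  to a reference subject (within the brain mask).
- **`gbmrad.radiomics`** — volumetrics (volumes, brain-ratios, exposed-face
  surface areas), first-order moments, 5-bin histogram percentages, GLCM
  texture (unit radius, 13 unique 3-D directions, pooled symmetric matrix),
  2-D morphology on the max-tumor-core axial slice, ventricle distances, and
  lobe proportions.
- **`gbmrad.location_atlas`** — per-subtype spatial frequency atlas pairs
  (P⁺/P⁻) built by superimposing tumor-core masks, and the 16 relative
  location features (L1–L4 per subtype).
- **`gbmrad.subtype_model`** — four one-vs-rest linear max-margin
  classifiers with sequential forward feature selection and inner-CV
  hyperparameter search, max-hyperplane-distance fusion, and leakage-safe
  stratified 5-fold cross-validation (atlases, scalers, imputation medians,
  and selected features are all recomputed per training fold); metric suite
  with per-class ROC/AUC.
- **`gbmrad.association_stats`** — tie-corrected Kruskal–Wallis screening of
  every feature with Benjamini–Hochberg q-values and group histograms.

## CLI

```sh
gbmrad simulate  --config config.yaml --out cohort/         # NIfTIs + manifest.csv
gbmrad preprocess --manifest cohort/manifest.csv --reference classical-000 --out matched/
gbmrad extract   --manifest cohort/manifest.csv --out features.csv
gbmrad train     --features features.csv --out model.json
gbmrad evaluate  --manifest cohort/manifest.csv --folds 5 --seed 1 --out report.json
gbmrad associate --features features.csv --out associations.csv
```

`simulate` config keys (YAML, all optional): `seed`, `n_per_class`,
`shape`, `spacing`, `noise_sd`, `center_jitter_mm`, and `effects: none`
for a null cohort.

## Conventions

- Segmentation labels follow the BraTS encoding: 1 = NET, 2 = ED, 4 = ET;
  TC = NET ∪ ET, WT = TC ∪ ED.
- Voxel indices are 0-based; axial slices are fixed-z planes; physical
  quantities multiply by the per-axis spacing (mm).
- Moments are population moments; kurtosis is non-excess. Surface area
  counts exposed voxel faces; 2-D perimeter counts exposed pixel edges.
- Feature names follow `<family>_<region>_<channel>_<stat>`; location
  features are `loc_<subtype>_L{1..4}`.
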