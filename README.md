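# ctradiomics

CT radiomics and multiomic response modelling toolkit: a 342-feature
radiomic extractor for tumor CT volumes, two feature-selection procedures
(ReliefF and a relevancy–redundancy statistical ranking), a small
classifier grid with stratified hold-out validation, four end-to-end
prediction experiments, and a synthetic cohort generator that emulates
the imaging + transcriptomic inputs so the whole pipeline runs without
any external data.

## What's inside

| module | role |
| --- | --- |
| `synthetic_cohort` | synthetic CT volumes/masks, a 2,559-gene log-expression matrix with a 27-gene HOT/COLD signature, and outcome labels |
| `imaging_io` | NIfTI and DICOM-series volume/mask I/O and the `(x, y, z)` geometry contract |
| `preprocessing` | isotropic nearest-neighbour resampling; equal-probability gray-level quantization (G ∈ {8, 16, 24, 32, 40, 48, 64}) |
| `shape_features` | size/surface/diameter, Hu (8), affine (6) and Zernike moments, skeleton and radial-distance features |
| `texture_features` | first-order histogram stats; GLCM/GLRLM (4 in-plane directions, offset 1), GLSZM/NGTDM (26-connectivity), lacunarity |
| `frequency_keypoint_features` | 5×6 Gabor bank (min wavelength 3), Fourier ring spectrum, blob/corner/gradient/LOSIB descriptors |
| `feature_table` | the pinned 342-feature registry, per-lesion extraction, Z-score normalization, omics merging |
| `feature_selection` | ReliefF (k = 10) and greedy ranking with S = \|Z\|·(1 − α·ρ), α = 0.7; Z from t-test, Wilcoxon or AUROC |
| `modeling_eval` | linear SVM (C = 1), feed-forward MLP, bagged 10-split decision trees; 75/25 hold-out; AUROC/accuracy/sensitivity/specificity/misclassification panel |
| `experiments_cli` | the four experiment drivers and the `ctradiomics` command line |

## Command line

```bash
# write a synthetic cohort (volumes, masks, expression, labels)
ctradiomics simulate --out cohort/ --seed 1 --n-subjects 20 --profile strong

# extract the 342-feature vector for one lesion
ctradiomics extract --volume cohort/S0000_ct.nii --mask cohort/S0000_mask.nii \
    --out features.tsv

# rank features from a feature table
ctradiomics select --table features_all.tsv --method t_test --n-select 30 \
    --out ranking.tsv

# run a full experiment from a YAML spec
ctradiomics run --config exp1.yaml --seed 7 --out results/
ctradiomics report --report-dir results/
```

An experiment YAML names one of `pfs_radiomics`, `pfs_multiomics`,
`hotcold_radiomics` or `pfs_radiomics_hotcold` and either a cohort
directory or a synthetic cohort block:

```yaml
experiment: pfs_radiomics
seed: 7
synthetic: {profile: strong, n_subjects: 110}
external_synthetic: {profile: strong, n_subjects: 85}
```

Experiment 1 runs a 2×2 grid (ReliefF/t-test × MLP/linear SVM, n = 30
selected features) with external validation; experiments 2–4 run 4×2
grids (t-test/Wilcoxon/AUROC/ReliefF × tree ensemble/linear SVM) with
n = 20/15/15 features and internal hold-out only.

## Notes

- The feature registry is a pinned manifest (SHA-256 asserted in tests);
  each entry carries a provenance tag (`paper-named`, `standard`,
  `artifact-defined`). Adding a feature is a breaking change.
- Tables are always normalized with their *own* Z-score statistics —
  training, internal-validation and external cohorts independently.
- Feature selection is refit inside the training partition of every
  hold-out split (leakage-safe order); a permutation-null test guards
  against optimistic bias.
- DICOM support covers uncompressed explicit-VR little-endian CT series
  via a bundled minimal codec; NIfTI is the primary interchange format.
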