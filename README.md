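# habicat — habitat radiomics for CT-based tumor grading

`habicat` is a tested, reusable implementation of a habitat-radiomics
pipeline for predicting the pathological grade of non-small cell lung
cancer (NSCLC) from non-contrast CT. Conventional radiomics summarizes
the whole tumor with one feature vector and ignores intratumoral
heterogeneity; habitat radiomics first partitions the tumor volume into
phenotypically distinct subregions ("habitats") and models each one.
The package covers the full chain from tumor/lung masks to a graded
evaluation report, and ships a synthetic 3-D phantom generator with
planted ground truth so that every stage is testable without any
patient data.

## The method

For each subject with an image volume, a gross tumor volume (GTV) mask
and a lung mask, the pipeline:

1. **Geometry** — resamples image and masks to an isotropic 1 mm grid
   (nearest-neighbor) and expands the GTV by a 3 mm Euclidean margin,
   clipped to the lung mask, giving the whole volume of interest
   WVOI = GTV ∪ ring.
2. **Habitats** — computes a voxel-wise first-order entropy map on the
   WVOI: per voxel, the kernel-neighborhood intensity histogram with
   N_g = 25 equal-width bins over the WVOI range gives
   H = −Σᵢ p(i) log₂(p(i) + ε), ε ≈ 2.2·10⁻¹⁶. Each voxel's
   (intensity, entropy) "super-voxel" vector is z-scored and clustered
   with K-means; k ∈ {2, 3, 4} is selected cohort-wide by mean
   Silhouette score (Davies–Bouldin reported alongside), and clusters
   are ranked by mean intensity so Habitat 1 is brightest.
3. **Features** — extracts a named 851-feature vector per region
   (WVOI, Habitat 1, Habitat 2): 13 shape, 19 first-order, 75 texture
   (24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM), and 93 features
   on each of the 8 sub-bands of a single-level stationary 3-D wavelet
   decomposition (744 wavelet features).
4. **Harmonization** — removes scanner/cohort batch effects with
   reference-batch empirical-Bayes ComBat (location and scale,
   parametric priors, no biological covariates); reference-batch rows
   are returned bit-unchanged.
5. **Models** — trains a two-step binary cascade: Model-1 separates
   grade 3 from grades 1–2, Model-2 separates grade 1 from grade 2.
   Four logistic-regression classifiers per model (Clf_WVOI,
   Clf_Habitats, Clf_Clinical on 13 clinical features, and Clf_Total on
   the union of the others' selections) with a 7:3 stratified split,
   IQR outlier clipping + z-scoring, SMOTE class balancing, mRMR
   filtering, and LASSO selection tuned by 5-fold cross-validation.
6. **Evaluation** — Mann–Whitney AUC with DeLong variance/CI, paired
   DeLong tests between classifiers, sensitivity/specificity at the
   training Youden threshold, balanced accuracy
   BACC = (SENS + SPEC)/2, exact linear SHAP attributions, and a
   Spearman screen of clinical features against grade.

The synthetic phantom plants all the structure the pipeline is supposed
to find: two texture-distinct tumor components whose mixing fraction
grows with grade, batch shifts at the feature level, and clinical
features with configured grade-correlation signs.

## Worked example

`examples/05_two_step_grading.py` plants a grade signal only in the
habitat feature blocks and trains the full two-step cascade:

```
 model   classifier  AUC  CI_low  CI_high  SENS  SPEC  BACC
model1     Clf_WVOI 0.49    0.31     0.67  0.13  0.90  0.52
model1 Clf_Habitats 1.00    0.98     1.00  1.00  0.93  0.97
model1 Clf_Clinical 0.81    0.69     0.94  0.67  0.73  0.70
model1    Clf_Total 0.99    0.98     1.00  1.00  0.90  0.95
```

Because the signal lives in the habitat subregions, the whole-volume
classifier is at chance (AUC 0.49) while the habitat classifier is
nearly perfect, and the combined model matches it; the paired DeLong
test separates Clf_Habitats from Clf_WVOI (p < 0.001) but not from
Clf_Total (p = 0.48) — the qualitative ordering habitat radiomics is
designed to produce. The other examples demonstrate the phantom
generator, habitat clustering (tumor-component recovery ARI ≈ 0.9),
feature extraction, and ComBat harmonization (planted-shift recovery
r ≈ 0.98, ~470-fold reduction of batch-explained variance) — each
prints the numbers it computes and what they mean.

There is also a thin CLI for shell use:

```bash
habicat run-all --out runs/demo --seed 1          # full pipeline
habicat phantom --out cohort/ --seed 1            # NIfTI cohort only
```

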