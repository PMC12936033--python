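# Methods

This note documents the models and procedures implemented in `habicat`,
the parameters that matter, the design choices made where the design
was genuinely open, and what the synthetic phantoms do and do not show
about real CT data.

## Geometry

Images and masks are resampled to an isotropic grid (default 1 mm)
with nearest-neighbor interpolation for both; the image interpolation
order is configurable (`image_order=1` for trilinear) because
nearest-neighbor on images is unusual outside this pipeline's own
convention. The peritumoral ring is defined in *physical* units: a
voxel joins the ring when its Euclidean distance to the nearest GTV
voxel is ≤ the margin (default 3 mm), computed by a Euclidean distance
transform with the grid spacing as sampling — so the code stays correct
for anisotropic spacings. The threshold is inclusive, which makes the
single-voxel oracle well defined: a 1-voxel GTV at 1 mm spacing and a
3 mm margin yields exactly the 123 lattice points with
x² + y² + z² ≤ 9. A GTV that leaks outside the lung mask is kept
verbatim with a warning; only the ring is clipped to lung.

## Entropy map and super-voxels

The voxel-wise first-order entropy uses a histogram with a fixed count
of N_g = 25 equal-width bins spanning the WVOI-wide min–max range,
shared by every kernel of a subject. This makes p(i) comparable across
voxels; empty bins contribute zero through the p·log₂(p + ε) guard
(ε = 2.2·10⁻¹⁶), so the "number of non-zero bins" and "fixed bin
count" readings coincide numerically. The kernel is a cubic
neighborhood of radius 1 voxel (3×3×3), restricted to WVOI voxels — the
common voxel-based radiomics default; the radius is configurable.
Entropy is bounded by [0, log₂ 25 ≈ 4.644] bits up to the −N_g·log₂(1+ε)
float guard, and is invariant to affine rescaling of the intensities
because the bins are range-relative.

Super-voxel vectors are the per-voxel (intensity, entropy) pairs,
z-standardized per channel across the WVOI before clustering (the two
channels have incommensurate scales); raw values are retained for
habitat ranking. A channel whose standard deviation is ≤ 10⁻¹² relative
to its mean is treated as constant and mapped to zero.

## Habitat clustering and k selection

K-means uses k-means++ initialization, 10 restarts, tolerance 10⁻⁶ and
a fixed seed; an empty cluster triggers a bounded re-initialization.
Clusters are relabeled by descending mean raw intensity (ties broken by
cluster index) so habitat 1 is always the brightest subregion. The
cluster count is selected cohort-wide: for each candidate k ∈ {2, 3, 4}
every subject is clustered and the mean Silhouette score and
Davies–Bouldin index are averaged over subjects; the Silhouette winner
is used for all subjects, and a disagreement with Davies–Bouldin is
logged. Samples in singleton clusters get silhouette 0; coincident
centroids return a large Davies–Bouldin sentinel (10⁶) so such a degenerate k can
never win. On the phantom, the WVOI genuinely contains three
populations (peritumoral ring plus two tumor components), so the
silhouette table may prefer k > 2 — the pipeline's habitat count is
therefore a configuration choice (default 2) with the metric table
always reported, mirroring a cohort-level decision.

## Feature schema (851 features)

Per region the vector holds 13 shape, 19 first-order, and 75 texture
features on the original image plus 744 wavelet features. The declared
counts of 19 first-order and 75 texture features imply 94 per image,
while 744/8 = 93 per wavelet band; the schema resolves this by dropping
TotalEnergy (Energy rescaled by voxel volume — fully redundant on a
fixed grid) from the per-band blocks: 8 × (18 + 75) = 744 and
13 + 19 + 75 + 744 = 851, asserted at schema construction.

Key numerical conventions:

- **Discretization** for texture matrices: fixed 25 equal-width bins
  over the region min–max (range-relative ⇒ affine-invariant texture).
- **GLCM**: symmetric co-occurrence over the 13 unique 3-D directions;
  features computed per direction and averaged. Degenerate marginals
  give Correlation = MCC = 1 (the perfectly-dependent limit).
- **GLRLM**: maximal runs per direction, averaged over 13 directions.
- **GLSZM**: zones are 26-connected components per gray level.
- **GLDM**: dependence = 1 + number of 26-neighbors whose level differs
  by at most α = 0.
- **NGTDM**: neighborhood means over in-region 26-neighbors; voxels
  without neighbors are excluded.
- **Shape**: surface area from a marching-cubes mesh of the padded
  mask (meshes of voxel cubes are edge-beveled, so a cube's measured
  sphericity sits a few percent above the analytic (π/6)^{1/3});
  principal-axis lengths 4·√λ from the physical-coordinate covariance
  eigenvalues; maximum diameters from surface-voxel centers with a
  convex-hull shortcut.
- **Wavelet**: single-level stationary (undecimated) 3-D `coif1`
  decomposition; axes padded to even length (edge mode) and cropped
  back, so all 8 sub-bands live on the input grid and reuse the mask.
- **Degenerate policy**: undefined values (skewness/kurtosis of a
  constant region, axis ratios of a point) take their analytic limit
  where one exists, else 0, and are flagged; regions under 10 voxels
  are flagged wholesale. This keeps the table dense for LASSO.
- Kurtosis is Pearson (normal → 3); variance is population (ddof 0).

Which 13 shape and which 19 first-order features enter is an explicit
schema declaration (`habicat.features.schema`), versioned and hashed
into every output manifest.

## ComBat harmonization

Reference-batch ComBat with parametric empirical Bayes: features are
standardized against the reference batch's mean and (ddof 1) standard
deviation; per-batch location (γ) and scale (δ²) estimates are shrunk
across features via the normal/inverse-gamma conjugate scheme with
fixed-point iteration to 10⁻⁸; non-reference rows are adjusted by
(z − γ*)/δ* and mapped back to the reference scale. Reference rows are
returned exactly unchanged. Features constant within any batch pass
through unharmonized and are flagged. With EB disabled the procedure
reduces to per-batch location-scale standardization onto the reference
moments (used as a closed-form check). Harmonization is fitted once on
the concatenated subject table before the train/test split — a
deliberate mirror of the cohort-level harmonize-then-model workflow;
this leaks marginal batch statistics (never labels) across the split,
and a fit-on-train mode is available by fitting on the training rows
and applying to all. Clinical features are never harmonized.

## Two-step models

Model-1 labels grade 3 vs grades 1–2; Model-2 labels grade 2 vs grade 1
on the G1/G2 subset. Each model draws its own stratified 7:3 split.
Per classifier the training pipeline is:

1. outlier clipping to [Q1 − 3·IQR, Q3 + 3·IQR] and z-scoring, both
   fitted on training rows only (zero-variance features dropped);
2. SMOTE (k = 5 minority neighbors, synthetic points uniform on
   segments to one of the k nearest minority neighbors) balancing the
   classes exactly; inside cross-validation, SMOTE is re-applied within
   each training fold so validation folds stay untouched;
3. mRMR filtering (top 30): greedy quotient scheme, relevance = ANOVA
   F statistic, redundancy = mean |Pearson r| with already-selected
   features, deterministic with column-order tie-breaks;
4. LASSO-logistic selection: the penalty is chosen by cross-validated
   deviance over a log-spaced grid; selected = nonzero coefficients;
   an all-zero solution falls back to the weakest penalty with a
   warning;
5. a final L2-logistic fit whose C is tuned by the same
   cross-validation, for numerical stability after SMOTE on small
   cohorts;
6. the decision threshold is Youden's J on the training ROC and is the
   only threshold ever used, including on test data.

Selection order mRMR → LASSO is the standard filter-then-embedded
composition; both stages and the SMOTE placement are configurable.
Clf_Total refits the final model on the exact union of the three
single-modality selections without further selection (an optional
re-LASSO exists, off by default). The cross-validation fold count drops
to the minority-class size on very small cohorts. Everything is
reproducible bit-for-bit from one master seed; per-stage seeds derive
as blake2(master, stage-name) mod 2³¹.

## Evaluation

AUC is the Mann–Whitney estimator (ties ½). Variances, 95% CIs and
paired comparisons use the DeLong structural-components estimator with
midranks; identical score vectors short-circuit to p = 1, and a
degenerate variance with a nonzero AUC difference reports p = NaN with
a warning rather than a fabricated number. SHAP values are exact for
the linear-logistic models: φⱼ(x) = βⱼ(zⱼ − mean(zⱼ)) in log-odds
space, so base + Σφ reproduces the model output to float precision and
the mean-|φ| ranking is deterministic. Report tables round half-up to
two decimals; BACC is exactly (SENS + SPEC)/2.

## The phantom: what it shows and what it does not

Each subject is an ellipsoidal tumor (radii drawn from 6–10 mm,
jittered center) inside a lung-like background (mean −800, SD 30
HU-like units, arbitrary calibration) on a 48³ grid at 1 mm. The tumor
mixes component A (mean −50, SD 25 — darker and rougher) and component
B (mean +50, SD 10 — brighter and smoother) as a concentric core whose
volume fraction is drawn around the grade mean (G1 0.10, G2 0.35,
G3 0.60, SD 0.06): a 100-unit contrast, i.e. 4 SD of the wider
component, with a texture difference that makes the entropy channel
informative. Clinical features come from grade-loaded latent Gaussians
thresholded into binary/ordinal levels; loadings are scaled so the
correlation *signs* (density, size, spiculation… positive; clear
interface, air bronchogram, vacuole… negative) are reproduced, with
lesion density the strongest correlate. Batch structure is assigned
round-robin within grade (orthogonal to grade by construction), and
batch effects are injected at the feature level — additive shifts in
units of each feature's SD with 50% per-feature jitter, log-normal
scale factors — because harmonization operates on features and this
gives an exact recovery target.

Passing tests on these phantoms demonstrates that the pipeline's
machinery is correct: the geometry is exact, entropy matches its closed
forms, clustering recovers planted components at the stated contrast,
ComBat recovers planted shifts and preserves planted grade effects, the
selection stack finds planted signals, and the evaluation statistics
are calibrated. It does *not* demonstrate clinical performance: real
tumors are not two-Gaussian ellipsoids, real batch effects are not
location-scale at the feature level, lung anatomy, motion and scanner
physics are absent, and real-data AUCs cannot be inferred from phantom
AUCs. Phantom classifier AUCs are near-ceiling by design at the default
effect sizes and should be read as plumbing checks, not benchmarks.

## Problem sizes

Default study sizes were chosen to exercise every code path at desk
scale: 20 subjects per grade (60 total, 3 batches) in the end-to-end
acceptance run, ~2000–5000-voxel tumors, 851 × 3 features per subject;
focused sub-experiments use n = 400 × 53 features for LASSO recovery,
100 subjects/batch × 50 features for ComBat, and 1000 replicates for
DeLong calibration. The Monte-Carlo acceptance suites (clustering
recovery over 20 seeds, k-selection over 100 replicates, habitat-vs-
whole-volume ordering over 20 replicates) run on reduced cohorts whose
statistics, not sizes, carry the claim.

## Known limitations

- GLCM/GLRLM direction weighting is simple averaging (no distance
  weighting); IBSI-certified equivalence is not claimed.
- The phantom's peritumoral ring is statistically homogeneous lung;
  ring-specific biology (vessels, atelectasis) is not modeled.
- Reference-batch ComBat assumes the reference batch is large enough
  to estimate per-feature moments; with < ~30 reference rows the
  standardization itself is noisy.
- With heavily correlated radiomic features and planted scale shifts,
  location-shift recovery is attenuated (the acceptance run reports
  r ≈ 0.87 under pipeline conditions vs ≥ 0.95 in the independent-
  feature setting).
- `habicat` trains logistic regression only, by design; alternative
  classifiers are out of scope.
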