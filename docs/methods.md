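# Methods

`habitatmri` implements a tumor-habitat radiomics workflow for glioblastoma
(GBM) on multi-parametric MR: four co-registered channels (T1-CE, T2-W,
T2-FLAIR, ADC) plus an integer label map dividing the abnormal region into
four nested habitats — necrosis (1), solid enhancing tumor (2), peritumoral
tissue (3) and peritumoral edema (4).  Because patient images cannot ship
with the package, a synthetic phantom generator reproduces the geometric,
intensity, textural and cohort-level volumetric structure the analysis
assumes, and every downstream stage is validated against it.

## Synthetic phantoms

**Geometry.** A subject is a set of nested shells around a common center.
Shell radii either come directly from a `HabitatGeometryConfig`
(core radius + per-shell thickness) or are solved from sampled habitat
volume fractions: with cumulative fractions `c_k` and ABV equivalent radius
`R`, the k-th boundary is `R * c_k^(1/3)`.  A non-spherical option applies a
single smooth angular modulation `m(u) = 1 + eps * s(u)` (first- and
second-order directional harmonics, normalized to max |s| = 1) to *all*
boundaries at once; since each directional volume element scales by `m^3`
for every shell alike, habitat volume *fractions* are exactly invariant
under the deformation, which makes volumetric recovery a true round trip.
Defaults: 64-voxel cube grid at 1 mm isotropic spacing, deformation
amplitude 0.1 for cohorts; ABV equivalent radius lognormal with median
17 mm and log-SD 0.08 (clipped to keep the deformed shell inside the grid).
These sizes keep voxelization error per subject near 0.1% while a
2000-subject cohort renders in about a minute.

**Cohort fraction sampling.** Per-subject ABV fractions
(necrosis, solid, PT, edema) are drawn from a two-component mixture of
normalized independent gammas: component `c` has shapes `k_ci` and scales
`theta_ci`, a subject draws `g_i ~ Gamma(k_ci, theta_ci)` and uses
`f_i = g_i / sum(g)`.  With equal scales a component reduces to a Dirichlet;
unequal scales free the ratio means from the Dirichlet's single-concentration
constraint, and the mixture adds cohort heterogeneity.  A plain Dirichlet was
rejected for cause: any common concentration compatible with the published
/ABV SDs puts the peritumoral shape below 1, which makes every ratio with a
PT denominator have an *infinite* mean.

The mixture (15 parameters) is calibrated per preset, deterministically, by
bounded least squares against the published cohort statistics: relative
errors of all ten ratio means (the four habitat/ABV fractions and the six
cross-habitat ratios) with weight 1, the ten ratio SDs with weight 0.3, and
a penalty keeping each component's mean habitat fractions above 0.02 so that
no subpopulation has an unvoxelizably thin habitat (the published per-ratio
ranges bottom out near 0.02).  Cross-ratio moments of gammas are closed
form (`E[g_i/g_j] = k_i theta_i / ((k_j - 1) theta_j)`, valid for
`k_j > 1`; second moments need `k_j > 2`, hence the shape floor of 2);
/ABV moments use the identity `1/S = ∫ exp(-tS) dt`, which turns them into
1-D integrals of gamma MGF products, evaluated on 400 fixed Gauss–Legendre
nodes (agreement with adaptive quadrature ~1e-12).  Residual mean errors for
the local preset are within ±4% (necrosis/ABV −1.4%, edema/solid +1.0%);
the residuals are a property of fitting ten interlocking ratio means with
one four-part composition and are reported by
`FractionSampler.expected_ratio_means()`.

Presets carry the published cohort targets: `local_cohort_preset()` (n=23)
and `tcia_cohort_preset()` (n=31).  The TCIA necrosis/ABV SD is stored as
0.083: the printed 0.83 contradicts both the printed range (0.05–0.33) and
CI (0.14–0.20) and is treated as a typo, noted in the preset metadata.

**Appearance.** Channels are rendered as per-habitat mean intensities
(arbitrary units chosen to mimic each sequence's contrast ordering, e.g.
solid brightest on T1-CE, edema brightest on FLAIR, necrosis highest on
ADC), plus a per-habitat texture field shared across channels — fine
speckle in necrosis (Gaussian-filtered white noise, 1.5 mm grain), coarse
speckle in solid (3 mm), 4 mm stripes in peritumoral tissue, flat edema —
an optional low-order polynomial bias field (off by default), and Rician
noise (`sqrt((x+n1)^2 + n2^2)`, sigma 5) matching magnitude-MR statistics.
Distinct textures make the four habitats separable by texture features,
which is what the classifier acceptance check exercises.  Geometry and
appearance consume separate child streams of the subject seed, so label
maps are bit-identical whether or not channels are rendered; all randomness
flows from explicit integer seeds.

What the phantoms do **not** emulate: anatomy outside the lesion, partial
volume and scanner-specific intensity nonlinearity, registration error,
infiltrative (non-nested) habitat topology, and inter-sequence texture
differences.  Green tests therefore demonstrate correctness of the
measurement machinery and calibration of the cohort statistics, not
clinical performance on patient data.

## Radiomic features (1316 per habitat)

Families, in fixed order: 32 geometry + 64 first-order histogram + 64 LBP +
88 GLCM + 44 GLRLM + 1024 SIFT bag-of-visual-words.  Intensity, texture and
SIFT features are computed on one designated channel, default T1-CE (the
sequence the annotations are drawn on); geometry uses only the mask.
Texture is computed slice-wise in 2D (axial) and pooled by summing count
matrices across slices before normalization — 2D keeps the brute-force
oracles exact and matches common BraTS-era practice.

* **Quantization:** 64 equal-width bins over the region min–max, last bin
  closed; constant regions map to level 0.  Per-region quantization makes
  all histogram/texture features invariant to affine intensity rescaling.
* **Geometry (32):** volume, voxel count, surface area, surface/volume,
  sphericity, two compactness variants, spherical disproportion, equivalent
  sphere radius/surface, maximum 3D diameter, per-plane maximum 2D
  diameters, PCA axis lengths (4·sqrt(eigenvalue)), elongation, flatness,
  bounding-box sizes/volume/extent, centroid-to-bbox-center offsets (+norm),
  centroid-radius mean/SD/max, surface/bbox-surface.  Surface area uses a
  normal-weighted boundary-face quadrature: each exposed voxel face
  contributes its area times the matching component of the local unit
  normal, estimated from the indicator smoothed at 1.5 voxels.  The
  estimator is unbiased for planes of any orientation and accurate to a few
  tenths of a percent on digital spheres (sphericity 0.999 at r=10 voxels);
  it undercounts sharp right-angle edges by up to ~10% because a sharp edge
  and a 45° staircase are indistinguishable at half-voxel scale — an
  intrinsic trade-off that was resolved in favor of the curved blob/shell
  shapes tumors actually have.  Smoothing in voxel units makes the estimate
  scale exactly as mm² under uniform spacing changes.
* **First order (64):** the normalized 64-bin histogram of quantized region
  voxels.
* **LBP (64):** slice-wise 2D local binary pattern with P=6 neighbors at
  R=1 (code space exactly 2^6 = 64), bilinear neighbor sampling from the
  underlying image (the mask selects pooled pixels, not readable neighbors,
  so one-voxel shells still contribute), ties (`neighbor == center`) count
  as ≥ so constant regions give the all-ones code; pooled over slices,
  L1-normalized.
* **GLCM (88):** symmetric co-occurrence at distance 1 along 0°/45°/90°/135°
  over in-mask pairs, pooled across slices; 22 statistics per offset
  (autocorrelation, cluster prominence/shade/tendency, contrast,
  correlation, joint average, difference entropy/variance, dissimilarity,
  energy, entropy, IMC1, IMC2, inverse difference, inverse difference
  moment, inverse variance, maximum probability, sum average/entropy/
  variance, sum of squares variance).  Gray levels enter 1-based.
  Degenerate constant regions: correlation defined as 1, entropies 0.
* **GLRLM (44):** maximal in-mask constant runs per direction, pooled
  across slices; 11 statistics per direction (SRE, LRE, GLN, RLN, RP,
  LGLRE, HGLRE, SRLGLE, SRHGLE, LRLGLE, LRHGLE).
* **SIFT (1024):** dense upright 128-d gradient-orientation descriptors
  (16×16 patch, 4×4 cells × 8 orientation bins, Gaussian-windowed,
  L2-normalized, clipped at 0.2, renormalized) at in-mask grid points with
  4-px stride on axial slices; a 1024-word codebook is learned by
  mini-batch k-means with a fixed seed on the training split's pooled
  tumor descriptors; a region's feature is its L1-normalized word-assignment
  histogram.  Regions too small for any descriptor return a zero vector
  with a warning.  The bag-of-visual-words aggregation is this package's
  choice of the (unstated) rule that maps variable descriptor sets to a
  fixed 1024-length vector.

`RegionFeatureExtractor` exposes this as a scikit-learn transformer:
`fit` learns the codebook, `transform` yields one 1316-column row per
subject × habitat.

## Volumetrics and statistics

TBV = necrosis + solid + peritumoral tissue; ABV = TBV + edema (edema is by
construction ABV − TBV — this is forced by the published fraction tables
summing to ~1 over the four habitats).  `compute_volumes` counts voxels ×
voxel volume and emits all ten cross/ABV ratios plus the four /TBV ratios.
Cohort statistics are computed on per-subject ratios (mean of ratios, not
ratio of means): mean, sample SD (n−1), min/max and the 95% t-interval.

The habitat comparison uses a one-way repeated-measures ANOVA (subject as
the repeated factor; closed-form F, cross-checked against statsmodels
`AnovaRM` in the tests) followed by paired t-tests with Bonferroni
correction over the family of pairwise comparisons.  Significance stars:
`*` p < 0.05, `**` p ≤ 0.005, `†` p < 0.001, applied to corrected p-values.
No Greenhouse–Geisser sphericity correction is applied.  Under a simulated
exchangeable null the ANOVA's type-I error at alpha = 0.05 stays within
[3%, 7%] over 1000 replicates (checked in the tests).

Feature heatmap clustering z-scores columns (zero-variance columns
dropped), builds average-linkage Euclidean dendrograms for rows and
columns, and cuts the row dendrogram into k = 5 flat clusters (the number
of distinct feature clusters the analysis reports); cluster ids are
renumbered by first appearance so the partition is invariant to row order.

## Habitat classification

One feature row (subject × habitat) is one classification unit.  The model
is a random forest whose `(n_trees, max_depth)` is chosen by out-of-bag
score on the training fold over a grid of 100–2000 trees (step 100) and
depths {unbounded, 10, …, 110} (depth 0 encodes unbounded); the grid bounds
follow the study protocol, with the "number of features" axis read as the
forest size since the feature count is fixed at 1316.  Evaluation is
leave-one-out cross-validation; metrics are per-class and overall
accuracy/precision/recall/F1, the confusion matrix, and one-vs-rest AUC
computed by the rank-based Mann–Whitney statistic with midrank ties
(validated against O(n²) pair counting).  Subject-level decisions use
majority vote with a 50% threshold; an exact tie falls back to plurality
with alphabetical tie-break and is flagged.  OOB selection (rather than a
nested LOOCV) keeps model selection honest at LOOCV cost O(n · grid).

Tests and the acceptance checks run the LOOCV with a reduced grid
(100 trees, unbounded depth) on a 12-subject phantom cohort with a
256-word codebook — problem sizes chosen so the whole suite runs in
minutes; the full protocol grid is `default_grid()`.  The published
patient-data metrics (95.8% accuracy etc.) are not reproducible without
the patient cohorts; the acceptance analogue requires LOOCV accuracy
≥ 0.90 and all four one-vs-rest AUCs ≥ 0.95 on the separable phantom, and
chance-level accuracy on permuted labels.

## Numerical choices and edge cases

* Equal-width quantization assigns `value == max` to the top bin.
* GLCM correlation of a constant region is 1; IMC1 is 0 when both marginal
  entropies vanish; inverse variance sums off-diagonal cells only.
* Single-voxel masks: PCA axis lengths 0, elongation/flatness defined as 1.
* The cohort generator refuses presets whose /ABV fraction targets are not
  positive or do not sum to 1 within 0.02, before generating anything.
* A habitat that voxelizes to zero voxels raises
  `DegenerateGeometryError` naming the habitat.
* Subject seeds derive from the cohort seed via `SeedSequence.spawn`, so
  cohorts are reproducible and subjects independent.

## Known limitations

* The sampler matches ratio means to a few percent, not exactly; matching
  all ten published means exactly with a four-part composition is
  overdetermined.
* Surface area (and therefore sphericity/compactness) is biased low on
  shapes with genuine sharp right-angle edges.
* SIFT descriptors are upright (no rotation invariance) — adequate for
  axial MR, not for arbitrarily rotated inputs.
* 2D slice-wise texture ignores through-plane structure by design.
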