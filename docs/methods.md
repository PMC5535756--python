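# Methods

## Problem and model

`ccvpatch` classifies 64×64 grayscale single-nucleus patches as *normal*
or *abnormal* (malignant).  Each patch comes with a binary mask of its
segmented nucleus; segmentation itself is out of scope — masks are inputs.
The method combines a conventional hand-crafted-feature classifier with a
shape prior: malignant nuclei have irregular, lobed outlines, so a
statistic counting contour inflections can correct a classifier's
low-confidence decisions.

## Concave-convex variation (CCV)

An inflection count of the nucleus boundary, computed without any analytic
curve expression.

1. The boundary is traced as an ordered clockwise pixel chain
   (Moore-neighbour tracing, starting at the topmost of the leftmost
   foreground pixels).  Coordinates are (col, row), origin top-left.
2. The four bounding-box tangent points (first-reached extreme pixel per
   axis direction) split the contour into four curves.  Extremes may
   coincide when the boundary touches a bounding-box corner; the affected
   arc is then empty and contributes 0.
3. Each curve is sampled every `interval` pixels (default 2, first and
   last points always kept).  Slopes k = Δrow/Δcol from the curve's first
   point (its anchor tangent point) to every later sample form a vector K;
   samples directly above/below the anchor (Δcol = 0) are skipped so K
   stays finite — retaining them as infinities would let near-anchor
   rasterization noise dominate.
4. ΔK is the first difference of K.  CCV of the curve is the number of
   adjacent opposite-sign pairs in ΔK, where zeros inherit the most recent
   nonzero sign (plateaus from rasterized straight runs are not
   inflections) and are neutral before any nonzero entry.  The contour's
   CCV sums the four curves, preserving the reading "number of inflections
   around the whole contour"; the per-curve construction itself does not
   prescribe an aggregate, and summation is this package's choice.

Properties: CCV is exactly invariant to translation, and invariant to
mirroring only in distribution — mirroring reverses arc traversal, which
shifts the sampling grid and tie-breaks, so individual irregular contours
may change by a few counts (symmetric shapes are exactly invariant).  Tests
assert exactly that.

## Posterior reweighting

From training contours, m₁ = mean(CCV_normal) and m₂ = mean(CCV_abnormal)
are learned; the model is usable only when m₁ < m₂ (a warning flags the
degenerate case).  For a test sample with initial winning-class
probability p and CCV value c:

    ω_normal(c)   = 1.2                       c ≤ m₁
                    1.2 + 0.4(c−m₁)/(m₁−m₂)   m₁ < c ≤ (m₁+m₂)/2
                    0.8 + 0.4(c−m₂)/(m₁−m₂)   (m₁+m₂)/2 < c < m₂
                    0.8                       c ≥ m₂

with ω_abnormal its mirror (ω_normal + ω_abnormal ≡ 2).  Both functions are
continuous, monotone and bounded in [0.8, 1.2]; the branch boundaries are
implemented in this continuous, non-overlapping form.  The adjusted
probability is p·ω clipped to [0, 1] (the raw product can reach 1.2); the
initial label is kept iff the adjusted probability is ≥ ½.  A flip is
possible only when p < 0.5/0.8 = 0.625, so confident predictions are never
overturned.  For PR/ROC curves of adjusted classifiers, the swept score is
the adjusted abnormal-class probability (1 − p_final for initially-normal
samples), not the thresholded labels.

## Feature bank

* **Intensity** (22): mean, median, variance, SD, Fisher skewness and
  excess kurtosis (0 on constant input), min, max, range, quartiles — over
  the whole patch and within the mask.
* **Morphology** (10): area, perimeter, equivalent diameter, major/minor
  axis, eccentricity, solidity, extent, centroid offset from patch centre,
  and nucleocytoplasmic ratio (mask area / patch area).
* **GLCM** (25): co-occurrence matrices at 16 gray levels, distance 1,
  offsets (1,0),(1,−1),(0,−1),(−1,−1) (0°/45°/90°/135°), symmetrized and
  sum-normalized; ASM, ENT (natural log), CON, COR (marginal means/SDs)
  and IDM per offset plus the mean over offsets.  IDM uses the
  homogeneity denominator 1+(i−j)²; the non-standard 1+(i+j)² variant is
  available behind `FeatureConfig.glcm_idm_literal` for comparison but is
  not a homogeneity measure.  A constant image has undefined correlation
  (zero marginal SD); it is reported as 0 with a degeneracy flag.
* **LBP** (4096 raw / 944 uniform): the patch is divided into sixteen
  16×16 cells; each pixel's 8-bit code sets a bit when the centre is less
  than the neighbour (clockwise from top-left, MSB first; borders
  edge-replicated so constant images give the all-zero code); per-cell
  histograms are normalized to sum 1 and concatenated.  Raw 256-bin
  histograms are the default; a 59-bin uniform-pattern option bounds the
  dimension.
* **SIFT** (257): standard difference-of-Gaussian keypoints and 128-d
  descriptors (scikit-image), aggregated to a fixed length as keypoint
  count plus per-dimension descriptor mean and SD.  Zero keypoints yield
  the zero vector.  The default disables initial scale-space upsampling:
  64×64 patches are already sampled near the nucleus scale and the
  doubled pyramid quadruples cost without changing the aggregate
  meaningfully.
* **Tamura** (3): coarseness (per-pixel best window among
  {1,2,4,8,16}-pixel mean-difference responses, averaged), contrast
  (σ/(μ₄/σ⁴)^¼), and directionality (magnitude-weighted circular resultant
  length of the doubled gradient orientation — 1 for stripes, ≈0 for
  isotropic noise).  The resultant-length form of directionality is this
  package's concrete choice of "orientation-histogram peakedness".

Total 4413 rows with the default configuration; the matrix is features ×
samples.  The documented feature budget is this package's own; the
original study's per-group dimension split is not recoverable and is not
claimed.  Intensity/texture features are computed on the bilateral-filtered
patch, matching the pipeline order (filtering before extraction).

The bilateral filter is the textbook operator (7×7 window,
σ_spatial = 3 px, σ_range = 25 gray levels, symmetric padding), implemented
directly so that its large-σ_range limit is exactly the truncated Gaussian
blur — a contract the tests check.

## SC feature selection

Step 1: min–max normalize each row to [0, 1]; constant rows are dropped.
Rows are then scanned in order and dropped when |Pearson ρ| with any
earlier kept row reaches ρ_max (default 0.95; keep-first is deterministic).
Step 2: each surviving row is contrast-mapped by x* = (x−μ)/(σ+ε) with
ε = max(0, max|x−μ| − σ), the smallest nonnegative value bounding |x*| by
1 (approximate normality of the mapped row is not enforced; ε serves the
range constraint only).  With s the sign of the normal-class mean and
y = √(1−x*²), each sample contributes s·sign(x*)·(1−y) if normal and
−s·sign(x*)·(1−y) if abnormal, so samples lying toward their own class
mean add positively; C(x) is the raw sum over samples (not class means).
Features whose class means share a sign are removed; features with
C(x) < δ₁ are removed.  δ₁ defaults to the 60th percentile of surviving
contributions — a relative threshold keeps the rule meaningful across
feature banks of very different dimension.  Step 3: selected rows are
mapped with the stored fit-time parameters and entries with |x| ≤ δ₂
(default 0.05) are zeroed.  At transform time, test values outside [−1, 1]
are clamped before sparsification.  Row counts shrink monotonically
through the chain, and C(x) is invariant under swapping the class labels.

## Base classifiers

The ELM is authored here: W, b ~ uniform(−1, 1) drawn once from the seed
(L = 100 hidden sigmoid units by default), H the hidden activation matrix,
and β = pinv(H)·T the minimum-norm least-squares solution — with L ≥ n and
full-rank H this interpolates the targets exactly, which the tests use as
the correctness oracle.  Probabilities are a softmax over the raw outputs
(the pseudoinverse fit defines none).  SVM (linear kernel, C = 1, sigmoid-
calibrated decision values) and random forest (100 trees; probability =
fraction of tree votes) come from scikit-learn.  All three expose
[normal, abnormal]-ordered `predict_proba`, so the CCV stage is
classifier-agnostic.  No kernel/C/tree-count tuning is attempted; the
defaults are declared, not optimized.

## Synthetic data

Nuclei are star-convex shapes r(θ) = r_ellipse(θ) + A·sin(n_lobes·θ + φ) +
ε(θ) rasterized onto the 64×64 grid, one border-free 4-connected component
per patch.  `boundary_noise_amp` (A, pixels) is both the lobe amplitude
and the scale of the smooth radial perturbation ε (four random harmonics
of orders 2–5, SD A/4 each); `n_lobes = 0` and `A = 0` give a pure
ellipse.  Texture is two flat class means plus noise: white outside the
nucleus, and inside optionally spatially correlated (Gaussian-filtered
noise with correlation length `chromatin_grain`, rescaled to `noise_sd`)
to mimic chromatin clumping.  Per-patch random streams are split from the
master seed by indexed `SeedSequence` keys, so datasets are
order-independent and byte-reproducible.

Default class presets: normal — radius 12 px, eccentricity 1.15, no lobes
or boundary noise, nucleus gray 100, noise SD 10, grain 1.0; abnormal —
radius 13 px, eccentricity 1.25, six lobes of amplitude 3 px, nucleus gray
80 (hyperchromatic), noise SD 14, grain 2.5; both jitter the centre by up
to 3 px.  Under these presets mean CCV is ≈1.6 (normal) vs ≈10.3
(abnormal).  The generator emulates the geometry and first-order texture
contrast of segmented nuclei, not H&E staining color, imaging artefacts,
touching nuclei or segmentation errors — so passing tests demonstrate the
machinery and the direction of the CCV effect, not clinical performance.

## Experiment harness and problem sizes

`run_experiment` executes the full pipeline per classifier, with and
without CCV, and reports metrics (accuracy, sensitivity = recall toward
the abnormal class, specificity, precision, F1; a metric with a zero
denominator is reported as undefined), ROC and PR curves (threshold sweep
over unique scores, trapezoidal AUC), per-sample CSV and reproducible JSON.
The default benchmark generates 200 training and 100 test patches per
class; the repeated-seed evaluation in the test suite uses 20 seeds.
Directory datasets are split stratified 70/30 by default.  After a label
flip the per-sample table reports both the adjusted probability of the
initial label and its complement for the final label.

## Known limitations

* CCV is resolution-dependent: counts scale with contour length and the
  sampling interval, so m₁/m₂ must be learned at the same scale as the
  test data.
* The weight functions assume m₁ < m₂; when contour irregularity does not
  separate the classes the CCV stage refuses to weight rather than degrade
  silently.
* Mirror invariance of CCV holds only in distribution (see above).
* On strongly separable synthetic data the SVM/RF baselines saturate at
  100% accuracy, so the CCV improvement is visible mainly on the weaker
  ELM; the adjustment provably never flips predictions with p ≥ 0.625.
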