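# ccvpatch

Classification of single-nucleus image patches (normal vs abnormal
hepatocellular-carcinoma cells) with **sparse-contribution (SC) feature
selection** and **concave-convex-variation (CCV) posterior reweighting**.

Pathologists grade H&E-stained liver tissue partly by nuclear shape: a
healthy nucleus has an approximately convex outline, while malignant nuclei
are irregular and lobed.  `ccvpatch` turns that prior into a classifier
correction.  The pipeline operates on 64×64 grayscale patches, each with a
binary mask of its segmented nucleus, and runs:

1. **Preprocessing** — bilateral filtering of the patch; ordered
   (Moore-neighbour, clockwise) tracing of the nucleus boundary.
2. **Feature extraction** — intensity statistics, mask morphology
   (including the nucleocytoplasmic ratio), and texture: GLCM statistics
   (ASM, ENT, CON, COR, IDM), cellwise LBP histograms, aggregated SIFT
   descriptors, and Tamura coarseness/contrast/directionality, stacked as
   a features × samples matrix `fs`.
3. **SC selection** — per-row min–max normalization, Pearson redundancy
   pruning (|ρ| ≥ ρ_max), a contrast map `x* = (x − μ)/(σ + ε)` onto
   [−1, 1], and a unit-circle contribution score: a sample at mapped value
   x contributes ±(1 − √(1 − x²)), positive when it lies toward its own
   class mean.  Features whose class means share a sign, or whose total
   contribution C(x) falls below δ₁, are dropped; surviving entries with
   |x| ≤ δ₂ are zeroed, giving a sparse `fs_final`.
4. **Base classifiers** — an extreme learning machine (random input layer,
   output weights `β̂ = H⁺T` via the Moore–Penrose pseudoinverse), a linear
   SVM, and a random forest, all emitting class probabilities.
5. **CCV adjustment** — the contour's bounding box gives four tangent
   points splitting it into four curves; each curve is sampled every 2
   pixels; slopes `k = Δy/Δx` from the curve's first tangent point to each
   sample form a vector K, and CCV is the number of sign alternations in
   ΔK, summed over the four curves.  From training data the class means
   m₁ = mean(CCV_normal) < m₂ = mean(CCV_abnormal) are learned; a test
   sample's winning-class probability is multiplied by a piecewise-linear
   weight ω ∈ [0.8, 1.2] (ω_normal falls, ω_abnormal rises, between m₁ and
   m₂; ω_normal + ω_abnormal ≡ 2), and the label flips when the adjusted
   probability drops below ½.

The hospital data this method was designed for is not public, so the
package ships a first-class synthetic generator (`synth_patches`): normal
nuclei are smooth ellipses, abnormal nuclei lobed star-like shapes with
boundary noise, with class-dependent texture.  It writes/reads the same
PNG-pairs + `labels.csv` layout expected of real data.

## Worked example

```python
from ccvpatch.evaluation import run_experiment

report = run_experiment({"seed": 3})   # 200/200 train, 100/100 test
print(report["ccv_model"])
for name, res in report["classifiers"].items():
    print(name, res["base"]["metrics"]["acc"], "->", res["ccv"]["metrics"]["acc"])
```

prints

```
{'m1': 1.77, 'm2': 10.095, 'valid': True}
elm 0.94 -> 1.0
svm 1.0 -> 1.0
rf 1.0 -> 1.0
```

Learned class means m₁ ≈ 1.8 and m₂ ≈ 10.1 say that synthetic normal
contours carry ~2 inflections and abnormal ones ~10.  The ELM, the weakest
base classifier here, mislabels 6% of test patches; reweighting its
posteriors by contour irregularity recovers all of them (0.94 → 1.00
accuracy), while the already-perfect SVM and RF are left unchanged —
the weight never flips a confident (p ≥ 0.625) prediction.

The same experiment is available from the shell:

```sh
ccvpatch generate --n-per-class 100 --seed 0 --out data/
ccvpatch -v pipeline --seed 3 --out report/
```

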