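# kneegrade

Automatic detection and Kellgren–Lawrence (KL) grading of knee
osteoarthritis from radiographs, using Hu's seven invariant moments of the
segmented joint-space region as shape features.

## The problem

In knee osteoarthritis the cartilage between femur and tibia deteriorates,
which shows on a radiograph as narrowing of the radiolucent joint space and
as osteophytes at the joint margins. Radiologists grade severity on the
five-level ordinal KL scale — Normal (0), Doubtful (1), Mild (2),
Moderate (3), Severe (4). Films are routinely distorted by handling and
digitization, so features that survive rotation, scaling and translation
are attractive. This package implements the classic automatic pipeline:

1. **Pre-processing** — 3×3 median filtering and bone-contour detection
   (Otsu threshold + connected-component boundary tracing).
2. **ROI localization by pixel density** — bone attenuates X-rays more
   than cartilage, so the projection profile (row-wise intensity sums) has
   two bright bone-band peaks with a valley at the joint space; the ROI is
   a band centered on that valley.
3. **Segmentation** — a region-based two-phase active contour (piecewise-
   constant means, 3×3 morphological smoothing per iteration) isolates the
   dark joint-space phase inside the ROI.
4. **Feature extraction** — Hu's invariants of the segmented region. With
   raw moments m_pq = Σ_x Σ_y x^p y^q f(x,y), central moments μ_pq about
   the intensity centroid (m10/m00, m01/m00), and normalized moments
   η_pq = μ_pq / μ00^γ with γ = (p+q)/2 + 1, the seven combinations
   φ1…φ7 (e.g. φ1 = η20 + η02, φ2 = (η20 − η02)² + 4η11², …) are
   invariant to translation, scale and in-plane rotation; φ7 flips sign
   under reflection.
5. **Classification** — K-NN (k = 3, standardized Euclidean; explicit
   tie-breaks) with a CART decision tree as comparison, evaluated by
   stratified 2-fold cross-validation into a 5×5 confusion matrix
   (rows = algorithm, columns = expert).
6. **Agreement statistics** — a goodness-of-fit chi-square between
   algorithm and expert per-grade counts (expected value = the average of
   the two observed counts, df = 4) and a paired t statistic over the five
   per-grade count differences, each compared against its critical value
   at the 5% level.

Because the original 2,000-image clinical dataset is not bundled, the
package ships a synthetic phantom generator — two bright bone bands
separated by a grade-dependent joint gap, optional osteophytes, Gaussian
noise — with exact ground truth, so the entire pipeline is testable end to
end, plus the published reader-study summary tables as CSV fixtures so the
evaluation statistics reproduce exactly.

## Worked example

```python
import numpy as np
import kneegrade as kg
from kneegrade.pipeline import PipelineConfig, run_experiment
from kneegrade.datasets import load_grade_counts

# grade one synthetic radiograph step by step
truth = kg.generate_phantom(kg.PhantomSpec(grade="Moderate", noise_sd=5, seed=4))
clean = kg.denoise(truth.image)
roi = kg.locate_joint_roi(clean)
seg = kg.active_contour_segment(roi.crop(clean))
hu = kg.features_from_region(roi.crop(clean), seg.mask)
print(roi.as_dict())
print(np.round(hu.as_array(), 6))

# an end-to-end grading experiment on 20 phantoms per grade
ds = kg.generate_feature_dataset(n_per_grade=20, seed=0, noise_sd=5)
res = run_experiment(ds, PipelineConfig(seed=0))
print(f"K-NN 2-fold accuracy: {res.accuracy:.4f}  (tree: {res.tree_accuracy:.4f})")

# rater agreement from the bundled reader-study counts
counts = load_grade_counts()
chi = kg.chi_square_agreement(counts["algorithm_vs_expert1"], counts["expert1"])
print(f"chi2 = {chi.statistic:.6f}, critical = {chi.critical_value:.5f}, {chi.decision}")
```

prints

```
{'row_start': 100, 'row_end': 164, 'col_start': 0, 'col_end': 465}
[ 9.2435e-02  8.5270e-03  1.0000e-06  0.0000e+00 -0.0000e+00 -0.0000e+00 -0.0000e+00]
K-NN 2-fold accuracy: 1.0000  (tree: 1.0000)
chi2 = 0.006858, critical = 9.48773, accept-H0
```

The ROI box brackets the joint space (the phantom's gap center is near row
128); φ1 and φ2 carry most of the grade signal because the segmented gap's
aspect ratio changes with KL grade; the chi-square statistic is far below
the df = 4 critical value 9.48773, so the algorithm's grade counts and the
expert's are in close consensus (H0 accepted).

A `kneegrade` console script exposes the same flow from the shell:
`simulate`, `features`, `fit`, `grade`, `evaluate`, `stats`
(`kneegrade grade image.png --model model.json` prints the predicted
grade; failures exit with stage-specific codes).

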