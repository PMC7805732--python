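# Methods

## Moments and invariants

Images are treated as discrete non-negative intensity functions f(x, y)
with x = column and y = row, both 0-based; the continuous moment integral
is discretized as a plain pixel sum. Raw intensities are used as weights —
no binarization and no rescaling to [0, 1] — and pixels outside a region
mask contribute zero. Raw, central and normalized central moments are
restricted to order p + q ≤ 3, which is all the seven invariants need;
γ = (p + q)/2 + 1 exactly, and the normalization denominator is μ00 raised
to γ. The invariants are stored on their raw scale. A
−sign(φ)·log10|φ| transform is available as an opt-in classifier-input
flag (`PipelineConfig.log_features`) because the seven components span
roughly four orders of magnitude, but the default pipeline instead
standardizes features inside the classifier, which achieves the same
conditioning without changing the stored features.

Degenerate inputs are contracts, not accidents: an all-zero image (m00 = 0)
raises a degenerate-input error everywhere a centroid or normalization is
needed; a single-pixel region is defined and yields all seven invariants
exactly zero (every central moment of order ≥ 1 vanishes).

Numerical expectations, verified by the test suite: lossless 90°-multiple
rotations (index permutations) preserve all seven invariants to 1e-9
relative; bilinear rotations of a smooth 256-px shape by 15°–180° change
φ1–φ4 by well under 2% relative and φ5–φ7 by under 1e-5 absolute; bilinear
rescaling by 0.2–0.6 changes φ1–φ4 by under 3%. φ5–φ7 are sixth-order
products and tiny on near-symmetric regions, so their stability is asserted
absolutely — relative error on near-zero quantities is ill-conditioned. The
independent cross-check oracle is scikit-image's Hu implementation; its
(row, col) axis convention is a reflection of ours, so the check compares
φ1–φ6 directly and |φ7| in magnitude.

## Synthetic phantoms

A phantom emulates a fixed-flexion knee radiograph at 256×465 (the
1,350×2,455 clinical aspect ratio at ~1/5 scale, keeping every test well
under a second): two bone bands at mean intensity ~200 separated by a
joint-space gap at ~60 on a ~30 background, a smooth low-amplitude cosine
joint line standing in for condyle roundness, grade-many osteophyte
half-discs intruding into the gap, and additive Gaussian noise (default
sd 8 intensity units, clipped to [0, 255]). Default gap widths are 30, 22,
14, 7, 2 px for Normal…Severe — strictly decreasing, with Severe close to
bone-on-bone. The gap-center row is jittered ±8 rows per seed so samples
within a grade are not identical. Every output is a pure function of the
spec including its seed.

What the phantoms do **not** model: bone texture, sclerosis intensity
changes, bilateral joints, beam-hardening or exposure gradients, and
anatomically realistic condyle shapes. Passing tests therefore demonstrate
that the pipeline recovers grade-determining geometry (gap width/shape)
under noise — not clinical performance on real radiographs. Feature
datasets default to grade proportions 65/53/28/26/28 per 200 samples,
mirroring the reader study's annotation imbalance.

## Pre-processing and ROI

The denoising filter is a 3×3 median with edge replication (the cited
pre-processing literature is median filtering; it is also idempotent on
piecewise-constant regions larger than the kernel). Bone contours come
from a global threshold — Otsu by default, overridable — followed by
connected-component boundary tracing; gradient edge detectors were
deliberately avoided because bone/soft-tissue histograms are near-bimodal
and a global threshold is deterministic and testable.

"Pixel density" ROI localization is a projection profile: row sums are
smoothed with a Gaussian of sd 3 rows, the two most prominent peaks are the
bone bands, and the joint row is the profile minimum between them. Both
projection axes are scored and the stronger two-band structure wins, so a
quarter-turned radiograph is still localized (as a full-height column
band). The returned band height defaults to 25% of the image extent along
the joint axis. Fewer than two peaks (uniform or bandless image) is a
dedicated ROI-not-found error.

## Active contour

Segmentation is a region-based two-phase piecewise-constant evolution:
initialize with a rectangle inset 10% from the ROI border; per iteration,
recompute the two phase means, reassign each pixel to the nearer mean, and
smooth the mask with a 3×3 binary median (the morphological
regularization); stop when fewer than a tolerance fraction (default 1e-3)
of pixels change, or at 200 iterations. A region energy was chosen over an
edge-based geodesic contour because the joint space is a homogeneous dark
region and the phantoms' edges are weak; the darker phase is returned as
foreground since cartilage/joint space is radiolucent. Constant crops and
single-phase convergence raise a segmentation-failed error. On noise-free
phantoms the recovered mask's Dice overlap with ground truth exceeds 0.98;
even the 2-px Severe gap survives the 3×3 smoothing because the median of
a 9-window centered in a 2-row band is still gap-valued.

## Classification

K-NN defaults: k = 3, Euclidean distance, per-feature z-standardization ON
(fitted on the training fold; zero-variance features get scale 1 and thus
carry no distance). Ties are a documented contract: majority vote, then
smallest summed distance among tied grades, then lowest ordinal grade. The
comparison classifier is a binary CART with Gini impurity, thresholds at
midpoints of consecutive sorted feature values, tie-breaking to the lowest
feature index then lowest threshold, default depth cap 8. Cross-validation
is a seeded stratified 2-fold split (plain random halves would be unstable
under the study's class imbalance); each half is predicted by a model
trained on the other and predictions are pooled into one 5×5 confusion
matrix with rows = algorithm, columns = expert.

## Evaluation statistics

The bundled reader-study tables fix the confusion-matrix orientation: the
row sums equal the algorithm's per-grade totals and the column sums the
experts' annotation totals. Under that orientation the study's "precision"
is diagonal/column-sum and its "recall" diagonal/row-sum — swapped relative
to the textbook definitions. Both conventions are implemented
(`convention="paper" | "standard"`); the paper convention is the default
for table reproduction, and the swap is documented here and in the API
docstring rather than silently corrected.

The chi-square agreement test is a goodness-of-fit with expected value
(algorithm + expert)/2 per grade, summed over both columns, df = 4 — not
the contingency-table formula. The paired t statistic uses
t = (ΣD/N) / sqrt((ΣD² − (ΣD)²/N)/((N−1)N)) with N = 5 grade pairs and a
one-sided critical value (2.1318 at df = 4, α = 0.05). Zero variance with
non-zero mean difference is reported as an infinite-statistic flag rather
than an exception, because ΣD = 0 with ΣD² > 0 is a legitimate outcome and
all-zero differences must still return t = 0. Applying a paired t-test to
five aggregate counts is statistically questionable; the formula is
implemented as published and not reinterpreted. Table-comparison rounding
is decimal half-up (4 decimals for metrics, 6 for chi-square); unrounded
values are the API truth.

## Problem sizes and tolerances

Moment-oracle equivalence is checked on 50 random images up to 16×16 at
1e-12 relative. The invariance suite uses a 256-px smooth blob (a sum of
three offset Gaussians — asymmetric so φ1–φ4 are well away from zero, yet
band-limited so interpolation error stays small). Pipeline recovery runs
100 phantoms per grade at noise sd 5 (~15 s total); the shuffled-label
baseline on the same features lands at chance (0.2 ± 0.1 for five balanced
grades). The acceptance script repeats all of the above from scratch under
a caller-supplied seed.

## Known limitations

- Phantom simplicity means classifier accuracies near 1.0 on synthetic
  data; the published real-data accuracies cannot be reproduced without
  the clinical images and are not targets here.
- The ROI search assumes one joint roughly axis-aligned (either
  orientation); bilateral films and oblique views are out of scope.
- The active contour converges to a two-means partition on strongly
  bimodal crops; heavily textured real bone may need the iteration cap and
  tolerance raised via `PipelineConfig`.
- Moments above order 3, Zernike/Legendre moments, and kappa-type
  agreement statistics are deliberately not implemented.
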