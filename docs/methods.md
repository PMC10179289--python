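# Methods

`boxnoise` studies how systematically mis-sized bounding-box labels propagate
through a supervised detector into its measured performance. The pipeline has
five stages: synthetic scene generation, label corruption, detector fitting,
mAP50 evaluation on noisy and accurate test labels, and Shapley super-pixel
attribution. This note documents the models, the defaults and the design
choices that were genuinely open.

## Label-noise models

**Consistent noise.** Every box keeps its center while each side is
multiplied by `sqrt(alpha)`, so the box *area* scales by exactly `alpha`
(`alpha = 2` doubles the area — "200 % boxes"). The sweep grid is
`0.1 … 0.9` (step 0.1), `1 … 10` (step 1), `20 … 100` (step 10): 28 values,
27 of them corruptions. This emulates a single annotator who is consistently
miscalibrated.

**Inconsistent noise.** The images are partitioned (seeded) into three
near-equal thirds standing for three annotators: one accurate (`alpha = 1`),
one too large (`alpha = 1 + delta`), one too small (`alpha = 1 - delta`),
with `delta ∈ (0, 1)` swept over `0.1 … 0.9`.

Two numerical guards apply after scaling: sides are floored at 1 px (a box
that is already sub-pixel is never grown by the floor, so `alpha = 1` is the
exact identity) and boxes are clipped to the image rectangle, which can shift
the center of a strongly enlarged box near the border. Clipping keeps every
corrupted annotation expressible in normalized YOLO coordinates. For
clip-free geometry the closed-form law `IoU(box, scaled box) =
min(alpha, 1/alpha)` holds exactly; it anchors several tests.

## Synthetic scenes

Real bitewing-style radiographs are standardized: dark background, a few
large smooth crowns, and small bright irregular mineralized deposits with
blur-softened boundaries. Each 256×256 scene contains:

* background at intensity 0.12 with Gaussian noise (sd 0.03),
* 2–4 smooth elliptical "teeth" at 0.40 ± 0.03,
* `k ≥ 1` deposits (truncated Poisson, mean 3 before truncation) at
  0.92 ± 0.04, each a union of 2–4 overlapping ellipses with overall
  diameter drawn from 4–16 px,
* a global Gaussian blur (sigma 1 px).

Ground-truth boxes are the tight bounding rectangles of each deposit's
pre-blur support — once blur has made boundaries ambiguous, the pre-blur
support is the only reproducible definition of an "accurate" label.
Generation is a pure function of `(seed, image_id)`.

Deposits are placed along tooth crown margins but 4–8 background pixels clear
of the tooth. Full attachment would be slightly more realistic, but it makes
the study mechanism degenerate: when training labels are strongly enlarged,
the learned threshold (see below) drops below tooth intensity, teeth become
foreground blobs, and attached deposits merge into them — at that point the
detector no longer has per-object predictions at all. The gap keeps every
deposit a distinct blob across the whole noise grid while teeth still provide
locally varying context. The three intensity bands are separated by ≥ 0.15
pre-blur (≥ 0.1 after blur, measured clear of deposit halos), so a threshold
rule has a clean operating point.

What the generator does *not* emulate: anatomical tooth shapes, caries and
restorations, exposure variation, overlapping deposits, and annotator
ambiguity in the ground truth itself. Passing tests therefore demonstrate the
noise → training → evaluation mechanism, not clinical performance.

## Surrogate detector

The study needs one property of a supervised detector: that it absorbs
systematic label-size bias. A deep network is neither desk-scale nor
deterministic, so the detector here has exactly two learned components,
both estimated from the training labels:

* **threshold** — midpoint between the pooled mean intensity of pixels
  inside training boxes and the pooled mean outside all boxes. Enlarged
  labels dilute the inside mean with background and lower the threshold;
  shrunken labels keep only bright object cores inside and raise it.
* **size prior** — per-axis median ratio of annotated box side to the side
  of the thresholded blob containing the annotation (blob matched by
  centroid containment; fallback 1.0). Training on `alpha`-scaled labels
  multiplies the prior by about `sqrt(alpha)` per side.

Inference thresholds the image, extracts 8-connected blobs of area ≥ 2 px,
and emits each blob's tight bounding rectangle rescaled about the blob
centroid by the size prior; confidence is
`min(1, (mean blob intensity − threshold)/(1 − threshold) + 0.5)`, a fixed
monotone mapping so ranking is deterministic. Both fit and detect are pure
functions.

Note that on blurred scenes the raw size prior is not exactly `sqrt(alpha)`:
a lower threshold also enlarges blob halos, and the two effects compose so
that *predicted box areas* — the quantity that matters downstream — scale by
about `alpha` relative to an accurately trained detector (tested at ±15 %).
There is no training loop, so the original protocol's early stopping has no
analogue here; nothing replaces it.

## Evaluation

Standard single-class detection metrics, implemented in continuous geometry:
greedy confidence-ordered matching at IoU ≥ 0.5 (ties on IoU broken by
lowest truth index, confidence ties by input order), precision `tp/(tp+fp)`,
recall `tp/(tp+fn)`, and AP as the integral of the monotone precision
envelope over recall (all-point interpolation; 101-point sampling would
differ by < 0.01 on these curve shapes). With one class, mAP50 = AP.

Two conventions deserve emphasis:

* **`≥` at the threshold.** A box and its area-doubled concentric version
  have IoU exactly 0.5. This measure-zero case arises *structurally* here
  (predictions learned from `alpha = 2` labels against accurate truth), so
  the boundary rule is load-bearing: IoU equal to the threshold counts as
  detected, as in COCO-style evaluators.
* **Pooled PR curve.** Detections are matched per image but pooled across
  images into one confidence-ranked list before computing AP. Per-image AP
  averaging is a defensible alternative; pooling is the common practice and
  is what is implemented.

Fold scores are compared with the base case by an exact two-sided
Mann-Whitney U test (p = `min(1, 2·min(P(U' ≤ U), P(U' ≥ U)))`). Tie-free
samples use the exact rank-sum counting recursion; tied samples use complete
enumeration of group assignments (fold samples have n = 5, so enumeration is
252 assignments). Normal approximation is never used silently.

## Experiment protocol

For each noise level the *entire* dataset — train, validation and test —
is corrupted, and the accurate test labels are retained in parallel; each
model is scored against both. "Five-fold cross-validation" combined with a
fixed 60/20/20 split is implemented as five independent seeded re-splits
(largest-remainder rounding of split sizes); fold seeds derive from one
master seed, and for inconsistent noise the annotator thirds are re-drawn
per fold from the fold seed. The default study size is 200 scenes × 5
folds, which keeps the full 28-value grid sweep to well under a minute per
condition on one CPU while leaving fold-to-fold variance visible.

Expected structure of the results (all reproduced by the test suite and
`scripts/acceptance.py`): an accurate base case (mAP50 ≥ 0.7; in practice
≈ 1.0 on these clean synthetic scenes); collapse on accurate test labels
for strongly shrunken (`alpha ≤ 0.3`) *and* strongly enlarged
(`alpha ≥ 10`) training labels; persistence of high mAP50 on equally noisy
test labels for enlarged boxes (the disguise effect); and insensitivity to
mild inconsistent noise (`delta = 0.05` moves accurate-test mAP50 by
< 0.05, since concentric IoU at `alpha = 1.05` is ≈ 0.95). One asymmetry of
the original study is *not* reproduced: a real network also fails on noisy
test data when trained on tiny boxes (too little signal to learn features),
whereas the surrogate still fits consistently shrunken labels; the surrogate
models label absorption, not feature starvation.

## Shapley attribution

Each image is tiled by a 20×20 super-pixel grid (400 cells; remainder pixels
join the last row/column). The explained scalar is detection persistence:
re-run the detector on the masked image and take the best
`confidence × IoU` agreement of any detection with the target detection.
Masked cells are filled with the mean sub-threshold (background) intensity,
which is neutral with respect to the learned threshold. Attributions come
from a permutation-sampling Shapley estimator — each of `n_evaluations`
(default 25) seeded random permutations inserts cells one at a time,
crediting each cell its marginal score change. The estimate telescopes, so
`sum(phi) = full − base` holds exactly on every run; with exhaustive
enumeration it equals the exact Shapley value (used as the test oracle on
small games). "One evaluation" is defined here as one permutation pass,
i.e. `cells + 1` detector calls; both the count and the fill value are
configurable since reasonable alternatives exist. Heatmaps are written as
red (positive) / blue (negative) overlays with a symmetric color scale,
at exactly the image's pixel dimensions.

## Known limitations

* The surrogate detector shares only the label-absorption mechanism with a
  trained network; absolute mAP50 values are not comparable to any real
  radiograph study, and near-perfect base-case scores reflect the clean
  synthetic scenes.
* Box deletions, additions, shifts and class flips are out of scope; only
  size noise is modeled.
* The Mann-Whitney enumeration path refuses samples whose assignment count
  exceeds 5·10⁶ rather than approximating.
* mAP@[.5:.95], per-size AP breakdowns and confusion matrices are not
  implemented.
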