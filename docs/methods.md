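# Methods

This note records the model, the conventions that make results
reproducible bit for bit, the design choices made where more than one
reading was defensible, and what the synthetic benchmark does and does not
demonstrate.

## LBP core

* **Sampling.** Each code thresholds 8 points on a circle of radius
  *r* ∈ {1, 3, 9, 27} px against the center pixel. Neighbor 0 lies along +x
  (column-increasing); the angle increases toward +y (row-increasing);
  neighbor *k* is the least-significant-plus-*k* bit. Any fixed convention
  would do — binning depends only on popcount and transition count — but
  the convention is pinned so independent oracles can reproduce codes
  exactly.
* **Interpolation.** Off-grid circle points are sampled by bilinear
  interpolation of the four surrounding pixels; offsets within 1e-9 of an
  integer are snapped, so the four axis-aligned neighbors read exact pixel
  values. Intensities are treated as reals; interpolated values are not
  re-quantized.
* **Tie rule.** The comparison is `neighbor >= center`: ties produce
  1-bits (a constant region yields code 255). Because bilinear weights are
  floating point, exact ties could flip on round-off; the comparison
  therefore uses a tolerance of 1e-6 intensity units, negligible on the
  0–255 scale. The same rule is part of the oracle used in the tests.
* **Binning.** Uniform codes (≤ 2 circular transitions; 58 of 256) are
  grouped by their number of 1-bits into bins 0–8; all non-uniform codes
  share bin 9. Each 10-bin histogram is normalized to unit Euclidean norm
  (an all-zero histogram stays zero). An L1 variant could be added behind
  a flag, but L2 is the package-wide convention.
* **Borders.** Codes are computed only where the whole circular
  neighborhood (including interpolation support) lies inside the region —
  no padding, no wrapping. A region too small for a single center is an
  error, not an empty histogram.

## mrcLBP descriptor

Features are computed on the central square of a patch — side
`round(fraction * min(H, W))` with round-half-up, offsets floored — with
fraction 1/6 of a 576-px patch by default (96 px), which keeps the
descriptor focused on the glomerular interior of a centered training
patch. All (channel, radius) histograms are computed over that *same*
standalone crop; larger radii simply have fewer valid centers. The
alternative (letting large radii reach into patch context outside the
crop) was rejected to keep a cropped region and a window in a larger slide
featurize identically. Blocks concatenate channel-major:
R1 R3 R9 R27 G1 G3 G9 G27 B1 B3 B9 B27, 120 values. Grayscale input is
replicated to three channels with a warning rather than rejected.

## Detector

* **Classifier.** `sklearn.svm.SVC(kernel="linear", C=1)`, no feature
  standardization and no class weighting: the histogram blocks are already
  unit-norm, and class imbalance is handled by data composition (the
  recommended ≥ 2:1 negative:positive ratio), not reweighting. The fit is
  deterministic given row order, so callers pass rows in filename-sorted
  order. Scores are raw signed decision values; no probability
  calibration.
* **Sign convention.** glom(+) maps to the negative side of the decision
  function, so score maps read "darker = more glomerulus-like". The
  convention is stored in the model file and asserted at training time.
* **Scanning.** The slide is resized by the calibration factor (bilinear;
  anti-aliasing when shrinking), then windows of 576 px at stride 64 are
  scored; windows that do not fit at the right/bottom edges are dropped,
  giving exactly `floor((H' - w)/s) + 1` rows. Implementation detail: LBP
  bin maps are precomputed once per (channel, radius) over the whole
  calibrated slide, and each window histogram reads the sub-array of
  centers whose neighborhoods lie inside its crop — bit-identical to
  featurizing each window standalone, at a fraction of the cost. No
  smoothing or aggregation across overlapping windows is applied.
* **Second stage.** A `SecondStageClassifier` hook (candidate crops in,
  keep/discard out) is defined with a pass-through default, for plugging a
  stronger patch classifier on top of the candidate set; no such
  classifier ships with the package.

## Score-map post-processing

Pipeline: threshold raw scores at 0 (strictly below passes) → keep
8-connected components of 6–50 map cells (both bounds inclusive; smaller
and larger components are removed — large ones are typically medulla-like
regions on real tissue) → intersect with cells below 0.25 on the min–max
normalized map → re-extract components → unweighted centroid per component
→ map to original slide pixels at the window center (calibrated
coordinates divided by the calibration factor) → clip crop boxes to slide
bounds. Two deliberate choices:

* The two thresholds live on two scales — raw signed scores first, the
  [0, 1] normalized map second. The final threshold's sensible working
  range (0.15–0.35; default 0.25, the midpoint) only exists on a
  normalized scale, while "leave the first threshold at 0" only makes
  sense on signed scores. Ordering the normalized threshold *after* the
  area filter also lets it split merged blobs into individual detections
  without re-imposing the size bounds.
* Area bounds are expressed in score-map cells and therefore depend on
  stride and calibration; 6–50 is calibrated for stride 64 at native
  resolution and exposed in `PostprocessConfig`.

Centroids are unweighted component means (not score-weighted); a
constant score map is a degenerate-input error; an empty detection set is
a valid result, not an error.

## Evaluation

Greedy one-to-one matching in ascending centroid-distance order (ties
broken by truth index), counting a detection as a true positive within
`match_radius` of an unmatched truth centroid. The default radius is half
a window (288 calibrated px): the true center must lie in the central half
of the detection window. Greedy matching equals the optimal assignment
for well-separated configurations (property-tested against brute force up
to 6 points) and is a deterministic approximation otherwise. Degenerate
denominators (e.g. no detections) yield 0 with an explicit flag rather
than NaN.

## Disease-vs-control score analysis

The same machinery retargeted: train the linear SVM to separate
glomerulus patches from a disease model (e.g. STZ-induced diabetes)
against control glomeruli, under repeated random cross-validation —
10 runs by default, each holding out 100 patches per class, training on
the rest, and scoring the holdouts. A master seed spawns per-run seeds.
Pooled holdout scores (with repetition across runs) form the per-class
histograms; per-run mean scores summarize separation. The overlap
fraction — the share of class-A scores above the pooled class-B median —
is reported as an assertable proxy for visual histogram overlap. Mean
scores are raw signed values; no normalization. A two-sample location
test on pooled scores is available in the tests but is not treated as
part of the method.

## Synthetic data: what it emulates and what it does not

The generator targets the one statistical property the detector exploits:
**object and background differ in the frequency of local intensity
transitions across scales**. Background is band-limited Gaussian noise at
0.01–0.05 cycles/px (granularity of tens of pixels, like tubular
cross-sections at low power) with a pink-ish mean color; each planted
glomerulus is a disk of 0.08–0.25 cycles/px noise (few-pixel granularity,
like packed capillaries and nuclei) in a purple-ish tone, blended into the
background over 5 px so there is no trivially detectable hard edge.
Channels are independent; color means are irrelevant to LBP (which is
shift-invariant) and serve only human inspection.

**Disk placement.** At the default density — 30 disks with radii sampled
from 120–200 px in a 2000×2000 slide — the sampled disks cover ~60 % of
the slide in expectation, more than sequential random (rejection)
placement can pack, so naive rejection sampling fails. Placement instead
spreads centers by seeded best-candidate sampling with greedy refinement
sweeps (each center moves to the most isolated of a random candidate
batch), then assigns each radius as the sampled target capped by the
distance to the slide edge and by half the nearest-center distance minus
a 45-px background gap, floored at the range minimum with an exact
pairwise non-overlap check. Two constants matter and were set by
measuring the generator against its own detector geometry:

* **45-px minimum gap**: adjacent disks with narrower background gaps
  produce score blobs that bridge into one connected component (measured
  merge threshold ~35–45 px at stride 64), which the area filter then
  deletes as oversized.
* **260-px interior margin** for centers: with a 576-px window the first
  window center sits at 288 px, so objects hugging the border are seen
  only by windows whose central region barely overlaps them. On a
  gigapixel WSI this penumbra is negligible; at desk scale it would
  otherwise swallow a third of the planted objects and the benchmark
  would measure border bookkeeping instead of detection.

Consequences: dense slides are biased toward the small end of the radius
range, and placement is near-evenly spaced rather than Poisson-like.
Training patches are rendered directly (one centered disk per positive
patch, pure background for negatives) with the same textures and geometry
as slide crops; the default class ratio is 1:2 positive:negative.

**Not emulated:** stain palettes and stain variability, nuclei, Bowman's
space, medulla, tissue folds, disease morphology, scanner artifacts, and
inter-channel correlation. Passing the synthetic benchmark therefore
shows that the pipeline's machinery — featurization, training, scanning,
post-processing, evaluation — is correct and that the descriptor
separates frequency-distinct textures; it does not certify performance on
stained tissue.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
detectors are trained on 40–200 positives (twice as many negatives), and
detection is benchmarked on five 2000×2000 slides with 30 planted
glomeruli each (150 objects pooled). The cross-validation analysis uses
10 runs × 100 holdouts per class on synthetic feature sets. On one CPU
the full suite runs in ~2 minutes and the acceptance script in ~1–2
minutes.

## Known limitations

* The linear-blend behavior of window scores means objects closer than
  roughly half a center region merge at the score-map level; the final
  threshold recovers pairs but not dense clusters.
* Greedy matching can undercount true positives in pathological
  arrangements where the optimal assignment differs; at the default match
  radius and realistic spacing this was never observed in testing.
* The 10-bin rotation-grouped histogram discards orientation information
  by construction; rotation-variant 59-bin LBP and opponent-color
  variants are out of scope.
* The area filter bounds are stride- and calibration-specific and must be
  rescaled if either changes.
* Tiled/pyramidal TIFF slides are read at a chosen level into memory;
  there is no out-of-core scanning.
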