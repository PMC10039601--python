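# Methods

`sellamorph` automates the classical linear morphometry of the sella
turcica (ST) on lateral cephalometric radiographs: segment the ST,
locate its four anatomical landmarks on the segmentation contour, and
convert pixel geometry to millimetre parameters. This note records the
models, parameter choices and numerical conventions, and what the
synthetic test bed does and does not establish.

## Coordinate and raster conventions

All rasters are `(row = y, col = x)` with the origin in the top-left
corner and y increasing downward. Printed image sizes such as
"2884 × 2304" are read as width × height. Crops are half-open slices
`image[y0:y1, x0:x1]`. Masks are boolean in memory and {0, 255} 8-bit
PNG on disk.

## Preprocessing

1. **ROI extraction.** The ST occupies a stable position on films from a
   given device, so the region of interest is a fixed 400 × 400 pixel
   window given by configuration (default `[500:900, 1200:1600]`; for
   the smaller public-dataset films `[800:1200, 600:1000]`). Learned ROI
   detection is out of scope.
2. **Histogram equalization**, global, over 256 bins: intensity *i* maps
   to `round(CDF(i) · 255)`. The mapping is monotone (preserves intensity
   order); constant images are returned unchanged.
3. **Median filtering** with a 5 × 5 window (configurable, odd ≥ 3),
   reflected borders. Removes impulse noise while keeping edges.

## Segmentation

The classic U-net: `depth` resolution levels of two 3 × 3 conv + ReLU
blocks with `base_channels · 2^level` features, 2 × 2 max-pooling down,
2 × 2 stride-2 transposed convolutions up, skip concatenation between
mirrored levels, and a 1 × 1 logit head. Padded convolutions keep the
output at input resolution. Two first-class profiles:

| profile  | depth | base | input  | use                        |
|----------|-------|------|--------|----------------------------|
| full     | 4     | 64   | 400 px | full-size radiographs      |
| reduced  | 3     | 16   | 128 px | CPU-scale tests            |

Because no GPU framework is available in the target environment, the
network is implemented on a small numpy engine (im2col convolutions in
channels-last layout, explicit backprop, verified against float64
finite differences). Training uses sigmoid cross-entropy on logits with
RMSprop (smoothing 0.99), batch size 8. Inputs are scaled to [0, 1];
masks to {0, 1}. Binarization threshold is 0.5 on the sigmoid output.

**Learning-rate schedule.** The plateau schedule (factor 0.5, patience
3 epochs, floor 1e-8) monitors *validation loss*, not validation dice:
with a hard 0.5 threshold the dice sits at exactly 0 during the early
phase in which foreground probabilities ramp toward the threshold, and
a dice-monitoring schedule decays the rate to nothing before the ramp
completes (observed: loss frozen at the constant-prediction entropy).
Checkpoint selection is still by best validation dice. The default rate
1e-5 matches the full-scale training protocol; the reduced profile uses
5e-4 — at 1e-5 a 10-epoch desk run never leaves initialization, and at
1e-3 RMSprop destabilizes late in short runs (observed loss spikes that
halve the validation dice for an epoch). 5e-4 trains stably to
validation dice ≈ 0.96 in 10 epochs on the synthetic bed.

Training/validation split: caller-supplied, else a seeded random 10%
holdout. Segmentation quality is scored with the dice coefficient
`2|A∩B| / (|A|+|B|)`; an additive epsilon (1e-6) defines
`dice(∅, ∅) = 1` (perfect agreement on absence). Reported dice is hard
(0.5-thresholded); the training history additionally logs soft dice.

## Postprocessing

The ST is unique per radiograph, so all but the largest 8-connected
foreground object are removed. Object size is the pixel count of the
*filled* outer boundary (holes count toward the area). Equal-area ties
keep the object whose first pixel comes earliest in row-major order.

## Landmark localization

* **ADP** (left-most contour point) and **BPF** (bottom-most) come from
  the raw mask contour (Moore-neighbor boundary trace). Ties: left-most
  tie → smallest y; bottom-most tie → smallest x.
* **TS** and **DS** are corner points at the ends of the top chord.
  The mask is first Gaussian-smoothed (5 × 5 kernel, σ = 1.1 — the
  standard kernel-size rule; configurable) because the serrated binary
  edge otherwise sprouts spurious corners. Shi-Tomasi corner detection
  then runs with `goodFeaturesToTrack` semantics: Sobel gradients
  (aperture 3), structure tensor averaged over a 5 × 5 block, response =
  minimum eigenvalue; candidates are 3 × 3 local maxima at ≥ 1% of the
  global maximum, accepted greedily in descending response subject to a
  40 px minimum pairwise distance, at most 3 corners. Equal responses
  break in row-major order. Among the detected corners, the two with the
  smallest ordinate are kept; the larger abscissa is TS, the smaller DS.
  Corner coordinates are integer pixels (no sub-pixel refinement).
* Defaults (3, 0.01, 40 px, 5) are tuned for 400 px rasters.
  `min_distance` must scale linearly with the raster
  (`CornerParams.scaled`; the reduced 128 px profile uses 12.8 —
  unscaled, the 40 px radius suppresses DS whenever it lies within
  4 mm of a stronger corner). The 5 px block is kept at all scales: on
  predicted masks a smaller averaging window is strictly noisier.
* The batch pipeline smooths with σ = 1.5 before corner detection
  (`PipelineConfig.corner_sigma`): U-net-predicted masks carry more
  edge serration than clean reference masks, and under-smoothing lets
  staircase artifacts on the chord win the smallest-ordinate screen.
  Direct `locate_landmarks` calls on clean masks keep the 1.1 default.
* A sanity gate requires `TS.x > DS.x` and both chord points above BPF;
  violations raise a landmark error instead of returning nonsense, so
  batch runs flag the image and continue.

## Linear parameters

With TS(x₁,y₁), DS(x₂,y₂), ADP(x₃,y₃), BPF(x₄,y₄) and scale R (mm/px,
default 0.1):

* Length = √((x₂−x₁)² + (y₂−y₁)²) · R
* Diameter = √((x₃−x₁)² + (y₃−y₁)²) · R
* Depth = |(y₁−y₂)x₄ + (x₂−x₁)y₄ + x₁y₂ − y₁x₂| / √((y₂−y₁)² + (x₂−x₁)²) · R

Depth is undefined when TS = DS (degenerate chord → error). Values are
kept at full precision internally and reported to 2 decimals.

## Agreement statistics

ICC model: **ICC(2,1)** — two-way random effects, absolute agreement,
single measurement — computed from the two-rater mean-squares
decomposition. This is the standard model for method comparison; note
ICC(3,1) (consistency) would be systematically higher when a fixed
offset exists between methods. Interpretation bands: moderate
(0.41, 0.60], substantial (0.60, 0.80], excellent (0.80, 1.00],
below-moderate otherwise. Bland-Altman analysis uses differences
`automatic − manual`, bias = mean difference, limits of agreement =
bias ± 1.96 · SD with the sample (n−1) standard deviation.

## Synthetic data

The generator draws a "nest" shape mirroring how the ST is annotated: a
straight chord from DS to TS across the top, and a smooth wall running
TS → anterior wall → BPF → floor → ADP → posterior wall → DS. Geometry
at the 400 px reference scale: TS–DS span 60–140 px, depth 45–115 px,
ADP bulge 5–25 px left of DS at 35–55% of the depth, rotation within
±5°, jittered center. Draws are rejection-resampled until the implied
Length lies in 4–14 mm and Diameter in 5–16 mm at R = 0.1, the range
reported for human sellae. The wall is a shape-preserving (PCHIP) cubic
through the landmarks and three waypoints — monotone segments guarantee
the curve's extremes sit at the knots, so BPF really is bottom-most and
ADP left-most after rasterization.

Ground-truth landmarks are **recomputed from the raster** (exact
left-most / bottom-most boundary pixels under the tie rules above;
nearest boundary pixels to the continuous chord ends), so tests never
dispute sub-pixel rounding, and the stored true parameters are exactly
the measurement formulas applied to those pixels.

The radiograph renderer paints a bright rim (open wall only — the chord
is not a radio-opaque structure), a darker fossa interior, a smooth
low-frequency background with bright distractor arcs kept away from the
sella, then Gaussian blur and additive Gaussian noise (SD 5–15).

**What the synthetic bed does not establish:** real cephalograms have
anatomical clutter crossing the sella (vessels, clinoid processes,
overlapping structures), variable exposure, and annotation ambiguity;
none of these are modeled. A green synthetic run validates the
pipeline's mechanics and its statistical machinery, not clinical
accuracy: clinical-scale claims (validation dice above 0.9, excellent-
band ICCs against manual measurement) are desk-checked only as
scaled-down analogues (dice ≥ 0.90, ICC ≥ 0.90 on 128 px synthetic
data).

## Numerical and degenerate-input choices

* dice(∅, ∅) = 1 via epsilon smoothing; empty predicted masks raise
  "no component found" in postprocessing (flagged per image in batch).
* Histogram equalization of a constant image is the identity.
* Median filter borders are reflected.
* Corner-response ties and component-area ties break in row-major order.
* ICC is clamped to [−1, 1] against float round-off; zero-variance data
  raise an undefined-ICC error rather than returning NaN.
* All randomness flows from explicit integer seeds; training, generation
  and the batch pipeline are bit-reproducible given the same seeds.

## Known limitations

* The numpy training engine is single-threaded and memory-bound; the
  full 400 px profile is practical for inference but training it at
  clinical scale is out of reach (and out of scope).
* `min_distance` is not auto-scaled with raster size; callers working
  below 400 px must scale it (the CLI exposes `--min-distance`).
* On near-flat fossa floors the bottom-most pixel can slide a few px
  along the contour; both ground truth and detector use the same tie
  rule, so measurements remain consistent, but the BPF coordinate
  itself is only stable to the flat-run length.
* The ADP bulge can fall within `min_distance` of DS, in which case the
  stronger corner response suppresses the other candidate; on the
  synthetic suite this affects ~2–3% of shapes and is counted as a
  recovery failure, mirroring the "almost all images" caveat of manual
  review on clinical material.
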