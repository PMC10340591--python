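# Methods

## Problem and pipeline

`berryprint` identifies the geographic origin of a fruit (the motivating
case is the Chinese wolfberry, *Lycium barbarum*, whose four main producing
regions — Gansu, Inner Mongolia, Ningxia, Qinghai — yield berries that
differ subtly in texture, shape and color) from a single photograph of one
fruit on a light background. The pipeline is:

1. **Preprocessing.** The photo is converted to grayscale
   (`Gray = 0.299·R + 0.587·G + 0.114·B`), thresholded with Otsu's
   maximum-between-class-variance criterion, and binarized with the
   strict-greater convention (pixel > k* → 1). Sobel gradient magnitude on
   the binary image localizes the fruit contour; the crop box is the
   bounding box of the largest run of nonzero edge rows/columns in which
   consecutive coordinates are ≤ `gap_thresh` (default 10 px) apart, which
   discards isolated specks. The object mask is then morphologically
   closed and opened with a disk (default radius 3 px) and every pixel
   outside it is set to exactly (0, 0, 0).
2. **HSI transformation.** The cropped image is mapped to
   hue/saturation/intensity: `I = (R+G+B)/3` exactly, `S = 1 − 3·min/sum`,
   and `H = θ` or `2π − θ` (for G < B) with
   `θ = arccos(0.5·[(R−G)+(R−B)] / √((R−G)² + (R−B)(G−B)))`.
3. **Texture features.** One complex Gabor filter per channel —
   wavelengths (13, 10, 10) px and orientations (π/4, π/3, π/12) for H, S,
   I; phase 0 — is convolved with the channel; the magnitude of the
   complex response is min–max rescaled to [0, 255] and counted into 256
   bins. The three histograms concatenate into 768 texture features.
4. **Shape features.** The 7 Hu invariant moments of the grayscale
   preprocessed image (raw values, no log transform), appended after the
   texture block: a 775-dimensional fused feature.
5. **Classification & evaluation.** A random forest (default 2000 trees,
   `mtry` = 50 candidate features per split) is trained on stratified 8:2
   train/test splits; the protocol repeats with fresh splits and fresh
   forests, and aggregates mean accuracy, a predicted×actual confusion
   matrix and per-sample error rates (times drawn into a test set vs.
   times misclassified).

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `grayscale.coeffs` | (0.299, 0.587, 0.114) | BT.601 luma; a legacy (0.299, 0.578, 0.114) triple is selectable for replicating older scripts |
| `crop.gap_thresh` | 10 px | max gap between edge coordinates merged into one object; larger gaps = noise |
| `morphology.radius` | 3 px | disk radius of the closing/opening cleanup at the default fixture scale |
| Gabor λ (H, S, I) | 13, 10, 10 px | per-channel carrier wavelengths of the texture filters |
| Gabor θ (H, S, I) | π/4, π/3, π/12 | filter orientations |
| Gabor σ | 0.56·λ | Gaussian envelope width; the ≈one-octave-bandwidth convention keeps the filter well-formed when only λ is specified |
| Gabor γ | 0.5 | envelope aspect ratio (elongated perpendicular to the carrier) |
| `histogram.normalize` | off | raw counts by default; normalizing by pixel count makes differently-sized crops comparable and is recommended when image sizes vary widely |
| `rf.n_trees`, `rf.mtry` | 2000, 50 | the operating point selected by the hyperparameter grid |
| `eval.train_fraction` | 0.8 | the 8:2 protocol |

## Numerical and design choices

* **Otsu.** σ_B²(k) is computed in the two-term variance form
  P1(m1−mG)² + P2(m2−mG)² over all 256 candidate levels; ties break to the
  smallest k. A constant image raises (no threshold exists). In the
  pipeline the threshold is applied to the floor-quantized gray so pixels
  at level k* land on the dark side, consistent with the histogram the
  threshold was selected on.
* **Foreground polarity.** The object class is the Otsu class occupying
  less of the image border (backgrounds touch the border). This makes the
  chain work both on raw light-background photos and on already-processed
  black-background images.
* **Sobel.** Correlation with the standard 3×3 kernels, replicate-edge
  padding, same-size output — keeps edge coordinates aligned with the
  source raster. Applied to the binary mask by default (configurable to
  grayscale input).
* **Morphology.** Closing then opening with a disk; the mask is padded by
  two radii (edge mode) before the operations so border-touching
  foreground is not eroded by the implicit zero border.
* **HSI degeneracies.** Black pixels → H = S = I = 0; gray pixels → H = 0;
  the arccos argument is clamped to [−1, 1].
* **Gabor fusion.** Real and imaginary responses fuse as the complex
  magnitude (Gabor energy); a `sum` alternative exists. Convolution uses
  FFT on an edge-padded array, so output size equals input size.
* **Histogram constancy guard.** A response whose spread is below 1e-9
  (relative) is treated as constant and mapped to bin 0; min–max rescaling
  would otherwise blow floating-point noise on an algebraically constant
  channel up to full histogram scale.
* **Hu moments.** 1-based indices with x over rows, matching the classical
  double-sum definition; the invariances make the convention immaterial
  but fixing it lets brute-force oracles reproduce raw moments exactly.
  Raw (non-log) values are the feature.
* **Splitting and seeding.** Splits are stratified per class so every
  origin appears in every test set. Repeat r of an evaluation uses split
  seed `master + r` and a forest seed offset by a large constant, so
  reports are bit-reproducible from one master seed and forest randomness
  is decoupled from split randomness.
* **Forest.** scikit-learn's `RandomForestClassifier` with
  `max_features = mtry`; no feature scaling (trees are scale-invariant).
  Vote ties resolve by averaged class probabilities, exact ties to the
  first class in sort order.
* **Grid ties.** The best (n_trees, mtry) combination breaks ties toward
  fewer trees, then smaller mtry.

## The synthetic study set

Origin-labelled fruit photo collections are rarely distributable, so the
package ships a generator that renders labelled stand-ins: one ellipse per
image on a near-white (≈245–255, lightly noisy) background, with class
identity carried by a sinusoidal ridge texture (wavelength, orientation,
contrast of a multiplicative darkening field), the ellipse geometry
(major axis, aspect ratio) and the base color. The default study set has
four classes × 90 images on a 128×128 canvas: two "rugged" classes
(ridge λ = 8 px, contrast 0.65/0.55) and two "delicate" ones (λ = 20 px,
contrast 0.22/0.18), with distinct aspect ratios (1.25/1.75/1.45/1.10),
major axes (76/68/60/54 px) and reddish base colors. Size, position,
rotation and ridge phase jitter per image; all randomness derives from a
master seed.

What the generator does **not** emulate: specular highlights, shadows,
illumination gradients, surface wrinkle networks (real texture is not a
single sinusoid), camera optics, or inter-image background variation.
Passing tests therefore demonstrate that the feature chain measures what
it claims (ridge frequency/orientation/contrast, shape, color) and that
the evaluation protocol is leak-free — not that field accuracy on real
fruit will match the synthetic numbers. The identical-recipe control set
(four classes with the same parameters, different labels) verifies the
latter: its accuracy sits at chance (≈25%).

## Problem sizes used in tests and the acceptance script

Feature extraction runs on the full 4×90 set. The repeated-evaluation
protocol is run at 30–50 repeats (tests) and the grid/sweep at 1–2 repeats
per cell, rather than the 200-repeat full protocol; the repeated-split
means are stable well before 200 repeats on the synthetic set, and the
package exposes `repeats=200` as the default for real studies.

## Known limitations

* Single-fruit scenes only; no multi-object segmentation.
* The preprocessing assumes a bimodal gray histogram (object vs.
  background); cluttered or low-contrast backgrounds break the Otsu step.
* One Gabor filter per channel — a deliberate design, but coarse compared
  to multi-scale/multi-orientation banks.
* Raw-count histograms make images of different crop sizes contribute
  different masses; turn on `histogram.normalize` when sizes vary.
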