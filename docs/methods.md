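# Methods

## The model

`sphereseg` implements ensemble segmentation of 2-channel MRI-like slices
(T1 and contrast-enhanced T1) by **spherical image projection**, with
pixel-wise aleatoric uncertainty estimated from ensemble disagreement.

### Spherical projection

A sphere of radius `r` is centered at the origin `O`; the image plane sits
orthogonal to the pole axis at distance `d < r` and spans `[-h, h]²` in
dimensionless sphere units.  A planar point at in-plane radius `ρ` from the
pole axis projects along the ray from `O` through the point, reaching the
sphere at polar angle

    θ(ρ) = arctan(ρ / d),   dθ/dρ = d / (d² + ρ²).

Because `dθ/dρ` is maximal at `ρ = 0`, the transform magnifies the
neighborhood of the **projection center** (the planar point placed on the
pole axis) while retaining the full field of view.  The default design
`(h, r, d) = (0.5, 1.0, 0.3)` is the configuration with the smallest
round-trip SSIM degradation; under it the local linear magnification falls
from `1/d ≈ 3.33` at the center to `≈ 0.88` at `ρ = 0.5` (a ratio of 3.78).

The spherical patch must live on a square Cartesian grid to be fed to a
CNN.  We use **azimuthal-equidistant coordinates** about the pole axis:
grid radius proportional to `θ`, grid angle equal to the azimuth `φ`.  The
radial scale is anchored so the plane's edge midpoint `θ(h)` maps to the
inscribed-circle radius of the spherical grid; plane corners then still
fall inside the square grid.  This parameterization is an explicit design
choice of this package — it is analytic, exactly invertible, and reproduces
the documented center-magnification behavior.  Varying the projection
center is implemented by translating the planar sampling window so the
chosen center lies on the pole axis; samples outside the source image take
a constant fill value (default 0).  Intensities are resampled bilinearly,
masks by nearest neighbor (so they stay binary); the interpolation order is
configurable.

Round-trip fidelity: forward-then-backward projection is the identity up to
interpolation loss.  The peripheral spherical grid is coarser than the
planar grid (that is the price of center magnification), so pixel-level
noise at the periphery does not survive a round trip; band-limited
("smooth") images do, with SSIM ≥ 0.95 under the default design.  The 0.95
figure is this package's acceptance threshold; the design source states
only that the chosen geometry minimizes SSIM degradation.

### Ensemble workflow

For an input slice `X` (planar grid `N²`, default 192², 2 channels):

1. build `k` projection centers on a `√k × √k` lattice, symmetric about the
   image center, spanning `extent_fraction` (default 0.5) of the field of
   view — the reference configuration uses `k = 121`, tests and the desk
   demo use `k ∈ {9, 25}`;
2. forward-project `X` about each center onto the spherical grid
   (default 256²);
3. segment each projected image with the plug-in predictor (probability map
   in `[0, 1]`);
4. backward-project the `k` maps onto the planar grid → probability stack `M`;
5. **binarize**: `Z(i,j) = 1` iff the ensemble mean `(Σₙ Mₙ(i,j))/k`
   exceeds a global Otsu threshold `T` computed on that same mean map.
   (Computing `T` on the mean rather than the sum keeps threshold and
   comparand on one scale; the binarization rule compares the mean to `T`.)
   A constant mean map carries no class structure: it yields an
   all-background mask with a logged warning;
6. **uncertainty**: per pixel, the `k` member probabilities are discretized
   into `value_bins` classes (default 2, i.e. binarization at 0.5 — raw
   continuous probabilities would make literal unique-value counting
   degenerate) and the Shannon entropy of the empirical class frequencies
   is reported in nats:  `U(i,j) = −Σ_v p̂_v ln p̂_v`.  `U` is normalized to
   `[0, 100]` by the fixed theoretical maximum `ln(min(k, value_bins))` —
   not per-slice min-max — so a filtering threshold τ means the same thing
   on every slice.

### Scoring

Classical per-slice metrics: accuracy, sensitivity, specificity, 2D Dice
coefficient, and symmetric surface distances.  Surfaces are foreground
pixels 4-adjacent to background or the image border.  The directed
nearest-surface distances are pooled in both directions; **mHD** is the
pooled mean and **HD95** the pooled 95th percentile (linear interpolation),
scaled by the pixel spacing and reported in cm.  The pooled-symmetric
reading (rather than max-of-directed) matches the "mean distance between
surface points" definition and is fixed here so comparisons are
reproducible.  Slices where either mask is empty get an infinite-distance
sentinel and are excluded from distance aggregates with a logged count;
empty-ground-truth slices have undefined sensitivity and are excluded from
that aggregate.

The **U-score** follows the QU-BraTS construction: for τ = 1..100, pixels
with normalized uncertainty `U < τ` are retained (τ = 100 retains
everything, so `TP₁₀₀`/`TN₁₀₀` are the unfiltered counts and
FTP₁₀₀ = FTN₁₀₀ = 0 by construction); filtered-out pixels are removed from
the evaluation, not reassigned to background.  With

    FTP_τ = (TP₁₀₀ − TP_τ) / TP₁₀₀,    FTN_τ = (TN₁₀₀ − TN_τ) / TN₁₀₀,

the areas under DSC(τ), FTP(τ), FTN(τ) (trapezoidal, τ rescaled to [0, 1])
combine into

    U-score = (AUC₁ + (1 − AUC₂) + (1 − AUC₃)) / 3 ∈ [0, 1].

A slice with no unfiltered true positives (or negatives) has an undefined
FTP (FTN) ratio; the curve is reported as zero with a degeneracy flag.
Across a test set the U-score is computed per slice and averaged.

## The predictor

The ensemble is model-agnostic: any deterministic map from a 2-channel
image to a same-shaped probability map plugs in.  Three predictors ship:

* **Reference U-Net** — encoder-decoder with double 3×3 convolutions +
  ReLU, 2×2 max pooling, skip concatenations, nearest-neighbor upsampling
  (followed by a 3×3 convolution), and a final 1×1 convolution + sigmoid.
  It is implemented directly in NumPy (im2col convolutions with
  hand-derived gradients, Adam, binary cross-entropy with logits) and is
  deliberately tiny — default depth 3, 16 base channels — sized for
  CPU-scale experiments; width, depth, learning rate, epochs and batch size
  are configurable.  Training is deterministic given the seed.
* **Mock predictors** (`perfect` / `blurred` / `noisy`) — analytic
  probability maps derived from an attached ground truth, used to test the
  projection/uncertainty machinery without training.  Called on a projected
  image, the mock projects its ground truth with the same geometry and
  center, acting as an oracle segmenter in projected space.
* **TTA baseline** — the same U-Net on unprojected images with 8 invertible
  test-time augmentations (identity, rotations by 90/180/270°, horizontal
  and vertical flip, two ±8 px cyclic translations; kinds and count follow
  the comparison protocol, magnitudes are this package's choice).  Each
  augmented prediction is inverse-transformed; the resulting stack flows
  through the *identical* binarization/entropy/scoring path as the
  projection ensemble, so the comparison isolates the projection mechanism.

## The phantom generator

Real cohort data is not available, so every experiment runs on synthetic
2-channel phantoms that emulate the structural features the method
exercises: a smooth low-frequency background shared by both channels; one
or more quasi-elliptical lesions strongly enhanced (default +0.6 of the
dynamic range) on the T1ce-like channel and faintly (+0.1) on the T1-like
channel; a thin curved "dural tail" appendage (default width 2 px,
probability 0.72 per lesion — matching the reported prevalence of dural
tails) that belongs to the ground truth; bright vessel-like curvilinear
distractors excluded from the ground truth; Gaussian smoothing of the
lesion signal (boundary ambiguity) and additive Gaussian noise (σ = 0.05 of
the dynamic range).  Everything is deterministic given the seed; cohorts
attach subject IDs (3 consecutive slices per subject) so train/test splits
can be grouped per subject.

What the phantom does **not** emulate: real brain anatomy, bias fields,
skull/dura geometry, 3D continuity across slices, scanner-specific noise.
Passing tests on phantoms therefore demonstrate the correctness and the
qualitative behavior of the machinery (boundary-localized uncertainty,
vessel confusers, tail sensitivity), not clinical-grade performance.

## The desk-scale study

`sphereseg.experiments.run_demo` reproduces the comparison protocol end to
end at sizes chosen for a single CPU: 240 phantom slices split 7:3 per
subject (168 train / 72 test), a depth-3 / 8-channel U-Net trained for 16
epochs (batch 8, Adam, lr 3·10⁻³) on training slices forward-projected at
randomly drawn lattice centers, then a k = 25 ensemble on the held-out
slices.  The grids are reduced proportionally (planar 96², spherical 128² —
preserving the 4:3 spherical/planar ratio of the reference configuration);
lesion and tail sizes scale with the grid.  The TTA baseline trains on the
unprojected slices (4 epochs suffice for the structural comparison) and is
scored identically.  All seeds derive from the single study seed.

## Numerical choices and edge cases

* Otsu threshold: 256-bin histogram by default; ties in the between-class
  variance break toward the lower threshold.
* Entropy: `0 · ln 0 = 0`; entropy is clipped at 0 against −0.0 rounding.
* Both-empty Dice = 1 by convention (logged); empty-mask Hausdorff =
  infinite sentinel + exclusion flag.
* Trapezoidal AUC over τ rescaled to [0, 1]; for the piecewise-linear
  curves used here this integration is exact.
* Max-pool backward routes gradient to all tied maxima; upsample-nearest
  backward sums each 2×2 block.
* Coordinates are 0-based pixel centers in (row, col) order everywhere;
  the image center of an N-grid is ((N−1)/2, (N−1)/2).
* Projection rays at θ ≥ π/2 (possible only for extreme off-center
  configurations) are clamped to the fill value.

## Known limitations

* Strictly 2D and slice-wise; no volumetric ensembles or 3D Hausdorff.
* Aleatoric uncertainty only: ensemble disagreement under a fixed model.
  Epistemic methods (Bayesian weights, MC dropout) are out of scope.
* The NumPy U-Net is for reference-scale experiments; it is not a
  performance-competitive training stack.
* Off-center projections lose content translated outside the sampling
  window (constant fill); centers are therefore restricted to the central
  half of the field of view by default.
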