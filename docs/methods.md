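# Methods

## The segmentation pipeline

`vesselseg` implements a multichannel retinal blood-vessel segmentation
method that combines unsupervised vessel enhancement with a supervised
encoder-decoder network.  A fundus photograph is reduced to its green
plane (strongest vessel/background contrast), contrast-enhanced with
CLAHE and a gamma transform, and then processed by three parallel
channels:

1. **Channel 1 — background removal.**  A grey morphological closing
   with a disc of radius 11 px estimates the background (the closing
   fills the dark vessels); the remap
   `255 − (closing − image) + mean(closing)`, followed by min-max
   rescaling to [0, 255], flattens illumination and suppresses the
   bright optic disc while keeping every vessel.
2. **Channel 2 — large-scale matched filter.**  A bank of rotated,
   zero-mean Gaussian matched filters with length `l = 10.8`, width
   `s = 1.9` and 8 orientations, tuned to thick vessels.  The per-pixel
   response is the maximum over orientations, min-max rescaled to
   [0, 255], then passed through the modified black-hat transform below.
3. **Channel 3 — small-scale matched filter.**  The same construction
   with `l = 5`, `s = 0.1` and 18 orientations, tuned to capillaries.

The **modified black-hat transform** ("black hat 2") computes
`B = closing(f) − f` (which highlights dark structures smaller than the
structuring element, disc radius 11 by default) and returns
`255 − (f − 2B)` clipped to [0, 255]; doubling the dark-structure term
deepens vessel contrast relative to the plain black-hat.

Each channel feeds its own copy of the U-Net (below); the three
probability maps are binarized with a local-mean adaptive threshold,
fused with a pixelwise OR — any vessel found by any channel survives —
restricted to the field of view, mapped back to native resolution, and
pruned of 8-connected components smaller than 25 pixels.

## Matched-filter kernels: numerical construction

The canonical template is a *discrete point set*: integer lattice points
`(u, v)` with `|u| ≤ max(3s, 1)` across the vessel and `|v| ≤ l/2` along
it, with weight `−exp(−u²/2s²)`; the mean over the set is subtracted so
the template sums exactly to zero (zero response on flat background).
The one-pixel half-width floor matters at `s = 0.1`, where `3s < 1`
would otherwise leave an empty support.

Rotated kernels are built by forward-rotating the canonical point set
and depositing each point's weight on its four surrounding pixels with
bilinear splatting.  Two alternatives were tried and rejected:

* evaluating the continuous Gaussian at inverse-mapped coordinates
  destroys the centerline ridge at sub-pixel widths (`exp(−u²/0.02)` is
  numerically zero for any off-lattice `u`), leaving oblique kernels
  with no orientation preference at all;
* nearest-neighbour rounding of the rotated points changes the number of
  deposited points per orientation, giving kernels unequal mass and a
  systematic bias toward particular orientations.

Splatting preserves the total (zero) mass and the sub-pixel geometry;
each rotated kernel is finally rescaled to the canonical template's L2
energy so all orientations compete on equal footing in the per-pixel
maximum.  With this construction the nearest bank angle wins on 1-px
synthetic lines for every orientation of both banks (8 and 18
directions).  Correlation uses reflective border handling.

## Network

The U-Net maps a 1×576×576 frame to per-pixel vessel probabilities:
five encoder DoubleConv blocks (widths 64, 128, 256, 512, 512) with 2×2
max pooling, bilinear 2× upsampling with skip concatenation, four
decoder DoubleConv blocks (256, 128, 64, 64), and a 1×1 output
convolution with sigmoid.  Every convolution is 3×3 with padding 1, bias,
batch normalization and leaky ReLU (negative slope 0.01), so a
DoubleConv C₁→C₂ carries `9(C₁+C₂)C₂ + 6C₂` learnable terms and the full
network 13,394,177 (13.39 M).  The net is fully convolutional: any input
side divisible by 16 works, and `UNetSpec.base` scales all widths
together for smaller experiments.  Inputs are scaled to [0, 1]; weights
are Kaiming-uniform (fan-in, leaky-ReLU gain), batch-norm scale 1 /
shift 0, all drawn from a seeded generator so builds are reproducible.

The network, its backward pass and the optimizer are a compact NumPy
engine: convolutions are im2col + GEMM (the input-gradient is itself a
convolution with spatially flipped, channel-transposed weights, so it
reuses the same path), pooling routes gradients to the first maximum on
ties, and bilinear upsampling is expressed as two 1-D interpolation
matrices whose transposes give the backward pass.  Analytic gradients
are verified against central finite differences in the test suite.

## Loss

Vessel pixels are a small minority (a few percent of the FOV), so the
objective combines a soft Dice loss
`1 − 2Σpq/(Σp² + Σq² + ε)` with a class-weighted cross-entropy in which
the positive branch is weighted `1 − TP/N_p` and the negative branch
`1 − TN/N_n` (N_p/N_n = predicted-positive/negative counts at a 0.5
threshold, recomputed per batch, no gradient through the weights; a
class with no predictions gets weight 1).  The total is
`dice + λ·ce` with λ = 0.5.  The cross-entropy sum is divided by the
pixel count so the loss magnitude is resolution-independent (this only
rescales the effective learning rate); ε = 1e-7 smooths both the Dice
denominator and the log clamp.

## Training

SGD with momentum 0.9 (no weight decay), batch size 2, 30 epochs, and a
three-stage learning rate: 0.01 for epochs 1–10, 0.001 for 11–20,
0.0001 for 21–30.  The training set is expanded fourfold by horizontal
flip, vertical flip and 180° rotation applied jointly to image and
label.  Each channel trains its own network.  By default 10 % of the
(unaugmented) pairs are held out and the checkpoint with the best
held-out Dice is kept; set `val_fraction: 0` for runs that train on
everything.  Training is deterministic under a fixed seed.

## Binarization defaults

The adaptive threshold is `T = −b + mean(window)` with a 31×31 window
(reflect borders) and a pixel is vessel iff its value exceeds `T`;
probability maps are scaled by 255 first so `b` lives on the gray scale.
The default is `b = −15`, i.e. a pixel must exceed its local mean by 15
gray levels: with a *bright* foreground on a smooth, near-constant
background a positive `b` would lower the threshold below the local mean
and mark the whole frame as vessel.  Both `b` and the window are
configurable.

## Synthetic phantoms

The generator renders what the pipeline actually depends on: a bright
green-plane background (base 200) with a smooth low-frequency
illumination field (±12), dark vessels along quadratic Bézier curves
from near the frame center to near the FOV rim with an
inverted-Gaussian cross-section (centerline dip 40–80, width 1–6 px,
σ_w = width/2), an optional bright optic-disc blob, additive Gaussian
noise (σ = 5), and a circular FOV (radius 0.48 × side).  Ground truth is
the analytic distance to the centerline (vessel iff within width/2), so
labels are exact rather than re-thresholded renders.  At these defaults
the vessel fraction inside the FOV falls in the 2–20 % band that
motivates the class-weighted loss, and the vessel/background green
contrast exceeds 20 gray levels.

What the phantoms do *not* emulate: branching trees, the central light
reflex of large vessels, lesions/exudates, JPEG artifacts, and the
color statistics of real fundus cameras.  Tests passing on phantoms
therefore demonstrate that the pipeline's machinery — enhancement
polarity, scale selectivity, learning, fusion, metrics — is correct,
not that the published benchmark numbers transfer to real photographs.

## Problem sizes used in the test suite

The end-to-end recovery test trains all three channels on 40 phantoms at
128×128 with a base-8 (width-scaled) network for 15 epochs, without
augmentation and without a validation holdout, then segments 10 held-out
phantoms; it asserts a mean fused Dice of at least 0.7 and that OR
fusion's sensitivity dominates every single channel.  These sizes are
the package's choice of a compact but non-trivial experiment; the
full-width architecture is exercised separately through the parameter
ledger, which must reproduce every published per-block count exactly.

## Known limitations

* Eq-style evaluation "AUC" here is (Se+Sp)/2 — balanced accuracy from a
  single binary mask, not ROC area; the two can differ substantially.
* The MCC implementation uses the standard Matthews numerator
  `TP·TN − FP·FN`; a typeset variant (`TP·TN − TP·FN`) is available
  behind `printed_variant=True` for auditing only.
* Skeletonization for the CAL Length term uses scikit-image's
  `skeletonize` as the realization of homotopic thinning; other thinning
  algorithms give slightly different skeletons and hence L values.
* The adaptive threshold assumes probability maps with near-zero smooth
  background; heavily miscalibrated networks may need a different `b`.
* CLAHE tile geometry follows the image aspect ratio (grid of 8×8
  tiles), so extremely elongated images get elongated tiles.
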