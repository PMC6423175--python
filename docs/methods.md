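# Methods

## Problem and approach

In dense cultures — hippocampal neuron/glia networks, pericyte monolayers,
fluorescently stained glia — individual cells overlap, touch and change
shape, so single-particle tracking loses its targets. `densemotion`
instead measures *global* motility of an object class per frame pair:
cellular structures are first isolated by segmentation operators suited to
low-magnification phase contrast (halo-carrying somata, dark filamentous
neurites, contrasted membranes), and a scalar descriptor then summarizes
how much the segmented scene moved between successive frames. Absolute
speed (pixels/frame) comes from a linear transfer function fitted on
simulated cells whose speed is known exactly.

## Descriptors

For a frame pair (f1, f2), both in [0, 255] after standardization:

* **DiffMove** `= Z / N_pixel * 10000` where `Z = #{|f1 − f2| > θ_d}` and
  `N_pixel` is the number of non-black (> 0) pixels of f1. The threshold
  θ_d defaults to 10 gray levels so sensor noise does not register as
  motion. Strict inequality; symmetric up to the N_pixel convention, which
  we evaluate on the first frame of the pair.
* **P-move** `= (1 − rP) * 100` with rP the Pearson correlation between
  the two frames after an optional 3×3 mean filter (on by default).
  A constant frame raises an error rather than returning rP = 0: a silent
  zero would fake "no motion". The ×100 scale is our choice, made so
  P-move shares the COPRA numerator.
* **ratio speed operator** `rSO = sqrt(rF · 20 / img_size) · 10`. rF
  counts pixels whose symmetric Sobel-edge ratio
  `r = (max(e1,e2)+1)/(min(e1,e2)+1)`, scaled as `d = min(255, (r−1)·255)`,
  exceeds θ_r (default 20; < 10 admits small changes, > 30 emphasizes fast
  objects). Pixels where both edge magnitudes fall below `EDGE_FLOOR = 30`
  (about the Sobel response of a 5-gray-level step, i.e. the sensor-noise
  scale) are treated as flat background: the ratio of two noise-level edge
  responses is meaningless and would otherwise saturate rF on any noisy
  image, whereas the ratio step is meant to focus on highly contrasted
  structure. rF counts pixels rather than accumulating magnitudes.
* **COPRAMove** `= (1 − rP) · 100 / rSO`. Pearson decorrelation with the
  ratio term as denominator: both respond similarly to focus drift,
  global brightness and structure density, so the quotient cancels these
  nuisances and leaves translocation speed dominant. `rSO = 0` (a static
  scene) defines COPRAMove = 0.

All thresholds use strict `>`.

## Preprocessing and focus

Frames are real-valued internally and quantized to 8-bit only on write.
Standardization resizes to 640×480 and centers the mean at 127 by an
additive offset (the simplest mean-preserving reading of histogram
centering). Background flattening subtracts a Gaussian blur of the frame
(default sigma = width/8, far above cell scale). Debris removal replaces
small (≤ 30 px²) high-local-z-score (> 3) components with a
normalized-convolution background estimate. Focus is
`F = ln(sd²) − 1`, sd the standard deviation of the 4-neighbor Laplacian
response; a constant frame returns the sentinel −10 (below the practical
−1 floor) to keep traces numeric. Halo leveling combines (a) subtraction
of a half-weighted low-passed image of the top-5% pixels with (b)
reciprocal-histogram intensity reweighting `i → i/(H(i)·255 + 1)` (H sums
to 1), merges the two by pixelwise mean (the merge rule is configurable;
no canonical definition exists) and inverts. The pseudo-DIC rendering is
inversion plus a diagonal first-difference relief term, recentered to 127.

## Segmentation conventions

8-connectivity everywhere; labels contiguous 1..K. SCD selects pixels from
256-bin histogram frequency (threshold as fraction of all pixels), gates
components by size and removes spikes by opening (disk radius 2). ICB
closes gradient-magnitude borders (disk radius 3), fills enclosed
interiors and gates by a size range. The soma detectors require either a
local-percentile brightness peak (ExtObj) or high local contrast combined
with brightness at least 5 gray levels above the frame mean (NSD) — the
margin keeps pixels adjacent to dark neurites from qualifying. Neurite
skeletons come from locally dark pixels, component-wise skeletonization,
and an elongation gate (skeleton length ≥ min_len, mean width =
area/length ≤ max_width, length/width ≥ 3). Perimeter masks are
4-connected erosion boundaries dilated to the requested line width.
Membrane perimeter *length* for APr uses marching-squares contours at the
0.5 iso-level (sub-pixel); absolute APr values depend on this convention.

## Membrane metrics

`APr = area / perimeter` (smoothness; protrusions lengthen the perimeter
and lower it). `pA_i = 100 · area_i / max_j area_j` and
`CtrM_i = (pA_i − pA_{i−1})² / (pA_i + pA_{i−1})²` (a squared *relative*
area change: symmetric, scale-invariant, zero for constant area, NaN at
the first frame rather than 0; also seen under the name CtraM). Frames
where the tracked label vanishes are flagged as gaps and bridged from the
last valid frame. Ruffling velocity is not a separate algorithm: the
motility descriptors run on perimeter-masked sub-series.

## Simulator

Cells are soft-edged ellipses (default radius 8 px, axis ratio 0.7) with
sinusoidal axis wobble (amplitude 0.1, period 10 frames), composited
additively over a static background, blurred with fuzziness sigma 2,
plus i.i.d. Gaussian noise (sigma 3, safely below θ_d = 10) and clipped.
The default background is a smooth blob texture (mean 100, sd 5, blob
scale 12 px): the descriptors consume *standardized* frames, and the
preprocessing chain (brightness centering, background flattening, mean
image subtraction) leaves only a few gray levels of background variation.
Default cell contrast is 35 gray levels — phase-contrast somata are
low-contrast after mean normalization.

Motion is a fixed-step persistent random walk: each frame every cell
advances exactly `speed` pixels along a heading incremented by a uniform
angle scaled by `1 − persistence` (default persistence 0.8; 0 is a fresh
uniform heading each frame). Steps fold back at frame borders; folding
preserves the step length but can shorten the center-to-center
displacement in the rare reflection frame, so ground-truth exactness
tests use interior configurations. Trajectories, background, noise and
cell shapes draw from separate child streams of the seed, so brightness
variants of a sweep share their motion realization bit-for-bit.

Calibration sweeps default to speeds 1..8 px/frame, 200 cells, 50 frames
per sweep at 640×480. The transfer function is an ordinary least-squares
line descriptor = a·speed + b (≥ 3 distinct speeds, positive slope
required); calibration inverts it and flags — never clips — values
outside the fitted speed range.

## Validation protocols and what they show

`protocols.py` reproduces the standard robustness experiments: descriptor
fold-change for a 100→500 cell-number increase at speed 4, fold-change
under post-hoc 50% intensity scaling of the identical rendered sequence,
R² of descriptor sweep-means against a 6-level per-cell brightness ladder
(levels 10–85 gray, chosen to span sub-threshold to clearly visible
contrast), the descriptor-vs-speed ladder, and held-out speed recovery
(fit on {1,2,3,4,6,7,8}, predict 5). The pytest suite runs quarter-area,
density-matched versions (320×240, 25→125 cells, 16–24 frames);
`scripts/acceptance.py` runs the full 640×480/50-frame protocol, 3 seed
replicates for fold-changes and 6 for the brightness ladder.

What passing these protocols does *not* show: the simulator renders
smooth ellipses without halos, internal organelle texture, mitosis,
cell–cell adhesion or genuine defocus optics, so robustness on synthetic
sweeps bounds — but does not guarantee — behavior on real recordings.

## Known limitations

* The COPRA-vs-speed response here is linear within noise over 1..8
  px/frame rather than visibly leveling off at high speed; the curvature
  depends on the cell appearance (edge fuzziness vs step length), which
  has no canonical value.
* Because brightness-ladder variants share the motion realization, sweep
  means carry essentially no replicate noise, and R² against brightness
  reflects any residual trend, however small. COPRAMove has by far the
  flattest brightness response (≈1.5× span across the ladder, vs ≈5.7×
  for DiffMove), yet its low-contrast transition still yields a high R²
  under this protocol.
* Pearson-based descriptors are undefined on constant frames (raised as
  errors); DiffMove is undefined on all-black first frames.
* Segmentation operators are tuned for bright-halo somata and dark
  neurites on mid-gray backgrounds; inverted-polarity imagery must be
  inverted first.
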