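# densemotion

Motility quantification for dense time-lapse cell cultures.

In dense cultures — hippocampal neuron/glia networks growing neurites,
pericyte monolayers ruffling their membranes, stained glia trafficking
organelles — single-cell tracking fails: cells touch, overlap and change
shape until any tracker loses its targets. `densemotion` takes the
alternative route: segment the structure class of interest (whole cells,
somata, neurites, plasma membranes) from low-magnification phase-contrast
imagery, then measure *global* motion of that class per pair of
successive frames with scalar descriptors, and calibrate descriptor units
to absolute speed (pixels/frame) on simulated cells of known velocity.

## Descriptors

For a standardized 8-bit frame pair (f₁, f₂):

* **DiffMove** = `Z / N_pixel · 10000`, where Z counts pixels whose
  brightness changed by more than a threshold (default 10) and N_pixel is
  the number of non-black pixels. Fast and precise when brightness, focus
  and cell number are constant.
* **P-move** = `(1 − r_P) · 100`, with r_P the Pearson correlation between
  the 3×3-mean-filtered frames. Brightness-invariant, focus-sensitive.
* **Ratio speed operator** `r_SO = √(r_F · 20 / img_size) · 10`, where r_F
  counts pixels whose Sobel-edge-image ratio between the frames deviates
  beyond a threshold (default 20). Saturates with speed and tracks focus —
  which makes it a focus *corrector* rather than a speed measure.
* **COPRAMove** = `(1 − r_P) · 100 / r_SO` — Pearson decorrelation with
  the ratio term as denominator. Both parts respond alike to focus drift,
  brightness and structure density, so the quotient cancels those
  nuisances. The most robust descriptor under variable conditions.

Membrane dynamics of segmented single cells are described by
**APr** = area/perimeter (boundary smoothness) and the contractility
**CtrM** = `(pAᵢ − pAᵢ₋₁)² / (pAᵢ + pAᵢ₋₁)²` with pA the cell area as a
percentage of its series maximum.

## Worked example

Simulate a sweep of 100 cells translocating at 4 pixels/frame, quantify
it, and recover the absolute speed through a calibration fitted on sweeps
of other speeds:

```python
import numpy as np
from densemotion import (SimConfig, simulate_sweep, compute_trace,
                         calibrate, apply_calibration)
from densemotion.protocols import speed_ladder_experiment

cfg = SimConfig(n_cells=100, speed=4.0, frames_per_sweep=30,
                frame_size=(320, 240), seed=42)
sweep = simulate_sweep(cfg)
trace = compute_trace(sweep.series, "copramove")
print(f"mean COPRAMove: {trace.mean():.3f} over {len(trace)} frame pairs")

base = SimConfig(n_cells=100, frames_per_sweep=30, frame_size=(320, 240), seed=0)
speeds = [1, 2, 3, 5, 6, 8]
means = speed_ladder_experiment(base, speeds)["copramove"]
model = calibrate(means, speeds)
print(f"transfer: descriptor = {model.slope:.3f} * speed + {model.intercept:.3f}"
      f"  (R2 = {model.r2:.3f})")
calibrated = apply_calibration(trace, model)
print(f"estimated speed: {np.mean(calibrated.values):.2f} pixels/frame (true 4.0)")
```

Output:

```
mean COPRAMove: 0.705 over 29 frame pairs
transfer: descriptor = 0.244 * speed + -0.215  (R2 = 0.996)
estimated speed: 3.77 pixels/frame (true 4.0)
```

The raw COPRAMove trace is in relative units; the linear transfer
function (R² ≈ 1 over the tested speed range) maps it to pixels/frame,
recovering the configured speed within ~6%.

A command-line interface wraps the same functionality:

```bash
densemotion simulate --speed 4 --n-cells 100 --out sweep/
densemotion motility sweep/sweep.tif --algo copramove --out trace.csv
densemotion calibrate --algo copramove --out model.json
densemotion run --config pipeline.yaml     # batch: prep -> segment -> quantify
```

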