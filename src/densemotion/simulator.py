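"""Synthetic moving-cell image generator with ground-truth trajectories.

The simulator is the calibration and benchmarking backbone of the package:
it renders sweeps (fixed-length image series, default 50 frames) of fuzzy
elliptical cells translocating over a static background at an exactly
controlled mean speed, so descriptor output can be mapped to absolute
pixels/frame and descriptor robustness can be probed by varying one
nuisance parameter at a time (global brightness, per-cell brightness,
cell number).

Motion model: every cell advances a fixed step of ``speed`` pixels each
frame along a heading that performs a persistent random walk (uniform
heading increments scaled by ``1 - heading_persistence``); steps fold back
at the frame borders.  The fixed-step construction makes the realized mean
step length equal the configured speed exactly (border folds can shorten
the *displacement* between stored centers in the rare reflection frames).

Appearance model: anti-aliased soft-edged ellipses composited additively
over the background, blurred by ``fuzziness`` (membrane optics), modulated
by a sinusoidal axis wobble (membrane movement), plus i.i.d. Gaussian
pixel noise, clipped to [0, 255].  The default background is a static
smooth blob texture emulating an out-of-focus culture field; a uniform
level or a user-supplied frame can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .frames import ImageSeries, as_frame, to_uint8

__all__ = [
    "SimConfig",
    "SimulationSweep",
    "textured_background",
    "simulate_sweep",
    "simulate_calibration_set",
    "vary_parameter",
    "overlay_red_green",
    "write_sweep",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults describe a dense hippocampal-culture-like field at 640x480:
    200 cells of ~8 px radius and modest (phase-contrast-like) 35-gray-level
    contrast over a textured background, 2 px edge fuzziness, noise sigma 3
    (safely below the DiffMove threshold of 10), sweeps of 50 frames.
    """

    n_cells: int = 200
    speed: float = 4.0
    cell_radius: float = 8.0
    axis_ratio: float = 0.7
    fuzziness: float = 2.0
    wobble_amplitude: float = 0.1
    wobble_period: float = 10.0
    cell_brightness: float = 35.0
    background: float | str | np.ndarray = "textured"
    background_sd: float = 5.0
    background_level: float = 100.0
    noise_sigma: float = 3.0
    frames_per_sweep: int = 50
    frame_size: tuple[int, int] = (640, 480)  # (width, height)
    heading_persistence: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.frames_per_sweep < 2:
            raise ValueError("frames_per_sweep must be >= 2")
        w, h = self.frame_size
        if 2 * self.cell_radius >= min(w, h):
            raise ValueError("cells larger than the frame")


@dataclass
class SimulationSweep:
    """Rendered series plus ground truth.

    ``trajectories`` has shape ``(n_frames, n_cells, 2)`` holding (x, y)
    cell centers; ``configured_speed`` is the fixed per-frame step length.
    """

    series: ImageSeries
    trajectories: np.ndarray
    configured_speed: float
    config: SimConfig

    def mean_step_length(self) -> float:
        steps = np.diff(self.trajectories, axis=0)
        return float(np.linalg.norm(steps, axis=-1).mean())


def textured_background(shape: tuple[int, int], rng: np.random.Generator,
                        level: float = 100.0, sd: float = 20.0,
                        blob_sigma: float = 12.0) -> np.ndarray:
    """Static smooth blob field: Gaussian noise low-passed at roughly the
    cell scale, normalized to the requested mean and standard deviation."""
    field_ = ndimage.gaussian_filter(rng.normal(size=shape), blob_sigma, mode="reflect")
    field_ = (field_ - field_.mean()) / max(field_.std(), 1e-12)
    return np.clip(level + sd * field_, 0.0, 255.0)


def _resolve_background(config: SimConfig, rng: np.random.Generator,
                        shape: tuple[int, int]) -> np.ndarray:
    bg = config.background
    if isinstance(bg, str):
        if bg != "textured":
            raise ValueError(f"unknown background spec {bg!r}")
        return textured_background(shape, rng, config.background_level, config.background_sd)
    if np.isscalar(bg):
        return np.full(shape, float(bg))
    return as_frame(bg).copy()


def _trajectories(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Fixed-step persistent random walk with border folding."""
    w, h = config.frame_size
    n, t = config.n_cells, config.frames_per_sweep
    margin = config.cell_radius
    pos = np.empty((t, n, 2))
    pos[0, :, 0] = rng.uniform(margin, w - 1 - margin, n)
    pos[0, :, 1] = rng.uniform(margin, h - 1 - margin, n)
    heading = rng.uniform(-np.pi, np.pi, n)
    jitter = (1.0 - config.heading_persistence) * np.pi
    for i in range(1, t):
        heading = heading + rng.uniform(-jitter, jitter, n)
        step = config.speed * np.stack([np.cos(heading), np.sin(heading)], axis=-1)
        nxt = pos[i - 1] + step
        # fold back at borders (reflection)
        for ax, limit in ((0, w - 1.0), (1, h - 1.0)):
            c = nxt[:, ax]
            c = np.abs(c)
            over = c > limit
            c[over] = 2 * limit - c[over]
            nxt[:, ax] = np.clip(c, 0.0, limit)
        pos[i] = nxt
    return pos


def _render_frame(bg: np.ndarray, centers: np.ndarray, axes: np.ndarray,
                  angles: np.ndarray, config: SimConfig,
                  noise: np.ndarray | None) -> np.ndarray:
    h, w = bg.shape
    layer = np.zeros_like(bg)
    for (cx, cy), (a, b), th in zip(centers, axes, angles):
        ext = max(a, b) + 2.0
        x0, x1 = int(max(0, np.floor(cx - ext))), int(min(w, np.ceil(cx + ext) + 1))
        y0, y1 = int(max(0, np.floor(cy - ext))), int(min(h, np.ceil(cy + ext) + 1))
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx, dy = xx - cx, yy - cy
        u = (dx * np.cos(th) + dy * np.sin(th)) / a
        v = (-dx * np.sin(th) + dy * np.cos(th)) / b
        q = u * u + v * v
        layer[y0:y1, x0:x1] += np.clip((1.0 - q) * 3.0, 0.0, 1.0)
    if config.fuzziness > 0:
        layer = ndimage.gaussian_filter(layer, config.fuzziness, mode="reflect")
    frame = bg + config.cell_brightness * layer
    if noise is not None:
        frame = frame + noise
    return np.clip(frame, 0.0, 255.0)


def simulate_sweep(config: SimConfig) -> SimulationSweep:
    """Render one sweep: all frames, one configured mean speed.

    Reproducible: the same config (including seed) yields a bit-identical
    series.  Trajectory, background and noise randomness come from
    separate child streams of the seed, so changing appearance parameters
    (e.g. cell brightness) leaves the motion realization untouched.
    """
    ss = np.random.SeedSequence(config.seed)
    traj_rng, bg_rng, noise_rng, shape_rng = (np.random.default_rng(c) for c in ss.spawn(4))
    w, h = config.frame_size
    bg = _resolve_background(config, bg_rng, (h, w))
    traj = _trajectories(config, traj_rng)
    angles = shape_rng.uniform(-np.pi, np.pi, config.n_cells)
    phases = shape_rng.uniform(0, 2 * np.pi, config.n_cells)

    frames = np.empty((config.frames_per_sweep, h, w))
    base_a = config.cell_radius
    base_b = config.cell_radius * config.axis_ratio
    for t in range(config.frames_per_sweep):
        mod = config.wobble_amplitude * np.sin(2 * np.pi * t / config.wobble_period + phases)
        axes = np.stack([base_a * (1 + mod), base_b * (1 - mod)], axis=-1)
        noise = (noise_rng.normal(0.0, config.noise_sigma, (h, w))
                 if config.noise_sigma > 0 else None)
        frames[t] = _render_frame(bg, traj[t], axes, angles, config, noise)
    return SimulationSweep(ImageSeries(frames), traj, config.speed, config)


def simulate_calibration_set(speeds=None, base: SimConfig = SimConfig()) -> list[SimulationSweep]:
    """One sweep per speed with everything else held fixed.

    Default speed ladder is 1..8 pixels/frame with 200 cells, matching the
    standard calibration protocol.  Speeds must be distinct (>= 3 of them);
    each sweep uses an independent motion realization (seed offset).
    """
    if speeds is None:
        speeds = list(range(1, 9))
    speeds = [float(s) for s in speeds]
    if len(set(speeds)) != len(speeds) or len(speeds) < 3:
        raise ValueError("need >= 3 distinct speeds")
    return [simulate_sweep(replace(base, speed=s, seed=base.seed + i))
            for i, s in enumerate(speeds)]


def vary_parameter(base: SimConfig, parameter: str, values) -> list[SimulationSweep]:
    """Sweeps differing only in one nuisance parameter.

    ``global_brightness``: the base sweep is rendered once and scaled
    pixelwise — identical motion, pure intensity change.
    ``cell_brightness``: same seed, hence identical trajectories and noise;
    only the rendered cell contrast differs.
    ``n_cells``: independent trajectories per value, identical speed.
    """
    if parameter == "global_brightness":
        ref = simulate_sweep(base)
        out = []
        for v in values:
            series = ImageSeries(np.clip(ref.series.data * float(v), 0.0, 255.0),
                                 ref.series.frame_interval)
            out.append(SimulationSweep(series, ref.trajectories, ref.configured_speed, base))
        return out
    if parameter == "cell_brightness":
        return [simulate_sweep(replace(base, cell_brightness=float(v))) for v in values]
    if parameter == "n_cells":
        return [simulate_sweep(replace(base, n_cells=int(v))) for v in values]
    raise ValueError(f"unsupported parameter {parameter!r}")


def overlay_red_green(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """Two-frame motion overlay: first frame red, second green, blue empty.

    Static structure renders yellow-gray; displaced structure shows a red
    crescent at the old position and a green one at the new.
    """
    f1, f2 = as_frame(f1), as_frame(f2)
    if f1.shape != f2.shape:
        raise ValueError("frames must share dimensions")
    rgb = np.zeros((*f1.shape, 3), dtype=np.uint8)
    rgb[..., 0] = to_uint8(f1)
    rgb[..., 1] = to_uint8(f2)
    return rgb


def write_sweep(sweep: SimulationSweep, directory) -> dict[str, Path]:
    """Write a sweep as TIFF stack + ground-truth trajectory CSV."""
    import pandas as pd

    from .imageprep import write_series

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = write_series(sweep.series, directory / "sweep.tif")
    t, n, _ = sweep.trajectories.shape
    df = pd.DataFrame({
        "frame": np.repeat(np.arange(t), n),
        "cell_id": np.tile(np.arange(n), t),
        "x": sweep.trajectories[:, :, 0].ravel(),
        "y": sweep.trajectories[:, :, 1].ravel(),
    })
    csv = directory / "trajectories.csv"
    df.to_csv(csv, index=False)
    return {"stack": stack, "trajectories": csv}
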