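"""Global motility descriptors for successive frame pairs.

Four descriptors summarize how much a scene moved between two frames:

* **DiffMove** — frame differencing.  ``Z`` pixels change brightness by
  more than a threshold (default 10, chosen so camera noise does not
  register); the descriptor is ``Z / N_pixel * 10000`` with ``N_pixel``
  the count of non-black pixels.  Fast and precise under constant imaging
  conditions, but sensitive to brightness, focus and structure density.
* **P-move** — plain Pearson decorrelation ``(1 - rP) * 100`` between
  3x3-mean-filtered frames.  Brightness-invariant but focus-sensitive.
* **ratio (rSO)** — Sobel-edge images of both frames are compared by a
  symmetric per-pixel ratio; pixels whose scaled ratio deviation exceeds a
  threshold are counted (``rF``) and condensed into the ratio speed
  operator ``rSO = sqrt(rF * 20 / img_size) * 10``.  Saturates for fast
  motion; tracks focus changes — which is exactly why it works as a
  corrector.
* **COPRAMove** — ``(1 - rP) * 100 / rSO``: Pearson decorrelation with the
  ratio term as denominator.  The two components respond similarly to
  focus drift and structure density, so their quotient cancels those
  nuisances, leaving translocation speed as the dominant signal.

Descriptor units are relative; absolute speed (pixels/frame) comes from a
linear transfer function fitted on simulated sweeps of known speed
(:func:`calibrate` / :func:`apply_calibration`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

from .errors import AllBlackFrameError, ConstantFrameError, DegenerateCalibrationError
from .frames import ImageSeries, as_frame

__all__ = [
    "MotilityParams",
    "FramePairStats",
    "MotilityTrace",
    "CalibrationModel",
    "ALGORITHMS",
    "pearson_rp",
    "ratio_factor",
    "ratio_speed_operator",
    "diffmove",
    "copramove",
    "copramove_from_stats",
    "pmove",
    "frame_pair_stats",
    "compute_trace",
    "calibrate",
    "apply_calibration",
]


@dataclass(frozen=True)
class MotilityParams:
    """Tunable descriptor parameters.

    ``diff_threshold`` is the brightness change a pixel must exceed to
    count as moved (default 10 in all experiment series).
    ``ratio_threshold`` gates the scaled edge-ratio deviation; low values
    (<10) include small changes, high values (>30) emphasize fast objects.
    ``mean_filter`` toggles the 3x3 noise-reduction prefilter for the
    Pearson step.
    """

    diff_threshold: float = 10.0
    ratio_threshold: float = 20.0
    mean_filter: bool = True

    def __post_init__(self) -> None:
        if self.diff_threshold < 0 or self.ratio_threshold < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class FramePairStats:
    """All intermediate quantities for one frame pair."""

    rP: float
    rF: int
    rSO: float
    Z: int
    N_pixel: int
    img_size: int


@dataclass
class MotilityTrace:
    """Descriptor values for every consecutive frame pair of a series."""

    values: np.ndarray
    algorithm: str
    params: MotilityParams
    calibrated: bool = False
    units: str = "descriptor"
    model: "CalibrationModel | None" = None
    out_of_range: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def __len__(self) -> int:
        return self.values.size

    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class CalibrationModel:
    """Linear transfer function ``descriptor = slope * speed + intercept``."""

    slope: float
    intercept: float
    r2: float
    speed_range: tuple[float, float]

    def predict_descriptor(self, speed):
        return self.slope * np.asarray(speed, dtype=float) + self.intercept

    def to_speed(self, descriptor):
        return (np.asarray(descriptor, dtype=float) - self.intercept) / self.slope

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "slope": self.slope, "intercept": self.intercept,
            "r2": self.r2, "speed_range": list(self.speed_range),
        }, indent=2))
        return path

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(d["slope"], d["intercept"], d["r2"], tuple(d["speed_range"]))


def _mean3(frame: np.ndarray) -> np.ndarray:
    return ndimage.uniform_filter(frame, 3, mode="reflect")


def pearson_rp(f1: np.ndarray, f2: np.ndarray, mean_filter: bool = True) -> float:
    """Pearson correlation coefficient between two frames.

    Frames are optionally 3x3 mean-filtered first.  A constant frame makes
    the correlation undefined and raises :class:`ConstantFrameError` —
    deliberately distinct from rP = 0, which would fake "no motion".
    """
    f1, f2 = as_frame(f1), as_frame(f2)
    if f1.shape != f2.shape:
        raise ValueError("frames must share dimensions")
    if mean_filter:
        f1, f2 = _mean3(f1), _mean3(f2)
    if f1.std() == 0.0 or f2.std() == 0.0:
        raise ConstantFrameError("Pearson correlation undefined for a constant frame")
    return float(np.corrcoef(f1.ravel(), f2.ravel())[0, 1])


def _sobel_mag(frame: np.ndarray) -> np.ndarray:
    gx = ndimage.sobel(frame, axis=1, mode="reflect")
    gy = ndimage.sobel(frame, axis=0, mode="reflect")
    return np.hypot(gx, gy)


#: Sobel magnitudes below this count as flat background in the ratio step.
#: 30 is the response to roughly a 5-gray-level step — the scale of sensor
#: noise — so the ratio focuses on genuinely contrasted structure instead
#: of exploding on near-zero edge pairs.
EDGE_FLOOR = 30.0


def ratio_factor(f1: np.ndarray, f2: np.ndarray, ratio_threshold: float = 20.0,
                 edge_floor: float = EDGE_FLOOR) -> int:
    """Count of pixels whose edge-image ratio deviates beyond a threshold.

    Both frames pass a Sobel edge filter; per pixel the symmetric ratio
    ``r = (max(e1, e2) + 1) / (min(e1, e2) + 1)`` is scaled onto a
    brightness-like 8-bit axis, ``d = min(255, (r - 1) * 255)``, and pixels
    with ``d > ratio_threshold`` increment the ratio factor rF.  Identical
    frames give r = 1 everywhere, hence rF = 0.  Pixels where both edge
    responses fall below ``edge_floor`` are flat background and never
    count: the ratio of two noise-level edges is meaningless, and the
    method deliberately focuses on highly contrasted moving structure.
    """
    f1, f2 = as_frame(f1), as_frame(f2)
    if f1.shape != f2.shape:
        raise ValueError("frames must share dimensions")
    e1, e2 = _sobel_mag(f1), _sobel_mag(f2)
    hi = np.maximum(e1, e2) + 1.0
    lo = np.minimum(e1, e2) + 1.0
    d = np.minimum(255.0, (hi / lo - 1.0) * 255.0)
    d[np.maximum(e1, e2) < edge_floor] = 0.0
    return int(np.count_nonzero(d > ratio_threshold))


def ratio_speed_operator(rF: int, img_size: int) -> float:
    """``rSO = sqrt((1 / img_size) * rF * 20) * 10``."""
    if img_size <= 0:
        raise ValueError("img_size must be positive")
    return float(np.sqrt(rF * 20.0 / img_size) * 10.0)


def diffmove(f1: np.ndarray, f2: np.ndarray,
             params: MotilityParams = MotilityParams()) -> float:
    """Difference descriptor ``Z / N_pixel * 10000``.

    ``Z`` counts pixels whose absolute brightness change strictly exceeds
    ``params.diff_threshold``; ``N_pixel`` counts non-black (> 0) pixels of
    the first frame.  Symmetric in its arguments up to the N_pixel
    convention.
    """
    f1, f2 = as_frame(f1), as_frame(f2)
    if f1.shape != f2.shape:
        raise ValueError("frames must share dimensions")
    n_pixel = int(np.count_nonzero(f1 > 0))
    if n_pixel == 0:
        raise AllBlackFrameError("DiffMove undefined on an all-black frame")
    z = int(np.count_nonzero(np.abs(f1 - f2) > params.diff_threshold))
    return z / n_pixel * 10000.0


def copramove_from_stats(rP: float, rSO: float) -> float:
    """``(1 - rP) * 100 / rSO``; defined as 0 when rSO = 0 (no detected
    edge change means a static scene)."""
    if rSO == 0.0:
        return 0.0
    return (1.0 - rP) * 100.0 / rSO


def copramove(f1: np.ndarray, f2: np.ndarray,
              params: MotilityParams = MotilityParams()) -> float:
    """Combined Pearson + ratio descriptor (see module docstring)."""
    rp = pearson_rp(f1, f2, params.mean_filter)
    rf = ratio_factor(f1, f2, params.ratio_threshold)
    rso = ratio_speed_operator(rf, f1.size)
    return copramove_from_stats(rp, rso)


def pmove(f1: np.ndarray, f2: np.ndarray,
          params: MotilityParams = MotilityParams()) -> float:
    """Plain Pearson descriptor ``(1 - rP) * 100`` (no ratio correction)."""
    return (1.0 - pearson_rp(f1, f2, params.mean_filter)) * 100.0


def _rso_descriptor(f1, f2, params: MotilityParams) -> float:
    return ratio_speed_operator(ratio_factor(f1, f2, params.ratio_threshold),
                                as_frame(f1).size)


ALGORITHMS = {
    "diffmove": diffmove,
    "copramove": copramove,
    "pmove": pmove,
    "ratio": _rso_descriptor,
}


def frame_pair_stats(f1: np.ndarray, f2: np.ndarray,
                     params: MotilityParams = MotilityParams()) -> FramePairStats:
    """All intermediate descriptor quantities for one frame pair."""
    f1, f2 = as_frame(f1), as_frame(f2)
    rp = pearson_rp(f1, f2, params.mean_filter)
    rf = ratio_factor(f1, f2, params.ratio_threshold)
    z = int(np.count_nonzero(np.abs(f1 - f2) > params.diff_threshold))
    return FramePairStats(
        rP=rp, rF=rf, rSO=ratio_speed_operator(rf, f1.size),
        Z=z, N_pixel=int(np.count_nonzero(f1 > 0)), img_size=f1.size,
    )


def compute_trace(series: ImageSeries, algorithm: str,
                  params: MotilityParams = MotilityParams()) -> MotilityTrace:
    """Descriptor trace over all consecutive frame pairs of a series."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}")
    if len(series) < 2:
        raise ValueError("a trace needs at least 2 frames")
    fn = ALGORITHMS[algorithm]
    vals = [fn(series[i], series[i + 1], params) for i in range(len(series) - 1)]
    return MotilityTrace(np.array(vals), algorithm, params)


def calibrate(descriptor_means, speeds) -> CalibrationModel:
    """Fit the linear transfer function descriptor = a*speed + b.

    Requires at least 3 distinct speeds and a positive slope (descriptors
    must increase with speed over the validated range).  Input order is
    irrelevant.
    """
    d = np.asarray(descriptor_means, dtype=float)
    v = np.asarray(speeds, dtype=float)
    if d.shape != v.shape or d.ndim != 1:
        raise ValueError("descriptor_means and speeds must be equal-length 1-D")
    if np.unique(v).size < 3:
        raise DegenerateCalibrationError("calibration needs >= 3 distinct speeds")
    res = stats.linregress(v, d)
    if res.slope <= 0:
        raise DegenerateCalibrationError(f"non-positive transfer slope {res.slope:.4g}")
    return CalibrationModel(float(res.slope), float(res.intercept),
                            float(res.rvalue**2), (float(v.min()), float(v.max())))


def apply_calibration(trace: MotilityTrace, model: CalibrationModel) -> MotilityTrace:
    """Map a raw trace to absolute speeds [pixels/frame] via the inverse
    transfer function.  Values outside the validated speed range are
    flagged (``out_of_range``), never clipped."""
    if trace.calibrated:
        raise ValueError("trace is already calibrated")
    if abs(model.slope) < 1e-12:
        raise DegenerateCalibrationError("transfer slope is ~0; cannot invert")
    speeds = model.to_speed(trace.values)
    lo, hi = model.speed_range
    flags = (speeds < lo) | (speeds > hi)
    return MotilityTrace(speeds, trace.algorithm, trace.params, calibrated=True,
                         units="pixels/frame", model=model, out_of_range=flags)
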