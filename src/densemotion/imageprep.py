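"""Series loading, standardization and preprocessing operators.

All operators consume and produce 2-D float frames in [0, 255] and leave
dimensions unchanged unless resizing is explicitly requested.  The focus
metric quantifies sharpness as ``F = ln(sd^2) - 1`` where ``sd`` is the
standard deviation of the Laplacian-filtered frame; in practice F spans
roughly -1 (uniformly blurred) to about 8 (hard binary edges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .errors import (
    EmptySeriesError,
    MixedDimensionsError,
    SeriesNotFoundError,
    UnreadableImageError,
)
from .frames import ImageSeries, as_frame, natural_key, to_uint8

__all__ = [
    "FocusScore",
    "read_series",
    "write_series",
    "standardize",
    "center_bright",
    "flatten_background",
    "sharpen_unsharp",
    "remove_debris",
    "subtract_mean_background",
    "focus_score",
    "focus_trace",
    "drop_low_focus",
    "level_diffraction_light",
    "phase_contrast_correct",
    "LAPLACIAN_KERNEL",
]

log = logging.getLogger(__name__)

#: canonical 4-neighbor discrete Laplacian
LAPLACIAN_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)

#: sentinel focus value for zero-variance (constant) frames; below the
#: practical floor of ~-1 so constant frames always sort as worst focus.
FOCUS_SENTINEL = -10.0

_LUMA = np.array([0.2126, 0.7152, 0.0722])

_IMAGE_EXTS = (".tif", ".tiff", ".png", ".bmp", ".jpg", ".jpeg")


@dataclass(frozen=True)
class FocusScore:
    """Sharpness of one frame: ``F = ln(sd**2) - 1`` for ``sd > 0``."""

    F: float
    sd: float


def _to_gray8(img: np.ndarray) -> np.ndarray:
    """Collapse color to luminance and rescale the dtype range to [0, 255]."""
    a = np.asarray(img)
    if a.ndim == 3:
        if a.shape[2] == 4:
            a = a[..., :3]
        a = a.astype(np.float64) @ _LUMA
    a = a.astype(np.float64)
    if img.dtype == np.uint16:
        a = a / 257.0
    elif np.issubdtype(np.asarray(img).dtype, np.floating) and a.max() <= 1.0:
        a = a * 255.0
    return np.clip(a, 0.0, 255.0)


def read_series(path_or_pattern, frame_interval: float | None = None) -> ImageSeries:
    """Load an image series from a TIFF stack, a directory, or a glob.

    Frames are ordered by natural (numeric-aware) filename sort, converted
    to grayscale by luminance, and rescaled to the 8-bit range.

    Raises
    ------
    SeriesNotFoundError
        Path or pattern resolves to no readable image file.
    MixedDimensionsError
        Frames do not share a single size.
    UnreadableImageError
        A file exists but cannot be decoded.
    """
    p = Path(path_or_pattern)
    files: list[Path]
    if p.is_dir():
        files = sorted(
            (f for f in p.iterdir() if f.suffix.lower() in _IMAGE_EXTS),
            key=lambda f: natural_key(f.name),
        )
    elif p.is_file():
        files = [p]
    else:
        parent, pattern = p.parent, p.name
        files = sorted(parent.glob(pattern), key=lambda f: natural_key(f.name))
    if not files:
        raise SeriesNotFoundError(f"no image files found at {path_or_pattern!r}")

    frames: list[np.ndarray] = []
    for f in files:
        try:
            if f.suffix.lower() in (".tif", ".tiff"):
                arr = tifffile.imread(f)
            else:
                arr = iio.imread(f)
        except Exception as exc:  # noqa: BLE001 - decoding failures vary by backend
            raise UnreadableImageError(f"cannot read image {f}: {exc}") from exc
        if arr.ndim == 3 and f.suffix.lower() in (".tif", ".tiff") and arr.shape[-1] not in (3, 4):
            # multi-page stack
            frames.extend(_to_gray8(page) for page in arr)
        else:
            frames.append(_to_gray8(arr))
    return ImageSeries.from_frames(frames, frame_interval)


def write_series(series: ImageSeries, path) -> Path:
    """Write a series as an 8-bit multi-page TIFF stack."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.stack([to_uint8(f) for f in series]),
                     photometric="minisblack")
    return path


def standardize(frame: np.ndarray, target_w: int = 640, target_h: int = 480) -> np.ndarray:
    """Resize a frame to the standard analysis size (default 640x480)."""
    frame = as_frame(frame)
    if target_w <= 0 or target_h <= 0:
        raise ValueError("target dimensions must be positive")
    if frame.shape == (target_h, target_w):
        return frame.copy()
    out = _sk_resize(frame, (target_h, target_w), order=1, anti_aliasing=True,
                     preserve_range=True)
    return np.clip(out, 0.0, 255.0)


def center_bright(frame: np.ndarray, target_mean: float = 127.0) -> np.ndarray:
    """Shift the brightness histogram so the frame mean sits at ``target_mean``.

    Implemented as an additive offset followed by clipping — the simplest
    mean-preserving normalization; clipping at 0/255 may leave the final
    mean within ±1 of the target rather than exact.
    """
    frame = as_frame(frame)
    return np.clip(frame + (target_mean - frame.mean()), 0.0, 255.0)


def flatten_background(frame: np.ndarray, blur_sigma: float | None = None,
                       target_mean: float = 127.0) -> np.ndarray:
    """Remove large-scale illumination gradients.

    Subtracts a heavily blurred copy of the frame (a proxy for the
    illumination field) and re-centers on ``target_mean``.  The default
    ``blur_sigma`` of width/8 is much larger than any cell, so cellular
    structure survives while slow gradients are equalized.
    """
    frame = as_frame(frame)
    if blur_sigma is None:
        blur_sigma = frame.shape[1] / 8.0
    if blur_sigma <= 0:
        raise ValueError("blur_sigma must be positive")
    bg = ndimage.gaussian_filter(frame, blur_sigma, mode="reflect")
    return np.clip(frame - bg + target_mean, 0.0, 255.0)


def sharpen_unsharp(frame: np.ndarray, radius: float = 2.0, amount: float = 1.0) -> np.ndarray:
    """Unsharp masking: amplify what a Gaussian blur of ``radius`` removes."""
    frame = as_frame(frame)
    if radius <= 0:
        raise ValueError("radius must be positive")
    if amount < 0:
        raise ValueError("amount must be non-negative")
    if amount == 0:
        return frame.copy()
    blur = ndimage.gaussian_filter(frame, radius, mode="reflect")
    return np.clip(frame + amount * (frame - blur), 0.0, 255.0)


def _local_background(frame: np.ndarray, exclude: np.ndarray, sigma: float) -> np.ndarray:
    """Blurred background estimate ignoring ``exclude`` pixels.

    Normalized convolution: blur the frame with excluded pixels zeroed and
    divide by the blurred validity mask, so filled values match the mean
    brightness of their (valid) neighborhood.
    """
    valid = (~exclude).astype(np.float64)
    num = ndimage.gaussian_filter(frame * valid, sigma, mode="reflect")
    den = ndimage.gaussian_filter(valid, sigma, mode="reflect")
    return num / np.maximum(den, 1e-9)


def remove_debris(frame: np.ndarray, max_size: int = 30,
                  contrast_thresh: float = 3.0, window: int = 15,
                  fill_sigma: float = 6.0) -> np.ndarray:
    """Erase small high-contrast particles.

    Particles are pixels whose local z-score (over a ``window``-sized
    neighborhood) exceeds ``contrast_thresh``, grouped into 8-connected
    components no larger than ``max_size`` px².  Their positions are filled
    with a heavily blurred local background so the patch blends into the
    neighborhood brightness.  Larger components are assumed to be cells and
    kept.
    """
    frame = as_frame(frame)
    if max_size <= 0:
        raise ValueError("max_size must be positive")
    mean = ndimage.uniform_filter(frame, window, mode="reflect")
    sq = ndimage.uniform_filter(frame * frame, window, mode="reflect")
    sd = np.sqrt(np.maximum(sq - mean * mean, 0.0))
    z = (frame - mean) / np.maximum(sd, 1e-9)
    candidate = np.abs(z) > contrast_thresh
    labels, n = ndimage.label(candidate, structure=np.ones((3, 3)))
    if n == 0:
        return frame.copy()
    sizes = ndimage.sum_labels(np.ones_like(frame), labels, index=np.arange(1, n + 1))
    small_ids = np.flatnonzero(sizes <= max_size) + 1
    if small_ids.size == 0:
        return frame.copy()
    speck = np.isin(labels, small_ids)
    speck = ndimage.binary_dilation(speck, structure=np.ones((3, 3)))
    bg = _local_background(frame, speck, fill_sigma)
    out = frame.copy()
    out[speck] = bg[speck]
    return np.clip(out, 0.0, 255.0)


def subtract_mean_background(series: ImageSeries, target_mean: float = 127.0) -> ImageSeries:
    """Remove stationary structures by subtracting a brightness-scaled mean image.

    The mean image is composed of all frames; per frame it is scaled so its
    mean matches that frame's mean before subtraction, which makes perfectly
    static structures vanish into a uniform field at ``target_mean``.
    """
    if len(series) < 2:
        raise EmptySeriesError("background subtraction needs at least 2 frames")
    mean_img = series.data.mean(axis=0)
    mean_level = mean_img.mean()
    out = []
    for f in series:
        s = f.mean() / mean_level if mean_level > 0 else 1.0
        out.append(np.clip(f - s * mean_img + target_mean, 0.0, 255.0))
    return ImageSeries(np.stack(out), series.frame_interval)


def focus_score(frame: np.ndarray) -> FocusScore:
    """Sharpness of a frame from its Laplacian response.

    ``F = ln(sd^2) - 1`` with ``sd`` the standard deviation of the
    4-neighbor Laplacian of the frame.  A constant frame (sd = 0) returns
    the finite sentinel ``FOCUS_SENTINEL`` instead of -inf so focus traces
    stay numeric.
    """
    frame = as_frame(frame)
    lap = ndimage.convolve(frame, LAPLACIAN_KERNEL, mode="reflect")
    sd = float(lap.std())
    if sd == 0.0:
        return FocusScore(FOCUS_SENTINEL, 0.0)
    return FocusScore(float(np.log(sd**2) - 1.0), sd)


def focus_trace(series: ImageSeries) -> np.ndarray:
    """F value of every frame in a series."""
    return np.array([focus_score(f).F for f in series])


def drop_low_focus(series: ImageSeries, threshold: float) -> ImageSeries:
    """Drop frames whose focus F falls below ``threshold`` (order preserved)."""
    fs = focus_trace(series)
    keep = fs >= threshold
    dropped = np.flatnonzero(~keep)
    if dropped.size:
        log.info("drop_low_focus: removed frames %s (F < %.3f)", dropped.tolist(), threshold)
    if not keep.any():
        raise EmptySeriesError(f"all {len(series)} frames fall below focus threshold {threshold}")
    return ImageSeries(series.data[keep], series.frame_interval)


def level_diffraction_light(frame: np.ndarray, bright_fraction: float = 0.05,
                            lowpass_sigma: float = 3.0) -> np.ndarray:
    """Suppress bright diffraction halos around loosely attached somata.

    Three steps: (a) the brightest ``bright_fraction`` of pixels are
    low-pass filtered, halved and subtracted from the original; (b) the
    original is re-weighted by the reciprocal of its normalized intensity
    histogram, ``i -> i / (H(i)*255 + 1)``, which compresses rare bright
    values; (c) the two results are merged pixelwise (mean) and inverted.
    The halo peak ends up strictly attenuated relative to the soma interior.
    """
    frame = as_frame(frame)
    thr = np.quantile(frame, 1.0 - bright_fraction)
    bright = np.where(frame >= thr, frame, 0.0)
    lp = ndimage.gaussian_filter(bright, lowpass_sigma, mode="reflect")
    b_img = frame - 0.5 * lp

    idx = np.clip(np.rint(frame), 0, 255).astype(np.intp)
    hist = np.bincount(idx.ravel(), minlength=256).astype(np.float64)
    hist /= idx.size  # normalized to total 1
    c_img = frame / (hist[idx] * 255.0 + 1.0)

    merged = np.clip(0.5 * (b_img + c_img), 0.0, 255.0)
    return 255.0 - merged


def phase_contrast_correct(frame: np.ndarray, relief_weight: float = 0.5,
                           target_mean: float = 127.0) -> np.ndarray:
    """Pseudo-DIC rendering: inversion plus a shaded (relief) contrast term.

    The relief term is a diagonal first difference of the original image,
    giving the opposing light/dark edge flanks characteristic of DIC optics.
    The output is recentered to ``target_mean``.  The operation is not an
    involution: applying it twice does not return the original image.
    """
    frame = as_frame(frame)
    kernel = np.array([[1.0, 0.0], [0.0, -1.0]])
    relief = ndimage.convolve(frame, kernel, mode="reflect")
    out = (255.0 - frame) + relief_weight * relief
    out = out + (target_mean - out.mean())
    return np.clip(out, 0.0, 255.0)
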