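"""Structure extraction: whole cells, somata, neurites, perimeters, ROIs.

The algorithms target low-magnification phase-contrast imagery, where
loosely attached somata carry bright diffraction halos, neurites appear as
thin dark filaments, and flat glia blend into the background.  Each
algorithm exploits one of those cues:

* ``scd_segment`` — histogram statistics: pixel populations (brightness
  bins) more frequent than a user threshold, size-gated and de-spiked.
* ``icb_segment`` — contrast at cell borders, closed and hole-filled into
  solid per-cell masks.
* ``extract_bright_objects`` / ``neuronal_somata_detect`` — halo-driven
  soma detectors (local percentile peaks, respectively local contrast).
* ``remove_cell_somata`` / ``neurite_skeletonize`` — neurite isolation by
  excising somata, respectively skeletonizing dark elongated structures.

Masks are :class:`SegmentationMask` objects: a non-negative integer label
grid (0 = background, labels contiguous ``1..K``) with a ``kind`` tag.
8-connectivity is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import rank

from .errors import ROIOutsideFrameError
from .frames import ImageSeries, as_frame, to_uint8
from .imageprep import _local_background

__all__ = [
    "SegmentationMask",
    "CellROI",
    "scd_segment",
    "icb_segment",
    "extract_bright_objects",
    "neuronal_somata_detect",
    "remove_cell_somata",
    "neurite_skeletonize",
    "perimeter_mask",
    "cut_cell_rois",
    "suggest_rois",
    "overlay_masks",
]

_S8 = np.ones((3, 3), dtype=bool)  # 8-connected structuring element


@dataclass
class SegmentationMask:
    """Label grid aligned to a source frame.

    ``labels`` holds contiguous integer ids ``1..K`` (0 = background);
    ``kind`` is one of {"cells", "somata", "neurites", "skeleton",
    "perimeter"}.
    """

    labels: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise ValueError("mask labels must be 2-D")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def binary(self) -> np.ndarray:
        return self.labels > 0

    def render(self, frame: np.ndarray, background: float = 0.0) -> np.ndarray:
        """Grayscale rendering: original intensities inside the mask, plain
        background elsewhere."""
        frame = as_frame(frame)
        return np.where(self.binary, frame, background)


@dataclass(frozen=True)
class CellROI:
    """Circular region of interest placed spaciously around one cell."""

    id: int
    center: tuple[float, float]  # (x, y) in pixels
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")


def _labeled(binary: np.ndarray, kind: str) -> SegmentationMask:
    labels, _ = ndimage.label(binary, structure=_S8)
    return SegmentationMask(labels, kind)


def _drop_small(binary: np.ndarray, min_size: int) -> np.ndarray:
    if min_size <= 1:
        return binary
    labels, n = ndimage.label(binary, structure=_S8)
    if n == 0:
        return binary
    sizes = ndimage.sum_labels(np.ones(binary.shape), labels, np.arange(1, n + 1))
    out = binary.copy()
    out[np.isin(labels, np.flatnonzero(sizes < min_size) + 1)] = False
    return out


def scd_segment(frame: np.ndarray, freq_threshold: float = 0.01,
                min_size: int = 50, spike_radius: int = 2) -> SegmentationMask:
    """Statistical cell detection from brightness-histogram frequency.

    Pixels whose 8-bit intensity bin holds more than ``freq_threshold``
    (fraction of all pixels) are selected, adjacent selected pixels are
    connected, components smaller than ``min_size`` px² are dropped and
    spiky appendages removed by a binary opening of radius
    ``spike_radius``.  On a constant frame the single populated bin selects
    everything — the degenerate histogram is handled, not rejected.
    """
    frame = as_frame(frame)
    if not 0.0 < freq_threshold < 1.0:
        raise ValueError("freq_threshold must lie in (0, 1)")
    idx = np.clip(np.rint(frame), 0, 255).astype(np.intp)
    hist = np.bincount(idx.ravel(), minlength=256).astype(np.float64) / idx.size
    selected = hist[idx] > freq_threshold
    selected = _drop_small(selected, min_size)
    if spike_radius > 0:
        selected = morphology.opening(selected, morphology.disk(spike_radius))
    return _labeled(selected, "cells")


def icb_segment(frame: np.ndarray, edge_thresh: float = 20.0,
                size_range: tuple[int, int] = (100, 50_000),
                close_radius: int = 3) -> SegmentationMask:
    """Isolate cells from background via border contrast.

    Gradient-magnitude pixels above ``edge_thresh`` are border candidates;
    borders are morphologically closed (completion fill of small gaps) and
    every enclosed interior filled, yielding one homogeneous mask per cell.
    Components outside ``size_range`` px² are discarded.
    """
    frame = as_frame(frame)
    lo, hi = size_range
    if lo < 0 or hi <= lo:
        raise ValueError("size_range must be (min, max) with 0 <= min < max")
    gx = ndimage.sobel(frame, axis=1, mode="reflect")
    gy = ndimage.sobel(frame, axis=0, mode="reflect")
    borders = np.hypot(gx, gy) > edge_thresh
    if close_radius > 0:
        borders = morphology.closing(borders, morphology.disk(close_radius))
    filled = ndimage.binary_fill_holes(borders)
    labels, n = ndimage.label(filled, structure=_S8)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(frame), labels, np.arange(1, n + 1))
        bad = (sizes < lo) | (sizes > hi)
        filled[np.isin(labels, np.flatnonzero(bad) + 1)] = False
    return _labeled(filled, "cells")


def extract_bright_objects(frame: np.ndarray, percentile: float = 80.0,
                           window: int = 31, min_size: int = 50,
                           offset: float = 2.0) -> SegmentationMask:
    """Halo-driven soma detection from local brightness peaks.

    A pixel is a peak when it exceeds the local ``percentile`` threshold
    (computed in a sliding ``window``) by more than ``offset`` gray levels.
    Peaks are connected, holes inside cell bodies filled, and small debris
    components removed.  Brightness polarity matters: dark objects on a
    bright field yield nothing.  Neighboring halo-disks closer than the
    window may merge into one label (cluster rather than single-cell
    detection).
    """
    frame = as_frame(frame)
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (0, 100)")
    if window % 2 == 0:
        window += 1
    fp = np.ones((window, window), dtype=bool)
    local = rank.percentile(to_uint8(frame), footprint=fp, p0=percentile / 100.0)
    peaks = frame > local.astype(np.float64) + offset
    peaks = morphology.closing(peaks, morphology.disk(1))
    peaks = ndimage.binary_fill_holes(peaks)
    peaks = _drop_small(peaks, min_size)
    # polarity gate: keep only components brighter than the global mean
    labels, n = ndimage.label(peaks, structure=_S8)
    if n:
        means = ndimage.mean(frame, labels, np.arange(1, n + 1))
        peaks[np.isin(labels, np.flatnonzero(means <= frame.mean()) + 1)] = False
    return _labeled(peaks, "somata")


def neuronal_somata_detect(frame: np.ndarray, contrast_window: int = 15,
                           debris_max: int = 30, halo_sigma: float = 5.0,
                           bright_offset: float = 5.0,
                           ) -> tuple[SegmentationMask, np.ndarray]:
    """Soma detection from high local contrast around diffraction halos.

    Candidate pixels combine high local contrast with brightness clearly
    above the frame mean (halos are distinctly bright; ``bright_offset``
    keeps pixels merely adjacent to dark neurites out).  Returns
    ``(mask, corrected)`` where ``mask`` marks halo regions (small debris
    components below ``debris_max`` px² removed) and ``corrected`` is the
    input with halos attenuated by subtracting a blurred image of those
    regions, then brightness-recorrected to the input mean.
    """
    frame = as_frame(frame)
    mean = ndimage.uniform_filter(frame, contrast_window, mode="reflect")
    sq = ndimage.uniform_filter(frame * frame, contrast_window, mode="reflect")
    lstd = np.sqrt(np.maximum(sq - mean * mean, 0.0))
    thr = lstd.mean() + 2.0 * lstd.std()
    halo = (lstd > thr) & (frame > frame.mean() + bright_offset)
    halo = morphology.closing(halo, morphology.disk(2))
    halo = ndimage.binary_fill_holes(halo)
    halo = _drop_small(halo, max(debris_max, 1))
    mask = _labeled(halo, "somata")

    region = ndimage.binary_dilation(halo, structure=_S8, iterations=2)
    halo_img = ndimage.gaussian_filter(np.where(region, frame, 0.0), halo_sigma)
    corrected = frame - 0.5 * halo_img
    corrected = corrected + (frame.mean() - corrected.mean())
    return mask, np.clip(corrected, 0.0, 255.0)


def remove_cell_somata(frame: np.ndarray, soma_mask: SegmentationMask | None = None,
                       margin: int = 2, fill_sigma: float = 8.0) -> np.ndarray:
    """Excise somata, leaving neurites and background untouched.

    Soma regions (from ``soma_mask`` or, when omitted, an internal
    ``extract_bright_objects`` pass) are filled with a blurred local
    background estimate and smoothed to blend into the surroundings.
    Pixels outside a ``margin``-px band around the somata are numerically
    unchanged.
    """
    frame = as_frame(frame)
    if soma_mask is None:
        soma_mask = extract_bright_objects(frame)
    if soma_mask.labels.shape != frame.shape:
        raise ValueError("soma mask dimensions do not match the frame")
    region = soma_mask.binary
    if not region.any():
        return frame.copy()
    region = ndimage.binary_dilation(region, structure=_S8, iterations=margin)
    bg = _local_background(frame, region, fill_sigma)
    out = frame.copy()
    out[region] = ndimage.gaussian_filter(bg, 2.0, mode="reflect")[region]
    return np.clip(out, 0.0, 255.0)


def neurite_skeletonize(frame: np.ndarray, local_thresh_window: int = 25,
                        min_len: int = 10, max_width: float = 6.0,
                        darkness_offset: float = 5.0) -> SegmentationMask:
    """Binary skeleton of dark elongated structures (neurites).

    Candidate pixels sit below their local-mean threshold by more than
    ``darkness_offset``.  Each candidate component is skeletonized;
    components whose skeleton is shorter than ``min_len``, wider on average
    than ``max_width`` (area / skeleton length) or insufficiently elongated
    (length / width < 3, the blob gate) are discarded.
    """
    frame = as_frame(frame)
    if local_thresh_window % 2 == 0:
        local_thresh_window += 1
    local_mean = ndimage.uniform_filter(frame, local_thresh_window, mode="reflect")
    dark = frame < local_mean - darkness_offset
    labels, n = ndimage.label(dark, structure=_S8)
    skeleton = np.zeros(frame.shape, dtype=bool)
    for i in range(1, n + 1):
        comp = labels == i
        skel = morphology.skeletonize(comp)
        length = int(skel.sum())
        if length < min_len:
            continue
        width = comp.sum() / max(length, 1)
        if width > max_width or length / max(width, 1e-9) < 3.0:
            continue
        skeleton |= skel
    return _labeled(skeleton, "skeleton")


def perimeter_mask(mask: SegmentationMask, line_width: int = 1) -> SegmentationMask:
    """Boundary line mask of each labeled cell (plasma-membrane proxy).

    The boundary of each label (pixels not surviving erosion) is dilated to
    ``line_width`` total thickness; labels are carried over.
    """
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    out = np.zeros_like(mask.labels)
    cross = ndimage.generate_binary_structure(2, 1)  # thin 8-connected contour
    for i in range(1, mask.n_labels + 1):
        region = mask.labels == i
        inner = ndimage.binary_erosion(region, structure=cross, border_value=0)
        bound = region & ~inner
        extra = (line_width - 1) // 2 + (line_width - 1) % 2
        if extra > 0:
            bound = ndimage.binary_dilation(bound, morphology.disk(extra))
        out[bound] = i
    return SegmentationMask(out, "perimeter")


def _circle(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    cx, cy = center
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def cut_cell_rois(series: ImageSeries, rois: list[CellROI],
                  background: float = 0.0) -> dict[int, ImageSeries]:
    """Cut one sub-series per circular ROI, blanking pixels outside the circle.

    ROIs must be centered inside the frame; circles are clipped at the
    frame border.
    """
    h, w = series.shape
    out: dict[int, ImageSeries] = {}
    for roi in rois:
        cx, cy = roi.center
        if not (0 <= cx < w and 0 <= cy < h):
            raise ROIOutsideFrameError(f"ROI {roi.id} center {roi.center} outside {w}x{h} frame")
        circ = _circle((h, w), roi.center, roi.radius)
        out[roi.id] = ImageSeries(np.where(circ, series.data, background), series.frame_interval)
    return out


def suggest_rois(mask: SegmentationMask, padding: float = 1.5) -> list[CellROI]:
    """Automatic ROI suggestions: circles around mask-component centroids,
    radius ``padding`` times the equivalent circle radius (spacious room
    for expansion/constriction)."""
    rois = []
    for p in measure.regionprops(mask.labels):
        cy, cx = p.centroid
        r = padding * np.sqrt(p.area / np.pi)
        rois.append(CellROI(p.label, (cx, cy), max(r, 1.0)))
    return rois


def overlay_masks(somata: SegmentationMask | None, neurites: SegmentationMask | None,
                  shape: tuple[int, int] | None = None) -> np.ndarray:
    """RGB overlay: somata red, neurites green (uint8)."""
    if shape is None:
        ref = somata if somata is not None else neurites
        if ref is None:
            raise ValueError("need at least one mask or an explicit shape")
        shape = ref.labels.shape
    rgb = np.zeros((*shape, 3), dtype=np.uint8)
    if somata is not None:
        rgb[..., 0][somata.binary] = 255
    if neurites is not None:
        rgb[..., 1][neurites.binary] = 255
    return rgb
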