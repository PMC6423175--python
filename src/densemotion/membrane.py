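"""Per-cell membrane dynamics: area/perimeter ratio and contractility.

Two complementary indices describe plasma-membrane activity of a
segmented single cell:

* **APr** = area / perimeter — a boundary-smoothness index.  A rough
  membrane (many protrusions) has a long perimeter for its area, hence a
  low APr; retraction of protrusions raises it.
* **CtrM** — contractility, the squared relative frame-to-frame change of
  the normalized area ``pA`` (area as % of the series maximum):
  ``CtrM_i = (pA_i - pA_{i-1})^2 / (pA_i + pA_{i-1})^2``.  It vanishes for
  a constant area, peaks where area changes fastest, and is invariant to
  the absolute cell size.  Undefined (NaN) for the first frame.

Ruffling *velocity* is not a separate algorithm: run the motility
descriptors on a perimeter-masked sub-series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .errors import LabelAbsentError
from .segmentation import SegmentationMask

__all__ = [
    "MembraneTrace",
    "area_perimeter",
    "apr",
    "contractility_trace",
    "moving_average",
]


@dataclass
class MembraneTrace:
    """Per-frame membrane quantities for one cell.

    Frames where the label is absent carry NaN in every column and are
    flagged in ``gaps``.  ``ctrm[0]`` is NaN by definition.
    """

    cell_id: int
    area: np.ndarray        # pixels^2
    perimeter: np.ndarray   # pixels (marching-squares contour length)
    apr: np.ndarray
    pa: np.ndarray          # % of series-maximum area
    ctrm: np.ndarray
    gaps: np.ndarray        # bool, True where the label vanished

    def __len__(self) -> int:
        return self.area.size


def area_perimeter(mask: SegmentationMask, label: int) -> tuple[float, float]:
    """Area (pixel count) and perimeter of one labeled cell.

    The perimeter is the marching-squares contour length at the 0.5
    iso-level (sub-pixel, includes hole contours), not a boundary-pixel
    count — absolute APr values depend on this convention.
    """
    region = mask.labels == label
    area = float(region.sum())
    if area == 0:
        raise LabelAbsentError(f"label {label} not present in mask")
    padded = np.pad(region.astype(float), 1)
    perim = 0.0
    for contour in measure.find_contours(padded, 0.5):
        perim += float(np.linalg.norm(np.diff(contour, axis=0), axis=1).sum())
    return area, perim


def apr(area: float, perimeter: float) -> float:
    """Area/perimeter ratio; higher means a smoother boundary."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return area / perimeter


def _ctrm(pa_now: float, pa_prev: float) -> float:
    s = pa_now + pa_prev
    if s == 0:
        return 0.0
    return (pa_now - pa_prev) ** 2 / s**2


def contractility_trace(masks, label: int, cell_id: int | None = None) -> MembraneTrace:
    """Area, perimeter, APr, pA and CtrM for one cell over a mask series.

    ``masks`` is a sequence of per-frame :class:`SegmentationMask`.  Frames
    where the label vanished are flagged as gaps (NaN rows); CtrM bridges
    over gaps using the last frame where the cell was present.
    """
    masks = list(masks)
    if len(masks) < 2:
        raise ValueError("contractility needs >= 2 frames")
    n = len(masks)
    area = np.full(n, np.nan)
    perim = np.full(n, np.nan)
    gaps = np.zeros(n, dtype=bool)
    for i, m in enumerate(masks):
        try:
            area[i], perim[i] = area_perimeter(m, label)
        except LabelAbsentError:
            gaps[i] = True
    if gaps.all():
        raise LabelAbsentError(f"label {label} absent from every frame")
    max_area = np.nanmax(area)
    pa = 100.0 * area / max_area
    apr_vals = np.where(perim > 0, area / np.where(perim > 0, perim, 1.0), np.nan)
    ctrm = np.full(n, np.nan)
    prev = None
    for i in range(n):
        if gaps[i]:
            continue
        if prev is not None:
            ctrm[i] = _ctrm(pa[i], pa[prev])
        prev = i
    # first valid frame has no predecessor: stays NaN by definition
    return MembraneTrace(cell_id if cell_id is not None else label,
                         area, perim, apr_vals, pa, ctrm, gaps)


def moving_average(values, window: int) -> np.ndarray:
    """Centered moving mean with shrinking windows at the edges.

    ``window`` must be odd; a window of 1 is the identity.  NaNs propagate.
    """
    v = np.asarray(values, dtype=np.float64)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > v.size:
        raise ValueError("window larger than the trace")
    half = window // 2
    out = np.empty_like(v)
    for i in range(v.size):
        lo, hi = max(0, i - half), min(v.size, i + half + 1)
        out[i] = v[lo:hi].mean()
    return out
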