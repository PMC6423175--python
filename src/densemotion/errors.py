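"""Exception hierarchy.

Every failure mode named in the public contracts gets its own class so
callers can discriminate without string matching.
"""


class DenseMotionError(Exception):
    """Base class for all package errors."""


class SeriesNotFoundError(DenseMotionError, FileNotFoundError):
    """Input path does not resolve to any readable image."""


class UnreadableImageError(DenseMotionError, ValueError):
    """A file exists but cannot be decoded as an image."""


class MixedDimensionsError(DenseMotionError, ValueError):
    """Frames in one series have inconsistent width/height."""


class EmptySeriesError(DenseMotionError, ValueError):
    """An operation produced or received a series with no frames."""


class ConstantFrameError(DenseMotionError, ValueError):
    """Pearson correlation is undefined when a frame has zero variance."""


class AllBlackFrameError(DenseMotionError, ValueError):
    """DiffMove normalization needs at least one non-black pixel."""


class LabelAbsentError(DenseMotionError, KeyError):
    """Requested label id is not present in a segmentation mask."""


class ROIOutsideFrameError(DenseMotionError, ValueError):
    """A circular ROI center lies outside the frame bounds."""


class DegenerateCalibrationError(DenseMotionError, ValueError):
    """Calibration needs >= 3 distinct speeds and a positive slope."""


class ConfigError(DenseMotionError, ValueError):
    """Pipeline configuration is structurally invalid."""
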