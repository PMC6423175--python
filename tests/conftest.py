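"""Shared fixtures: synthetic phantoms generated at test time."""

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def textured(rng):
    """A noisy textured frame with plenty of edges (non-degenerate stats)."""
    from scipy import ndimage
    base = ndimage.gaussian_filter(rng.normal(size=(120, 160)), 3)
    base = 127 + 60 * base / base.std()
    return np.clip(base + rng.normal(0, 5, base.shape), 0, 255)


def disk_frame(shape=(120, 160), center=(80, 60), radius=12,
               fg=200.0, bg=50.0):
    """Filled bright disk phantom; center given as (x, y)."""
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    cx, cy = center
    f = np.full((h, w), bg, dtype=float)
    f[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2] = fg
    return f


def ring_frame(shape=(120, 160), center=(80, 60), r_in=10, r_out=14,
               fg=220.0, bg=50.0):
    """Bright annulus (halo) phantom."""
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    cx, cy = center
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    f = np.full((h, w), bg, dtype=float)
    f[(d2 >= r_in**2) & (d2 <= r_out**2)] = fg
    return f
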