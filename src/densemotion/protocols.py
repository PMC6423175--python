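"""Simulator-based validation protocols for the motility descriptors.

These routines reproduce the standard robustness experiments on synthetic
sweeps: descriptor response to translocation speed, to cell number, to
global image brightness and to per-cell brightness, plus held-out speed
recovery through the linear calibration transfer function.  Each protocol
varies exactly one factor and reports descriptor summary statistics, so
the sensitivity of DiffMove / COPRAMove / P-move / ratio to that factor
can be compared quantitatively.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage, stats

from .frames import ImageSeries
from .motility import (EDGE_FLOOR, MotilityParams, calibrate,
                       copramove_from_stats, ratio_speed_operator, _sobel_mag)
from .simulator import SimConfig, simulate_sweep, vary_parameter

__all__ = [
    "DESCRIPTOR_NAMES",
    "all_descriptor_means",
    "cell_number_experiment",
    "global_brightness_experiment",
    "brightness_ladder_experiment",
    "speed_ladder_experiment",
    "holdout_speed_recovery",
]

DESCRIPTOR_NAMES = ("diffmove", "copramove", "pmove", "ratio")


def all_descriptor_means(series: ImageSeries,
                         params: MotilityParams = MotilityParams()) -> dict[str, float]:
    """Mean of all four descriptors over a series, sharing per-frame work.

    Numerically identical to running :func:`~densemotion.motility.compute_trace`
    once per algorithm; the mean-filtered and Sobel images of each frame
    are just computed once instead of once per pair.
    """
    frames = list(series)
    mf = ([ndimage.uniform_filter(f, 3, mode="reflect") for f in frames]
          if params.mean_filter else frames)
    sb = [_sobel_mag(f) for f in frames]
    sums = dict.fromkeys(DESCRIPTOR_NAMES, 0.0)
    n_pairs = len(frames) - 1
    img_size = frames[0].size
    for i in range(n_pairs):
        f1, f2 = frames[i], frames[i + 1]
        rp = float(np.corrcoef(mf[i].ravel(), mf[i + 1].ravel())[0, 1])
        hi = np.maximum(sb[i], sb[i + 1]) + 1.0
        lo = np.minimum(sb[i], sb[i + 1]) + 1.0
        d = np.minimum(255.0, (hi / lo - 1.0) * 255.0)
        d[np.maximum(sb[i], sb[i + 1]) < EDGE_FLOOR] = 0.0
        rf = int(np.count_nonzero(d > params.ratio_threshold))
        rso = ratio_speed_operator(rf, img_size)
        z = int(np.count_nonzero(np.abs(f1 - f2) > params.diff_threshold))
        n_pixel = int(np.count_nonzero(f1 > 0))
        sums["diffmove"] += z / n_pixel * 10000.0
        sums["copramove"] += copramove_from_stats(rp, rso)
        sums["pmove"] += (1.0 - rp) * 100.0
        sums["ratio"] += rso
    return {k: v / n_pairs for k, v in sums.items()}


def _seed_variants(base: SimConfig, seeds) -> list[SimConfig]:
    return [replace(base, seed=int(s)) for s in seeds]


def cell_number_experiment(base: SimConfig, n_low: int = 100, n_high: int = 500,
                           seeds=(0,)) -> dict[str, float]:
    """Fold-change of each descriptor when cell number rises n_low -> n_high.

    Both sweeps share speed and rendering parameters; the fold is the ratio
    of sweep-mean descriptors (high over low), averaged over seed replicates.
    """
    folds = {k: [] for k in DESCRIPTOR_NAMES}
    for cfg in _seed_variants(base, seeds):
        lo, hi = vary_parameter(cfg, "n_cells", [n_low, n_high])
        m_lo = all_descriptor_means(lo.series)
        m_hi = all_descriptor_means(hi.series)
        for k in DESCRIPTOR_NAMES:
            folds[k].append(m_hi[k] / m_lo[k])
    return {k: float(np.mean(v)) for k, v in folds.items()}


def global_brightness_experiment(base: SimConfig, factor: float = 0.5,
                                 seeds=(0,)) -> dict[str, float]:
    """Descriptor fold-change (full over dimmed) when the identical rendered
    sequence is scaled to ``factor`` of its intensity."""
    folds = {k: [] for k in DESCRIPTOR_NAMES}
    for cfg in _seed_variants(base, seeds):
        full, dim = vary_parameter(cfg, "global_brightness", [1.0, factor])
        m_full = all_descriptor_means(full.series)
        m_dim = all_descriptor_means(dim.series)
        for k in DESCRIPTOR_NAMES:
            folds[k].append(m_full[k] / m_dim[k] if m_dim[k] > 0 else np.inf)
    return {k: float(np.mean(v)) for k, v in folds.items()}


def brightness_ladder_experiment(base: SimConfig, levels=(10, 25, 40, 55, 70, 85),
                                 seeds=(0,)) -> dict[str, float]:
    """R² of descriptor sweep-means regressed on per-cell brightness.

    A brightness-sensitive descriptor tracks the ladder closely (R² near
    1); a brightness-robust one leaves only replicate noise, for which the
    expected R² of a k-point regression is ~1/(k-1).  R² is computed per
    seed replicate and averaged.
    """
    r2s = {k: [] for k in DESCRIPTOR_NAMES}
    levels = np.asarray(levels, dtype=float)
    for cfg in _seed_variants(base, seeds):
        sweeps = vary_parameter(cfg, "cell_brightness", levels)
        means = {k: [] for k in DESCRIPTOR_NAMES}
        for sw in sweeps:
            m = all_descriptor_means(sw.series)
            for k in DESCRIPTOR_NAMES:
                means[k].append(m[k])
        for k in DESCRIPTOR_NAMES:
            r = stats.linregress(levels, means[k])
            r2s[k].append(r.rvalue**2)
    return {k: float(np.mean(v)) for k, v in r2s.items()}


def speed_ladder_experiment(base: SimConfig, speeds=tuple(range(1, 9)),
                            ) -> dict[str, list[float]]:
    """Descriptor sweep-means over a ladder of translocation speeds."""
    means = {k: [] for k in DESCRIPTOR_NAMES}
    for i, s in enumerate(speeds):
        sw = simulate_sweep(replace(base, speed=float(s), seed=base.seed + i))
        m = all_descriptor_means(sw.series)
        for k in DESCRIPTOR_NAMES:
            means[k].append(m[k])
    return means


def holdout_speed_recovery(base: SimConfig, fit_speeds=(1, 2, 3, 4, 6, 7, 8),
                           holdout: float = 5.0, algorithm: str = "copramove",
                           ) -> dict[str, float]:
    """Fit the transfer function on ``fit_speeds``, predict the held-out speed.

    Returns the fitted model quality and the recovered speed of the
    held-out sweep (descriptor mean mapped through the inverse transfer).
    """
    all_speeds = list(fit_speeds) + [holdout]
    means = speed_ladder_experiment(base, all_speeds)[algorithm]
    fit_means, held_mean = means[:-1], means[-1]
    model = calibrate(fit_means, fit_speeds)
    return {"recovered": float(model.to_speed(held_mean)), "true": float(holdout),
            "r2": model.r2, "slope": model.slope, "intercept": model.intercept}
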