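"""Preprocessing operators and the focus metric."""

import numpy as np
import pytest
from scipy import ndimage

import densemotion as dm
from densemotion.errors import (EmptySeriesError, MixedDimensionsError,
                                SeriesNotFoundError)
from densemotion.frames import ImageSeries, natural_key
from densemotion.imageprep import FOCUS_SENTINEL

from conftest import disk_frame, ring_frame


class TestReadSeries:
    def test_folder_roundtrip(self, tmp_path, rng):
        import imageio.v3 as iio
        frames = [rng.integers(0, 256, (48, 64)).astype(np.uint8) for _ in range(3)]
        for i, f in enumerate(frames):
            iio.imwrite(tmp_path / f"frame_{i}.png", f)
        series = dm.read_series(tmp_path)
        assert len(series) == 3 and series.shape == (48, 64)
        np.testing.assert_allclose(series.data, np.stack(frames).astype(float))

    def test_multipage_tiff(self, tmp_path, rng):
        import tifffile
        stack = rng.integers(0, 256, (5, 32, 40)).astype(np.uint8)
        tifffile.imwrite(tmp_path / "stack.tif", stack)
        series = dm.read_series(tmp_path / "stack.tif")
        assert len(series) == 5 and series.shape == (32, 40)

    def test_mixed_dimensions_raise(self, tmp_path):
        import imageio.v3 as iio
        iio.imwrite(tmp_path / "a.png", np.zeros((48, 64), dtype=np.uint8))
        iio.imwrite(tmp_path / "b.png", np.zeros((32, 40), dtype=np.uint8))
        with pytest.raises(MixedDimensionsError):
            dm.read_series(tmp_path)

    def test_missing_path_raises(self, tmp_path):
        with pytest.raises(SeriesNotFoundError):
            dm.read_series(tmp_path / "nowhere")

    def test_natural_sort_order(self, tmp_path):
        import imageio.v3 as iio
        for i in (2, 10, 1):
            iio.imwrite(tmp_path / f"frame_{i}.png",
                        np.full((8, 8), i, dtype=np.uint8))
        series = dm.read_series(tmp_path)
        assert [f[0, 0] for f in series] == [1, 2, 10]
        assert natural_key("frame_0010") > natural_key("frame_0002")


class TestStandardize:
    def test_identity_size(self, textured):
        out = dm.standardize(textured, 160, 120)
        np.testing.assert_allclose(out, textured)

    def test_downscale_preserves_mean(self, rng):
        big = rng.uniform(0, 255, (960, 1280))
        out = dm.standardize(big, 640, 480)
        assert out.shape == (480, 640)
        # block-average oracle for an exact 2x downscale
        oracle = big.reshape(480, 2, 640, 2).mean(axis=(1, 3))
        assert abs(out.mean() - oracle.mean()) < 1.0

    def test_constant_upscale_stays_constant(self):
        out = dm.standardize(np.full((100, 100), 50.0), 640, 480)
        np.testing.assert_allclose(out, 50.0, atol=1e-6)

    def test_bad_target_raises(self, textured):
        with pytest.raises(ValueError):
            dm.standardize(textured, 0, 480)


class TestCenterBright:
    def test_constant_shifted_to_target(self):
        out = dm.center_bright(np.full((20, 20), 50.0))
        np.testing.assert_allclose(out, 127.0)

    def test_already_centered_unchanged(self, textured):
        f = np.clip(textured, 30.0, 220.0)
        f = f - f.mean() + 127.0
        np.testing.assert_allclose(dm.center_bright(f), f, atol=1e-9)

    def test_binary_extremes_offset_oracle(self):
        f = np.zeros((10, 10))
        f[:, 5:] = 255.0
        out = dm.center_bright(f)
        # offset oracle: mean 127.5, offset -0.5, clipping at 0 only
        oracle = np.clip(f + (127.0 - 127.5), 0, 255)
        np.testing.assert_allclose(out, oracle)

    def test_idempotent_within_one(self, textured):
        once = dm.center_bright(textured)
        twice = dm.center_bright(once)
        assert abs(once.mean() - twice.mean()) <= 1.0


class TestFlattenBackground:
    def test_constant_maps_to_target_mean(self):
        out = dm.flatten_background(np.full((60, 80), 90.0), blur_sigma=10)
        np.testing.assert_allclose(out, 127.0)

    def test_linear_ramp_equalized(self):
        ramp = np.tile(np.linspace(40, 210, 160), (120, 1))
        out = dm.flatten_background(ramp, blur_sigma=15)
        col_means = out[:, 50:-50].mean(axis=0)  # away from borders
        assert col_means.max() - col_means.min() < 4.0  # vs ~64 before

    def test_bright_disk_survives_flattening(self):
        ramp = np.tile(np.linspace(40, 160, 160), (120, 1))
        f = ramp.copy()
        f[55:66, 35:46] += 70.0
        out = dm.flatten_background(f, blur_sigma=40)
        iy, ix = np.unravel_index(np.argmax(out), out.shape)
        assert 55 <= iy < 66 and 35 <= ix < 46


class TestSharpen:
    def test_amount_zero_identity(self, textured):
        np.testing.assert_allclose(dm.sharpen_unsharp(textured, 2, 0), textured)

    def test_constant_unchanged(self):
        f = np.full((30, 30), 80.0)
        np.testing.assert_allclose(dm.sharpen_unsharp(f, 2, 1.5), f)

    def test_step_edge_gradient_increases(self):
        f = np.full((40, 60), 100.0)
        f[:, 30:] = 160.0
        def grad(x):
            return np.hypot(ndimage.sobel(x, 0), ndimage.sobel(x, 1)).max()
        assert grad(dm.sharpen_unsharp(f, 2, 1.0)) > grad(f)


class TestRemoveDebris:
    def test_blank_unchanged(self):
        f = np.full((60, 80), 100.0)
        np.testing.assert_allclose(dm.remove_debris(f), f)

    def test_small_speck_removed(self):
        f = np.full((60, 80), 100.0)
        f[30:33, 40:43] = 250.0
        out = dm.remove_debris(f, max_size=30)
        assert abs(out[30:33, 40:43].mean() - 100.0) < 2.0

    def test_large_disk_retained(self):
        f = disk_frame(shape=(60, 80), center=(40, 30), radius=10, fg=250, bg=100)
        out = dm.remove_debris(f, max_size=30)
        assert out[30, 40] > 200.0


class TestSubtractMeanBackground:
    def test_identical_frames_become_uniform(self, textured):
        series = ImageSeries(np.stack([textured] * 4))
        out = dm.subtract_mean_background(series)
        for f in out:
            assert abs(f.mean() - 127.0) < 1.0
            assert f.std() < 1e-6

    def test_static_background_variance_collapses(self, textured):
        frames = []
        for i in range(6):
            f = textured.copy()
            f[10 + 5 * i:14 + 5 * i, 20:24] = 255.0  # moving dot
            frames.append(f)
        series = ImageSeries(np.stack(frames))
        out = dm.subtract_mean_background(series)
        assert out.data.var() < series.data.var() / 10.0
        # dot still detectable: its position is the brightest spot
        iy, ix = np.unravel_index(np.argmax(out[0]), out[0].shape)
        assert 10 <= iy < 14 and 20 <= ix < 24

    def test_two_frame_minimum(self, textured):
        with pytest.raises(EmptySeriesError):
            dm.subtract_mean_background(ImageSeries(textured[None]))


class TestFocus:
    def test_matches_brute_force_oracle(self):
        cb = np.indices((48, 64)).sum(axis=0) % 2 * 255.0
        score = dm.focus_score(cb)
        # independent oracle: explicit double-loop Laplacian on a
        # symmetric-padded copy (same boundary convention)
        p = np.pad(cb, 1, mode="symmetric")
        h, w = cb.shape
        lap = np.empty((h, w))
        for y in range(1, h + 1):
            for x in range(1, w + 1):
                lap[y - 1, x - 1] = (p[y - 1, x] + p[y + 1, x] + p[y, x - 1]
                                     + p[y, x + 1] - 4 * p[y, x])
        expected = np.log(lap.std() ** 2) - 1.0
        assert score.F == pytest.approx(expected, rel=1e-3)
        assert score.F == pytest.approx(np.log(score.sd**2) - 1.0)

    def test_constant_frame_sentinel(self):
        assert dm.focus_score(np.full((20, 20), 7.0)).F == FOCUS_SENTINEL

    def test_shift_invariance(self, textured):
        f = np.clip(textured, 30, 220)
        assert dm.focus_score(f).F == pytest.approx(dm.focus_score(f + 20).F, abs=1e-9)

    def test_monotone_decreasing_under_blur(self, textured):
        fs = [dm.focus_score(ndimage.gaussian_filter(textured, s)).F
              for s in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(fs, fs[1:]))


class TestDropLowFocus:
    def test_neg_inf_threshold_identity(self, textured):
        series = ImageSeries(np.stack([textured] * 3))
        out = dm.drop_low_focus(series, -np.inf)
        assert len(out) == 3

    def test_blurred_middle_frame_dropped(self, textured):
        blurred = ndimage.gaussian_filter(textured, 3)
        f_sharp = dm.focus_score(textured).F
        f_blur = dm.focus_score(blurred).F
        thr = (f_sharp + f_blur) / 2
        series = ImageSeries(np.stack([textured, blurred, textured]))
        out = dm.drop_low_focus(series, thr)
        assert len(out) == 2
        np.testing.assert_allclose(out[0], textured)

    def test_all_dropped_raises(self, textured):
        series = ImageSeries(np.stack([textured] * 2))
        with pytest.raises(EmptySeriesError):
            dm.drop_low_focus(series, 1e9)


class TestLevelDiffractionLight:
    def test_constant_stays_constant(self):
        out = dm.level_diffraction_light(np.full((40, 40), 120.0))
        assert out.std() < 1e-9

    def test_halo_attenuated_relative_to_soma(self):
        f = disk_frame(shape=(120, 160), radius=10, fg=120, bg=60)
        ring = ring_frame(shape=(120, 160), r_in=10, r_out=13, fg=230, bg=0)
        f = np.maximum(f, ring)
        ring_px = ring > 0
        disk_px = disk_frame(shape=(120, 160), radius=9, fg=1, bg=0) > 0
        before = f[ring_px].mean() / f[disk_px].mean()
        out = dm.level_diffraction_light(f)
        after = out[ring_px].mean() / out[disk_px].mean()
        assert after < before

    def test_histogram_reweighting_formula(self):
        # a value with H(i) = 1/255 maps to i/2 in the reweighting branch
        i = 100.0
        h_i = 1.0 / 255.0
        assert i * 1.0 / (h_i * 255.0 + 1.0) == pytest.approx(i / 2.0)


class TestPhaseContrastCorrect:
    def test_constant_to_127(self):
        out = dm.phase_contrast_correct(np.full((30, 30), 40.0))
        np.testing.assert_allclose(out, 127.0)

    def test_mean_recentered(self, textured):
        assert abs(dm.phase_contrast_correct(textured).mean() - 127.0) < 2.0

    def test_dark_disk_becomes_bright_with_relief_flanks(self):
        f = disk_frame(shape=(80, 100), center=(50, 40), radius=10, fg=40, bg=180)
        out = dm.phase_contrast_correct(f)
        assert out[40, 50] > out[5, 5]  # disk now brighter than field
        # opposing flanks along the diagonal relief axis
        upper_left = out[28:34, 38:44].mean()
        lower_right = out[46:52, 56:62].mean()
        assert (upper_left - out[5, 5]) * (lower_right - out[5, 5]) < 0

    def test_not_an_involution(self, textured):
        twice = dm.phase_contrast_correct(dm.phase_contrast_correct(textured))
        assert not np.allclose(twice, textured, atol=1.0)


class TestRangeInvariant:
    @pytest.mark.parametrize("op", [
        lambda f: dm.center_bright(f),
        lambda f: dm.flatten_background(f, 20),
        lambda f: dm.sharpen_unsharp(f, 2, 2.0),
        lambda f: dm.remove_debris(f),
        lambda f: dm.level_diffraction_light(f),
        lambda f: dm.phase_contrast_correct(f),
    ])
    def test_output_in_8bit_range_same_shape(self, textured, op):
        out = op(textured)
        assert out.shape == textured.shape
        assert out.min() >= 0.0 and out.max() <= 255.0
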