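import numpy as np
import pytest

from nodulect.preprocess import (
    CTVolume,
    GrayCube,
    NoduleAnnotation,
    ThresholdPair,
    bbox_to_cube,
    build_mask,
    interclass_variance,
    normalized_histogram,
    otsu_two_thresholds,
    quantize_to_gray,
    resample_cube,
)
from oracles import otsu_bruteforce


class TestQuantize:
    def test_window_clamping(self):
        assert np.all(quantize_to_gray(np.full((4, 4, 4), -2000.0), (0, 300)).voxels == 0)
        assert np.all(quantize_to_gray(np.full((4, 4, 4), 500.0), (0, 300)).voxels == 255)

    def test_linear_midpoint(self):
        cube = quantize_to_gray(np.full((2, 2, 2), 150.0), (0, 300))
        assert np.all(cube.voxels == 127)  # floor(255 * 0.5)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            quantize_to_gray(np.full((2, 2, 2), np.nan), (0, 300))
        with pytest.raises(ValueError):
            quantize_to_gray(np.zeros((2, 2, 2)), (300, 0))


class TestHistogram:
    def test_constant_and_bimodal(self):
        h = normalized_histogram(GrayCube(np.full((3, 3, 3), 7), (0, 300)))
        assert h[7] == 1.0 and h.sum() == 1.0
        v = np.zeros((2, 2, 2), dtype=int)
        v[0] = 255
        h = normalized_histogram(GrayCube(v, (0, 300)))
        assert h[0] == 0.5 and h[255] == 0.5

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(3)
        v = rng.integers(0, 256, size=(9, 9, 9))
        h = normalized_histogram(GrayCube(v, (0, 300)))
        for level in range(256):
            assert h[level] == np.count_nonzero(v == level) / v.size
        assert abs(h.sum() - 1.0) < 1e-12


class TestInterclassVariance:
    def test_constant_histogram_is_zero(self):
        h = np.zeros(256)
        h[100] = 1.0
        for k1, k2 in [(10, 50), (99, 150), (100, 200)]:
            assert interclass_variance(h, k1, k2) == 0.0

    def test_three_spike_closed_form(self):
        h = np.zeros(256)
        h[[10, 128, 240]] = 1 / 3
        expected = ((10 - 126) ** 2 + (128 - 126) ** 2 + (240 - 126) ** 2) / 3
        assert interclass_variance(h, 60, 180) == pytest.approx(expected, rel=1e-12)

    def test_bounded_by_total_variance(self):
        rng = np.random.default_rng(11)
        h = rng.random(256)
        h /= h.sum()
        i = np.arange(256)
        total = float(h @ (i - h @ i) ** 2)
        for _ in range(50):
            k1 = int(rng.integers(1, 253))
            k2 = int(rng.integers(k1 + 1, 255))
            s = interclass_variance(h, k1, k2)
            assert 0.0 <= s <= total + 1e-9

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            interclass_variance(np.full(256, 1 / 256), 100, 100)


class TestOtsu:
    def test_matches_bruteforce_on_random_histograms(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            v = rng.integers(0, 256, size=600)
            h = np.bincount(v, minlength=256) / 600
            pair = otsu_two_thresholds(h)
            k1, k2, best = otsu_bruteforce(h)
            assert pair.k1 == pytest.approx(k1, abs=1e-9)
            assert pair.k2 == pytest.approx(k2, abs=1e-9)
            assert pair.sigma2 == pytest.approx(best, rel=1e-12)

    def test_three_spike_tie_averaging(self):
        # any k1 in [10,127], k2 in [128,239] is tied-optimal
        h = np.zeros(256)
        h[[10, 128, 240]] = 1 / 3
        pair = otsu_two_thresholds(h)
        assert pair.k1 == pytest.approx(np.mean(np.arange(10, 128)))
        assert pair.k2 == pytest.approx(np.mean(np.arange(128, 240)))

    def test_symmetric_histogram_gives_symmetric_pair(self):
        rng = np.random.default_rng(5)
        h = rng.random(256)
        h = h + h[::-1]
        h /= h.sum()
        pair = otsu_two_thresholds(h)
        assert pair.k1 + pair.k2 == pytest.approx(254.0, abs=1e-6)

    def test_gaussian_mixture_matches_oracle(self):
        rng = np.random.default_rng(9)
        v = np.concatenate([
            rng.normal(40, 8, 400), rng.normal(130, 10, 300), rng.normal(220, 6, 300)])
        v = np.clip(np.round(v), 0, 255).astype(int)
        h = np.bincount(v, minlength=256) / len(v)
        pair = otsu_two_thresholds(h)
        k1, k2, best = otsu_bruteforce(h)
        assert (pair.k1, pair.k2) == (k1, k2)
        assert pair.sigma2 == pytest.approx(best, rel=1e-12)

    def test_sparse_histogram_warns(self):
        h = np.zeros(256)
        h[[3, 200]] = 0.5
        with pytest.warns(UserWarning):
            otsu_two_thresholds(h)


class TestBuildMask:
    def test_retention_rule(self):
        v = np.arange(27).reshape(3, 3, 3) * 9
        gray = GrayCube(np.clip(v, 0, 255), (0, 300))
        pair = ThresholdPair(k1=90.0, k2=200.0, sigma2=1.0)
        mask = build_mask(gray, pair)
        assert np.array_equal(mask, gray.voxels > 90)  # level at K1 excluded

    def test_all_above_threshold(self):
        gray = GrayCube(np.full((3, 3, 3), 200), (0, 300))
        mask = build_mask(gray, ThresholdPair(10.0, 100.0, 1.0))
        assert mask.all()

    def test_fractional_threshold_rounds_half_up(self):
        gray = GrayCube(np.full((2, 2, 2), 91), (0, 300))
        assert not build_mask(gray, ThresholdPair(90.5, 200.0, 1.0)).any()
        assert build_mask(gray, ThresholdPair(90.4, 200.0, 1.0)).all()

    def test_empty_mask_warns(self):
        gray = GrayCube(np.full((2, 2, 2), 5), (0, 300))
        with pytest.warns(UserWarning):
            build_mask(gray, ThresholdPair(10.0, 100.0, 1.0))


class TestBboxToCube:
    def _volume(self, shape=(20, 20, 20), seed=0):
        rng = np.random.default_rng(seed)
        return CTVolume(rng.uniform(-1000, 400, shape))

    def test_equal_extents_identity(self):
        vol = self._volume()
        ann = NoduleAnnotation(xmin=2, xmax=11, ymin=3, ymax=12, zmin=4, zmax=13)
        cube = bbox_to_cube(vol, ann)
        assert cube.shape == (10, 10, 10)
        np.testing.assert_array_equal(cube, vol.voxels[4:14, 3:13, 2:12])

    def test_padding_layout_for_unequal_extents(self):
        # extents (z, y, x) = (5, 8, 6) -> side 8; z pads (1, 2); x pads (1, 1)
        vol = self._volume()
        ann = NoduleAnnotation(xmin=5, xmax=10, ymin=5, ymax=12, zmin=8, zmax=12)
        cube = bbox_to_cube(vol, ann, fill=-1024.0)
        assert cube.shape == (8, 8, 8)
        np.testing.assert_array_equal(cube[1:6, :, 1:7], vol.voxels[8:13, 5:13, 5:11])
        assert np.all(cube[0] == -1024.0) and np.all(cube[6:] == -1024.0)
        assert np.all(cube[:, :, 0][1:6] == -1024.0)

    def test_border_overrun_uses_fill(self):
        vol = self._volume()
        ann = NoduleAnnotation(xmin=0, xmax=3, ymin=0, ymax=3, zmin=0, zmax=7)
        cube = bbox_to_cube(vol, ann, fill=-1024.0)
        assert cube.shape == (8, 8, 8)
        assert np.all(cube[:, 0:2, 0:2] == -1024.0)  # low-side pad falls outside

    def test_recrop_recovers_bbox_content(self):
        vol = self._volume(seed=4)
        ann = NoduleAnnotation(xmin=6, xmax=9, ymin=2, ymax=10, zmin=5, zmax=10)
        cube = bbox_to_cube(vol, ann)
        ext = ann.extents
        side = max(ext)
        starts = [(side - e) // 2 for e in ext]
        inner = cube[starts[0]:starts[0] + ext[0],
                     starts[1]:starts[1] + ext[1],
                     starts[2]:starts[2] + ext[2]]
        np.testing.assert_array_equal(inner, vol.voxels[5:11, 2:11, 6:10])

    def test_annotation_outside_volume_rejected(self):
        vol = self._volume(shape=(8, 8, 8))
        with pytest.raises(ValueError):
            bbox_to_cube(vol, NoduleAnnotation(xmin=0, xmax=9, ymin=0, ymax=3, zmin=0, zmax=3))


class TestResample:
    def test_identity_and_constant(self):
        rng = np.random.default_rng(0)
        cube = rng.random((6, 6, 6))
        np.testing.assert_array_equal(resample_cube(cube, 6), cube)
        out = resample_cube(np.full((4, 4, 4), 3.5), 9)
        assert np.allclose(out, 3.5)

    def test_linear_ramp_preserved(self):
        src = 8
        ramp = np.broadcast_to(np.arange(src, dtype=float), (src, src, src)).copy()
        out = resample_cube(ramp, 15)
        expected = np.linspace(0, src - 1, 15)
        assert np.allclose(out[4, 7, :], expected, atol=1e-6)

    def test_mask_stays_boolean(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        out = resample_cube(mask, 12, is_mask=True)
        assert out.dtype == bool and out.any() and not out.all()
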