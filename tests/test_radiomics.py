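"""Catalogue structure, first-order statistics and shape descriptors."""

import numpy as np
import pytest

from nodulect.radiomics import (
    FEATURE_CLASSES,
    default_profile,
    extract_profile,
    first_order,
    full_profile,
    shape_2d,
    shape_3d,
)
from nodulect.radiomics.shape import largest_axial_slice


class TestCatalogue:
    def test_per_class_counts(self):
        expected = {"first_order": 19, "shape3d": 16, "shape2d": 10, "glcm": 24,
                    "glrlm": 16, "glszm": 16, "ngtdm": 5, "gldm": 14}
        assert {cls: len(names) for cls, names in FEATURE_CLASSES.items()} == expected

    def test_profile_sizes(self):
        assert len(default_profile()) == 107
        assert len(full_profile()) == 120

    def test_no_duplicate_entries(self):
        assert len(set(full_profile())) == 120


class TestFirstOrder:
    def test_constant_region(self):
        f = first_order(np.full(40, 9.0))
        assert f["Variance"] == 0 and f["Entropy"] == 0
        assert f["Range"] == 0 and f["Uniformity"] == 1.0

    def test_tiny_sample_arithmetic(self):
        f = first_order(np.array([1.0, 2.0, 3.0]))
        assert f["Mean"] == 2.0 and f["Range"] == 2.0 and f["Energy"] == 14.0
        assert f["Median"] == 2.0 and f["Maximum"] == 3.0 and f["Minimum"] == 1.0

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0, 255, 500)
        f = first_order(x, voxel_volume=2.0, n_bins=32)
        n = len(x)
        mean = x.sum() / n
        var = ((x - mean) ** 2).sum() / n
        # independent formula-by-formula recomputation
        assert f["Energy"] == pytest.approx((x ** 2).sum(), rel=1e-12)
        assert f["TotalEnergy"] == pytest.approx(2.0 * (x ** 2).sum(), rel=1e-12)
        assert f["Mean"] == pytest.approx(mean, rel=1e-12)
        assert f["Variance"] == pytest.approx(var, rel=1e-12)
        assert f["StandardDeviation"] == pytest.approx(np.sqrt(var), rel=1e-12)
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt((x ** 2).sum() / n), rel=1e-12)
        assert f["MeanAbsoluteDeviation"] == pytest.approx(np.abs(x - mean).sum() / n, rel=1e-12)
        assert f["Skewness"] == pytest.approx(
            (((x - mean) ** 3).sum() / n) / var ** 1.5, rel=1e-9)
        assert f["Kurtosis"] == pytest.approx(
            (((x - mean) ** 4).sum() / n) / var ** 2, rel=1e-9)
        p10, p90 = np.percentile(x, [10, 90])
        mid = x[(x >= p10) & (x <= p90)]
        assert f["RobustMeanAbsoluteDeviation"] == pytest.approx(
            np.abs(mid - mid.mean()).sum() / len(mid), rel=1e-9)
        # histogram-based features against a direct binning
        lo, hi = x.min(), x.max()
        bins = np.minimum(((x - lo) / ((hi - lo) / 32)).astype(int), 31)
        p = np.bincount(bins, minlength=32) / n
        nz = p[p > 0]
        assert f["Uniformity"] == pytest.approx((p ** 2).sum(), rel=1e-12)
        assert f["Entropy"] == pytest.approx(-(nz * np.log2(nz)).sum(), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            first_order(np.array([]))


def ball_mask(side: int, radius: float) -> np.ndarray:
    c = (side - 1) / 2
    zz, yy, xx = np.meshgrid(*[np.arange(side)] * 3, indexing="ij")
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2


class TestShape3D:
    def test_single_voxel_volume(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        f = shape_3d(mask, (1.0, 1.0, 1.0))
        assert f["VoxelVolume"] == 1.0

    def test_cube_sphericity_near_closed_form(self):
        # large-cube limit: sphericity -> (pi/6)^(1/3) ~ 0.806
        mask = np.zeros((24, 24, 24), dtype=bool)
        mask[2:22, 2:22, 2:22] = True
        f = shape_3d(mask, (1.0, 1.0, 1.0))
        assert f["Sphericity"] == pytest.approx((np.pi / 6) ** (1 / 3), abs=0.03)

    def test_ball_rounder_than_cube(self):
        ball = ball_mask(24, 10.0)
        f_ball = shape_3d(ball, (1.0, 1.0, 1.0))
        assert 0.95 < f_ball["Sphericity"] <= 1.01
        cube = np.zeros((24, 24, 24), dtype=bool)
        cube[4:20, 4:20, 4:20] = True
        assert f_ball["Sphericity"] > shape_3d(cube, (1.0, 1.0, 1.0))["Sphericity"]

    def test_translation_invariance(self):
        base = np.zeros((20, 20, 20), dtype=bool)
        base[3:9, 4:10, 5:11] = True
        shifted = np.roll(base, (4, 3, 2), axis=(0, 1, 2))
        f1 = shape_3d(base, (1.0, 1.0, 1.0))
        f2 = shape_3d(shifted, (1.0, 1.0, 1.0))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-6), k

    def test_volume_scales_with_spacing_cubed(self):
        mask = ball_mask(16, 6.0)
        f1 = shape_3d(mask, (1.0, 1.0, 1.0))
        f2 = shape_3d(mask, (2.0, 2.0, 2.0))
        assert f2["VoxelVolume"] == pytest.approx(8 * f1["VoxelVolume"], rel=1e-12)
        assert f2["MeshVolume"] == pytest.approx(8 * f1["MeshVolume"], rel=1e-9)

    def test_ball_diameters_consistent(self):
        f = shape_3d(ball_mask(25, 9.0), (1.0, 1.0, 1.0))
        assert 16.0 < f["Maximum3DDiameter"] < 20.5
        for k in ("Maximum2DDiameterSlice", "Maximum2DDiameterColumn", "Maximum2DDiameterRow"):
            assert f[k] <= f["Maximum3DDiameter"] + 1e-9


class TestShape2D:
    def test_single_pixel_surface(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        f = shape_2d(m, (0.5, 0.8))
        assert f["PixelSurface"] == pytest.approx(0.4)

    def test_square_perimeter(self):
        # marching-squares contour of an s x s square has perimeter close to 4s
        m = np.zeros((14, 14), dtype=bool)
        m[2:12, 2:12] = True
        f = shape_2d(m, (1.0, 1.0))
        assert f["Perimeter"] == pytest.approx(4 * 10, rel=0.05)

    def test_disk_beats_square_on_perimeter_ratio(self):
        yy, xx = np.meshgrid(np.arange(21), np.arange(21), indexing="ij")
        disk = (yy - 10) ** 2 + (xx - 10) ** 2 <= 64
        square = np.zeros((21, 21), dtype=bool)
        square[3:17, 3:17] = True  # area 196 vs disk ~201
        f_disk = shape_2d(disk, (1.0, 1.0))
        f_square = shape_2d(square, (1.0, 1.0))
        assert f_disk["PerimeterSurfaceRatio"] < f_square["PerimeterSurfaceRatio"]

    def test_largest_axial_slice_selection(self):
        mask = np.zeros((6, 8, 8), dtype=bool)
        mask[2, 1:3, 1:3] = True
        mask[4, 1:7, 1:7] = True
        assert largest_axial_slice(mask) == 4


class TestExtractProfile:
    def test_default_and_full_lengths(self, random_gray_cube):
        gray, mask = random_gray_cube
        values, names = extract_profile(gray, mask)
        assert len(values) == len(names) == 107
        values_full, _ = extract_profile(gray, mask, profile=full_profile())
        assert len(values_full) == 120
        assert np.all(np.isfinite(values_full))

    def test_deterministic(self, random_gray_cube):
        gray, mask = random_gray_cube
        v1, _ = extract_profile(gray, mask)
        v2, _ = extract_profile(gray, mask)
        np.testing.assert_array_equal(v1, v2)

    def test_first_order_shuffle_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 200, 300)
        f1 = first_order(x)
        f2 = first_order(rng.permutation(x))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-12)

    def test_empty_mask_rejected(self, random_gray_cube):
        gray, _ = random_gray_cube
        with pytest.raises(ValueError):
            extract_profile(gray, np.zeros_like(gray, dtype=bool))

    def test_axis_permutation_invariance(self, random_gray_cube):
        # direction-averaged texture + first-order stats ignore axis order
        gray, mask = random_gray_cube
        prof = [(c, n) for c, n in full_profile() if c not in ("shape3d", "shape2d")]
        v1, _ = extract_profile(gray, mask, profile=prof)
        v2, _ = extract_profile(gray.transpose(2, 0, 1), mask.transpose(2, 0, 1), profile=prof)
        np.testing.assert_allclose(v1, v2, rtol=1e-9)
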