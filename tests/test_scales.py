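"""Morphological scale analysis: disk SEs, opening, and scale selection."""

import numpy as np
import pytest

from crownseg.raster import RasterGrid
from crownseg.scales import (
    ScaleCurve,
    disk_structuring_element,
    grayscale_open,
    mean_difference_curve,
    select_dominant_scales,
)


def brute_force_open(values: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Independent erosion+dilation oracle with explicit loops."""
    r = se.shape[0] // 2
    nr, nc = values.shape
    offsets = [(i - r, j - r) for i, j in zip(*np.nonzero(se))]

    def erode(a):
        out = np.empty_like(a)
        for i in range(nr):
            for j in range(nc):
                m = np.inf
                for di, dj in offsets:
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nr and 0 <= jj < nc:
                        m = min(m, a[ii, jj])
                out[i, j] = m
        return out

    def dilate(a):
        out = np.empty_like(a)
        for i in range(nr):
            for j in range(nc):
                m = -np.inf
                for di, dj in offsets:
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nr and 0 <= jj < nc:
                        m = max(m, a[ii, jj])
                out[i, j] = m
        return out

    return dilate(erode(values))


class TestDiskSE:
    @pytest.mark.parametrize("diameter,expected", [(1, 1), (3, 5), (5, 13), (7, 29)])
    def test_pixel_counts(self, diameter, expected):
        assert disk_structuring_element(diameter).sum() == expected

    @pytest.mark.parametrize("diameter", [0, 2, 4, -3])
    def test_rejects_even_or_nonpositive(self, diameter):
        with pytest.raises(ValueError):
            disk_structuring_element(diameter)

    def test_diameter3_is_the_axial_cross(self):
        se = disk_structuring_element(3)
        np.testing.assert_array_equal(
            se, np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
        )


class TestGrayscaleOpen:
    def test_constant_grid_invariant(self, flat_grid):
        out = grayscale_open(flat_grid, disk_structuring_element(3))
        np.testing.assert_allclose(out.values, flat_grid.values)

    def test_single_pixel_spike_removed(self):
        vals = np.zeros((9, 9))
        vals[4, 4] = 10.0
        out = grayscale_open(RasterGrid(vals, 1.0, (0, 9)), disk_structuring_element(3))
        np.testing.assert_allclose(out.values, 0.0)

    def test_idempotent(self, rng):
        grid = RasterGrid(rng.uniform(0, 9, (20, 20)), 1.0, (0, 20))
        se = disk_structuring_element(5)
        once = grayscale_open(grid, se)
        twice = grayscale_open(once, se)
        np.testing.assert_allclose(once.values, twice.values)

    def test_anti_extensive(self, rng):
        grid = RasterGrid(rng.uniform(0, 9, (20, 20)), 1.0, (0, 20))
        out = grayscale_open(grid, disk_structuring_element(5))
        assert np.all(out.values <= grid.values + 1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            vals = rng.uniform(0, 10, (16, 16))
            grid = RasterGrid(vals, 1.0, (0, 16))
            for d in (3, 5):
                se = disk_structuring_element(d)
                np.testing.assert_allclose(
                    grayscale_open(grid, se).values, brute_force_open(vals, se)
                )

    def test_se_larger_than_grid_raises(self, flat_grid):
        with pytest.raises(ValueError):
            grayscale_open(flat_grid, disk_structuring_element(33))


class TestMeanDifferenceCurve:
    def test_constant_chm_all_differences_zero(self, flat_grid):
        curve = mean_difference_curve(flat_grid, d_start=3, d_end=9)
        np.testing.assert_allclose(curve.differences, 0.0)

    def test_differences_nonpositive_and_means_decreasing(self, rng):
        grid = RasterGrid(rng.uniform(0, 15, (40, 40)), 1.0, (0, 40))
        curve = mean_difference_curve(grid, d_start=3, d_end=15)
        assert np.all(curve.differences <= 1e-12)
        assert np.all(np.diff(curve.means) <= 1e-12)

    def test_cylinders_drop_at_first_diameter_beyond_their_width(self):
        # flat-topped crowns of diameter 9 px vanish at the first SE > 9 px
        vals = np.zeros((60, 60))
        yy, xx = np.mgrid[:60, :60]
        for cy, cx in [(15, 15), (15, 45), (45, 15), (45, 45)]:
            vals[(yy - cy) ** 2 + (xx - cx) ** 2 <= 4.0**2 + 1e-9] = 10.0
        curve = mean_difference_curve(RasterGrid(vals, 1.0, (0, 60)), d_start=3, d_end=17)
        drop_at = curve.difference_diameters[np.argmin(curve.differences)]
        assert drop_at == 11

    def test_empty_mask_raises(self, flat_grid):
        with pytest.raises(ValueError):
            mean_difference_curve(flat_grid, mask=np.zeros((16, 16), bool))

    def test_even_step_required(self, flat_grid):
        with pytest.raises(ValueError):
            mean_difference_curve(flat_grid, d_start=3, d_end=9, step=1)


class TestSelectDominantScales:
    def make_curve(self, diffs):
        diffs = np.asarray(diffs, dtype=float)
        dias = np.arange(3, 3 + 2 * (len(diffs) + 1), 2)
        means = np.concatenate([[0.0], np.cumsum(diffs)])
        return ScaleCurve(dias, means, diffs)

    def test_finds_minima_at_expected_diameters(self):
        # qualifying minima at 7, 13, 21 within bounds
        dias = np.arange(3, 33, 2)  # differences at 5..31
        diffs = -0.2 * np.ones(len(dias) - 1)
        by_dia = dict(zip(dias[1:].tolist(), range(len(diffs))))
        for d, depth in ((7, -1.0), (13, -1.2), (21, -0.9)):
            diffs[by_dia[d]] = depth
        curve = ScaleCurve(dias, np.concatenate([[0], np.cumsum(diffs)]), diffs)
        assert select_dominant_scales(curve, 5, 31) == [7, 13, 21]

    def test_monotone_curve_has_no_minima(self):
        curve = self.make_curve(np.linspace(-1.0, -0.1, 12))
        assert select_dominant_scales(curve, 5, 31) == []

    def test_invariant_to_constant_chm_offset(self, rng):
        vals = rng.uniform(0, 12, (48, 48))
        a = mean_difference_curve(RasterGrid(vals, 1.0, (0, 48)), d_start=3, d_end=21)
        b = mean_difference_curve(RasterGrid(vals + 5.0, 1.0, (0, 48)), d_start=3, d_end=21)
        assert select_dominant_scales(a, 5, 21) == select_dominant_scales(b, 5, 21)

    def test_bounds_filter_minima(self):
        dias = np.arange(3, 33, 2)
        diffs = -0.2 * np.ones(len(dias) - 1)
        diffs[list(dias[1:]).index(7)] = -1.0
        diffs[list(dias[1:]).index(21)] = -1.0
        curve = ScaleCurve(dias, np.concatenate([[0], np.cumsum(diffs)]), diffs)
        assert select_dominant_scales(curve, 9, 31) == [21]
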