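"""Treetop extraction, Gaussian crown fitting, and cross-scale merging."""

import numpy as np
import pytest

from conftest import gaussian_cap_grid
from crownseg.raster import RasterGrid
from crownseg.scales import disk_structuring_element, grayscale_open
from crownseg.treetops import (
    TreetopRegion,
    extract_treetop_regions,
    fit_gaussian_crown,
    intensity_f_test,
    merge_across_scales,
    residual_f_test,
    disk_seeds_from_centres,
)


def region_from_mask(mask, scale=7, rid=1):
    rows, cols = np.nonzero(mask)
    return TreetopRegion(id=rid, rows=rows, cols=cols, scale=scale)


def two_crown_grid():
    """Two Gaussian crowns, 8 m and 14 m apices, side by side."""
    grid = RasterGrid(np.zeros((64, 64)), 0.25, (0.0, 16.0))
    X, Y = grid.cell_centers()
    z = 8.0 * np.exp(-(((X - 5.0) ** 2 + (Y - 8.0) ** 2) / (2 * 0.8**2)))
    z2 = 14.0 * np.exp(-(((X - 9.0) ** 2 + (Y - 8.0) ** 2) / (2 * 0.8**2)))
    z = np.maximum(np.where(z >= 0.4, z, 0), np.where(z2 >= 0.7, z2, 0))
    return RasterGrid(z, 0.25, (0.0, 16.0))


class TestExtractTreetopRegions:
    def test_all_zero_image_yields_nothing(self, flat_grid):
        zero = flat_grid.copy_with(np.zeros(flat_grid.shape))
        assert extract_treetop_regions(zero, np.ones(zero.shape, bool), 3) == []

    def test_single_crown_gives_one_region_containing_apex(self):
        chm = gaussian_cap_grid(apex=12.0, sx=1.2, sy=1.2, cutoff=0.05)
        opened = grayscale_open(chm, disk_structuring_element(7))
        regions = extract_treetop_regions(opened, chm.values > 0, 7)
        assert len(regions) == 1
        apex_r, apex_c = np.unravel_index(np.argmax(chm.values), chm.shape)
        flat = regions[0].flat_pixels(chm.shape[1])
        assert apex_r * chm.shape[1] + apex_c in flat

    def test_two_crowns_give_two_disjoint_regions(self):
        chm = two_crown_grid()
        opened = grayscale_open(chm, disk_structuring_element(5))
        regions = extract_treetop_regions(opened, chm.values > 0, 5)
        assert len(regions) == 2
        a, b = (r.flat_pixels(chm.shape[1]) for r in regions)
        assert not (a & b)


class TestFitGaussianCrown:
    def test_recovers_noiseless_parameters(self):
        chm = gaussian_cap_grid(apex=10.0, cx=8.05, cy=7.95, sx=1.0, sy=1.0)
        region = region_from_mask(chm.values > 0.5)
        model = fit_gaussian_crown(chm, region)
        assert model.A == pytest.approx(10.0, rel=1e-3)
        assert model.mu_x == pytest.approx(8.05, abs=1e-3)
        assert model.mu_y == pytest.approx(7.95, abs=1e-3)
        assert model.sigma_x == pytest.approx(1.0, rel=1e-3)
        assert model.residual < 1e-8

    def test_peak_value_identities(self):
        chm = gaussian_cap_grid(apex=10.0, sx=1.0, sy=1.0)
        model = fit_gaussian_crown(chm, region_from_mask(chm.values > 0.5))
        assert model.evaluate(model.mu_x, model.mu_y) == pytest.approx(model.A)
        assert model.evaluate(model.mu_x + model.sigma_x, model.mu_y) == pytest.approx(
            model.A * np.exp(-0.5)
        )

    def test_tiny_region_flagged_degenerate(self, flat_grid):
        region = region_from_mask(np.pad(np.ones((2, 2), bool), ((0, 14), (0, 14))))
        assert fit_gaussian_crown(flat_grid, region) is None
        assert region.degenerate


class TestFTests:
    def _fitted(self, chm, mask, scale, rid):
        region = region_from_mask(mask, scale, rid)
        fit_gaussian_crown(chm, region)
        return region

    def test_both_residuals_perfect_keeps_upper(self):
        chm = gaussian_cap_grid(apex=10.0, sx=1.0, sy=1.0)
        low = self._fitted(chm, chm.values > 5.0, 7, 1)
        up = self._fitted(chm, chm.values > 1.0, 13, 2)
        assert residual_f_test(up, [low]) == "keep_upper"

    def test_upper_straddling_two_crowns_keeps_lower(self):
        chm = two_crown_grid()
        both = chm.values > 0.3
        left = both & (np.arange(64)[None, :] < 28)
        right = both & (np.arange(64)[None, :] >= 28)
        rng = np.random.default_rng(0)
        noisy = chm.copy_with(np.maximum(chm.values + rng.normal(0, 0.05, chm.shape), 0))
        up = self._fitted(noisy, both, 13, 1)
        lows = [self._fitted(noisy, m, 7, i + 2) for i, m in enumerate((left, right))]
        assert residual_f_test(up, lows) == "keep_lower"

    def test_identical_region_self_comparison_keeps_upper(self, rng):
        stack = rng.normal(100, 5, (3, 16, 16))
        region = region_from_mask(np.ones((16, 16), bool))
        other = region_from_mask(np.ones((16, 16), bool), rid=2)
        assert intensity_f_test(region, [other], stack) == "keep_upper"

    def test_spectrally_split_upper_keeps_lower(self, rng):
        stack = rng.normal(100.0, 5.0, (3, 20, 20))
        stack[:, :, 10:] += 100.0  # two crowns with very different means
        mask = np.zeros((20, 20), bool)
        mask[5:15, :] = True
        up = region_from_mask(mask, 13, 1)
        left = region_from_mask(mask & (np.arange(20)[None, :] < 10), 7, 2)
        right = region_from_mask(mask & (np.arange(20)[None, :] >= 10), 7, 3)
        assert intensity_f_test(up, [left, right], stack) == "keep_lower"

    def test_homogeneous_concentric_usually_keeps_upper(self, rng):
        # single spectral population: upper should win almost always
        keep_lower = 0
        for _ in range(20):
            stack = rng.normal(100.0, 10.0, (3, 24, 24))
            inner = np.zeros((24, 24), bool)
            inner[8:16, 8:16] = True
            outer = np.zeros((24, 24), bool)
            outer[4:20, 4:20] = True
            up = region_from_mask(outer, 13, 1)
            low = region_from_mask(inner, 7, 2)
            if intensity_f_test(up, [low], stack) == "keep_lower":
                keep_lower += 1
        assert keep_lower <= 4


class TestMergeAcrossScales:
    def test_concentric_single_crown_keeps_upper_scale(self):
        chm = gaussian_cap_grid(n=80, apex=12.0, cx=10.0, cy=10.0, sx=1.2, sy=1.2, cutoff=0.05)
        mask = chm.values > 0
        final = merge_across_scales(chm, None, mask, [7, 13])
        assert len(final) == 1
        assert final[0].scale == 13

    def test_two_small_crowns_survive_a_covering_upper_region(self):
        chm = two_crown_grid()
        rng = np.random.default_rng(1)
        noisy = chm.copy_with(np.maximum(chm.values + rng.normal(0, 0.05, chm.shape), 0))
        final = merge_across_scales(noisy, None, chm.values > 0, [5, 17], min_prominence=0.2)
        # the two crowns remain distinct treetops
        assert len(final) >= 2
        centres = set()
        for r in final:
            centres.add(np.argmax(np.bincount((r.cols < 28).astype(int))))
        assert centres == {0, 1}

    def test_crown_seen_only_at_smallest_scale_is_retained(self):
        # small crown vanishes at scale 13 but exists at 5; big crown at both
        grid = RasterGrid(np.zeros((80, 80)), 0.25, (0.0, 20.0))
        X, Y = grid.cell_centers()
        small = 9.0 * np.exp(-(((X - 4.0) ** 2 + (Y - 4.0) ** 2) / (2 * 0.5**2)))
        big = 14.0 * np.exp(-(((X - 13.0) ** 2 + (Y - 13.0) ** 2) / (2 * 1.5**2)))
        z = np.maximum(np.where(small >= 0.45, small, 0), np.where(big >= 0.7, big, 0))
        chm = RasterGrid(z, 0.25, (0.0, 20.0))
        final = merge_across_scales(chm, None, z > 0, [5, 13])
        # the small crown sits at world (4, 4): low columns, high rows
        holds_small = any((r.cols < 40).all() and (r.rows > 40).all() for r in final)
        assert holds_small
        assert len(final) == 2

    def test_final_regions_pairwise_disjoint(self):
        chm = two_crown_grid()
        final = merge_across_scales(chm, None, chm.values > 0, [5, 9, 13])
        seen: set = set()
        for r in final:
            flat = r.flat_pixels(chm.shape[1])
            assert not (seen & flat)
            seen |= flat


class TestDiskSeeds:
    def test_disks_clipped_and_disjoint(self, flat_grid):
        centres = [(1.0, 3.0, 9.0), (1.5, 3.0, 8.0)]
        seeds = disk_seeds_from_centres(centres, flat_grid, radius_px=3)
        assert len(seeds) == 2
        a = seeds[0].flat_pixels(flat_grid.shape[1])
        b = seeds[1].flat_pixels(flat_grid.shape[1])
        assert not (a & b)
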