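"""Neutrosophic primitives and seeded region growing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crownseg.neutrosophic import (
    NeutrosophicParams,
    combined_truth,
    grow_crowns,
    indeterminacy_degree,
    sigmoid_threshold,
    truth_degree_pixel,
    truth_degree_window,
    window_statistics,
)
from crownseg.synthetic import SyntheticSceneSpec, generate_scene
from crownseg.treetops import TreetopRegion


class TestIndeterminacy:
    def test_constant_windows_give_zero(self):
        assert indeterminacy_degree(np.zeros(3)) == 0.0

    def test_single_channel_closed_form(self):
        assert indeterminacy_degree([100.0]) == pytest.approx(1 - np.exp(-1), abs=1e-9)

    def test_two_channel_mean(self):
        assert indeterminacy_degree([0.0, 100.0]) == pytest.approx(
            0.5 * (1 - np.exp(-1)), abs=1e-9
        )

    @given(st.lists(st.floats(0, 1e5), min_size=1, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_bounded_below_one(self, variances):
        v = indeterminacy_degree(np.array(variances))
        # mathematically I < 1; float64 saturates to exactly 1 for huge variances
        assert 0.0 <= v <= 1.0

    def test_strictly_increasing_in_each_channel_variance(self):
        base = np.array([50.0, 80.0])
        bumped = np.array([60.0, 80.0])
        assert indeterminacy_degree(bumped) > indeterminacy_degree(base)


class TestTruthDegrees:
    @pytest.mark.parametrize(
        "mean,pixel,expected",
        [(100.0, 100.0, 1.0), (0.0, 50.0, 0.0), (120.0, 100.0, 0.8), (210.0, 100.0, 0.0)],
    )
    def test_pixel_truth(self, mean, pixel, expected):
        assert truth_degree_pixel(mean, pixel) == pytest.approx(expected, abs=1e-9)

    def test_window_truth_midpoint(self):
        assert truth_degree_window(50.0, 100.0) == pytest.approx(0.5, abs=1e-9)

    def test_zero_pixel_conventions(self):
        assert truth_degree_pixel(0.0, 0.0) == 1.0
        assert truth_degree_pixel(5.0, 0.0) == 0.0


class TestCombinedTruth:
    def test_equal_variances_reduce_to_mean(self):
        assert combined_truth([0.8, 0.6], [1.0, 1.0]) == pytest.approx(0.7, abs=1e-9)

    def test_inverse_variance_weighting(self):
        assert combined_truth([0.8, 0.6], [1.0, 4.0]) == pytest.approx(0.76, abs=1e-9)

    @given(
        st.floats(0, 1),
        st.lists(st.floats(1e-3, 1e3), min_size=1, max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_constant_truths_pass_through(self, c, variances):
        assert combined_truth(
            np.full(len(variances), c), np.array(variances)
        ) == pytest.approx(c, abs=1e-9)


class TestSigmoidThreshold:
    @pytest.mark.parametrize(
        "I,expected",
        [(1.0, 1.0), (0.5, 0.70474), (0.75, 0.92936), (0.6, 0.81325)],
    )
    def test_closed_form_values(self, I, expected):
        assert sigmoid_threshold(I) == pytest.approx(expected, abs=1e-4)

    def test_nondecreasing_above_half(self):
        vals = [sigmoid_threshold(i) for i in np.linspace(0.5, 1.0, 40)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestWindowStatistics:
    def test_constant_image(self):
        mean, var = window_statistics(np.full((6, 6), 4.0))
        np.testing.assert_allclose(mean, 4.0)
        np.testing.assert_allclose(var, 0.0, atol=1e-12)

    def test_interior_window_matches_direct_computation(self, rng):
        img = rng.uniform(0, 9, (7, 7))
        mean, var = window_statistics(img)
        w = img[2:5, 2:5]
        assert mean[3, 3] == pytest.approx(w.mean())
        assert var[3, 3] == pytest.approx(w.var())

    def test_corner_window_shrinks(self, rng):
        img = rng.uniform(0, 9, (5, 5))
        mean, _ = window_statistics(img)
        assert mean[0, 0] == pytest.approx(img[:2, :2].mean())


def seeds_from_truth(truth, apex_radius=2):
    """Small seed disks at the true apices."""
    seeds = []
    grid = truth.label_map
    for k, (x, y, _) in enumerate(truth.treetop_centres, start=1):
        r0, c0 = grid.world_to_cell(x, y)
        rr, cc = np.mgrid[r0 - apex_radius : r0 + apex_radius + 1,
                          c0 - apex_radius : c0 + apex_radius + 1]
        ok = (truth.labels[rr, cc] == k)
        seeds.append(TreetopRegion(id=k, rows=rr[ok], cols=cc[ok], scale=5))
    return seeds


class TestGrowCrowns:
    def test_no_seeds_grows_nothing(self):
        scene, _ = generate_scene(SyntheticSceneSpec(extent=(10, 10), n_trees=1, rng_seed=2))
        labels = grow_crowns(scene, [], NeutrosophicParams())
        assert (labels == 0).all()

    def test_single_crown_fills_exactly(self):
        scene, truth = generate_scene(SyntheticSceneSpec(extent=(14, 14), n_trees=1, rng_seed=2))
        labels = grow_crowns(scene, seeds_from_truth(truth), NeutrosophicParams(tau_h=3.0))
        np.testing.assert_array_equal(labels > 0, truth.labels > 0)

    def test_two_separated_crowns_match_ground_truth(self):
        scene, truth = generate_scene(SyntheticSceneSpec(extent=(22, 22), n_trees=2, rng_seed=6))
        labels = grow_crowns(scene, seeds_from_truth(truth), NeutrosophicParams(tau_h=3.0))
        np.testing.assert_array_equal(labels, truth.labels)

    def test_deterministic(self):
        spec = SyntheticSceneSpec(
            extent=(20, 20), n_trees=3, rng_seed=8, intensity_noise_sd=5.0, chm_noise_sd=0.1
        )
        scene, truth = generate_scene(spec)
        seeds = seeds_from_truth(truth)
        a = grow_crowns(scene, seeds, NeutrosophicParams(tau_h=3.0))
        b = grow_crowns(scene, seeds, NeutrosophicParams(tau_h=3.0))
        np.testing.assert_array_equal(a, b)

    def test_components_are_connected_and_contain_their_seed(self):
        from scipy import ndimage

        spec = SyntheticSceneSpec(
            extent=(20, 20), n_trees=3, rng_seed=8, intensity_noise_sd=5.0, chm_noise_sd=0.1
        )
        scene, truth = generate_scene(spec)
        seeds = seeds_from_truth(truth)
        labels = grow_crowns(scene, seeds, NeutrosophicParams(tau_h=3.0))
        four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        for seed in seeds:
            comp, n = ndimage.label(labels == seed.id, structure=four)
            assert n == 1
            assert (comp[seed.rows, seed.cols] == 1).all()

    def test_overlapping_seeds_rejected(self):
        scene, truth = generate_scene(SyntheticSceneSpec(extent=(14, 14), n_trees=1, rng_seed=2))
        seed = seeds_from_truth(truth)[0]
        clone = TreetopRegion(id=2, rows=seed.rows, cols=seed.cols, scale=5)
        with pytest.raises(ValueError):
            grow_crowns(scene, [seed, clone], NeutrosophicParams())

    def test_labels_respect_tree_mask(self):
        spec = SyntheticSceneSpec(extent=(20, 20), n_trees=2, rng_seed=6)
        scene, truth = generate_scene(spec)
        labels = grow_crowns(scene, seeds_from_truth(truth), NeutrosophicParams(tau_h=3.0))
        assert (labels[~scene.tree_mask] == 0).all()


class TestTemplateShapeMode:
    def test_template_mode_recovers_a_clean_crown(self):
        from crownseg.treetops import fit_gaussian_crown

        scene, truth = generate_scene(SyntheticSceneSpec(extent=(14, 14), n_trees=1, rng_seed=2))
        seed = seeds_from_truth(truth)[0]
        # widen the seed so the 5-parameter surface is well constrained
        rows, cols = np.nonzero(truth.labels == 1)
        top = scene.chm.values[rows, cols] > 0.5 * scene.chm.values.max()
        seed.rows, seed.cols = rows[top], cols[top]
        fit_gaussian_crown(scene.chm, seed)
        assert seed.model is not None
        labels = grow_crowns(
            scene, [seed], NeutrosophicParams(tau_h=1.0, shape_mode="template"), fill=False
        )
        grown = labels == 1
        # the fitted template admits the whole crown despite steep flanks
        assert grown.sum() == (truth.labels == 1).sum()

    def test_unknown_shape_mode_rejected(self):
        with pytest.raises(ValueError):
            NeutrosophicParams(shape_mode="nonsense")


class TestMergeDecisionThresholds:
    """The I-gated decision rule at its published switch points."""

    def _grow_one(self, scene, seed, params):
        return grow_crowns(scene, [seed], params)

    def test_low_indeterminacy_uses_fixed_cut(self):
        # homogeneous intensities -> I = 0 < 0.5; pixel truth 1.0 > 0.6 -> all merge
        scene, truth = generate_scene(SyntheticSceneSpec(extent=(12, 12), n_trees=1, rng_seed=2))
        labels = grow_crowns(
            scene, seeds_from_truth(truth), NeutrosophicParams(tau_h=100.0), source="intensity"
        )
        np.testing.assert_array_equal(labels > 0, truth.labels > 0)

    def test_merge_blocked_when_truth_below_cut(self):
        # background-coloured stripe inside the mask: truth ~ 1-|120-20|/20 -> 0
        scene, truth = generate_scene(SyntheticSceneSpec(extent=(12, 12), n_trees=1, rng_seed=2))
        stripe = truth.labels > 0
        rows, cols = np.nonzero(stripe)
        cut = cols > np.median(cols)
        for band in scene.intensity:
            band.values[rows[cut], cols[cut]] = 1.0
        labels = grow_crowns(
            scene, seeds_from_truth(truth), NeutrosophicParams(tau_h=100.0),
            source="intensity", fill=False,
        )
        assert (labels[rows[cut], cols[cut]] == 0).any()
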