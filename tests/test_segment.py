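"""Binarization, wall cleanup, markers, SKIZ, watershed, and the full chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi
from skimage.measure import label as cc_label

from brightmorph import (
    FISSION_YEAST,
    BUDDING_YEAST,
    MarkerSet,
    adaptive_binarize,
    background_markers,
    clean_wall_mask,
    clear_border,
    foreground_markers,
    generate_budding_scene,
    generate_rod_scene,
    match_labels,
    merge_foreground_markers,
    run_pipeline,
    watershed_segment,
)
from brightmorph.segment import CellWallMask, LabelMap, default_window_px

from conftest import make_image, ring_mask, rect_ring


# ---------------------------------------------------------------------------
# adaptive binarization vs a brute-force local-mean oracle
# ---------------------------------------------------------------------------

def brute_force_binarize(px, sensitivity, window):
    """Oracle: sliding-window mean with replicate padding, computed naively."""
    pad = window // 2
    p = np.pad(px, pad, mode="edge")
    out = np.zeros_like(px, dtype=bool)
    for i in range(px.shape[0]):
        for j in range(px.shape[1]):
            mu = p[i : i + window, j : j + window].mean()
            out[i, j] = px[i, j] > mu * (1 + (0.5 - sensitivity))
    return out


class TestAdaptiveBinarize:
    @pytest.mark.parametrize("sensitivity", [0.35, 0.5, 0.65])
    @pytest.mark.parametrize("window", [3, 15, 33])
    def test_matches_brute_force_oracle_on_random_images(self, rng, sensitivity, window):
        px = rng.uniform(0, 1, size=(64, 64))
        got = adaptive_binarize(make_image(px), sensitivity, window)
        np.testing.assert_array_equal(got, brute_force_binarize(px, sensitivity, window))

    def test_constant_image_is_all_background(self):
        got = adaptive_binarize(make_image(np.full((32, 32), 0.5)), 0.35, 15)
        assert not got.any()

    def test_half_black_half_white_oracle(self, rng):
        px = np.zeros((64, 64))
        px[:, 32:] = 1.0
        got = adaptive_binarize(make_image(px), 0.5, 15)
        np.testing.assert_array_equal(got, brute_force_binarize(px, 0.5, 15))
        # far from the boundary: white side foreground? white == local mean ->
        # not strictly above it; the transition region near the step is what
        # the local mean resolves
        assert not got[:, :20].any()

    def test_bright_ridge_on_dark_background(self):
        px = np.full((64, 64), 0.1)
        px[:, 30:33] = 0.9
        got = adaptive_binarize(make_image(px), 0.35, 33)
        assert got[:, 30:33].all()
        assert not got[:, :20].any() and not got[:, 45:].any()

    def test_invalid_parameters_rejected(self):
        img = make_image(np.zeros((32, 32)))
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                adaptive_binarize(img, bad, 15)
        with pytest.raises(ValueError):
            adaptive_binarize(img, 0.35, 16)  # even window

    def test_default_window_scales_with_image(self):
        assert default_window_px((512, 512)) == 65
        assert default_window_px((64, 64)) == 15  # floor
        assert default_window_px((700, 900)) % 2 == 1


@settings(derandomize=True, max_examples=20, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    sensitivity=st.floats(0.2, 0.8),
    window=st.sampled_from([3, 5, 9, 15]),
)
def test_binarize_oracle_equivalence_property(seed, sensitivity, window):
    px = np.random.default_rng(seed).uniform(0, 1, size=(20, 20))
    got = adaptive_binarize(make_image(px), sensitivity, window)
    np.testing.assert_array_equal(got, brute_force_binarize(px, sensitivity, window))


# ---------------------------------------------------------------------------
# wall cleanup
# ---------------------------------------------------------------------------

class TestCleanWallMask:
    def test_min_area_boundary_component_of_exact_size_retained(self):
        mask = np.zeros((64, 128), dtype=bool)
        mask[2:13, 2:16] = True  # 11 x 14 = 154 px -> shave to 150 and 149
        mask[2, 2:6] = False  # 150
        mask[40:50, 40:55] = True  # 150 px
        mask[40, 40:45] = False  # 145 < 150
        cleaned = clean_wall_mask(mask, 150, 2)
        labs = cc_label(cleaned.mask, connectivity=2)
        assert labs.max() == 1
        assert cleaned.mask[5, 5] and not cleaned.mask[45, 45]

    def test_closing_seals_small_wall_gap(self):
        ring = rect_ring((48, 48), 8, 8, 30, 30, thickness=5)
        ring[20:23, 8:13] = False  # 3-px gap in the left wall
        holes_before = foreground_markers(CellWallMask(ring)).max()
        cleaned = clean_wall_mask(ring, 50, 2)
        holes_after = foreground_markers(cleaned).max()
        assert holes_before == 0 and holes_after == 1

    def test_empty_mask_passes_through(self):
        cleaned = clean_wall_mask(np.zeros((32, 32), dtype=bool), 150, 2)
        assert not cleaned.mask.any()


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

class TestForegroundMarkers:
    def test_single_ring_yields_one_interior_marker(self):
        ring = ring_mask((64, 64), (32, 32), 10, 14)
        fg = foreground_markers(CellWallMask(ring))
        assert fg.max() == 1
        inside = np.hypot(*(np.argwhere(fg > 0) - [32, 32]).T) < 10
        assert inside.all()

    def test_two_rings_yield_two_markers(self):
        ring = ring_mask((64, 128), (32, 32), 8, 12) | ring_mask(
            (64, 128), (32, 96), 8, 12
        )
        fg = foreground_markers(CellWallMask(ring))
        assert fg.max() == 2

    def test_open_c_shape_has_no_hole(self):
        ring = ring_mask((64, 64), (32, 32), 10, 14)
        ring[28:36, 42:] = False  # cut the ring open
        fg = foreground_markers(CellWallMask(ring))
        assert fg.max() == 0


class TestMergeForegroundMarkers:
    def test_identical_inputs_idempotent(self):
        ring = ring_mask((64, 64), (32, 32), 8, 12)
        fg = foreground_markers(CellWallMask(ring))
        merged = merge_foreground_markers(fg, fg)
        assert merged.max() == fg.max()
        np.testing.assert_array_equal(merged > 0, fg > 0)

    def test_disjoint_markers_keep_two_labels(self):
        a = np.zeros((32, 32), dtype=np.int32)
        b = np.zeros((32, 32), dtype=np.int32)
        a[5:8, 5:8] = 1
        b[20:23, 20:23] = 1
        assert merge_foreground_markers(a, b).max() == 2

    def test_overlapping_markers_merge_into_one(self):
        a = np.zeros((32, 32), dtype=np.int32)
        b = np.zeros((32, 32), dtype=np.int32)
        a[5:12, 5:12] = 1
        b[9:16, 9:16] = 1
        merged = merge_foreground_markers(a, b)
        # oracle: connected components of the union
        assert merged.max() == cc_label((a > 0) | (b > 0), connectivity=2).max() == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            merge_foreground_markers(np.zeros((8, 8), int), np.zeros((9, 8), int))


class TestBackgroundMarkers:
    def test_skiz_between_two_bars_is_the_midline(self):
        wall = np.zeros((64, 64), dtype=bool)
        wall[:, 20] = True
        wall[:, 44] = True
        skiz = background_markers(CellWallMask(wall))
        cols = np.unique(np.argwhere(skiz)[:, 1])
        assert len(cols) > 0
        assert np.all(np.abs(cols - 32) <= 1)

    def test_single_component_yields_empty_skiz(self):
        wall = ring_mask((64, 64), (32, 32), 8, 12)
        assert not background_markers(CellWallMask(wall)).any()

    def test_empty_wall_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            skiz = background_markers(CellWallMask(np.zeros((32, 32), dtype=bool)))
        assert not skiz.any()
        assert "empty wall" in caplog.text

    def test_skiz_disjoint_from_wall(self):
        wall = ring_mask((96, 96), (30, 30), 8, 12) | ring_mask(
            (96, 96), (65, 65), 8, 12
        )
        skiz = background_markers(CellWallMask(wall))
        assert not (skiz & wall).any()


# ---------------------------------------------------------------------------
# watershed + border clearing
# ---------------------------------------------------------------------------

def _two_ring_setup():
    shape = (64, 128)
    wall = ring_mask(shape, (32, 32), 10, 13) | ring_mask(shape, (32, 96), 10, 13)
    px = np.where(wall, 0.9, 0.1)
    img = make_image(px, inverted=True)
    fg = foreground_markers(CellWallMask(wall))
    bg = background_markers(CellWallMask(wall))
    return img, MarkerSet(fg, bg), fg


class TestWatershedSegment:
    def test_each_region_contains_its_marker(self):
        img, markers, fg = _two_ring_setup()
        out = watershed_segment(img, markers)
        assert out.n_objects == 2
        for k in (1, 2):
            assert np.all(out.labels[fg == k] == k)

    def test_marker_count_conservation_on_random_scene(self):
        scene = generate_rod_scene(6, seed=7, shape=(400, 400), length_range_um=(6, 10))
        from brightmorph.segment import run_pipeline as rp

        result = rp(scene.raw, FISSION_YEAST, 0.1, return_intermediates=True)
        assert result.n_before_border_clear == result.markers.n_foreground

    def test_zero_markers_warns_and_returns_empty(self, caplog):
        img = make_image(np.full((32, 32), 0.5), inverted=True)
        empty = MarkerSet(np.zeros((32, 32), np.int32), np.zeros((32, 32), bool))
        with caplog.at_level("WARNING"):
            out = watershed_segment(img, empty)
        assert out.n_objects == 0

    def test_markers_must_be_disjoint(self):
        fg = np.zeros((32, 32), np.int32)
        fg[5:8, 5:8] = 1
        bg = np.zeros((32, 32), bool)
        bg[6, 6] = True
        with pytest.raises(ValueError):
            MarkerSet(fg, bg)

    def test_zero_markers_flag_matches_default_on_clean_scene(self):
        img, markers, _ = _two_ring_setup()
        a = watershed_segment(img, markers)
        b = watershed_segment(img, markers, zero_markers=True)
        assert a.n_objects == b.n_objects == 2


class TestClearBorder:
    def test_border_object_removed_interior_relabeled(self):
        lab = np.zeros((32, 32), np.int32)
        lab[0:5, 10:15] = 1  # touches row 0
        lab[15:20, 15:20] = 2
        out = clear_border(LabelMap(lab, 0.1))
        assert out.n_objects == 1
        assert np.all(out.labels[15:20, 15:20] == 1)

    def test_all_interior_is_identity(self):
        lab = np.zeros((32, 32), np.int32)
        lab[5:10, 5:10] = 1
        lab[15:20, 15:20] = 2
        out = clear_border(LabelMap(lab, 0.1))
        np.testing.assert_array_equal(out.labels, lab)

    def test_all_border_objects_removed(self):
        lab = np.zeros((32, 32), np.int32)
        lab[0:5, 0:5] = 1
        lab[28:, 28:] = 2
        assert clear_border(LabelMap(lab, 0.1)).n_objects == 0


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

class TestRunPipeline:
    def test_sparse_rod_scene_recovers_all_cells(self):
        scene = generate_rod_scene(10, seed=3)
        labels = run_pipeline(scene.raw, FISSION_YEAST, 0.1)
        assert labels.n_objects == 10
        m = match_labels(scene.truth_labels.labels, labels.labels, 0.6)
        assert m.match_rate == 1.0

    def test_budding_scene_merged_markers_count_cells(self):
        scene = generate_budding_scene(5, bud_fraction=0.6, seed=5)
        labels = run_pipeline(scene.raw, BUDDING_YEAST, 0.1)
        assert labels.n_objects == scene.truth_labels.n_objects

    def test_blank_image_yields_zero_objects_without_crash(self, caplog):
        scene = generate_rod_scene(0, seed=0)
        with caplog.at_level("WARNING"):
            labels = run_pipeline(scene.raw, FISSION_YEAST, 0.1)
        assert labels.n_objects == 0

    def test_markers_never_overlap_wall_or_each_other(self):
        scene = generate_rod_scene(8, seed=11)
        result = run_pipeline(scene.raw, FISSION_YEAST, 0.1, return_intermediates=True)
        fg = result.markers.foreground
        assert not ((fg > 0) & result.wall.mask).any()
        assert not ((fg > 0) & result.markers.background).any()

    def test_determinism_identical_label_maps(self):
        scene = generate_rod_scene(6, seed=9, shape=(400, 400), length_range_um=(6, 10))
        a = run_pipeline(scene.raw, FISSION_YEAST, 0.1)
        b = run_pipeline(scene.raw, FISSION_YEAST, 0.1)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_label_components_are_connected_and_consecutive(self):
        scene = generate_rod_scene(8, seed=13)
        labels = run_pipeline(scene.raw, FISSION_YEAST, 0.1)
        n = labels.n_objects
        present = np.unique(labels.labels)
        np.testing.assert_array_equal(present, np.arange(n + 1))
        for k in range(1, n + 1):
            assert cc_label(labels.labels == k, connectivity=2).max() == 1
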