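"""Threshold segmentation, manual outlines, and skeleton length."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormscatter import Image, SceneSpec, manual_mask, render_scene, segment_worms, worm_length
from wormscatter.illumination import GeometryError
from wormscatter.segmentation import WormMask


def _img(arr):
    return Image(pixels=np.asarray(arr, dtype=float), bit_depth=16, modality="darkfield")


def _point_in_polygon(r, c, poly):
    """Even-odd ray casting oracle (independent of shapely)."""
    inside = False
    n = len(poly)
    for i in range(n):
        r1, c1 = poly[i]
        r2, c2 = poly[(i + 1) % n]
        # on-edge check: collinear and within segment bounds
        cross = (r2 - r1) * (c - c1) - (c2 - c1) * (r - r1)
        if abs(cross) < 1e-12 and min(r1, r2) - 1e-12 <= r <= max(r1, r2) + 1e-12 \
                and min(c1, c2) - 1e-12 <= c <= max(c1, c2) + 1e-12:
            return True
        if (r1 > r) != (r2 > r):
            x = c1 + (r - r1) * (c2 - c1) / (r2 - r1)
            if x > c:
                inside = not inside
    return inside


class TestSegmentWorms:
    def test_all_zero_image_empty(self):
        assert segment_worms(_img(np.zeros((20, 20))), threshold=10) == []

    def test_threshold_above_max_empty(self):
        assert segment_worms(_img(np.full((20, 20), 5)), threshold=5) == []

    def test_single_blob_exact_area(self):
        arr = np.zeros((40, 40))
        arr[5:25, 10:35] = 100  # 20 x 25 = 500 px
        masks = segment_worms(_img(arr), threshold=50, min_area_px=50)
        assert len(masks) == 1
        assert masks[0].area_px == 500
        assert masks[0].threshold_used == 50

    def test_min_area_filters_small_blob(self):
        arr = np.zeros((60, 60))
        arr[5:25, 5:45] = 100   # 800 px
        arr[40:55, 40:60] = 100  # 300 px
        masks = segment_worms(_img(arr), threshold=50, min_area_px=400)
        assert [m.area_px for m in masks] == [800]

    def test_sorted_by_area_descending(self):
        arr = np.zeros((60, 60))
        arr[2:12, 2:12] = 9    # 100
        arr[20:40, 20:50] = 9  # 600
        masks = segment_worms(_img(arr), threshold=5)
        assert [m.area_px for m in masks] == [600, 100]
        assert [m.label for m in masks] == ["worm_00", "worm_01"]

    def test_holes_filled(self):
        arr = np.zeros((30, 30))
        arr[5:25, 5:25] = 100
        arr[10:20, 10:20] = 0  # interior hole
        masks = segment_worms(_img(arr), threshold=50)
        assert masks[0].area_px == 400  # 20x20, hole filled

    def test_max_worms_cap(self):
        arr = np.zeros((60, 60))
        arr[2:12, 2:12] = 9
        arr[20:40, 20:50] = 9
        masks = segment_worms(_img(arr), threshold=5, max_worms=1)
        assert len(masks) == 1 and masks[0].area_px == 600

    @given(st.integers(0, 2 ** 31 - 1), st.integers(10, 120), st.integers(10, 120))
    @settings(max_examples=25, deadline=None)
    def test_threshold_monotonicity(self, seed, t_lo, t_hi):
        """Raising the threshold never increases total segmented area."""
        lo, hi = sorted((t_lo, t_hi))
        arr = np.random.default_rng(seed).integers(0, 150, size=(48, 48)).astype(float)
        img = _img(arr)
        area_lo = sum(m.area_px for m in segment_worms(img, threshold=lo))
        area_hi = sum(m.area_px for m in segment_worms(img, threshold=hi))
        assert area_hi <= area_lo


class TestManualMask:
    def test_square_area(self):
        """Square with corner vertices on pixel centers 0..9 covers 100 px."""
        img = _img(np.zeros((20, 20)))
        wm = manual_mask(img, [(0, 0), (0, 9), (9, 9), (9, 0)])
        assert wm.area_px == 100
        assert wm.source == "manual_polygon"

    def test_square_minus_concentric_square(self):
        img = _img(np.zeros((20, 20)))
        outer = [(0, 0), (0, 9), (9, 9), (9, 0)]
        inner = [(3, 3), (3, 6), (6, 6), (6, 3)]
        full = manual_mask(img, outer).area_px
        hole = manual_mask(img, inner).area_px
        wm = manual_mask(img, outer, exclusions=[inner])
        assert wm.area_px == full - hole

    @pytest.mark.parametrize("poly", [
        [(0, 0), (0, 4), (4, 0)],
        [(1, 1), (2, 8), (8, 5), (6, 1)],
        [(0, 3), (4, 9), (9, 4), (5, 0), (2, 0)],
    ])
    def test_matches_point_in_polygon_enumeration(self, poly):
        img = _img(np.zeros((12, 12)))
        wm = manual_mask(img, poly)
        expected = {(r, c) for r in range(12) for c in range(12)
                    if _point_in_polygon(r, c, poly)}
        got = {tuple(p) for p in np.argwhere(wm.mask)}
        assert got == expected

    def test_self_intersecting_rejected(self):
        img = _img(np.zeros((12, 12)))
        with pytest.raises(GeometryError):
            manual_mask(img, [(0, 0), (9, 9), (0, 9), (9, 0)])

    def test_too_few_vertices(self):
        with pytest.raises(GeometryError):
            manual_mask(_img(np.zeros((5, 5))), [(0, 0), (1, 1)])


class TestWormLength:
    def test_straight_bar(self, mask_factory):
        bar = np.zeros((20, 210), dtype=bool)
        bar[7:13, 5:205] = True  # 200 x 6 px
        length = worm_length(mask_factory(bar), pixel_size_um=1.0)
        assert length == pytest.approx(199, abs=6)

    def test_rotation_symmetry(self, mask_factory):
        # odd width: even-width bars have a half-pixel centerline ambiguity
        bar = np.zeros((21, 210), dtype=bool)
        bar[7:14, 5:205] = True
        a = worm_length(mask_factory(bar), 1.0)
        b = worm_length(mask_factory(np.rot90(bar).copy()), 1.0)
        assert abs(a - b) / a < 0.01

    def test_sinusoid_matches_arc_length(self):
        spec = SceneSpec(seed=1, background_sd=0, shot_noise_gain=0)
        _, truth = render_scene(spec)
        wm = WormMask(mask=truth.body_mask, label="w", source="manual_polygon")
        length = worm_length(wm, spec.pixel_size_um)
        assert length == pytest.approx(truth.arc_length_um, rel=0.05)

    def test_empty_mask_errors(self, mask_factory):
        with pytest.raises(ValueError):
            worm_length(mask_factory(np.zeros((5, 5), dtype=bool)), 1.0)
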