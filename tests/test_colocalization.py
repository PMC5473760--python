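"""High-pass filtering, percentile selection, and Sørensen–Dice overlap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from wormscatter import (Image, WormMask, coloc_pipeline, dice, highpass,
                         render_coloc_pair, top_percentile_mask)
from wormscatter.illumination import GeometryError


def _img(arr, modality="darkfield"):
    return Image(pixels=np.asarray(arr, dtype=float), bit_depth=16, modality=modality)


def _wm(mask):
    return WormMask(mask=np.asarray(mask, dtype=bool), label="w", source="manual_polygon")


class TestHighpass:
    def test_constant_image_zero_inside_mask(self, mask_factory):
        mask = np.zeros((32, 32), dtype=bool)
        mask[4:28, 4:28] = True
        out = highpass(_img(np.full((32, 32), 91.0)), _wm(mask), sigma_px=2)
        assert np.allclose(out[mask], 0, atol=1e-9)
        assert np.all(out[~mask] == 0)

    def test_impulse_response_shape(self):
        arr = np.full((33, 33), 10.0)
        arr[16, 16] = 200.0
        mask = np.ones((33, 33), dtype=bool)
        out = highpass(_img(arr), _wm(mask), sigma_px=2)
        assert out[16, 16] == out.max()
        # negative moat around the impulse
        assert out[16, 12] < 0 and out[12, 16] < 0

    def test_matches_discrete_convolution_oracle(self, rng):
        """Mask-aware high-pass equals an explicit renormalized-kernel loop."""
        arr = rng.integers(0, 500, size=(16, 16)).astype(float)
        mask = rng.random((16, 16)) > 0.3
        mask[0, 0] = True
        sigma = 1.2
        # extract the exact truncated kernel scipy uses
        radius = int(4.0 * sigma + 0.5)
        impulse = np.zeros(2 * radius + 1)
        impulse[radius] = 1.0
        k1 = ndimage.gaussian_filter1d(impulse, sigma, mode="constant", truncate=4.0)
        k2 = np.outer(k1, k1)
        expected = np.zeros((16, 16))
        for r in range(16):
            for c in range(16):
                if not mask[r, c]:
                    continue
                wsum, vsum = 0.0, 0.0
                for dr in range(-radius, radius + 1):
                    for dc in range(-radius, radius + 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < 16 and 0 <= cc < 16 and mask[rr, cc]:
                            w = k2[dr + radius, dc + radius]
                            wsum += w
                            vsum += w * arr[rr, cc]
                expected[r, c] = arr[r, c] - vsum / wsum
        got = highpass(_img(arr), _wm(mask), sigma_px=sigma)
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_kernel_exceeding_frame_errors(self):
        with pytest.raises(ValueError):
            highpass(_img(np.zeros((10, 10))), _wm(np.ones((10, 10))), sigma_px=50)


class TestTopPercentile:
    def test_exact_20_of_100_distinct(self, rng):
        mask = np.zeros((10, 10), dtype=bool)
        mask[:, :] = True
        vals = rng.permutation(100).astype(float).reshape(10, 10)
        sel = top_percentile_mask(vals, _wm(mask), pct=80)
        assert sel.sum() == 20

    def test_all_ties_select_nothing(self):
        mask = np.ones((5, 5), dtype=bool)
        sel = top_percentile_mask(np.full((5, 5), 3.0), _wm(mask), pct=80)
        assert sel.sum() == 0

    def test_matches_sort_oracle(self):
        """Strict-above selection at the interpolated percentile, values 1..10."""
        vals = np.arange(1.0, 11.0).reshape(2, 5)
        mask = np.ones((2, 5), dtype=bool)
        sel = top_percentile_mask(vals, _wm(mask), pct=50)
        thr = np.percentile(np.arange(1.0, 11.0), 50)  # sort-based linear interp
        expected = vals > thr
        np.testing.assert_array_equal(sel, expected)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            top_percentile_mask(np.zeros((4, 4)), _wm(np.zeros((4, 4))), pct=80)


class TestDice:
    def test_identical_nonempty(self):
        a = np.zeros((4, 4), dtype=bool)
        a[1:3, 1:3] = True
        assert dice(a, a).qs == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0] = b[3, 3] = True
        assert dice(a, b).qs == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a.flat[:4] = True
        b.flat[2:6] = True
        res = dice(a, b)
        assert (res.n_selected_a, res.n_selected_b, res.n_overlap) == (4, 4, 2)
        assert res.qs == 0.5

    def test_vacuous_agreement_and_empty_vs_nonempty(self):
        e = np.zeros((3, 3), dtype=bool)
        f = np.zeros((3, 3), dtype=bool)
        f[0, 0] = True
        assert dice(e, e.copy()).qs == 1.0
        assert dice(e, f).qs == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(GeometryError):
            dice(np.zeros((2, 2), dtype=bool), np.zeros((3, 3), dtype=bool))

    @given(st.integers(0, 2 ** 16 - 1), st.integers(0, 2 ** 16 - 1))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_bounds(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(16)], dtype=bool).reshape(4, 4)
        b = np.array([(bits_b >> i) & 1 for i in range(16)], dtype=bool).reshape(4, 4)
        assert dice(a, b).qs == dice(b, a).qs
        assert 0.0 <= dice(a, b).qs <= 1.0


class TestPipeline:
    def test_identical_channels_full_overlap(self):
        df, _, truth = render_coloc_pair(seed=4)
        wm = _wm(truth.body_mask)
        same = Image(pixels=df.pixels, bit_depth=16, modality="fluor_red")
        res = coloc_pipeline(df, same, wm)
        assert res.qs == 1.0
        assert res.percentile == 80.0

    def test_rank_invariance_under_monotone_transform(self, rng):
        """Selection depends only on ranks of the filtered values."""
        mask = np.ones((20, 20), dtype=bool)
        vals = rng.normal(size=(20, 20))
        sel = top_percentile_mask(vals, _wm(mask), pct=80)
        sel_t = top_percentile_mask(np.exp(3 * vals), _wm(mask), pct=80)
        np.testing.assert_array_equal(sel, sel_t)

    def test_coincident_puncta_high_overlap(self):
        df, fl, truth = render_coloc_pair(seed=11, mode="coincident")
        res = coloc_pipeline(df, fl, _wm(truth.body_mask))
        assert res.qs >= 0.7

    def test_independent_puncta_near_null(self):
        qs = []
        for seed in range(15):
            df, fl, truth = render_coloc_pair(seed=seed, mode="independent")
            qs.append(coloc_pipeline(df, fl, _wm(truth.body_mask)).qs)
        assert np.mean(qs) == pytest.approx(0.2, abs=0.05)
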