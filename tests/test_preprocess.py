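"""Intensity conditioning, cropping, resampling and the inverse chain."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from pseudoct.phantom import CTVolume
from pseudoct.physics import PETImage
from pseudoct.preprocess import (
    PreprocessConfig, build_slice_pairs, crop_bounding_box, inverse_softsign,
    normalize_ct, normalize_pet, rescale_to_hu, resample_bilinear,
    restore_to_source, softsign)

CFG = PreprocessConfig(target_matrix=(32, 32))
SPACING = (3.0, 3.0, 6.0)


class TestIntensity:
    @pytest.mark.parametrize("bq,expected", [(6000.0, 1.0), (0.0, 0.0), (3000.0, 0.5)])
    def test_pet_scaling(self, bq, expected):
        assert normalize_pet(np.array([bq]), CFG)[0] == pytest.approx(expected)

    def test_pet_rejects_negative(self):
        with pytest.raises(ValueError):
            normalize_pet(np.array([-1.0]), CFG)

    @pytest.mark.parametrize("hu,expected", [(-1000.0, 0.0), (1000.0, 1.0), (0.0, 0.5)])
    def test_ct_offset_and_scale(self, hu, expected):
        assert normalize_ct(np.array([hu]), CFG)[0] == pytest.approx(expected)

    def test_hu_round_trip_through_softsign(self):
        hu = np.array([317.2, -950.0, 1234.5])
        y = softsign(normalize_ct(hu, CFG))
        back = rescale_to_hu(y, CFG)
        np.testing.assert_allclose(back, hu, atol=1e-6)


class TestSoftsign:
    @pytest.mark.parametrize("x,y", [(0.0, 0.0), (1.0, 0.5), (-1.0, -0.5)])
    def test_closed_form_points(self, x, y):
        assert softsign(np.array([x]))[0] == pytest.approx(y)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(arrays(np.float64, (8,), elements=st.floats(-50, 50)))
    def test_round_trip_is_exact(self, x):
        np.testing.assert_allclose(inverse_softsign(softsign(x)), x, atol=1e-9)

    def test_inverse_domain_error(self):
        with pytest.raises(ValueError):
            inverse_softsign(np.array([1.0]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(-100, 100), st.floats(-100, 100))
    def test_strictly_monotone(self, a, b):
        if a < b:
            assert softsign(np.array([a]))[0] < softsign(np.array([b]))[0]


class TestCrop:
    def test_box_matches_brute_force_scan(self):
        v = np.zeros((40, 40, 2))
        v[10:21, 5:16, :] = 1.0
        cfg = replace(CFG, crop_margin=0)
        _, box = crop_bounding_box(v, cfg)
        assert box == (10, 5, 21, 16)

    def test_all_foreground_gives_full_image(self):
        v = np.ones((12, 15, 1))
        _, box = crop_bounding_box(v, replace(CFG, crop_margin=0))
        assert box == (0, 0, 12, 15)

    def test_margin_clipped_at_edges(self):
        v = np.zeros((10, 10, 1))
        v[0:3, 7:10, 0] = 1.0
        _, box = crop_bounding_box(v, replace(CFG, crop_margin=2))
        assert box == (0, 5, 5, 10)

    def test_empty_foreground_raises(self):
        with pytest.raises(ValueError, match="threshold"):
            crop_bounding_box(np.zeros((8, 8, 1)), CFG)


class TestResample:
    def test_identity_when_shapes_match(self, rng):
        s = rng.normal(size=(20, 17))
        np.testing.assert_array_equal(resample_bilinear(s, (20, 17)), s)

    def test_constant_stays_constant(self):
        out = resample_bilinear(np.full((9, 9), 3.7), (21, 13))
        np.testing.assert_allclose(out, 3.7)

    def test_smooth_round_trip_error_small(self):
        r = np.linspace(0, np.pi, 24)
        s = np.outer(np.sin(r), np.cos(r / 2))
        up = resample_bilinear(s, (48, 48))
        back = resample_bilinear(up, (24, 24))
        assert np.abs(back - s).max() < 0.01 * np.ptp(s)

    def test_restore_fills_outside_with_air_constant(self):
        pred = np.full((8, 8), 0.25)
        out = restore_to_source(pred, (2, 3, 10, 11), (16, 16), fill_value=0.0)
        assert out.shape == (16, 16)
        np.testing.assert_allclose(out[2:10, 3:11], 0.25)
        assert (out[0, :] == 0.0).all() and (out[:, -1] == 0.0).all()


class TestSlicePairs:
    def _volumes(self, rng, n=40, nz=8):
        pet = np.zeros((n, n, nz))
        ct = np.full((n, n, nz), -1000.0)
        pet[8:40 - 8, 8:40 - 8, :] = rng.uniform(500, 9000, size=(24, 24, nz))
        ct[8:40 - 8, 8:40 - 8, :] = rng.uniform(-200, 1400, size=(24, 24, nz))
        return (PETImage(voxels=pet, spacing=SPACING),
                CTVolume(voxels=ct, spacing=SPACING))

    def test_one_pair_per_axial_slice_inside_softsign_range(self, rng):
        pet, ct = self._volumes(rng)
        pairs = build_slice_pairs(pet, ct, CFG)
        assert len(pairs) == 8
        for p in pairs:
            assert p.input_slice.shape == CFG.target_matrix
            assert p.target_slice.shape == CFG.target_matrix
            assert np.abs(p.input_slice).max() < 1
            assert np.abs(p.target_slice).max() < 1

    def test_crop_box_shared_between_modalities_and_slices(self, rng):
        pet, ct = self._volumes(rng)
        pairs = build_slice_pairs(pet, ct, CFG)
        assert len({p.crop_box for p in pairs}) == 1

    def test_grid_mismatch_rejected(self, rng):
        pet, ct = self._volumes(rng)
        bad_ct = CTVolume(voxels=ct.voxels[:-2], spacing=SPACING)
        with pytest.raises(ValueError, match="differ"):
            build_slice_pairs(pet, bad_ct, CFG)

    def test_full_inverse_chain_reproduces_cropped_ct(self, rng):
        """normalise → crop → resample → Softsign, then the inverse chain,
        agrees with the original CT to far below 1 HU at matched size."""
        pet, ct = self._volumes(rng)
        pet_n = normalize_pet(pet, CFG)
        _, box = crop_bounding_box(pet_n, CFG)
        r0, c0, r1, c1 = box
        cfg = replace(CFG, target_matrix=(r1 - r0, c1 - c0))  # matched resolution
        pairs = build_slice_pairs(pet, ct, cfg)
        for p in pairs:
            hu = rescale_to_hu(p.target_slice, cfg)
            restored = restore_to_source(
                normalize_ct(hu, cfg), p.crop_box, ct.voxels.shape[:2])
            hu_full = restored * cfg.ct_scale - cfg.ct_offset
            truth = ct.voxels[..., p.slice_index]
            np.testing.assert_allclose(hu_full[r0:r1, c0:c1],
                                       truth[r0:r1, c0:c1], atol=1e-6)
            # outside the box the canvas is air
            assert hu_full[0, 0] == pytest.approx(-1000.0)
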