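"""Registration, warping, and groupwise mean-frame construction."""

import numpy as np
import pytest
from scipy import ndimage

from stvquant import (DeformationField, PhantomSpec, Volume, binarize_mean_mask,
                      build_mean_frame, generate_cohort, identity_field,
                      invert_field, mask_like, register_pair,
                      translation_field, warp_mask, warp_volume)
from stvquant.phantom import random_displacement, warp_arrays

SP = (0.5, 0.5, 3.3)


def interior(arr, border=(4, 4, 1)):
    return arr[border[0]:-border[0], border[1]:-border[1],
               border[2]:-border[2]]


class TestDeformationField:
    def test_rejects_bad_shape(self):
        with pytest.raises(ValueError):
            DeformationField(np.zeros((4, 4, 4)), SP)

    def test_identity_field_has_unit_jacobian(self):
        f = identity_field((8, 8, 4), SP)
        assert np.allclose(f.jacobian_determinant(), 1.0)

    def test_smooth_random_field_is_diffeomorphic(self):
        rng = np.random.default_rng(0)
        d = random_displacement((32, 32, 8), SP, 1.0, (6, 6, 1), rng)
        f = DeformationField(d, SP)
        assert f.jacobian_determinant().min() > 0


class TestRegisterPair:
    def test_self_registration_is_identity(self, textured_volume):
        f = register_pair(textured_volume, textured_volume)
        max_vox = np.abs(f.disp).max(axis=(0, 1, 2)) / np.array(SP)
        assert np.all(max_vox < 0.1)

    def test_known_translation_recovered(self, textured_volume):
        shift_vox = (2, 3, 0)
        shifted = Volume(np.roll(textured_volume.data, shift_vox, (0, 1, 2)),
                         SP)
        f = register_pair(textured_volume, shifted)
        mean_mm = interior(f.disp).reshape(-1, 3).mean(axis=0)
        # resampling convention: fixed + d lands in moving, so d = -shift
        err_vox = np.abs(mean_mm / np.array(SP) + np.array(shift_vox))
        assert np.all(err_vox < 0.5)

    def test_known_smooth_warp_recovered(self, textured_volume):
        rng = np.random.default_rng(42)
        d = random_displacement(textured_volume.shape, SP, 1.0, (8, 8, 1.5), rng)
        warped = Volume(warp_arrays(textured_volume.data, d, SP, 1), SP)
        f = register_pair(textured_volume, warped)
        epe_vox = np.sqrt((((f.disp - d) / np.array(SP)) ** 2).sum(-1))
        # end-point error over the interior, where the FFD has image support
        assert interior(epe_vox).mean() < 1.0


class TestWarping:
    def test_identity_field_leaves_mask_unchanged(self, base_phantom):
        _, mask, _ = base_phantom
        f = identity_field(mask.shape, SP)
        out = warp_mask(mask, f, "to_reference")
        assert np.array_equal(out.data, mask.data)

    def test_pure_translation_shifts_mask_exactly(self, base_phantom):
        _, mask, _ = base_phantom
        f = translation_field(mask.shape, SP, (2 * SP[0], 0, 0))
        out = warp_mask(mask, f, "to_reference")
        # out(i) = mask(i + 2) => contents move toward lower indices
        expected = np.zeros_like(mask.data)
        expected[:-2] = mask.data[2:]
        assert np.array_equal(out.data[:-2], expected[:-2])

    def test_warp_then_inverse_warp_recovers_blob(self):
        shape = (48, 48, 10)
        blob = np.zeros(shape)
        xs, ys, zs = np.indices(shape)
        blob[((xs - 24) ** 2 + (ys - 24) ** 2 + ((zs - 5) * 4) ** 2) < 130] = 1
        vol = Volume(np.zeros(shape), SP)
        mask = mask_like(vol, blob)
        rng = np.random.default_rng(9)
        d = random_displacement(shape, SP, 1.0, (6, 6, 1), rng)
        f = DeformationField(d, SP)
        there = warp_mask(mask, f, "to_reference")
        back = warp_mask(there, f, "to_subject")
        inter = (back.data * mask.data).sum()
        dice = 2 * inter / (back.data.sum() + mask.data.sum())
        assert dice >= 0.9

    def test_direction_validation(self, base_phantom):
        _, mask, _ = base_phantom
        f = identity_field(mask.shape, SP)
        with pytest.raises(ValueError):
            warp_mask(mask, f, "sideways")
        small = identity_field((8, 8, 4), SP)
        with pytest.raises(ValueError):
            warp_mask(mask, small, "to_reference")

    def test_near_volume_preserving_warp_preserves_count(self, base_phantom):
        _, mask, _ = base_phantom
        rng = np.random.default_rng(12)
        # gentle, well-resolved field whose Jacobian stays in [0.8, 1.25]
        d = random_displacement(mask.shape, SP, 0.15, (10, 10, 2), rng)
        f = DeformationField(d, SP)
        jac = f.jacobian_determinant()
        assert 0.8 < jac.min() and jac.max() < 1.25
        out = warp_mask(mask, f, "to_reference")
        assert abs(out.data.sum() - mask.data.sum()) / mask.data.sum() < 0.15

    def test_invert_field_composes_to_identity(self):
        rng = np.random.default_rng(13)
        d = random_displacement((32, 32, 8), SP, 1.0, (6, 6, 1), rng)
        f = DeformationField(d, SP)
        inv = invert_field(f)
        # d(x + e(x)) + e(x) ~ 0
        idx = np.indices(f.shape).astype(float)
        coords = np.stack([idx[k] + inv.disp[..., k] / SP[k] for k in range(3)])
        comp = np.stack([ndimage.map_coordinates(d[..., c], coords, order=1,
                                                 mode="nearest")
                         for c in range(3)], axis=-1) + inv.disp
        assert interior(np.abs(comp)).max() < 0.1


class TestBinarizeMeanMask:
    def test_threshold_arithmetic(self, base_phantom):
        vol = base_phantom[0]
        ones = mask_like(vol, np.ones(vol.shape), kind="probabilistic")
        assert binarize_mean_mask(ones, 0.5).data.all()
        uniform = mask_like(vol, np.full(vol.shape, 0.3), kind="probabilistic")
        assert binarize_mean_mask(uniform, 0.25).data.all()
        assert binarize_mean_mask(uniform, 0.5).voxel_count == 0

    def test_tau_out_of_range(self, base_phantom):
        prob = mask_like(base_phantom[0], np.zeros(base_phantom[0].shape),
                         kind="probabilistic")
        for tau in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                binarize_mean_mask(prob, tau)

    def test_threshold_nesting_monotone(self, base_phantom):
        rng = np.random.default_rng(3)
        prob = mask_like(base_phantom[0], rng.random(base_phantom[0].shape),
                         kind="probabilistic")
        loose = binarize_mean_mask(prob, 0.2).data
        tight = binarize_mean_mask(prob, 0.6).data
        assert np.all(tight <= loose)


class TestBuildMeanFrame:
    def test_requires_two_subjects(self, base_phantom):
        vol, mask, _ = base_phantom
        with pytest.raises(ValueError):
            build_mean_frame([vol], [mask])

    def test_identical_subjects_reproduce_input(self, base_phantom):
        vol, mask, _ = base_phantom
        frame = build_mean_frame([vol, vol, vol], [mask, mask, mask],
                                 iterations=1)
        # registration of identical images is the identity, so the mean frame
        # is the input up to interpolation tolerance
        scale = np.abs(vol.data).max()
        assert np.allclose(frame.mean_image.data, vol.data,
                           atol=1e-3 * scale)
        assert np.allclose(frame.mean_mask.data, mask.data, atol=1e-6)
        for f in frame.fields:
            assert np.abs(f.disp).max() < 1e-3

    def test_disjoint_cubes_average_to_half(self):
        # two disjoint unit-cube masks under zero deformation: warping is the
        # identity, so the mean mask is 0.5 on each cube
        shape = (16, 16, 6)
        vol = Volume(np.random.default_rng(0).normal(size=shape), (1, 1, 1))
        m1 = np.zeros(shape)
        m2 = np.zeros(shape)
        m1[4:6, 4:6, 2:4] = 1
        m2[10:12, 10:12, 2:4] = 1
        field = identity_field(shape, (1, 1, 1))
        warped = [warp_mask(mask_like(vol, m), field, "to_reference").data
                  for m in (m1, m2)]
        mean = np.mean(warped, axis=0)
        assert set(np.unique(mean[m1.astype(bool)])) == {0.5}
        assert set(np.unique(mean[m2.astype(bool)])) == {0.5}

    def test_phantom_cohort_mean_mask_overlaps_all_subjects(self, phantom_spec):
        cohort = generate_cohort(phantom_spec, 4, seed=21)
        images = [c[0] for c in cohort]
        masks = [c[1] for c in cohort]
        frame = build_mean_frame(images, masks, iterations=2)
        mean_bin = binarize_mean_mask(frame.mean_mask, 0.25)
        for mk, f in zip(masks, frame.fields):
            warped_gt = warp_mask(mk, f, "to_reference")
            inter = (mean_bin.data * warped_gt.data).sum()
            dice = 2 * inter / (mean_bin.data.sum() + warped_gt.data.sum())
            assert dice >= 0.5
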