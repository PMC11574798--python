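"""Rigid, demons and refinement registration plus field algebra."""

import numpy as np
import pytest
from scipy import ndimage

from reharm.core import DisplacementField, GeometryError
from reharm.metrics import dice
from reharm.phantom import (
    GaussianBump,
    PhantomSpec,
    TimepointDistortion,
    generate_subject,
    structure_mask,
)
from reharm.registration import (
    RegistrationParams,
    body_mask,
    compose,
    invert_field,
    jacobian_positive_fraction,
    refine_near_prostate,
    register_demons,
    register_longitudinal,
    register_rigid,
    warp,
)

PARAMS = RegistrationParams(seed=2)


def bump_field(geometry, center, sigma, amplitude):
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in geometry.shape], indexing="ij"), axis=-1
    )
    pts = geometry.index_to_physical(idx.reshape(-1, 3)).reshape(geometry.shape + (3,))
    r2 = ((pts - np.asarray(center)) ** 2).sum(-1, keepdims=True)
    data = np.asarray(amplitude) * np.exp(-r2 / (2.0 * sigma**2))
    return DisplacementField(data, geometry.spacing, geometry.origin, geometry.direction)


class TestRigid:
    def test_self_registration_is_identity(self, zero_noise_subject):
        res = register_rigid(zero_noise_subject.volume, zero_noise_subject.volume, PARAMS)
        assert np.abs(res.translation_of_center).max() < 0.1
        assert np.abs(res.rotation_angles_deg).max() < 0.1

    def test_translation_recovered_within_half_mm(self):
        spec = PhantomSpec(
            noise_sd=0.0, seed=4, distortions=[TimepointDistortion(translation=(4.0, -2.0, 0.0))]
        ).scaled((64, 64, 32))
        t1, t2 = generate_subject(spec, 2)
        res = register_rigid(t1.volume, t2.volume, PARAMS)
        err = res.translation_of_center - t2.truth.expected_registration_translation()
        assert np.abs(err).max() < 0.5

    def test_inplane_rotation_recovered_within_one_degree(self):
        spec = PhantomSpec(
            noise_sd=0.0, seed=4, distortions=[TimepointDistortion(rotation_deg=5.0)]
        ).scaled((64, 64, 32))
        t1, t2 = generate_subject(spec, 2)
        res = register_rigid(t1.volume, t2.volume, PARAMS)
        assert res.rotation_angles_deg[2] == pytest.approx(5.0, abs=1.0)
        assert np.abs(res.rotation_angles_deg[:2]).max() < 1.0


class TestDemons:
    def test_self_registration_near_zero_field(self, zero_noise_subject):
        fld, _ = register_demons(zero_noise_subject.volume, zero_noise_subject.volume, PARAMS)
        max_vox = fld.magnitude().max() / min(zero_noise_subject.volume.spacing)
        assert max_vox <= 0.2

    def test_six_mm_bump_recovered(self):
        # |amplitude| = 6 mm single bump, zero noise, native grid
        spec = PhantomSpec(
            noise_sd=0.0,
            seed=9,
            distortions=[
                TimepointDistortion(bumps=[GaussianBump((48, 52, 48), 20.0, (4.0, 3.5, -2.6))])
            ],
        )
        t1, t2 = generate_subject(spec, 2)
        fld, trace = register_demons(t1.volume, t2.volume, PARAMS)
        truth = t2.truth.recovery_field(t1.volume.geometry)
        inside = body_mask(t1.volume)
        mean_err = np.linalg.norm(fld.data - truth.data, axis=-1)[inside].mean()
        assert mean_err <= 1.5
        warped = warp(t2.mask, fld)
        dsc = dice(structure_mask(t1.mask, "prostate"), structure_mask(warped, "prostate"))
        assert dsc >= 0.95
        assert all(level["mse_after"] <= level["mse_before"] for level in trace)

    def test_geometry_mismatch_rejected(self, zero_noise_subject):
        other = PhantomSpec(noise_sd=0.0).scaled((32, 32, 16))
        t1 = generate_subject(other, 2)[0]
        with pytest.raises(GeometryError):
            register_demons(zero_noise_subject.volume, t1.volume, PARAMS)


class TestRefinement:
    def test_aligned_pair_gives_near_zero_field(self, zero_noise_subject):
        vol, mask = zero_noise_subject.volume, zero_noise_subject.mask
        fld = refine_near_prostate(vol, vol, structure_mask(mask, "prostate"), PARAMS)
        assert fld.magnitude().max() / min(vol.spacing) <= 0.2

    def test_local_shift_improves_gtv_overlap(self):
        spec = PhantomSpec(noise_sd=10.0, seed=12)
        t1 = generate_subject(spec, 2)[0]
        geom = t1.volume.geometry
        residual = bump_field(geom, (51, 60, 46), 12.0, (2.0, 1.2, 0.0))
        moved_vol = warp(t1.volume, residual)
        moved_mask = warp(t1.mask, residual)
        gtv_ref = structure_mask(t1.mask, "GTV")
        before = dice(gtv_ref, structure_mask(moved_mask, "GTV"))
        fld = refine_near_prostate(
            t1.volume, moved_vol, structure_mask(t1.mask, "prostate"), PARAMS
        )
        after = dice(gtv_ref, structure_mask(warp(moved_mask, fld), "GTV"))
        assert after > before

    def test_displacement_zero_far_from_prostate(self, distorted_pair):
        t1, t2 = distorted_pair
        rigid = register_rigid(t1.volume, t2.volume, PARAMS)
        prostate = structure_mask(t1.mask, "prostate")
        fld = refine_near_prostate(t1.volume, rigid.resampled, prostate, PARAMS)
        dist = ndimage.distance_transform_edt(~prostate, sampling=t1.volume.spacing)
        margin = PARAMS.dilation_radius_mm + PARAMS.control_point_spacing_mm
        far = dist > margin + 2 * max(t1.volume.spacing)
        assert np.all(fld.magnitude()[far] == 0.0)

    def test_empty_mask_rejected(self, zero_noise_subject):
        vol = zero_noise_subject.volume
        with pytest.raises(ValueError, match="empty"):
            refine_near_prostate(vol, vol, np.zeros(vol.data.shape, bool), PARAMS)


class TestFieldAlgebra:
    def test_compose_with_zero_is_identity(self, rng):
        geom = DisplacementField(rng.normal(0, 1, (8, 8, 8, 3)), (1, 1, 2))
        zero = DisplacementField.zeros(geom.geometry)
        np.testing.assert_array_equal(compose(geom, zero).data, geom.data)
        np.testing.assert_allclose(compose(zero, geom).data, geom.data, atol=1e-12)

    def test_constant_fields_compose_to_sum(self):
        geom = DisplacementField.zeros(
            PhantomSpec().scaled((16, 16, 8)).geometry
        ).geometry
        u = DisplacementField(np.full((16, 16, 8, 3), (1.0, 2.0, -1.0)), geom.spacing)
        v = DisplacementField(np.full((16, 16, 8, 3), (0.5, -1.0, 2.0)), geom.spacing)
        np.testing.assert_allclose(compose(u, v).data, u.data + v.data, atol=1e-9)

    def test_compose_matches_sequential_warping(self, zero_noise_subject):
        vol = zero_noise_subject.volume.with_data(
            ndimage.gaussian_filter(zero_noise_subject.volume.data, 2.0)
        )
        geom = vol.geometry
        f = bump_field(geom, (48, 48, 48), 20.0, (3.0, 1.0, -2.0))
        g = bump_field(geom, (40, 56, 40), 16.0, (-1.0, 2.0, 1.0))
        lhs = warp(vol, compose(f, g))
        rhs = warp(warp(vol, f), g)
        scale = vol.data.max() - vol.data.min()
        assert np.abs(lhs.data - rhs.data).mean() < 0.01 * scale

    def test_invert_field_round_trip(self, zero_noise_subject):
        geom = zero_noise_subject.volume.geometry
        f = bump_field(geom, (48, 48, 48), 20.0, (3.0, 1.0, -2.0))
        inv = invert_field(f)
        residual = compose(outer=f, inner=inv)  # v(x) + f(x + v(x)) == 0
        assert np.linalg.norm(residual.data, axis=-1).max() < 1e-6

    def test_geometry_mismatch_rejected(self):
        a = DisplacementField(np.zeros((8, 8, 8, 3)), (1, 1, 1))
        b = DisplacementField(np.zeros((8, 8, 8, 3)), (2, 2, 2))
        with pytest.raises(GeometryError):
            compose(a, b)


class TestWarp:
    def test_zero_field_identity_for_masks(self, zero_noise_subject):
        mask = zero_noise_subject.mask
        zero = DisplacementField.zeros(mask.geometry)
        np.testing.assert_array_equal(warp(mask, zero).data, mask.data)

    def test_constant_shift_preserves_label_counts(self):
        import numpy as np

        from reharm.core import LabelMask

        data = np.zeros((16, 16, 8), np.uint16)
        data[4:8, 4:8, 2:5] = 3
        mask = LabelMask(data, (1, 1, 2), label_table={3: "cube"})
        shift = DisplacementField(np.full((16, 16, 8, 3), (2.0, 0.0, 0.0)), (1, 1, 2))
        out = warp(mask, shift)
        assert out.voxel_count(3) == mask.voxel_count(3)
        assert set(np.unique(out.data)) <= set(np.unique(mask.data))

    def test_unknown_interpolation_rejected(self, zero_noise_subject):
        zero = DisplacementField.zeros(zero_noise_subject.volume.geometry)
        with pytest.raises(ValueError, match="interpolation"):
            warp(zero_noise_subject.volume, zero, interpolation="cubic")


class TestFullPipeline:
    def test_translation_dice_and_jacobian_recovery(self, distorted_pair):
        t1, t2 = distorted_pair
        res = register_longitudinal(
            t1.volume, t2.volume, structure_mask(t1.mask, "prostate"), PARAMS
        )
        err = res.rigid.translation_of_center - t2.truth.expected_registration_translation()
        assert np.abs(err).max() < 0.5
        warped_mask = warp(t2.mask, res.composed_field)
        dsc = dice(structure_mask(t1.mask, "prostate"), structure_mask(warped_mask, "prostate"))
        assert dsc >= 0.90
        assert res.qc["jacobian_positive_fraction"] >= 0.99

    def test_composed_field_consistent_with_parts(self, distorted_pair):
        t1, t2 = distorted_pair
        res = register_longitudinal(
            t1.volume, t2.volume, structure_mask(t1.mask, "prostate"), PARAMS
        )
        direct = warp(t2.volume, res.composed_field)
        np.testing.assert_allclose(direct.data, res.warped.data, atol=1e-9)
        # deformable part alone has positive Jacobian nearly everywhere
        inside = body_mask(t1.volume)
        assert jacobian_positive_fraction(res.demons_field, inside) >= 0.99
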