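import numpy as np
import pytest

from oartmotion.geometry import (
    BinaryMask,
    DisplacementField,
    ImageGrid,
    ScalarVolume,
)
from oartmotion.registration import (
    RegistrationConfig,
    RegistrationDomainError,
    compose_fields,
    deformable_register,
    invert_field,
    rigid_register,
    warp_mask,
)

FAST = RegistrationConfig(levels=3, iterations=(40, 25, 8), rigid_first=False)


def shifted_copy(vol: ScalarVolume, shift_mm) -> ScalarVolume:
    """Same voxel data placed shift_mm further along in physical space, so
    moving(x) = fixed(x - shift)."""
    g = vol.grid
    origin = tuple(np.asarray(g.origin) + np.asarray(shift_mm))
    return ScalarVolume(ImageGrid(origin, g.spacing, g.size, g.direction), vol.values.copy())


class TestRigid:
    def test_identity_on_same_image(self, small_fraction):
        t = rigid_register(small_fraction.pcbct, small_fraction.pcbct)
        assert np.allclose(t.rotation_rad, 0, atol=np.deg2rad(0.1))
        assert np.allclose(t.translation_mm, 0, atol=0.1)

    def test_recovers_known_cranial_shift(self, small_fraction):
        moving = shifted_copy(small_fraction.pcbct, (0, 0, 5.0))
        t = rigid_register(small_fraction.pcbct, moving)
        assert np.allclose(t.translation_mm, (0, 0, 5.0), atol=0.5)

    def test_mutual_information_rescale_invariance(self, small_fraction):
        """MI sees through affine intensity changes between the two scans."""
        moving = shifted_copy(small_fraction.pcbct, (0, 0, 4.0))
        moving.values = moving.values * 2.5 + 100.0
        t = rigid_register(small_fraction.pcbct, moving, "mutual_information")
        assert np.allclose(t.translation_mm, (0, 0, 4.0), atol=0.5)

    def test_disjoint_extents_rejected(self, unit_grid):
        a = ScalarVolume(unit_grid, np.zeros(unit_grid.size))
        far = ImageGrid((500, 500, 500), (1, 1, 1), (20, 20, 20))
        b = ScalarVolume(far, np.zeros(far.size))
        with pytest.raises(RegistrationDomainError):
            rigid_register(a, b)


class TestDeformable:
    def test_identity_pair_near_zero_field(self, small_fraction):
        res = deformable_register(small_fraction.pcbct, small_fraction.pcbct, FAST)
        mag = res.dvf.magnitude()
        assert np.percentile(mag, 99) < 0.5

    def test_phantom_recovery_dsc_and_field_error(self, small_fraction):
        """Recovered motion meets the clinical DSC validation bar and tracks
        the ground-truth field inside the bladder."""
        rec = small_fraction
        res = deformable_register(
            rec.vcbct, rec.pcbct, FAST,
            fixed_mask=rec.bladder_v, moving_mask=rec.bladder_p,
        )
        assert res.validation_dsc >= 0.9
        err = np.linalg.norm(res.dvf.vectors - rec.truth_dvf.vectors, axis=-1)
        voxel = min(rec.pcbct.grid.spacing)
        assert err[rec.bladder_v.values].mean() <= voxel

    def test_validation_dsc_reproducible_from_field(self, small_fraction):
        from oartmotion.contour_metrics import dice

        rec = small_fraction
        res = deformable_register(
            rec.vcbct, rec.pcbct, FAST,
            fixed_mask=rec.bladder_v, moving_mask=rec.bladder_p,
        )
        redone = dice(rec.bladder_v, warp_mask(rec.bladder_p, res.dvf))
        assert redone == pytest.approx(res.validation_dsc, abs=1e-6)

    def test_smoothing_tames_jacobian_spread(self, small_fraction):
        """Stronger field regularization never widens the Jacobian range."""
        from oartmotion.deformation import jacobian_map

        rec = small_fraction
        spreads = []
        for sigma in (2.0, 4.0, 8.0):
            cfg = RegistrationConfig(
                levels=3, iterations=(40, 25, 8), rigid_first=False,
                smoothing_sigmas=(sigma,) * 3,
            )
            res = deformable_register(rec.vcbct, rec.pcbct, cfg)
            det = jacobian_map(res.dvf).values
            spreads.append(det.max() - det.min())
        assert spreads[1] <= spreads[0] + 1e-6
        assert spreads[2] <= spreads[1] + 1e-6


class TestWarpMask:
    def test_zero_field_identity(self, sphere_mask):
        zero = DisplacementField.zero(sphere_mask.grid)
        out = warp_mask(sphere_mask, zero)
        assert np.array_equal(out.values, sphere_mask.values)

    def test_uniform_field_sign_convention(self, unit_grid):
        """d = (0,0,-5): out(x) = mask(x - 5 mm z), i.e. the object appears
        5 mm more cranially in the fixed frame."""
        vals = np.zeros(unit_grid.size, bool)
        vals[5:12, 5:12, 3:9] = True
        mask = BinaryMask(unit_grid, vals)
        field = DisplacementField(unit_grid, np.broadcast_to(
            np.array([0.0, 0.0, -5.0]), (*unit_grid.size, 3)).copy())
        out = warp_mask(mask, field, interpolation="nearest")
        expected = np.zeros(unit_grid.size, bool)
        expected[5:12, 5:12, 8:14] = True
        assert np.array_equal(out.values, expected)

    def test_truth_field_reproduces_verification(self, small_fraction):
        from oartmotion.contour_metrics import dice

        rec = small_fraction
        out = warp_mask(rec.bladder_p, rec.truth_dvf)
        assert dice(rec.bladder_v, out) >= 0.98


class TestFieldAlgebra:
    def test_compose_with_zero(self, small_fraction):
        f = small_fraction.truth_dvf
        zero = DisplacementField.zero(f.grid)
        assert np.allclose(compose_fields(zero, f).vectors, f.vectors, atol=1e-9)
        assert np.allclose(compose_fields(f, zero).vectors, f.vectors, atol=1e-9)

    def test_uniform_translations_add(self, unit_grid):
        a = DisplacementField(unit_grid, np.broadcast_to(
            np.array([1.0, 2.0, 0.5]), (*unit_grid.size, 3)).copy())
        b = DisplacementField(unit_grid, np.broadcast_to(
            np.array([-0.5, 1.0, 2.0]), (*unit_grid.size, 3)).copy())
        comp = compose_fields(b, a)
        interior = comp.vectors[3:-3, 3:-3, 3:-3]
        assert np.allclose(interior, [0.5, 3.0, 2.5], atol=1e-9)

    def test_inverse_composes_to_identity(self, small_fraction):
        f = small_fraction.truth_dvf
        g = invert_field(f)
        resid = compose_fields(f, g).vectors
        mag = np.linalg.norm(resid, axis=-1)
        voxel = min(f.grid.spacing)
        assert np.percentile(mag, 95) < 0.5 * voxel
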