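import numpy as np
import pytest

from oartmotion.contour_metrics import UndefinedMetricError
from oartmotion.dosimetry import (
    DoseMetricSpec,
    Goal,
    compare_plans,
    compute_dvh,
    dose_metric,
    parse_metric,
    warp_dose,
)
from oartmotion.geometry import BinaryMask, DisplacementField, DoseGrid, ImageGrid

from .conftest import ball
from .oracles import dose_metric_bruteforce, dvh_bruteforce


def uniform_field(grid, vec):
    return DisplacementField(grid, np.broadcast_to(np.asarray(vec, float),
                                                   (*grid.size, 3)).copy())


class TestWarpDose:
    def test_zero_field_identity(self, unit_grid):
        rng = np.random.default_rng(0)
        dose = DoseGrid(unit_grid, rng.uniform(0, 10, unit_grid.size))
        out = warp_dose(dose, DisplacementField.zero(unit_grid))
        assert np.allclose(out.dose, dose.dose, atol=1e-6)

    def test_uniform_dose_invariant(self, unit_grid):
        dose = DoseGrid(unit_grid, np.full(unit_grid.size, 8.0))
        f = uniform_field(unit_grid, (1.5, -2.0, 3.0))
        out = warp_dose(dose, f)
        interior = out.dose[4:-4, 4:-4, 4:-4]
        assert np.allclose(interior, 8.0, atol=1e-9)

    def test_linear_ramp_uniform_shift_exact(self, unit_grid):
        """Trilinear warping is exact on a linear dose: shifting by d moves
        the ramp by exactly d."""
        xs, _, _ = unit_grid.coordinate_arrays()
        dose = DoseGrid(unit_grid, xs + 20.0)
        f = uniform_field(unit_grid, (5.0, 0, 0))
        out = warp_dose(dose, f)
        interior = slice(2, -7), slice(2, -2), slice(2, -2)
        assert np.allclose(out.dose[interior], xs[interior] + 25.0, atol=1e-6)

    def test_never_exceeds_source_maximum(self, unit_grid):
        rng = np.random.default_rng(1)
        dose = DoseGrid(unit_grid, rng.uniform(0, 10, unit_grid.size))
        f = DisplacementField(unit_grid, rng.normal(0, 2, (*unit_grid.size, 3)))
        out = warp_dose(dose, f)
        assert out.dose.max() <= dose.dose.max() + 1e-9

    def test_outside_flagged_zero(self, unit_grid):
        dose = DoseGrid(unit_grid, np.full(unit_grid.size, 5.0))
        f = uniform_field(unit_grid, (0, 0, 30.0))  # everything maps outside
        out, outside = warp_dose(dose, f, return_outside=True)
        assert outside.values.all()
        assert np.allclose(out.dose, 0.0)


class TestDVH:
    def test_uniform_dose_curve(self, unit_grid):
        mask = ball(unit_grid, (10, 10, 10), 6)
        dose = DoseGrid(unit_grid, np.full(unit_grid.size, 10.0))
        dvh = compute_dvh(dose, mask, 0.05)
        below = dvh.dose_edges <= 10.0
        assert np.allclose(dvh.cumulative_volume[below], 1.0)
        assert np.allclose(dvh.cumulative_volume[dvh.dose_edges > 10.0 + 1e-6], 0.0)

    def test_two_level_dose(self, unit_grid):
        mask = BinaryMask(unit_grid, np.ones(unit_grid.size, bool))
        vals = np.full(unit_grid.size, 10.0)
        vals[:10] = 20.0
        dvh = compute_dvh(DoseGrid(unit_grid, vals), mask, 0.05)
        v15 = np.interp(15.0, dvh.dose_edges, dvh.cumulative_volume)
        assert v15 == pytest.approx(0.5)

    def test_mean_dose_layer_cake(self, unit_grid):
        rng = np.random.default_rng(2)
        mask = ball(unit_grid, (10, 10, 10), 7)
        dose = DoseGrid(unit_grid, rng.uniform(0, 30, unit_grid.size))
        bw = 0.05
        dvh = compute_dvh(dose, mask, bw)
        mean_curve = np.trapezoid(dvh.cumulative_volume, dvh.dose_edges)
        mean_direct = dose.dose[mask.values].mean()
        assert mean_curve == pytest.approx(mean_direct, abs=bw / 2)

    def test_matches_bruteforce_counting(self, unit_grid):
        rng = np.random.default_rng(3)
        for _ in range(5):
            mask = ball(unit_grid, (10, 10, 10), rng.uniform(4, 8))
            dose = DoseGrid(unit_grid, rng.uniform(0, 20, unit_grid.size))
            dvh = compute_dvh(dose, mask, 0.5)
            oracle = dvh_bruteforce(dose.dose, mask.values, dvh.dose_edges)
            assert np.allclose(dvh.cumulative_volume, oracle, atol=1e-12)

    def test_empty_mask_undefined(self, unit_grid):
        dose = DoseGrid(unit_grid, np.zeros(unit_grid.size))
        with pytest.raises(UndefinedMetricError):
            compute_dvh(dose, BinaryMask(unit_grid, np.zeros(unit_grid.size, bool)))


class TestDoseMetric:
    def test_uniform_dose_metrics(self, unit_grid):
        mask = ball(unit_grid, (10, 10, 10), 6)
        dvh = compute_dvh(DoseGrid(unit_grid, np.full(unit_grid.size, 10.0)), mask)
        assert dose_metric(dvh, DoseMetricSpec("V_relative", 100, 10.0)) == pytest.approx(100.0)
        assert dose_metric(dvh, DoseMetricSpec("D_relative", 10)) == pytest.approx(10.0, abs=0.05)

    def test_two_level_v95(self, unit_grid):
        mask = BinaryMask(unit_grid, np.ones(unit_grid.size, bool))
        vals = np.full(unit_grid.size, 10.0)
        vals[:10] = 20.0
        dvh = compute_dvh(DoseGrid(unit_grid, vals), mask)
        v95 = dose_metric(dvh, DoseMetricSpec("V_relative", 95, 20.0))
        assert v95 == pytest.approx(50.0, abs=0.5)

    def test_hottest_voxel_d003cc(self):
        """With voxels larger than 0.03 cc, D0.03cc is the hottest voxel."""
        grid = ImageGrid((0, 0, 0), (4, 4, 4), (10, 10, 10))  # 0.064 cc voxels
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 10, grid.size)
        vals[5, 5, 5] = 25.0
        mask = BinaryMask(grid, np.ones(grid.size, bool))
        dvh = compute_dvh(DoseGrid(grid, vals), mask, 0.05)
        d = dose_metric(dvh, DoseMetricSpec("D_absolute_cc", 0.03))
        assert d == pytest.approx(25.0, abs=0.05)

    def test_overfull_cc_undefined(self, unit_grid):
        mask = ball(unit_grid, (10, 10, 10), 3)
        dvh = compute_dvh(DoseGrid(unit_grid, np.full(unit_grid.size, 5.0)), mask)
        with pytest.raises(UndefinedMetricError):
            dose_metric(dvh, DoseMetricSpec("D_absolute_cc", 1000.0))

    def test_parse_metric_shorthand(self):
        assert parse_metric("V100%", 10).kind == "V_relative"
        assert parse_metric("V45Gy").kind == "V_absolute"
        assert parse_metric("D0.03cc").argument == 0.03
        assert parse_metric("D10%").kind == "D_relative"
        with pytest.raises(ValueError):
            parse_metric("X5%")


class TestComparePlans:
    def test_identical_plans_zero_delta(self, unit_grid):
        mask = ball(unit_grid, (10, 10, 10), 6)
        dose = DoseGrid(unit_grid, np.full(unit_grid.size, 10.0))
        goals = [Goal("CTV", "V100%", ">=", 95, 10.0), Goal("CTV", "D10%", "<=", 11, 10.0)]
        comp = compare_plans(dose, dose, {"CTV": mask}, goals)
        assert (comp.table["delta"] == 0).all()
        assert (comp.table["intended_pass"] == comp.table["treated_pass"]).all()

    def test_missing_structure_reported(self, unit_grid):
        dose = DoseGrid(unit_grid, np.full(unit_grid.size, 10.0))
        with pytest.raises(KeyError, match="PTV"):
            compare_plans(dose, dose, {}, [Goal("PTV", "V95%", ">=", 95, 10.0)])

    def test_identity_warp_preserves_dvh(self, unit_grid):
        rng = np.random.default_rng(5)
        mask = ball(unit_grid, (10, 10, 10), 6)
        dose = DoseGrid(unit_grid, rng.uniform(0, 10, unit_grid.size))
        treated = warp_dose(dose, DisplacementField.zero(unit_grid))
        a = compute_dvh(dose, mask, 0.05)
        b = compute_dvh(treated, mask, 0.05)
        assert np.allclose(a.cumulative_volume, b.cumulative_volume, atol=1e-12)
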