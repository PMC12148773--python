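import numpy as np
import pytest

from oartmotion.contour_metrics import UndefinedMetricError
from oartmotion.deformation import (
    InsufficientDataError,
    course_statistics,
    cumulative_histogram,
    directional_exceedance,
    jacobian_map,
    summarize_deformation,
    surface_point_cloud,
)
from oartmotion.geometry import BinaryMask, DisplacementField, ImageGrid
from oartmotion.phantom import analytic_exceedance

from .conftest import ball
from .oracles import jacobian_analytic_oracle


def uniform_field(grid, vec):
    return DisplacementField(grid, np.broadcast_to(np.asarray(vec, float),
                                                   (*grid.size, 3)).copy())


class TestExceedance:
    def test_zero_field(self, unit_grid):
        mask = ball(unit_grid, (10, 10, 10), 6)
        zero = DisplacementField.zero(unit_grid)
        assert np.all(directional_exceedance(zero, mask, (1, 2, 3), "magnitude") == 0)

    def test_uniform_cranial_field(self, unit_grid):
        mask = ball(unit_grid, (10, 10, 10), 6)
        f = uniform_field(unit_grid, (0, 0, 4.0))
        assert np.allclose(
            directional_exceedance(f, mask, (3, 5, 7), "CrCa"), (1.0, 0.0, 0.0)
        )
        # the lateral component of a pure cranial shift never exceeds anything
        assert np.all(directional_exceedance(f, mask, (1,), "LR") == 0)

    def test_matches_analytic_truth(self, small_fraction):
        rec = small_fraction
        for axis in ("LR", "AP", "CrCa", "magnitude"):
            got = directional_exceedance(rec.truth_dvf, rec.bladder_v, (3, 5, 7), axis)
            want = [analytic_exceedance(rec.truth, rec.bladder_v, t, axis)
                    for t in (3, 5, 7)]
            assert np.allclose(got, want, atol=0.02)

    def test_magnitude_dominates_components(self, small_fraction):
        rec = small_fraction
        mag = directional_exceedance(rec.truth_dvf, rec.bladder_v, (3, 5), "magnitude")
        for axis in ("LR", "AP", "CrCa"):
            comp = directional_exceedance(rec.truth_dvf, rec.bladder_v, (3, 5), axis)
            assert np.all(mag >= comp - 1e-12)

    def test_monotone_in_threshold(self, small_fraction):
        rec = small_fraction
        fr = directional_exceedance(rec.truth_dvf, rec.bladder_v,
                                    np.linspace(0.5, 8, 12), "magnitude")
        assert np.all(np.diff(fr) <= 1e-12)

    def test_empty_mask_undefined(self, unit_grid):
        empty = BinaryMask(unit_grid, np.zeros(unit_grid.size, bool))
        with pytest.raises(UndefinedMetricError):
            directional_exceedance(DisplacementField.zero(unit_grid), empty)


class TestCumulativeHistogram:
    def test_uniform_field_step(self, unit_grid):
        mask = ball(unit_grid, (10, 10, 10), 6)
        f = uniform_field(unit_grid, (0, 0, 4.0))
        edges, surv = cumulative_histogram(f, mask, 0.5, "magnitude")
        assert surv[0] == 1.0
        assert np.all(surv[edges < 4.0 - 1e-9] == 1.0)
        assert np.all(surv[edges > 4.0 + 1e-9] == 0.0)

    def test_consistent_with_exceedance(self, small_fraction):
        rec = small_fraction
        edges, surv = cumulative_histogram(rec.truth_dvf, rec.bladder_v, 1.0, "CrCa")
        at = [np.interp(t, edges, surv) for t in (3.0, 5.0, 7.0)]
        ex = directional_exceedance(rec.truth_dvf, rec.bladder_v, (3, 5, 7), "CrCa")
        # edges land exactly on integer thresholds with bin width 1 mm
        assert np.allclose(at, ex, atol=1e-12)

    def test_layer_cake_identity(self, small_fraction):
        """Integral of the survival curve equals the mean displacement."""
        rec = small_fraction
        edges, surv = cumulative_histogram(rec.truth_dvf, rec.bladder_v, 0.05,
                                           "magnitude")
        integral = np.trapezoid(surv, edges)
        mean = rec.truth_dvf.magnitude()[rec.bladder_v.values].mean()
        assert integral == pytest.approx(mean, abs=0.05)

    def test_bad_bin_width(self, unit_grid):
        mask = ball(unit_grid, (10, 10, 10), 6)
        with pytest.raises(ValueError):
            cumulative_histogram(DisplacementField.zero(unit_grid), mask, 0.0)


class TestJacobian:
    def test_zero_field_unity(self, unit_grid):
        det = jacobian_map(DisplacementField.zero(unit_grid)).values
        assert np.allclose(det, 1.0, atol=1e-12)

    def test_linear_volume_doubling(self):
        """u(x) = (2^(1/3)-1) x doubles volume: determinant 2 at interior."""
        grid = ImageGrid((-15.5,) * 3, (1, 1, 1), (32, 32, 32))
        xs, ys, zs = grid.coordinate_arrays()
        c = 2 ** (1 / 3) - 1
        f = DisplacementField(grid, c * np.stack([xs, ys, zs], axis=-1))
        det = jacobian_map(f).values
        assert np.allclose(det[1:-1, 1:-1, 1:-1], 2.0, atol=1e-3)

    def test_smooth_field_against_analytic_oracle(self):
        """Central-difference determinant tracks the analytic Jacobian of a
        smooth sinusoidal field to 1% at interior voxels."""
        grid = ImageGrid((0, 0, 0), (2, 2, 2), (20, 20, 20))
        k = np.array([0.05, 0.07, 0.04])

        def field_fn(p):
            s = np.sin(p @ k)
            return np.array([1.5 * s, -1.0 * np.cos(0.06 * p[1]), 0.8 * s])

        xs, ys, zs = grid.coordinate_arrays()
        pts = np.stack([xs, ys, zs], axis=-1)
        vec = np.apply_along_axis(field_fn, -1, pts)
        det = jacobian_map(DisplacementField(grid, vec)).values
        interior = np.argwhere(np.ones(grid.size, bool))
        sel = [tuple(i) for i in interior if all(1 <= v <= 18 for v in i)][::37]
        pts_sel = grid.index_to_physical(np.asarray(sel, float))
        oracle = jacobian_analytic_oracle(field_fn, pts_sel)
        got = np.array([det[i] for i in sel])
        assert np.allclose(got, oracle, rtol=0.01)


class TestCourseStatistics:
    def test_identical_fields_zero_sd(self, unit_grid):
        mask = ball(unit_grid, (10, 10, 10), 6)
        f = uniform_field(unit_grid, (1, 2, 2))
        mean, sd = course_statistics([f, f, f], mask)
        assert np.allclose(sd.values, 0.0)
        assert np.allclose(mean.values[mask.values], 3.0)

    def test_two_uniform_fields_conventions(self, unit_grid):
        mask = ball(unit_grid, (10, 10, 10), 6)
        f2 = uniform_field(unit_grid, (0, 0, 2.0))
        f4 = uniform_field(unit_grid, (0, 0, 4.0))
        mean, sd_sample = course_statistics([f2, f4], mask, ddof=1)
        _, sd_pop = course_statistics([f2, f4], mask, ddof=0)
        assert np.allclose(mean.values[mask.values], 3.0)
        assert np.allclose(sd_sample.values[mask.values], np.sqrt(2.0))
        assert np.allclose(sd_pop.values[mask.values], 1.0)

    def test_single_field_rejected(self, unit_grid):
        mask = ball(unit_grid, (10, 10, 10), 6)
        with pytest.raises(InsufficientDataError):
            course_statistics([uniform_field(unit_grid, (1, 0, 0))], mask)

    def test_surface_point_cloud_values(self, unit_grid):
        mask = ball(unit_grid, (10, 10, 10), 6)
        f = uniform_field(unit_grid, (0, 0, 2.0))
        mean, _ = course_statistics([f, f], mask)
        cloud = surface_point_cloud(mean, mask)
        assert (cloud["value"] == 2.0).all()
        assert len(cloud) > 0


def test_summary_invariants(small_fraction):
    rec = small_fraction
    s = summarize_deformation(rec.truth_dvf, rec.bladder_v)
    ex = s.exceedance
    assert ((ex["fraction"] >= 0) & (ex["fraction"] <= 1)).all()
    for axis, grp in ex.groupby("axis"):
        assert np.all(np.diff(grp.sort_values("threshold_mm")["fraction"]) <= 1e-12)
    assert s.jacobian_min > 0
    assert s.mean_magnitude >= 0
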