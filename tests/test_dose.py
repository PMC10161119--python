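"""Pencil-beam engine: aperture rule, analytic dose properties, normalization."""

import numpy as np
import pytest

from protonspot.dose import (SpotOpticsModel, aperture_filter, compute_dose,
                             deletion_impact, normalize_plan, spot_dose,
                             spot_dose_at_points)
from protonspot.geometry import VoxelGrid, beam_unit_vectors
from protonspot.plan import Aperture, Beam, EnergyLayer, Spot, TreatmentPlan
from protonspot.robust import dvh_index

SQUARE = np.array([[-10.0, -10.0], [10.0, -10.0], [10.0, 10.0], [-10.0, 10.0]])


def _uniform_grid(n=40, spacing=2.5):
    half = n * spacing / 2.0
    return VoxelGrid(np.array([-half] * 3), np.array([spacing] * 3),
                     np.ones((n, n, n)))


def _one_spot_plan(energy=100.0, mu=1.0, uv=(0.0, 0.0), gantry=0.0):
    beam = Beam("b0", gantry, 200.0, np.zeros(3),
                [EnergyLayer(energy, [Spot(uv[0], uv[1], mu)])])
    return TreatmentPlan("t", 3000.0, 5, [beam])


class TestApertureFilter:
    @pytest.mark.parametrize("uv,kept", [
        ((0.0, 0.0), True),
        ((10.5, 0.0), False),
        ((10.0, 0.0), True),    # boundary-inclusive rule
        ((-10.0, 10.0), True),  # corner on boundary
    ])
    def test_square_aperture_rule(self, uv, kept):
        k, d = aperture_filter(np.array([uv]), SQUARE)
        assert (k.size == 1) is kept

    def test_degenerate_polygon_rejected(self):
        line = np.array([[0, 0], [1, 1], [2, 2]])
        with pytest.raises(ValueError, match="degenerate"):
            aperture_filter(np.array([[0.0, 0.0]]), line)


class TestSpotDose:
    def test_mu_linearity_exact(self, optics):
        grid = _uniform_grid(24)
        beam = _one_spot_plan().beams[0]
        d1 = spot_dose(Spot(0, 0, 1.0), beam, 80.0, grid, optics)
        d2 = spot_dose(Spot(0, 0, 2.0), beam, 80.0, grid, optics)
        assert np.array_equal(d2, 2.0 * d1)

    def test_lateral_ratio_at_one_sigma(self, optics):
        grid = _uniform_grid(24)
        beam = _one_spot_plan().beams[0]
        direction, u_hat, _ = beam_unit_vectors(0.0)
        lo, _ = grid.bounds()
        depth = 20.0
        axis_pt = np.array([[0.0, 0.0, lo[2] + depth]])
        sigma = float(optics.sigma_mm(100.0, np.array([depth]))[0])
        off_pt = axis_pt + sigma * u_hat
        d_axis = spot_dose_at_points(axis_pt, beam, 100.0, np.zeros(2), grid, optics)[0]
        d_off = spot_dose_at_points(off_pt, beam, 100.0, np.zeros(2), grid, optics)[0]
        assert d_off / d_axis == pytest.approx(np.exp(-0.5), abs=1e-6)

    def test_lateral_integral_recovers_depth_dose(self, optics):
        """2-D lateral quadrature at fixed depth equals calibration * DD."""
        grid = _uniform_grid(48, 2.5)
        beam = _one_spot_plan().beams[0]
        energy, depth = 90.0, 30.0
        lo, _ = grid.bounds()
        sigma = float(optics.sigma_mm(energy, np.array([depth]))[0])
        step = 1.0
        ax = np.arange(-6 * sigma, 6 * sigma + step, step)
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        pts = np.stack([xx.ravel(), yy.ravel(),
                        np.full(xx.size, lo[2] + depth)], axis=1)
        dose = spot_dose_at_points(pts, beam, energy, np.zeros(2), grid, optics)
        integral = dose.sum() * step * step
        dd = float(optics.depth_dose(np.array([depth]), energy)[0])
        expected = optics.calibration_cgy_mm2_per_mu * dd
        assert integral == pytest.approx(expected, rel=1e-3)

    def test_energy_out_of_range_rejected(self, optics):
        grid = _uniform_grid(16)
        beam = _one_spot_plan().beams[0]
        with pytest.raises(ValueError, match="outside optics validity"):
            spot_dose(Spot(0, 0, 1.0), beam, 10.0, grid, optics)


class TestBraggPeak:
    def test_peak_depth_monotone_in_energy(self, optics):
        depths = np.linspace(0.1, 300.0, 3000)
        peaks = []
        for e in [60.0, 80.0, 100.0, 120.0, 150.0]:
            dd = optics.depth_dose(depths, e)
            peaks.append(depths[np.argmax(dd)])
        assert np.all(np.diff(peaks) > 0)

    def test_peak_depth_scales_inverse_density(self, optics):
        grid = _uniform_grid(48, 2.5)
        beam = _one_spot_plan().beams[0]
        energy = 100.0
        lo, _ = grid.bounds()
        depths = np.arange(0.5, 115.0, 0.2)
        pts = np.stack([np.zeros_like(depths), np.zeros_like(depths),
                        lo[2] + depths], axis=1)
        d_nom = spot_dose_at_points(pts, beam, energy, np.zeros(2), grid, optics)
        d_dense = spot_dose_at_points(pts, beam, energy, np.zeros(2), grid, optics,
                                      density_scale=1.035)
        z_nom = depths[np.argmax(d_nom)]
        z_dense = depths[np.argmax(d_dense)]
        assert z_dense / z_nom == pytest.approx(1.0 / 1.035, rel=0.01)


class TestComputeDose:
    def test_superposition_base_case(self, optics):
        grid = _uniform_grid(24)
        plan = _one_spot_plan(energy=80.0, mu=1.3)
        total = compute_dose(plan, grid, optics).dose
        single = spot_dose(Spot(0, 0, 1.3), plan.beams[0], 80.0, grid, optics)
        assert np.array_equal(total, single)

    def test_two_identical_spots_additivity(self, optics):
        grid = _uniform_grid(24)
        plan1 = _one_spot_plan(mu=1.0)
        plan2 = _one_spot_plan(mu=1.0)
        plan2.beams[0].layers[0].spots.append(Spot(0.0, 0.0, 1.0))
        d1 = compute_dose(plan1, grid, optics).dose
        d2 = compute_dose(plan2, grid, optics).dose
        assert np.allclose(d2, 2.0 * d1, rtol=0, atol=1e-12)

    def test_shift_equivariance_on_uniform_phantom(self, optics):
        grid = _uniform_grid(32, 2.5)
        plan = _one_spot_plan(energy=80.0)
        nominal = compute_dose(plan, grid, optics).dose
        shifted = compute_dose(plan, grid, optics,
                               shift_mm=np.array([5.0, 0.0, 0.0])).dose
        # lateral 2-voxel shift: dose translates with the beam
        rolled = np.roll(nominal, 2, axis=0)
        core = (slice(4, -4),) * 3
        assert np.allclose(shifted[core], rolled[core], atol=1e-6 * nominal.max())

    def test_integrated_dose_invariant_under_lateral_shift(self, optics):
        grid = _uniform_grid(56, 2.5)  # generous lateral room: spot stays well inside
        a = compute_dose(_one_spot_plan(uv=(0.0, 0.0), energy=80.0), grid, optics).dose
        b = compute_dose(_one_spot_plan(uv=(6.0, 4.0), energy=80.0), grid, optics).dose
        assert b.sum() == pytest.approx(a.sum(), rel=1e-3)


class TestNormalization:
    def test_factor_exact_for_linear_engine(self, small_phantom, small_plan, optics):
        grid, st = small_phantom
        normed, factor = normalize_plan(small_plan, grid, optics, st["CTV"], 3000.0)
        ctv = compute_dose(normed, grid, optics).dose[st["CTV"]]
        assert dvh_index(ctv, "D99%") == pytest.approx(3000.0, abs=0.1)
        assert factor > 0

    def test_idempotent(self, small_phantom, small_plan, optics):
        grid, st = small_phantom
        normed, _ = normalize_plan(small_plan, grid, optics, st["CTV"], 3000.0)
        _, factor2 = normalize_plan(normed, grid, optics, st["CTV"], 3000.0)
        assert factor2 == pytest.approx(1.0, abs=1e-4)

    def test_cross_checked_by_bisection(self, small_phantom, small_plan, optics):
        grid, st = small_phantom
        _, factor = normalize_plan(small_plan, grid, optics, st["CTV"], 3000.0)
        base = compute_dose(small_plan, grid, optics).dose[st["CTV"]]
        lo_f, hi_f = factor / 4.0, factor * 4.0
        for _ in range(50):
            mid = 0.5 * (lo_f + hi_f)
            if dvh_index(base * mid, "D99%") < 3000.0:
                lo_f = mid
            else:
                hi_f = mid
        assert factor == pytest.approx(0.5 * (lo_f + hi_f), rel=1e-6)

    def test_zero_dose_rejected(self, small_phantom, optics):
        grid, st = small_phantom
        plan = _one_spot_plan(mu=0.0)  # no MU delivered anywhere
        with pytest.raises((ValueError, RuntimeError)):
            normalize_plan(plan, grid, optics, st["CTV"], 3000.0)


class TestDeletionImpact:
    def test_zero_mu_spot_has_no_impact(self, small_phantom, optics, small_plan):
        from protonspot.plan import replace_spots

        grid, st = small_phantom
        plan = replace_spots(small_plan, {(0, 0, 0): Spot(
            small_plan.beams[0].layers[0].spots[0].x_mm,
            small_plan.beams[0].layers[0].spots[0].y_mm, 0.0)})
        impact = deletion_impact(plan, grid, optics, st["CTV"], [(0, 0, 0)])
        assert impact["delta_d99_cgy"] == 0.0
        assert impact["delta_d0_03cc_cgy"] == 0.0

    def test_deleting_all_spots_zeroes_d99(self, small_phantom, optics, small_plan):
        grid, st = small_phantom
        all_ids = [(bi, li, si) for bi, li, si, _ in small_plan.spot_table()]
        base = compute_dose(small_plan, grid, optics).dose[st["CTV"]]
        impact = deletion_impact(small_plan, grid, optics, st["CTV"], all_ids)
        assert impact["delta_d99_cgy"] == pytest.approx(-dvh_index(base, "D99%"))

    def test_single_edge_spot_impact_is_small(self, small_phantom, optics, small_plan):
        grid, st = small_phantom
        normed, _ = normalize_plan(small_plan, grid, optics, st["CTV"], 3000.0)
        # lowest-MU spot of the first beam
        table = [(i, s.mu) for i, (_, _, _, s) in enumerate(normed.spot_table())]
        idx = min(table, key=lambda t: t[1])[0]
        spot_id = normed.spot_table()[idx][:3]
        impact = deletion_impact(normed, grid, optics, st["CTV"], [spot_id])
        assert abs(impact["delta_d99_cgy"]) < 0.01 * 3000.0

    def test_unknown_spot_id_rejected(self, small_phantom, optics, small_plan):
        grid, st = small_phantom
        with pytest.raises(KeyError):
            deletion_impact(small_plan, grid, optics, st["CTV"], [(99, 0, 0)])
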