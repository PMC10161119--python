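"""Scenario generation, DVH computation, indices, banding, verdicts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from protonspot.robust import (NOMINAL, Scenario, ScenarioConfig, banded_dvh,
                               compare_plans, compute_dvh, ctv_v95_by_scenario,
                               dvh_index, evaluate_scenarios, generate_scenarios,
                               index_resolution_limited, percent_of_prescription,
                               robustness_check, scenario_indices, volume_at_least,
                               worst_case_table)


class TestScenarios:
    def test_default_corner_mode_gives_16(self):
        assert len(generate_scenarios(ScenarioConfig())) == 16

    def test_axis_aligned_gives_12(self):
        assert len(generate_scenarios(ScenarioConfig(mode="axis_aligned"))) == 12

    def test_degenerate_config_collapses_to_nominal(self):
        sc = generate_scenarios(ScenarioConfig(shift_mm=0.0, density_frac=0.0))
        assert len(sc) == 1
        assert np.all(sc[0].shift_mm == 0) and sc[0].density_scale == 1.0

    def test_corner_structure(self):
        sc = generate_scenarios(ScenarioConfig(shift_mm=3.0, density_frac=0.035))
        shifts = {tuple(s.shift_mm) for s in sc}
        assert len(shifts) == 8
        assert all(set(np.abs(s.shift_mm)) == {3.0} for s in sc)
        assert {s.density_scale for s in sc} == {0.965, 1.035}

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ScenarioConfig(shift_mm=-1.0)
        with pytest.raises(ValueError):
            ScenarioConfig(density_frac=0.5)


class TestDvhCurve:
    def test_uniform_dose_step_function(self):
        curve = compute_dvh(np.full(100, 50.0), 0.01, bin_width_cgy=1.0)
        assert curve.volume_at(0.0) == 100.0
        assert curve.volume_at(49.0) == 100.0
        assert curve.volume_at(51.0) == 0.0

    def test_two_voxel_half_volume(self):
        curve = compute_dvh(np.array([100.0, 300.0]), 1.0, bin_width_cgy=1.0)
        assert curve.volume_at(200.0) == 50.0
        assert curve.total_volume_cc == 2.0

    def test_monotone_non_increasing(self, rng):
        curve = compute_dvh(rng.uniform(0, 100, 500), 0.01)
        assert np.all(np.diff(curve.volume_pct) <= 0)
        assert curve.volume_pct[0] == 100.0
        assert curve.volume_pct[-1] == 0.0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_sort_and_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        doses = rng.uniform(0, 80, int(rng.integers(2, 200)))
        curve = compute_dvh(doses, 0.5, bin_width_cgy=2.0)
        for edge, vol in zip(curve.dose_edges_cgy, curve.volume_pct):
            brute = 100.0 * sum(1 for d in doses if d >= edge) / len(doses)
            assert vol == pytest.approx(brute, abs=1e-9)


class TestDvhIndex:
    def test_uniform_dose_all_indices_equal(self):
        doses = np.full(200, 42.0)
        assert dvh_index(doses, "D99%") == 42.0
        assert dvh_index(doses, "D0.03cc", voxel_volume_cc=0.01) == 42.0

    def test_order_statistics_example(self):
        doses = np.array([50.0] * 99 + [100.0])  # 100 voxels of 1 cc
        assert dvh_index(doses, "D99%") == 50.0
        assert dvh_index(doses, "D1cc", voxel_volume_cc=1.0) == 100.0

    def test_monotone_in_volume(self, rng):
        doses = rng.uniform(0, 100, 300)
        ps = [10, 50, 90, 99]
        vals = [dvh_index(doses, f"D{p}%") for p in ps]
        assert np.all(np.diff(vals) <= 0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_profile_walk(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 150))
        doses = rng.uniform(0, 100, m)
        p = float(rng.uniform(1, 100))
        # oracle: walk the descending profile and interpolate at p% of volume
        desc = sorted(doses, reverse=True)
        h = p / 100.0 * m - 1.0
        h = min(max(h, 0.0), m - 1)
        lo = int(np.floor(h))
        hi = min(lo + 1, m - 1)
        expected = desc[lo] + (h - lo) * (desc[hi] - desc[lo])
        assert dvh_index(doses, f"D{p}%") == pytest.approx(expected, abs=1e-9)

    def test_excess_volume_rejected(self):
        with pytest.raises(ValueError, match="exceeds structure volume"):
            dvh_index(np.ones(10), "D5cc", voxel_volume_cc=0.1)

    def test_resolution_limit_flag(self):
        assert index_resolution_limited("D0.03cc", voxel_volume_cc=0.0156)
        assert not index_resolution_limited("D5cc", voxel_volume_cc=0.0156)
        assert not index_resolution_limited("D99%", voxel_volume_cc=1.0)

    def test_volume_at_least_counts(self):
        doses = np.array([10.0, 20.0, 30.0, 40.0])
        assert volume_at_least(doses, 25.0) == 50.0
        assert volume_at_least(doses, 10.0) == 100.0


class TestPercentOfPrescription:
    @pytest.mark.parametrize("value,rx,expected", [
        (2846.0, 3000.0, 94.9),
        (4936.0, 5040.0, 97.9),
        (1234.0, 1234.0, 100.0),
    ])
    def test_one_decimal_convention(self, value, rx, expected):
        assert percent_of_prescription(value, rx) == expected

    def test_positive_prescription_required(self):
        with pytest.raises(ValueError):
            percent_of_prescription(100.0, 0.0)


class TestBandedDvh:
    def _curves(self, profiles, edges=None):
        edges = np.arange(0.0, 10.0, 1.0) if edges is None else edges
        from protonspot.robust import DVHCurve

        return {f"s{i}": {"CTV": DVHCurve(edges, np.asarray(p, float), "CTV", 1.0)}
                for i, p in enumerate(profiles)}

    def test_identical_curves_collapse(self):
        p = [100, 100, 80, 50, 20, 0, 0, 0, 0, 0]
        band = banded_dvh(self._curves([p, p, p]))
        assert np.array_equal(band.lower_pct["CTV"], band.upper_pct["CTV"])

    def test_crossing_curves_take_outer_branches(self):
        a = [100, 90, 80, 70, 60, 50, 40, 30, 20, 10]
        b = [100, 95, 70, 60, 55, 52, 45, 35, 15, 5]
        band = banded_dvh(self._curves([a, b]))
        assert np.array_equal(band.upper_pct["CTV"], np.maximum(a, b))
        assert np.array_equal(band.lower_pct["CTV"], np.minimum(a, b))

    def test_every_curve_within_band(self, rng):
        profiles = [np.sort(rng.uniform(0, 100, 10))[::-1] for _ in range(6)]
        band = banded_dvh(self._curves(profiles))
        for p in profiles:
            assert np.all(band.lower_pct["CTV"] <= p + 1e-12)
            assert np.all(p <= band.upper_pct["CTV"] + 1e-12)

    def test_mismatched_axes_rejected(self):
        curves = self._curves([[100] * 10])
        curves.update({"odd": {"CTV": list(self._curves(
            [[100] * 5], edges=np.arange(5.0)).values())[0]["CTV"]}})
        with pytest.raises(ValueError, match="dose axis"):
            banded_dvh(curves)


class TestWorstCaseAndCompare:
    def _indices(self, rows):
        return pd.DataFrame(rows, columns=["scenario", "structure", "index", "value"])

    def test_single_scenario_min_equals_max(self):
        table = worst_case_table(self._indices([("s0", "CTV", "D99%", 2900.0)]))
        row = table.loc[("CTV", "D99%")]
        assert row["min"] == row["max"] == 2900.0

    def test_extrema(self):
        rows = [(f"s{i}", "CTV", "D99%", v) for i, v in enumerate([2846, 2895, 2991])]
        table = worst_case_table(self._indices(rows))
        assert table.loc[("CTV", "D99%"), "min"] == 2846
        assert table.loc[("CTV", "D99%"), "max"] == 2991

    def test_per_pair_extrema_independent(self):
        # structure A's worst scenario differs from structure B's
        rows = [("s0", "A", "D99%", 10.0), ("s1", "A", "D99%", 20.0),
                ("s0", "B", "D99%", 20.0), ("s1", "B", "D99%", 10.0)]
        table = worst_case_table(self._indices(rows))
        assert table.loc[("A", "D99%"), "argmin_scenario"] == "s0"
        assert table.loc[("B", "D99%"), "argmin_scenario"] == "s1"

    def test_compare_plans_signed_difference(self):
        a = worst_case_table(self._indices([("s0", "Cord", "D5cc", 2407.0)]))
        b = worst_case_table(self._indices([("s0", "Cord", "D5cc", 2537.0)]))
        diff = compare_plans(a, b)
        assert diff.loc[("Cord", "D5cc"), "min"] == pytest.approx(130.0)

    def test_compare_identical_is_zero_and_antisymmetric(self):
        rows = [("s0", "CTV", "D99%", 2991.0), ("s1", "CTV", "D99%", 2846.0)]
        a = worst_case_table(self._indices(rows))
        assert (compare_plans(a, a).to_numpy() == 0).all()
        rows_b = [("s0", "CTV", "D99%", 3000.0), ("s1", "CTV", "D99%", 2900.0)]
        b = worst_case_table(self._indices(rows_b))
        assert compare_plans(a, b).equals(-compare_plans(b, a))

    def test_mismatched_reports_rejected(self):
        a = worst_case_table(self._indices([("s0", "CTV", "D99%", 1.0)]))
        b = worst_case_table(self._indices([("s0", "OAR", "D99%", 1.0)]))
        with pytest.raises(ValueError):
            compare_plans(a, b)


class TestRobustnessCheck:
    def test_all_pass(self):
        verdict = robustness_check({"a": 100.0, "b": 99.0})
        assert verdict["pass"] and verdict["failing_scenarios"] == []

    def test_single_failure_listed(self):
        verdict = robustness_check({"a": 100.0, "bad": 94.9})
        assert not verdict["pass"]
        assert verdict["failing_scenarios"] == ["bad"]
        assert verdict["worst_scenario"] == "bad"

    def test_boundary_is_pass(self):
        assert robustness_check({"edge": 95.0})["pass"]  # "at least" rule

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            robustness_check({})


@pytest.fixture(scope="module")
def evaluation(small_phantom, small_plan, optics):
    grid, structures = small_phantom
    scenarios = [NOMINAL,
                 Scenario(np.zeros(3), 1.035, "dense"),
                 Scenario(np.zeros(3), 1.035, "dense-dup"),
                 Scenario(np.zeros(3), 0.965, "light")]
    return evaluate_scenarios(small_plan, grid, optics, structures, scenarios,
                              structure_names=["CTV", "OAR"])


class TestEvaluateScenarios:

    def test_duplicated_scenario_identical(self, evaluation):
        a = evaluation.structure_doses["dense"]["CTV"]
        b = evaluation.structure_doses["dense-dup"]["CTV"]
        assert np.array_equal(a, b)

    def test_nominal_scenario_equals_unperturbed_plan(self, evaluation, small_phantom,
                                                      small_plan, optics):
        from protonspot.dose import compute_dose

        grid, structures = small_phantom
        direct = compute_dose(small_plan, grid, optics).dose[structures["CTV"]]
        assert np.array_equal(evaluation.structure_doses["nominal"]["CTV"], direct)

    def test_density_overshoot_lowers_distal_coverage(self, evaluation, small_phantom):
        """Higher stopping power pulls peaks shallower: the distal CTV half
        (away from the beams) receives less dose than with undershoot."""
        grid, structures = small_phantom
        ctv = structures["CTV"]
        zc = grid.voxel_centers().reshape(*grid.shape, 3)[..., 2][ctv]
        distal = zc > np.median(zc)  # beams enter anteriorly (low z)
        dense = evaluation.structure_doses["dense"]["CTV"][distal].mean()
        light = evaluation.structure_doses["light"]["CTV"][distal].mean()
        assert dense < light

    def test_worst_case_brackets_nominal(self, evaluation):
        specs = {"CTV": ["D99%"], "OAR": ["D0.03cc"]}
        idx = scenario_indices(evaluation, specs)
        nominal = idx[idx["scenario"] == "nominal"]
        table = worst_case_table(idx, nominal)
        assert (table["min"] <= table["nominal"] + 1e-9).all()
        assert (table["nominal"] <= table["max"] + 1e-9).all()

    def test_banded_dvh_contains_all_scenarios(self, evaluation):
        band = banded_dvh(evaluation.dvhs)
        for label in evaluation.dvhs:
            for name, curve in evaluation.dvhs[label].items():
                assert np.all(band.lower_pct[name] <= curve.volume_pct + 1e-12)
                assert np.all(curve.volume_pct <= band.upper_pct[name] + 1e-12)

    def test_v95_and_verdict_plumbing(self, evaluation):
        v95 = ctv_v95_by_scenario(evaluation, 3000.0)
        assert set(v95) == {"nominal", "dense", "dense-dup", "light"}
        verdict = robustness_check(v95)
        assert set(verdict) == {"pass", "min_v95_pct", "worst_scenario",
                                "failing_scenarios"}
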