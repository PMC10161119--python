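"""Scenario-based robustness evaluation: DVHs, banded DVHs, worst-case indices.

A perturbation scenario is a rigid setup shift (mm, patient RL/IS/PA axes)
combined with a global density (stopping-power) scale.  The default
scenario set crosses the 8 simultaneous +/-delta corner shifts with the
two density scales (1 -/+ f), giving 16 perturbed scenarios; an
axis-aligned mode (6 single-axis shifts x 2 densities = 12) is provided
as an alternative reading of "isotropic shifts".

The plan verdict follows the 95/95 rule: a plan is robust iff every
scenario keeps at least 95% of the CTV at or above 95% of the
prescription dose.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose import SpotOpticsModel, compute_dose
from .geometry import StructureSet, VoxelGrid
from .plan import TreatmentPlan


@dataclass
class ScenarioConfig:
    shift_mm: float = 5.0
    density_frac: float = 0.035
    mode: str = "isotropic_corners"   # or "axis_aligned"
    include_nominal: bool = False

    def __post_init__(self) -> None:
        if self.shift_mm < 0:
            raise ValueError("shift magnitude must be >= 0")
        if not 0.0 <= self.density_frac < 0.2:
            raise ValueError("density fraction must lie in [0, 0.2)")
        if self.mode not in ("isotropic_corners", "axis_aligned"):
            raise ValueError(f"unknown scenario mode {self.mode!r}")


@dataclass
class Scenario:
    shift_mm: np.ndarray      # (3,) patient axes RL/IS/PA
    density_scale: float
    label: str

    def __post_init__(self) -> None:
        self.shift_mm = np.asarray(self.shift_mm, dtype=float)


NOMINAL = Scenario(np.zeros(3), 1.0, "nominal")


def generate_scenarios(config: ScenarioConfig) -> list[Scenario]:
    """Enumerate the perturbed scenario set for a config (deduplicated).

    isotropic_corners: (+/-d, +/-d, +/-d) x (1-f, 1+f) -> 16 scenarios.
    axis_aligned: +/-d on one axis at a time x (1-f, 1+f) -> 12.
    A degenerate config (d = 0, f = 0) collapses to a single scenario
    identical to nominal.
    """
    d, f = config.shift_mm, config.density_frac
    densities = [1.0 - f, 1.0 + f] if f > 0 else [1.0]
    shifts: list[np.ndarray]
    if config.mode == "isotropic_corners":
        signs = (-d, d) if d > 0 else (0.0,)
        shifts = [np.array(s) for s in itertools.product(signs, signs, signs)]
    else:
        if d > 0:
            shifts = []
            for ax in range(3):
                for s in (-d, d):
                    v = np.zeros(3)
                    v[ax] = s
                    shifts.append(v)
        else:
            shifts = [np.zeros(3)]
    scenarios = []
    for shift in shifts:
        for rho in densities:
            label = "shift({:+g},{:+g},{:+g})mm_rho{:+.1f}%".format(
                *shift, (rho - 1.0) * 100.0)
            scenarios.append(Scenario(shift, rho, label))
    if config.include_nominal:
        scenarios.append(Scenario(np.zeros(3), 1.0, "nominal"))
    return scenarios


@dataclass
class DVHCurve:
    """Cumulative DVH: % of structure volume receiving >= each dose edge."""

    dose_edges_cgy: np.ndarray
    volume_pct: np.ndarray
    structure: str
    total_volume_cc: float

    def volume_at(self, dose_cgy: float) -> float:
        return float(np.interp(dose_cgy, self.dose_edges_cgy, self.volume_pct))


@dataclass
class BandedDvh:
    """Pointwise min/max DVH envelopes over a scenario set, per structure."""

    dose_edges_cgy: np.ndarray
    lower_pct: dict[str, np.ndarray]
    upper_pct: dict[str, np.ndarray]
    nominal: dict[str, DVHCurve] = field(default_factory=dict)


def compute_dvh(doses: np.ndarray, voxel_volume_cc: float, bin_width_cgy: float = 1.0,
                structure: str = "", max_dose_cgy: float | None = None) -> DVHCurve:
    """Cumulative DVH from voxel doses by sort-free counting."""
    doses = np.asarray(doses, float).ravel()
    if doses.size == 0:
        raise ValueError("empty structure mask")
    top = max_dose_cgy if max_dose_cgy is not None else float(doses.max())
    edges = np.arange(0.0, top + 2.0 * bin_width_cgy, bin_width_cgy)
    srt = np.sort(doses)
    # volume receiving >= edge: count of doses >= edge
    at_least = doses.size - np.searchsorted(srt, edges, side="left")
    vol_pct = 100.0 * at_least / doses.size
    return DVHCurve(edges, vol_pct, structure, doses.size * voxel_volume_cc)


def _hot_quantile(doses: np.ndarray, hot_fraction: float) -> float:
    """Dose received by the hottest ``hot_fraction`` of the volume.

    The sorted-descending dose profile is read at the requested cumulative
    volume with fractional-voxel linear interpolation; a request within the
    hottest single voxel returns that voxel's dose, and a request of the
    full volume returns the coldest voxel's dose.
    """
    desc = np.sort(np.asarray(doses, float).ravel())[::-1]
    m = desc.size
    if m == 0:
        raise ValueError("empty dose profile")
    h = hot_fraction * m - 1.0          # descending index at the requested volume
    h = min(max(h, 0.0), m - 1.0)
    lo = int(np.floor(h))
    hi = min(lo + 1, m - 1)
    return float(desc[lo] + (h - lo) * (desc[hi] - desc[lo]))


def dvh_index(doses: np.ndarray, spec: str, voxel_volume_cc: float | None = None) -> float:
    """Scalar DVH index from voxel doses.

    ``spec`` forms: ``"D99%"`` (dose to the hottest 99% of relative volume),
    ``"D0.03cc"`` (dose to the hottest 0.03 cc; needs ``voxel_volume_cc``).
    """
    doses = np.asarray(doses, float).ravel()
    if doses.size == 0:
        raise ValueError("empty dose profile")
    spec = spec.strip()
    if not spec.startswith("D"):
        raise ValueError(f"unknown index spec {spec!r}")
    body = spec[1:]
    if body.endswith("%"):
        p = float(body[:-1])
        if not 0 < p <= 100:
            raise ValueError("relative volume must lie in (0, 100]")
        return _hot_quantile(doses, p / 100.0)
    if body.endswith("cc"):
        if voxel_volume_cc is None:
            raise ValueError("absolute-volume index needs voxel_volume_cc")
        cc = float(body[:-2])
        total = doses.size * voxel_volume_cc
        if cc > total:
            raise ValueError(f"requested volume {cc} cc exceeds structure volume {total:.3f} cc")
        return _hot_quantile(doses, cc / total)
    raise ValueError(f"unknown index spec {spec!r}")


def index_resolution_limited(spec: str, voxel_volume_cc: float, min_voxels: int = 3) -> bool:
    """True when an absolute-volume index spans fewer than ``min_voxels`` voxels."""
    body = spec.strip()[1:]
    if not body.endswith("cc"):
        return False
    return float(body[:-2]) < min_voxels * voxel_volume_cc


def volume_at_least(doses: np.ndarray, dose_cgy: float) -> float:
    """V_d: percent of the structure volume receiving at least ``dose_cgy``."""
    doses = np.asarray(doses, float).ravel()
    if doses.size == 0:
        raise ValueError("empty dose profile")
    return 100.0 * float(np.count_nonzero(doses >= dose_cgy)) / doses.size


def percent_of_prescription(index_value_cgy: float, prescription_cgy: float) -> float:
    """Index value as percent of prescription, to one decimal."""
    if prescription_cgy <= 0:
        raise ValueError("prescription must be positive")
    return round(100.0 * index_value_cgy / prescription_cgy, 1)


@dataclass
class ScenarioEvaluation:
    """Per-scenario structure doses and DVHs on a shared dose axis."""

    scenarios: list[Scenario]
    structure_doses: dict[str, dict[str, np.ndarray]]  # label -> structure -> doses
    dvhs: dict[str, dict[str, DVHCurve]]
    voxel_volume_cc: float


def evaluate_scenarios(plan: TreatmentPlan, grid: VoxelGrid, optics: SpotOpticsModel,
                       structures: StructureSet, scenarios: list[Scenario],
                       bin_width_cgy: float = 1.0,
                       structure_names: list[str] | None = None) -> ScenarioEvaluation:
    """Recompute dose and per-structure DVHs for every scenario.

    All DVH curves share one dose axis spanning the global scenario maximum,
    so banded envelopes can be formed pointwise.
    """
    names = structure_names or structures.names()
    doses: dict[str, dict[str, np.ndarray]] = {}
    for sc in scenarios:
        dg = compute_dose(plan, grid, optics, shift_mm=sc.shift_mm,
                          density_scale=sc.density_scale)
        doses[sc.label] = {name: dg.dose[structures[name]] for name in names}
    top = max(float(d.max()) for per in doses.values() for d in per.values())
    dvhs = {
        label: {name: compute_dvh(per[name], structures.grid.voxel_volume_cc,
                                  bin_width_cgy, name, max_dose_cgy=top)
                for name in names}
        for label, per in doses.items()
    }
    return ScenarioEvaluation(list(scenarios), doses, dvhs,
                              structures.grid.voxel_volume_cc)


def banded_dvh(scenario_dvhs: dict[str, dict[str, DVHCurve]],
               nominal_dvhs: dict[str, DVHCurve] | None = None) -> BandedDvh:
    """Pointwise min/max envelopes over the scenario curves, per structure.

    Nominal curves (not part of the perturbed set) are carried alongside and
    may legitimately fall outside the band.
    """
    labels = list(scenario_dvhs)
    if not labels:
        raise ValueError("no scenario curves")
    structures = list(scenario_dvhs[labels[0]])
    edges = scenario_dvhs[labels[0]][structures[0]].dose_edges_cgy
    lower, upper = {}, {}
    for name in structures:
        stack = []
        for label in labels:
            curve = scenario_dvhs[label][name]
            if (len(curve.dose_edges_cgy) != len(edges)
                    or not np.allclose(curve.dose_edges_cgy, edges)):
                raise ValueError("scenario DVHs do not share a dose axis")
            stack.append(curve.volume_pct)
        arr = np.stack(stack)
        lower[name] = arr.min(axis=0)
        upper[name] = arr.max(axis=0)
    return BandedDvh(edges, lower, upper, dict(nominal_dvhs or {}))


def scenario_indices(ev: ScenarioEvaluation, index_specs: dict[str, list[str]]
                     ) -> pd.DataFrame:
    """Tidy table of DVH indices: one row per (scenario, structure, index)."""
    rows = []
    for sc in ev.scenarios:
        for name, specs in index_specs.items():
            for spec in specs:
                val = dvh_index(ev.structure_doses[sc.label][name], spec,
                                voxel_volume_cc=ev.voxel_volume_cc)
                rows.append((sc.label, name, spec, val))
    return pd.DataFrame(rows, columns=["scenario", "structure", "index", "value"])


def worst_case_table(indices: pd.DataFrame,
                     nominal_indices: pd.DataFrame | None = None) -> pd.DataFrame:
    """Min/max over scenarios per (structure, index), each pair independently.

    The scenario achieving the minimum for one structure-index pair need not
    be the one achieving it for another; extrema are taken per pair, and the
    achieving scenario labels are reported.
    """
    out = []
    for (name, spec), grp in indices.groupby(["structure", "index"], sort=False):
        i_min = grp["value"].idxmin()
        i_max = grp["value"].idxmax()
        row = {"structure": name, "index": spec,
               "min": grp["value"].min(), "max": grp["value"].max(),
               "argmin_scenario": grp.loc[i_min, "scenario"],
               "argmax_scenario": grp.loc[i_max, "scenario"]}
        out.append(row)
    table = pd.DataFrame(out).set_index(["structure", "index"])
    if nominal_indices is not None:
        nom = nominal_indices.set_index(["structure", "index"])["value"]
        table["nominal"] = nom
    return table


def compare_plans(report_a: pd.DataFrame, report_b: pd.DataFrame) -> pd.DataFrame:
    """Signed per-cell differences (b - a) between two worst-case tables."""
    num_a = report_a.select_dtypes("number")
    num_b = report_b.select_dtypes("number")
    if not num_a.index.equals(num_b.index) or list(num_a.columns) != list(num_b.columns):
        raise ValueError("reports do not share structures/indices")
    return num_b - num_a


def ctv_v95_by_scenario(ev: ScenarioEvaluation, prescription_cgy: float,
                        ctv_name: str = "CTV") -> dict[str, float]:
    """V at 95% of prescription for the CTV, per scenario."""
    out = {}
    for sc in ev.scenarios:
        if ctv_name not in ev.structure_doses[sc.label]:
            raise KeyError(f"structure {ctv_name!r} missing from evaluation")
        out[sc.label] = volume_at_least(ev.structure_doses[sc.label][ctv_name],
                                        0.95 * prescription_cgy)
    return out


def robustness_check(v95_by_scenario: dict[str, float]) -> dict:
    """95/95 verdict: PASS iff every scenario keeps V(95% Rx) >= 95%."""
    if not v95_by_scenario:
        raise ValueError("no scenarios evaluated")
    failing = sorted(label for label, v in v95_by_scenario.items() if v < 95.0)
    worst = min(v95_by_scenario, key=v95_by_scenario.get)
    return {"pass": len(failing) == 0,
            "min_v95_pct": float(v95_by_scenario[worst]),
            "worst_scenario": worst,
            "failing_scenarios": failing}
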