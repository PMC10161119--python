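"""Synthetic study inputs: phantoms, plans, pulse-level logs, QA grids.

Everything downstream of this module (QA agreement, model training, dose,
robustness) consumes only what is generated here, with a *known* delivery
error structure, so the whole pipeline is testable without clinical data.

The error model of the generator reflects what delivery records from a
compact PBS machine show: per-spot position errors that are Gaussian about
a small systematic component (mean magnitude of order 1 mm or below),
multiplicative MU noise of a few percent, and sub-0.1 mm pulse-level
scatter about each spot's delivered position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint

from .geometry import StructureSet, VoxelGrid, beam_unit_vectors, ray_box_entry
from .logfile import PULSE_COLUMNS, LogFile, LogHeader
from .plan import Aperture, Beam, EnergyLayer, Spot, TreatmentPlan

SystematicFn = float | Callable[[float, float], float]


@dataclass
class ErrorModelTruth:
    """Ground-truth delivery-error distribution used by the generators.

    ``systematic_*`` may be constants (mm) or callables of
    ``(gantry_angle_deg, energy_mev)``; random components are Gaussian SDs.
    """

    systematic_x_mm: SystematicFn = 0.6
    systematic_y_mm: SystematicFn = -0.8
    random_sigma_x_mm: float = 0.30
    random_sigma_y_mm: float = 0.35
    mu_noise_frac: float = 0.02
    pulse_jitter_sigma_mm: float = 0.05
    layer_shared_sigma_mm: float = 0.0  # optional layer-level common offset

    def __post_init__(self) -> None:
        for name in ("random_sigma_x_mm", "random_sigma_y_mm",
                     "pulse_jitter_sigma_mm", "layer_shared_sigma_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.mu_noise_frac < 1:
            raise ValueError("mu_noise_frac must lie in [0, 1)")

    def systematic(self, gantry_angle_deg: float, energy_mev: float) -> tuple[float, float]:
        sx = self.systematic_x_mm
        sy = self.systematic_y_mm
        if callable(sx):
            sx = sx(gantry_angle_deg, energy_mev)
        if callable(sy):
            sy = sy(gantry_angle_deg, energy_mev)
        return float(sx), float(sy)


@dataclass
class StructurePrimitive:
    """A sphere or axis-aligned box rasterized onto the phantom grid."""

    name: str
    kind: str                      # "sphere" | "box"
    center_mm: Sequence[float]
    radius_mm: float = 0.0         # sphere
    half_size_mm: Sequence[float] = (0.0, 0.0, 0.0)  # box
    rsp: float | None = None       # override the region's stopping power


@dataclass
class PhantomSpec:
    origin_mm: Sequence[float] = (-55.0, -55.0, -55.0)
    spacing_mm: Sequence[float] = (2.5, 2.5, 2.5)
    shape: Sequence[int] = (44, 44, 44)
    background_rsp: float = 1.0
    structures: list[StructurePrimitive] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.spacing_mm) <= 0):
            raise ValueError("spacing must be positive")


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, StructureSet]:
    """Rasterize a phantom spec to an RSP grid plus boolean structure masks."""
    grid = VoxelGrid(np.asarray(spec.origin_mm, float),
                     np.asarray(spec.spacing_mm, float),
                     np.full(tuple(spec.shape), spec.background_rsp, dtype=float))
    centers = grid.voxel_centers()
    lo, hi = grid.bounds()
    masks: dict[str, np.ndarray] = {}
    for s in spec.structures:
        c = np.asarray(s.center_mm, float)
        if s.kind == "sphere":
            if np.any(c - s.radius_mm < lo) or np.any(c + s.radius_mm > hi):
                raise ValueError(f"structure {s.name!r} extends outside the grid")
            mask = np.sum((centers - c) ** 2, axis=1) <= s.radius_mm ** 2
        elif s.kind == "box":
            h = np.asarray(s.half_size_mm, float)
            if np.any(c - h < lo) or np.any(c + h > hi):
                raise ValueError(f"structure {s.name!r} extends outside the grid")
            mask = np.all(np.abs(centers - c) <= h, axis=1)
        else:
            raise ValueError(f"unknown primitive kind {s.kind!r}")
        mask = mask.reshape(grid.shape)
        if s.rsp is not None:
            grid.rsp[mask] = s.rsp
        masks[s.name] = mask
    if "CTV" in masks and not masks["CTV"].any():
        raise ValueError("CTV mask is empty")
    return grid, StructureSet(grid, masks)


@dataclass
class PlanSpec:
    """Geometric recipe for a synthetic PBS plan on a phantom."""

    prescription_cgy: float = 3000.0
    fractions: int = 5
    gantry_angles_deg: Sequence[float] = (345.0, 15.0)
    snout_extension_mm: float = 200.0
    spot_spacing_mm: float = 9.0
    layer_spacing_mm: float = 5.0       # WEPL between energy layers
    target_margin_mm: float = 15.0      # coverage margin: uniform-dose region = CTV + this
    lateral_margin_mm: float = 15.0     # spot lattice extent beyond CTV outline
    distal_margin_mm: float = 15.0      # extra range beyond distal CTV edge
    proximal_margin_mm: float = 15.0
    aperture_mode: str = "static"
    aperture_margin_mm: float = 17.0
    mu_range: tuple[float, float] = (0.8, 1.2)
    optimize_weights: bool = True       # conformal spot weighting toward uniform target dose
    setup_shift_mm: float = 5.0         # recommended robustness shift for this plan class

    def __post_init__(self) -> None:
        if self.mu_range[0] <= 0:
            raise ValueError("MU must be positive")
        if self.aperture_margin_mm < self.lateral_margin_mm:
            raise ValueError("aperture margin must cover the spot lattice margin")


def plan_spec_preset(name: str) -> PlanSpec:
    """Named plan profiles.

    ``two_beam``: two near-anterior beams, static aperture, generous margins,
    5 mm robustness shift (partial-breast-like geometry class).
    ``six_beam``: six beams (RAO/LAO/LPO/RPO/LL/RL pattern), dynamic
    per-layer aperture, 3 mm shift (cranial geometry class).
    ``zero_margin``: two-beam geometry stripped of every margin — a
    deliberately non-robust plan with a sharp distal gradient.
    """
    if name == "two_beam":
        return PlanSpec()
    if name == "six_beam":
        return PlanSpec(prescription_cgy=5040.0, fractions=28,
                        gantry_angles_deg=(45.0, 315.0, 225.0, 135.0, 270.0, 90.0),
                        aperture_mode="dynamic", setup_shift_mm=3.0)
    if name == "zero_margin":
        # zero RANGE margins: energy layers stop exactly at the distal CTV
        # edge, so the distal dose gradient sits on the target boundary and
        # range/setup perturbations along the beam axis cut into coverage.
        return PlanSpec(target_margin_mm=0.0, lateral_margin_mm=0.0,
                        distal_margin_mm=0.0, proximal_margin_mm=0.0,
                        aperture_margin_mm=0.0, gantry_angles_deg=(0.0,))
    raise KeyError(f"unknown plan preset {name!r}")


def _bev_outline(points_uv: np.ndarray, margin_mm: float) -> shapely.Geometry:
    hull = MultiPoint(points_uv).convex_hull
    if margin_mm > 0:
        hull = hull.buffer(margin_mm, quad_segs=8)
    return hull


def _polygon_vertices(geom: shapely.Geometry) -> np.ndarray:
    if geom.geom_type == "Point":
        geom = geom.buffer(1.0, quad_segs=4)
    elif geom.geom_type == "LineString":
        geom = geom.buffer(1.0, quad_segs=4)
    return np.asarray(geom.exterior.coords[:-1], dtype=float)


def generate_plan(grid: VoxelGrid, structures: StructureSet, spec: PlanSpec,
                  seed: int = 0, optics=None) -> TreatmentPlan:
    """Lay out beams, energy layers, spot lattices and apertures over the CTV.

    Per beam: the CTV is projected into the BEV plane; spots sit on a
    regular lattice covering that outline dilated by the lateral margin;
    the aperture is the outline dilated by the aperture margin; energy
    layers step in WEPL from the proximal to the distal CTV edge extended
    by the range margins.
    """
    from .dose import SpotOpticsModel, central_axis_wepl

    optics = optics or SpotOpticsModel()
    rng = np.random.default_rng(seed)
    ctv = structures["CTV"]
    if not ctv.any():
        raise ValueError("CTV mask is empty")
    centers = grid.voxel_centers().reshape(*grid.shape, 3)
    ctv_points = centers[ctv]
    isocenter = ctv_points.mean(axis=0)
    lo, hi = grid.bounds()

    beams: list[Beam] = []
    for k, gantry in enumerate(spec.gantry_angles_deg):
        direction, u_hat, v_hat = beam_unit_vectors(gantry)
        try:
            t_entry = ray_box_entry(isocenter, direction, lo, hi)
        except ValueError:
            raise ValueError(f"beam {k} (gantry {gantry}) does not intersect the CTV region")
        rel = ctv_points - isocenter
        uu = rel @ u_hat
        vv = rel @ v_hat
        depth_geo = rel @ direction - t_entry      # geometric depth of CTV voxels
        # WEPL of the CTV extent along the central axis
        t_grid, cum_wepl = central_axis_wepl(grid, isocenter, direction, 1.0)
        wepl_of = lambda d: np.interp(d, t_grid - t_entry, cum_wepl)
        w_min = float(wepl_of(depth_geo.min())) - spec.proximal_margin_mm
        w_max = float(wepl_of(depth_geo.max())) + spec.distal_margin_mm
        w_min = max(w_min, 2.0)
        # layers descend from the distal edge so the deepest peak sits exactly
        # at w_max; a zero distal margin therefore gives a sharp distal gradient
        n_layers = max(1, int(np.floor((w_max - w_min) / spec.layer_spacing_mm)) + 1)
        layer_wepls = (w_max - np.arange(n_layers) * spec.layer_spacing_mm)[::-1]

        outline = _bev_outline(np.stack([uu, vv], axis=1), 0.0)
        lattice_region = outline.buffer(spec.lateral_margin_mm) if spec.lateral_margin_mm > 0 else outline
        aperture_poly = _bev_outline(np.stack([uu, vv], axis=1), spec.aperture_margin_mm)

        # spot lattice over the lattice region's bounding box
        bx0, by0, bx1, by1 = lattice_region.bounds
        us = np.arange(bx0, bx1 + spec.spot_spacing_mm, spec.spot_spacing_mm)
        vs = np.arange(by0, by1 + spec.spot_spacing_mm, spec.spot_spacing_mm)
        uu_l, vv_l = np.meshgrid(us, vs, indexing="ij")
        pts = np.stack([uu_l.ravel(), vv_l.ravel()], axis=1)
        inside = shapely.covers(lattice_region, shapely.points(pts))
        lattice = pts[inside]
        if lattice.size == 0:
            c = lattice_region.centroid
            lattice = np.array([[c.x, c.y]])

        layers = []
        layer_polys = []
        for w in layer_wepls:
            if spec.aperture_mode == "dynamic":
                band = np.abs(wepl_of(depth_geo) - w) <= spec.layer_spacing_mm
                if band.sum() >= 3:
                    poly = _bev_outline(np.stack([uu[band], vv[band]], axis=1),
                                        max(spec.aperture_margin_mm, 1.0))
                else:
                    poly = aperture_poly
            else:
                poly = aperture_poly
            layer_polys.append(poly)
            keep = shapely.covers(poly, shapely.points(lattice))
            spots_uv = lattice[keep]
            if spots_uv.size == 0:
                c = poly.centroid
                spots_uv = np.array([[c.x, c.y]])
            mus = rng.uniform(*spec.mu_range, size=len(spots_uv))
            energy = optics.energy_for_range_mm(float(w))
            layers.append(EnergyLayer(energy, [Spot(float(u), float(v), float(m))
                                               for (u, v), m in zip(spots_uv, mus)]))
        if spec.aperture_mode == "dynamic":
            aperture = Aperture("dynamic", [_polygon_vertices(p) for p in layer_polys])
        else:
            aperture = Aperture("static", [_polygon_vertices(aperture_poly)])
        beams.append(Beam(f"beam{k}", gantry, spec.snout_extension_mm,
                          isocenter, layers, aperture))
    plan = TreatmentPlan("synthetic", spec.prescription_cgy, spec.fractions, beams)
    if spec.optimize_weights:
        _optimize_spot_weights(plan, grid, ctv, spec, optics, rng)
    return plan


def _optimize_spot_weights(plan: TreatmentPlan, grid: VoxelGrid, ctv_mask: np.ndarray,
                           spec: PlanSpec, optics, rng: np.random.Generator,
                           max_points: int = 1500) -> None:
    """Conformal spot weighting: bounded (non-negative, ridge-regularized)
    least squares toward a uniform unit dose over the CTV dilated by the
    coverage margin — a stand-in for the TPS intensity optimization that
    shapes clinical input plans.  Weights are rescaled so the hottest spot
    carries 2 MU; a tiny floor keeps every planned spot's MU positive."""
    from scipy.ndimage import distance_transform_edt
    from scipy.optimize import lsq_linear

    from .dose import spot_dose_at_points

    dist_out = distance_transform_edt(~ctv_mask, sampling=grid.spacing_mm)
    target = dist_out <= spec.target_margin_mm
    # clip the uniform-dose region in depth by the range margins, per beam:
    # with a zero distal margin the target (hence the optimized dose) stops
    # at the distal CTV edge, leaving the sharp Bragg falloff on the boundary
    centers3 = grid.voxel_centers().reshape(*grid.shape, 3)
    ctv_pts = centers3[ctv_mask]
    flat_t = centers3.reshape(-1, 3)
    window = np.ones(len(flat_t), dtype=bool)
    for beam in plan.beams:
        direction, _, _ = beam_unit_vectors(beam.gantry_angle_deg)
        t_ctv = (ctv_pts - beam.isocenter_mm) @ direction
        t_all = (flat_t - beam.isocenter_mm) @ direction
        window &= (t_all >= t_ctv.min() - spec.proximal_margin_mm) & \
                  (t_all <= t_ctv.max() + spec.distal_margin_mm)
    target &= window.reshape(grid.shape)
    target |= ctv_mask  # the CTV itself always belongs to the target region
    points = centers3[target]
    if len(points) > max_points:
        points = points[rng.choice(len(points), size=max_points, replace=False)]
    cols = []
    for beam in plan.beams:
        for layer in beam.layers:
            for s in layer.spots:
                cols.append(spot_dose_at_points(points, beam, layer.energy_mev,
                                                np.array([s.x_mm, s.y_mm]), grid, optics))
    A = np.stack(cols, axis=1)
    lam = 1e-3 * float(np.mean(np.linalg.norm(A, axis=0))) ** 2
    n = A.shape[1]
    A_reg = np.vstack([A, np.sqrt(lam) * np.eye(n)])
    b = np.concatenate([np.ones(len(points)), np.zeros(n)])
    res = lsq_linear(A_reg, b, bounds=(0.0, np.inf), tol=1e-10)
    w = np.maximum(res.x, 0.0)
    if w.max() <= 0:
        raise RuntimeError("spot-weight optimization produced an all-zero plan")
    w = w * (2.0 / w.max())
    # prune spots the optimizer switched off (keeping >= 1 spot per layer);
    # the retained floor keeps every planned MU strictly positive
    k = 0
    for beam in plan.beams:
        for layer in beam.layers:
            w_layer = w[k:k + len(layer.spots)]
            keep = w_layer >= 1e-3
            if not keep.any():
                keep[int(np.argmax(w_layer))] = True
            layer.spots = [Spot(s.x_mm, s.y_mm, float(max(wi, 1e-6)))
                           for s, wi, kp in zip(layer.spots, w_layer, keep) if kp]
            k += len(w_layer)


def _synthesize_beam_pulses(planned: pd.DataFrame, truth: ErrorModelTruth,
                            gantry_angle_deg: float, pulses_per_spot: int,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Expand a planned-spot table into pulse rows with the truth's errors.

    ``planned`` needs columns x, y, mu, energy and optionally layer (for the
    layer-shared offset).  Per spot: delivered position = planned +
    systematic(gantry, E) + N(0, sigma) (+ shared layer offset), delivered
    MU = planned MU * (1 + mu noise); pulse actual positions scatter
    zero-mean about the delivered position and pulse actual MUs sum exactly
    to the delivered MU.
    """
    n = len(planned)
    P = int(pulses_per_spot)
    if P < 1:
        raise ValueError("pulses_per_spot must be >= 1")
    energy = planned["energy"].to_numpy()
    sys_xy = np.array([truth.systematic(gantry_angle_deg, e) for e in energy])
    dx = sys_xy[:, 0] + rng.normal(0.0, truth.random_sigma_x_mm, size=n)
    dy = sys_xy[:, 1] + rng.normal(0.0, truth.random_sigma_y_mm, size=n)
    if truth.layer_shared_sigma_mm > 0 and "layer" in planned:
        layers, inv = np.unique(planned["layer"].to_numpy(), return_inverse=True)
        shared = rng.normal(0.0, truth.layer_shared_sigma_mm, size=(len(layers), 2))
        dx = dx + shared[inv, 0]
        dy = dy + shared[inv, 1]
    mu_eps = rng.normal(0.0, truth.mu_noise_frac, size=n) if truth.mu_noise_frac > 0 else np.zeros(n)
    mu_eps = np.clip(mu_eps, -0.9, None)
    delivered_x = planned["x"].to_numpy() + dx
    delivered_y = planned["y"].to_numpy() + dy
    delivered_mu = planned["mu"].to_numpy() * (1.0 + mu_eps)

    rep = np.repeat(np.arange(n), P)
    jitter = (rng.normal(0.0, truth.pulse_jitter_sigma_mm, size=(n * P, 2))
              if truth.pulse_jitter_sigma_mm > 0 else np.zeros((n * P, 2)))
    return pd.DataFrame({
        "pulse_index": np.arange(n * P),
        "spot_index": rep,
        "nominal_energy_mev": energy[rep],
        "target_x_mm": planned["x"].to_numpy()[rep],
        "target_y_mm": planned["y"].to_numpy()[rep],
        "actual_x_mm": delivered_x[rep] + jitter[:, 0],
        "actual_y_mm": delivered_y[rep] + jitter[:, 1],
        "target_mu": planned["mu"].to_numpy()[rep] / P,
        "actual_mu": delivered_mu[rep] / P,
    }, columns=PULSE_COLUMNS)


def generate_log_files(plan: TreatmentPlan, truth: ErrorModelTruth,
                       pulses_per_spot: int = 8, seed: int = 0,
                       date: str = "1970-01-01") -> list[LogFile]:
    """One pulse-level log file per beam, with the truth's error structure."""
    rng = np.random.default_rng(seed)
    logs = []
    for beam in plan.beams:
        rows = [(s.x_mm, s.y_mm, s.mu, layer.energy_mev, li)
                for li, layer in enumerate(beam.layers) for s in layer.spots]
        planned = pd.DataFrame(rows, columns=["x", "y", "mu", "energy", "layer"])
        pulses = _synthesize_beam_pulses(planned, truth, beam.gantry_angle_deg,
                                         pulses_per_spot, rng)
        header = LogHeader(date=date, plan_id=plan.plan_id, beam_id=beam.beam_id,
                           gantry_angle_deg=beam.gantry_angle_deg,
                           snout_extension_mm=beam.snout_extension_mm,
                           total_prescribed_mu=float(planned["mu"].sum()))
        logs.append(LogFile(header, pulses))
    return logs


def generate_training_corpus(n_spots: int, truth: ErrorModelTruth, seed: int = 0,
                             pulses_per_spot: int = 5, n_beams: int = 25) -> list[LogFile]:
    """A mixed-field log corpus for model training.

    Beams span the gantry circle, snout extensions and the clinical energy
    range; spot positions cover +/-100 mm of the scanning field with MUs in
    a realistic per-spot range.
    """
    rng = np.random.default_rng(seed)
    per_beam = np.full(n_beams, n_spots // n_beams)
    per_beam[: n_spots % n_beams] += 1
    logs = []
    for b in range(n_beams):
        n = int(per_beam[b])
        if n == 0:
            continue
        gantry = float(rng.uniform(0.0, 360.0))
        snout = float(rng.uniform(100.0, 300.0))
        planned = pd.DataFrame({
            "x": rng.uniform(-100.0, 100.0, size=n),
            "y": rng.uniform(-100.0, 100.0, size=n),
            "mu": rng.uniform(0.2, 2.0, size=n),
            "energy": rng.uniform(50.0, 180.0, size=n),
        })
        pulses = _synthesize_beam_pulses(planned, truth, gantry, pulses_per_spot, rng)
        header = LogHeader(date="1970-01-01", plan_id="corpus", beam_id=f"corpus{b}",
                           gantry_angle_deg=gantry, snout_extension_mm=snout,
                           total_prescribed_mu=float(planned["mu"].sum()))
        logs.append(LogFile(header, pulses))
    return logs


@dataclass
class QaSession:
    """One QA measurement: nominal, log-recorded and detector-measured positions."""

    gantry_angle_deg: float
    nominal_mm: np.ndarray    # (n, 2)
    recorded_mm: np.ndarray   # (n, 2) positions written to the log
    measured_mm: np.ndarray   # (n, 2) detector positions (quantized)
    energy_mev: float = 150.0
    detector_resolution_mm: float = 0.5


def generate_qa_grid(gantry_angle_deg: float, truth: ErrorModelTruth,
                     detector_resolution_mm: float = 0.5, seed: int = 0,
                     grid_n: int = 11, grid_spacing_mm: float = 20.0,
                     detector_noise_sigma_mm: float = 0.15,
                     energy_mev: float = 150.0) -> QaSession:
    """Simulate an evenly spaced odd QA spot grid (default 11 x 11).

    Recorded positions carry the truth's systematic + random error; measured
    positions add isotropic detector noise and are quantized to the
    detector's spatial resolution.
    """
    if grid_n % 2 == 0 or grid_n < 1:
        raise ValueError("grid dimension must be odd and positive")
    rng = np.random.default_rng(seed)
    half = (grid_n - 1) / 2.0
    axis = (np.arange(grid_n) - half) * grid_spacing_mm
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    nominal = np.stack([gx.ravel(), gy.ravel()], axis=1)
    sx, sy = truth.systematic(gantry_angle_deg, energy_mev)
    recorded = nominal + np.array([sx, sy]) + rng.normal(
        0.0, [max(truth.random_sigma_x_mm, 0.0), max(truth.random_sigma_y_mm, 0.0)],
        size=nominal.shape)
    measured = recorded + rng.normal(0.0, detector_noise_sigma_mm, size=nominal.shape)
    if detector_resolution_mm > 0:
        measured = np.round(measured / detector_resolution_mm) * detector_resolution_mm
    return QaSession(gantry_angle_deg, nominal, recorded, measured,
                     energy_mev, detector_resolution_mm)


def save_qa_session(path, session: QaSession) -> None:
    df = pd.DataFrame({
        "nominal_x_mm": session.nominal_mm[:, 0], "nominal_y_mm": session.nominal_mm[:, 1],
        "recorded_x_mm": session.recorded_mm[:, 0], "recorded_y_mm": session.recorded_mm[:, 1],
        "measured_x_mm": session.measured_mm[:, 0], "measured_y_mm": session.measured_mm[:, 1],
    })
    with open(path, "w") as fh:
        fh.write(f"# gantry_angle_deg={session.gantry_angle_deg!r}\n")
        fh.write(f"# energy_mev={session.energy_mev!r}\n")
        fh.write(f"# detector_resolution_mm={session.detector_resolution_mm!r}\n")
        df.to_csv(fh, index=False)


def load_qa_session(path) -> QaSession:
    import io as _io
    text = open(path).read().splitlines()
    meta = {}
    n_hdr = 0
    for line in text:
        if not line.startswith("#"):
            break
        n_hdr += 1
        k, v = line[1:].strip().split("=", 1)
        meta[k.strip()] = float(v)
    df = pd.read_csv(_io.StringIO("\n".join(text[n_hdr:])), float_precision="round_trip")
    return QaSession(meta["gantry_angle_deg"],
                     df[["nominal_x_mm", "nominal_y_mm"]].to_numpy(),
                     df[["recorded_x_mm", "recorded_y_mm"]].to_numpy(),
                     df[["measured_x_mm", "measured_y_mm"]].to_numpy(),
                     meta.get("energy_mev", 150.0),
                     meta.get("detector_resolution_mm", 0.5))
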