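"""Treatment-plan containers (beams → energy layers → spots) and JSON I/O.

Spot coordinates are beam's-eye-view (u = crossplane, v = inplane) mm at
isocenter; MU are monitor units.  An aperture is a simple polygon in the
same BEV frame, either static (one shape for every energy layer) or
dynamic (one shape per layer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class Spot:
    x_mm: float
    y_mm: float
    mu: float

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("spot MU must be non-negative")


@dataclass
class EnergyLayer:
    energy_mev: float
    spots: list[Spot] = field(default_factory=list)


@dataclass
class Aperture:
    """Collimating polygon(s) in the BEV frame.

    mode "static": ``polygons`` holds one vertex list used for all layers;
    mode "dynamic": one vertex list per energy layer.
    """

    mode: str
    polygons: list[np.ndarray]

    def __post_init__(self) -> None:
        if self.mode not in ("static", "dynamic"):
            raise ValueError(f"unknown aperture mode {self.mode!r}")
        self.polygons = [np.asarray(p, dtype=float) for p in self.polygons]
        for p in self.polygons:
            if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
                raise ValueError("aperture polygon needs >= 3 (u, v) vertices")

    def polygon_for_layer(self, layer_index: int) -> np.ndarray:
        if self.mode == "static":
            return self.polygons[0]
        return self.polygons[layer_index]


@dataclass
class Beam:
    beam_id: str
    gantry_angle_deg: float
    snout_extension_mm: float
    isocenter_mm: np.ndarray
    layers: list[EnergyLayer] = field(default_factory=list)
    aperture: Aperture | None = None

    def __post_init__(self) -> None:
        self.isocenter_mm = np.asarray(self.isocenter_mm, dtype=float)
        if not 0.0 <= self.gantry_angle_deg < 360.0:
            raise ValueError("gantry angle must lie in [0, 360)")

    @property
    def n_spots(self) -> int:
        return sum(len(layer.spots) for layer in self.layers)

    def total_mu(self) -> float:
        return float(sum(s.mu for layer in self.layers for s in layer.spots))


@dataclass
class TreatmentPlan:
    plan_id: str
    prescription_cgy: float
    fractions: int
    beams: list[Beam] = field(default_factory=list)

    @property
    def n_spots(self) -> int:
        return sum(b.n_spots for b in self.beams)

    def spot_table(self) -> list[tuple[int, int, int, Spot]]:
        """Flatten to delivery order: (beam_idx, layer_idx, spot_idx, spot)."""
        rows = []
        for bi, beam in enumerate(self.beams):
            for li, layer in enumerate(beam.layers):
                for si, spot in enumerate(layer.spots):
                    rows.append((bi, li, si, spot))
        return rows

    def scale_mu(self, factor: float) -> "TreatmentPlan":
        """Return a copy with every spot MU multiplied by ``factor``."""
        return replace_spots(
            self,
            {(bi, li, si): Spot(s.x_mm, s.y_mm, s.mu * factor)
             for bi, li, si, s in self.spot_table()},
        )


def replace_spots(plan: TreatmentPlan, new_spots: dict[tuple[int, int, int], Spot]) -> TreatmentPlan:
    """Copy a plan, substituting spots addressed by (beam, layer, spot) index."""
    beams = []
    for bi, beam in enumerate(plan.beams):
        layers = []
        for li, layer in enumerate(beam.layers):
            spots = [new_spots.get((bi, li, si), s) for si, s in enumerate(layer.spots)]
            layers.append(EnergyLayer(layer.energy_mev, spots))
        beams.append(Beam(beam.beam_id, beam.gantry_angle_deg, beam.snout_extension_mm,
                          beam.isocenter_mm.copy(), layers, beam.aperture))
    return TreatmentPlan(plan.plan_id, plan.prescription_cgy, plan.fractions, beams)


def drop_spots(plan: TreatmentPlan, spot_ids: set[tuple[int, int, int]]) -> TreatmentPlan:
    """Copy a plan with the addressed spots removed."""
    known = {(bi, li, si) for bi, li, si, _ in plan.spot_table()}
    unknown = spot_ids - known
    if unknown:
        raise KeyError(f"unknown spot ids: {sorted(unknown)}")
    beams = []
    for bi, beam in enumerate(plan.beams):
        layers = []
        for li, layer in enumerate(beam.layers):
            spots = [s for si, s in enumerate(layer.spots) if (bi, li, si) not in spot_ids]
            layers.append(EnergyLayer(layer.energy_mev, spots))
        beams.append(Beam(beam.beam_id, beam.gantry_angle_deg, beam.snout_extension_mm,
                          beam.isocenter_mm.copy(), layers, beam.aperture))
    return TreatmentPlan(plan.plan_id, plan.prescription_cgy, plan.fractions, beams)


def plan_to_dict(plan: TreatmentPlan) -> dict:
    return {
        "plan_id": plan.plan_id,
        "prescription_cgy": plan.prescription_cgy,
        "fractions": plan.fractions,
        "beams": [
            {
                "beam_id": b.beam_id,
                "gantry_angle_deg": b.gantry_angle_deg,
                "snout_extension_mm": b.snout_extension_mm,
                "isocenter_mm": b.isocenter_mm.tolist(),
                "aperture": None if b.aperture is None else {
                    "mode": b.aperture.mode,
                    "polygons": [p.tolist() for p in b.aperture.polygons],
                },
                "layers": [
                    {
                        "energy_mev": layer.energy_mev,
                        "spots": [[s.x_mm, s.y_mm, s.mu] for s in layer.spots],
                    }
                    for layer in b.layers
                ],
            }
            for b in plan.beams
        ],
    }


def plan_from_dict(d: dict) -> TreatmentPlan:
    beams = []
    for bd in d["beams"]:
        aperture = None
        if bd.get("aperture"):
            aperture = Aperture(bd["aperture"]["mode"],
                                [np.array(p) for p in bd["aperture"]["polygons"]])
        layers = [
            EnergyLayer(ld["energy_mev"], [Spot(*row) for row in ld["spots"]])
            for ld in bd["layers"]
        ]
        beams.append(Beam(bd["beam_id"], bd["gantry_angle_deg"], bd["snout_extension_mm"],
                          np.array(bd["isocenter_mm"]), layers, aperture))
    return TreatmentPlan(d["plan_id"], d["prescription_cgy"], d["fractions"], beams)


def save_plan(path: str | Path, plan: TreatmentPlan) -> None:
    Path(path).write_text(json.dumps(plan_to_dict(plan), indent=2))


def load_plan(path: str | Path) -> TreatmentPlan:
    return plan_from_dict(json.loads(Path(path).read_text()))
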