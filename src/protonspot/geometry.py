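"""Voxel-grid containers and beam-frame geometry.

Patient axes follow the usual convention: x = right-left (RL),
y = inferior-superior (IS), z = posterior-anterior (PA), all in mm.
The gantry rotates in the axial (x-z) plane about the isocenter; the
beam's-eye-view (BEV) axes are u = crossplane (in the axial plane,
perpendicular to the beam) and v = inplane (= patient y).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class VoxelGrid:
    """Regular voxel grid carrying relative stopping power (RSP)."""

    origin_mm: np.ndarray          # (3,) corner of voxel (0,0,0)
    spacing_mm: np.ndarray         # (3,) > 0
    rsp: np.ndarray                # (nx, ny, nz) relative stopping power

    def __post_init__(self) -> None:
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.rsp = np.asarray(self.rsp, dtype=float)
        if np.any(self.spacing_mm <= 0):
            raise ValueError("voxel spacing must be positive")
        if np.any(self.rsp <= 0):
            raise ValueError("relative stopping power must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.rsp.shape

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    def voxel_centers(self) -> np.ndarray:
        """Return an (n_voxels, 3) array of voxel-center coordinates in mm."""
        axes = [
            self.origin_mm[i] + (np.arange(self.shape[i]) + 0.5) * self.spacing_mm[i]
            for i in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.origin_mm
        hi = self.origin_mm + self.spacing_mm * np.array(self.shape)
        return lo, hi

    def center_mm(self) -> np.ndarray:
        lo, hi = self.bounds()
        return (lo + hi) / 2.0


@dataclass
class StructureSet:
    """Named boolean masks sharing one grid geometry."""

    grid: VoxelGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise KeyError(f"structure {name!r} not defined")
        return self.masks[name]

    def volume_cc(self, name: str) -> float:
        return float(np.count_nonzero(self[name])) * self.grid.voxel_volume_cc

    def names(self) -> list[str]:
        return list(self.masks)


@dataclass
class DoseGrid:
    """Dose in cGy(RBE) on the geometry of an existing :class:`VoxelGrid`."""

    grid: VoxelGrid
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.grid.shape:
            raise ValueError("dose array does not match grid shape")
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")


def beam_unit_vectors(gantry_angle_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Beam direction and BEV axes for a gantry angle.

    Returns ``(direction, u_hat, v_hat)``: the unit vector the beam travels
    along, the crossplane axis and the inplane axis.  At gantry 0 the beam
    enters anteriorly and travels toward +z.
    """
    g = np.deg2rad(gantry_angle_deg)
    direction = np.array([np.sin(g), 0.0, np.cos(g)])
    u_hat = np.array([np.cos(g), 0.0, -np.sin(g)])
    v_hat = np.array([0.0, 1.0, 0.0])
    return direction, u_hat, v_hat


def ray_box_entry(point: np.ndarray, direction: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> float:
    """Parameter t at which the ray ``point + t*direction`` enters the box.

    Returns the entry t (may be negative if ``point`` is inside the box);
    raises if the ray misses the box entirely.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - point) / direction
        t2 = (hi - point) / direction
    tmin = np.where(np.isfinite(t1), np.minimum(t1, t2), -np.inf)
    tmax = np.where(np.isfinite(t2), np.maximum(t1, t2), np.inf)
    # Axes with zero direction: ray parallel; inside-slab check.
    for ax in range(3):
        if direction[ax] == 0.0 and not (lo[ax] <= point[ax] <= hi[ax]):
            raise ValueError("ray misses the grid")
    t_enter = float(np.max(tmin))
    t_exit = float(np.min(tmax))
    if t_enter > t_exit:
        raise ValueError("ray misses the grid")
    return t_enter


def save_grid(path: str | Path, grid: VoxelGrid, masks: dict[str, np.ndarray] | None = None,
              dose: np.ndarray | None = None) -> None:
    """Write a grid (plus optional masks/dose) as .npz with a JSON geometry sidecar."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {"rsp": grid.rsp}
    if masks:
        for name, m in masks.items():
            arrays[f"mask__{name}"] = m.astype(bool)
    if dose is not None:
        arrays["dose"] = dose
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "origin_mm": grid.origin_mm.tolist(),
        "spacing_mm": grid.spacing_mm.tolist(),
        "shape": list(grid.shape),
        "structures": sorted(masks) if masks else [],
        "has_dose": dose is not None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_grid(path: str | Path) -> tuple[VoxelGrid, StructureSet, np.ndarray | None]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path.with_suffix(".npz"))
    grid = VoxelGrid(np.array(meta["origin_mm"]), np.array(meta["spacing_mm"]), data["rsp"])
    masks = {name: data[f"mask__{name}"] for name in meta["structures"]}
    dose = data["dose"] if meta.get("has_dose") else None
    return grid, StructureSet(grid, masks), dose
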