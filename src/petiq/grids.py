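"""Regular world-space grids and volumetric containers.

All geometry is expressed in world millimetres.  A :class:`Grid` maps voxel
indices ``(i, j, k)`` (array axes x, y, z) to world coordinates through
``world = origin + index * spacing``; ``origin`` is the centre of voxel
``(0, 0, 0)``.  Volumes built by the simulator place the world origin at the
phantom centre, so grids are usually constructed with :meth:`Grid.centered`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConfigError

__all__ = [
    "Grid",
    "ActivityVolume",
    "CountVolume",
    "save_volume",
    "load_volume",
]


@dataclass(frozen=True)
class Grid:
    """A regular 3-D voxel grid with spacing and origin in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ConfigError("Grid shape, spacing and origin must be 3-vectors")
        if any(n <= 0 for n in self.shape):
            raise ConfigError(f"grid shape must be positive, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ConfigError(f"voxel size must be positive, got {self.spacing}")

    @classmethod
    def centered(cls, shape, spacing) -> "Grid":
        """Grid whose voxel-centre cloud is symmetric about the world origin."""
        shape = tuple(int(n) for n in shape)
        spacing = tuple(float(s) for s in spacing)
        origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
        return cls(shape, spacing, origin)

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def meshgrid(self):
        """Broadcastable (open) world-coordinate arrays (X, Y, Z)."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([*self.spacing, 1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class ActivityVolume:
    """3-D scalar field (activity concentration or SUV) on a regular grid."""

    data: np.ndarray
    grid: Grid
    units: str = "kBq/ml"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != tuple(self.grid.shape):
            raise ConfigError(
                f"data shape {self.data.shape} does not match grid {self.grid.shape}"
            )

    def with_data(self, data: np.ndarray, units: str | None = None) -> "ActivityVolume":
        return ActivityVolume(data, self.grid, units or self.units)

    @property
    def total_activity(self) -> float:
        """Sum of voxel values times voxel volume (e.g. total kBq)."""
        return float(self.data.sum()) * self.grid.voxel_volume_ml


@dataclass
class CountVolume:
    """Simulated detected counts per voxel.

    ``scale`` is the deterministic counts-per-(kBq/ml) factor (voxel volume ×
    sensitivity × time × keep-fraction); dividing by it converts counts back
    into the concentration units of the originating :class:`ActivityVolume`.
    """

    data: np.ndarray
    grid: Grid
    scale: float
    source_units: str = "kBq/ml"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != tuple(self.grid.shape):
            raise ConfigError(
                f"data shape {self.data.shape} does not match grid {self.grid.shape}"
            )
        if self.scale < 0:
            raise ConfigError("count scale factor must be non-negative")

    def to_activity(self) -> ActivityVolume:
        """Convert counts back to concentration by the deterministic scale."""
        if self.scale == 0:
            raise ConfigError("cannot convert a zero-scale (zero-time) count volume")
        return ActivityVolume(self.data / self.scale, self.grid, self.source_units)


def save_volume(volume: ActivityVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with a JSON sidecar declaring units."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), volume.grid.affine)
    img.header.set_zooms(volume.grid.spacing)
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    sidecar.write_text(json.dumps({"units": volume.units}, indent=2) + "\n")
    return path


def load_volume(path: str | Path) -> ActivityVolume:
    """Read a NIfTI-1 volume written by :func:`save_volume`."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(v) for v in aff[:3, 3])
    grid = Grid(tuple(int(n) for n in data.shape), spacing, origin)
    units = "kBq/ml"
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        units = json.loads(sidecar.read_text()).get("units", units)
    return ActivityVolume(data, grid, units)
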