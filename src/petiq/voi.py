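"""Volume-of-interest construction and per-VOI statistics.

Masks use voxel-centre containment (a voxel belongs to a shape iff its
centre does), so masks are deterministic, resolution-convergent and share
the grid of the volume they are measured on.  Standard deviations are sample
(n−1) by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DegenerateVOIError, NoLesionError, PlacementError
from .grids import ActivityVolume, Grid
from .phantom import PhantomSpec

__all__ = [
    "VOIMask",
    "VOIStats",
    "make_sphere_voi",
    "make_cylinder_voi",
    "place_background_vois",
    "threshold_lesion_voi",
    "voi_stats",
]


@dataclass(frozen=True)
class VOIMask:
    """Boolean voxel set plus the shape descriptor it was built from."""

    mask: np.ndarray
    grid: Grid
    kind: str
    center_mm: tuple[float, float, float]
    dims_mm: tuple[float, ...]

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_ml


@dataclass(frozen=True)
class VOIStats:
    mean: float
    sd: float
    max: float
    voxel_count: int
    volume_ml: float


def make_sphere_voi(center_mm, diameter_mm: float, grid: Grid) -> VOIMask:
    """Spherical VOI; e.g. one matching a fillable sphere, or the 3 cm liver VOI."""
    if diameter_mm <= 0:
        raise ConfigError("sphere diameter must be > 0")
    cx, cy, cz = (float(v) for v in center_mm)
    X, Y, Z = grid.meshgrid()
    mask = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= (diameter_mm / 2.0) ** 2
    if not mask.any():
        raise DegenerateVOIError(
            f"sphere VOI (d={diameter_mm} mm at {center_mm}) contains no voxel centre"
        )
    return VOIMask(mask, grid, "sphere", (cx, cy, cz), (diameter_mm,))


def make_cylinder_voi(
    center_mm, diameter_mm: float, height_mm: float, grid: Grid, axis=(0.0, 0.0, 1.0)
) -> VOIMask:
    """Finite circular cylinder around ``axis`` (default axial/z)."""
    if diameter_mm <= 0 or height_mm <= 0:
        raise ConfigError("cylinder dimensions must be > 0")
    u = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ConfigError("cylinder axis must be a non-zero vector")
    u = u / norm
    cx, cy, cz = (float(v) for v in center_mm)
    X, Y, Z = grid.meshgrid()
    dx, dy, dz = X - cx, Y - cy, Z - cz
    axial = dx * u[0] + dy * u[1] + dz * u[2]
    radial2 = (dx * dx + dy * dy + dz * dz) - axial * axial
    mask = (np.abs(axial) <= height_mm / 2.0) & (radial2 <= (diameter_mm / 2.0) ** 2)
    if not mask.any():
        raise DegenerateVOIError("cylinder VOI contains no voxel centre")
    return VOIMask(mask, grid, "cylinder", (cx, cy, cz), (diameter_mm, height_mm))


def _point_to_ellipse_distance(point_xy, semi_axes, n_samples: int = 4096) -> float:
    """Distance from an interior point to an axis-aligned ellipse boundary."""
    a, b = semi_axes
    phi = np.linspace(0.0, 2.0 * np.pi, n_samples, endpoint=False)
    return float(
        np.min(np.hypot(a * np.cos(phi) - point_xy[0], b * np.sin(phi) - point_xy[1]))
    )


def place_background_vois(
    spec: PhantomSpec,
    grid: Grid,
    n: int = 6,
    diameter_mm: float = 27.0,
    height_mm: float = 70.0,
    clearance_mm: float = 15.0,
) -> list[VOIMask]:
    """Deterministic ring of axial background cylinders.

    Centres sit on an ellipse shrunk from the body outline, at equal angular
    spacing rotated half a step from the sphere ring so every cylinder stays
    at least ``clearance_mm`` from each sphere surface, the lung insert and
    the body wall.  The exact positions are a convention of this package (the
    ring placement is not standardised).
    """
    if n < 1:
        raise ConfigError("need at least one background VOI")
    a, b = spec.body_semi_axes_mm
    voi_r = diameter_mm / 2.0
    ring_a = a - (clearance_mm + voi_r + 6.5)
    ring_b = b - (clearance_mm + voi_r + 1.5)
    if ring_a <= 0 or ring_b <= 0:
        raise PlacementError("background too small for the requested VOIs")
    offset = math.pi / n
    masks: list[VOIMask] = []
    for i in range(n):
        ang = offset + 2.0 * math.pi * i / n
        c = (ring_a * math.cos(ang), ring_b * math.sin(ang), 0.0)
        # clearance checks (in-plane distances are binding: cylinders and
        # spheres both straddle the central plane)
        for sc, d in zip(spec.sphere_centers_mm, spec.sphere_diameters_mm):
            gap = math.hypot(c[0] - sc[0], c[1] - sc[1]) - voi_r - d / 2.0
            if gap < clearance_mm:
                raise PlacementError(
                    f"background VOI {i} only {gap:.1f} mm from the {d:.0f} mm sphere"
                )
        if math.hypot(c[0], c[1]) - voi_r - spec.lung_diameter_mm / 2.0 < clearance_mm:
            raise PlacementError(f"background VOI {i} too close to the lung insert")
        if _point_to_ellipse_distance(c[:2], (a, b)) - voi_r < clearance_mm:
            raise PlacementError(f"background VOI {i} too close to the body wall")
        if spec.body_height_mm / 2.0 - height_mm / 2.0 < clearance_mm:
            raise PlacementError("background VOI too close to the end plates")
        masks.append(make_cylinder_voi(c, diameter_mm, height_mm, grid))
    return masks


def threshold_lesion_voi(
    volume: ActivityVolume,
    seed_point_mm,
    fraction: float = 0.5,
    search_radius_mm: float = 15.0,
    max_volume_ml: float = 100.0,
    liver_mask: VOIMask | None = None,
    fallback_diameter_mm: float = 10.0,
    background_level: float | None = None,
) -> VOIMask:
    """Isocontour lesion VOI: the connected component of voxels above
    ``fraction`` × (local max) that contains the hottest voxel near the seed.

    Falls back to a fixed small sphere at the hottest voxel when the
    component is implausibly large (> ``max_volume_ml``) or merges into the
    liver VOI — the cases where a relative threshold is meaningless.
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigError("threshold fraction must lie in (0, 1)")
    grid = volume.grid
    X, Y, Z = grid.meshgrid()
    sx, sy, sz = (float(v) for v in seed_point_mm)
    near = (X - sx) ** 2 + (Y - sy) ** 2 + (Z - sz) ** 2 <= search_radius_mm**2
    if not near.any():
        raise DegenerateVOIError("no voxel centre within the seed search radius")
    neighborhood = np.where(near, volume.data, -np.inf)
    peak_idx = np.unravel_index(int(np.argmax(neighborhood)), volume.data.shape)
    peak = float(volume.data[peak_idx])
    if background_level is not None and peak <= background_level:
        raise NoLesionError(
            f"peak value {peak:.3g} does not exceed background {background_level:.3g}"
        )
    binary = volume.data >= fraction * peak
    labels, _ = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=int))
    comp = labels == labels[peak_idx]
    peak_mm = (
        float(grid.axis_coords(0)[peak_idx[0]]),
        float(grid.axis_coords(1)[peak_idx[1]]),
        float(grid.axis_coords(2)[peak_idx[2]]),
    )
    comp_ml = float(comp.sum()) * grid.voxel_volume_ml
    touches_liver = liver_mask is not None and bool(np.any(comp & liver_mask.mask))
    if comp_ml > max_volume_ml or touches_liver:
        return make_sphere_voi(peak_mm, fallback_diameter_mm, grid)
    return VOIMask(comp, grid, "threshold", peak_mm, (fraction,))


def voi_stats(volume: ActivityVolume, mask: VOIMask) -> VOIStats:
    """Mean / sample SD / max / size of the voxels under a mask."""
    if mask.grid != volume.grid:
        raise ConfigError("mask and volume are defined on different grids")
    values = volume.data[mask.mask]
    if values.size == 0:
        raise DegenerateVOIError("empty VOI")
    if values.size < 2:
        raise DegenerateVOIError("single-voxel VOI: sample SD undefined")
    return VOIStats(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        max=float(values.max()),
        voxel_count=int(values.size),
        volume_ml=float(values.size) * volume.grid.voxel_volume_ml,
    )
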