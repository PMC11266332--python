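"""Synthetic activity sources and a post-reconstruction noise surrogate.

This module generates ground-truth activity maps for a NEMA image-quality
(IQ) body phantom and for simple synthetic patients (homogeneous liver plus
spherical lesions), and simulates the statistical properties of a
reconstructed PET image with a deliberately light-weight forward model:

1. the true activity map is blurred with an isotropic Gaussian point spread
   function (PSF, given as FWHM in mm);
2. the blurred expectation is scaled into expected detected counts per voxel
   (activity × voxel volume × system sensitivity × acquisition time);
3. each voxel receives an independent Poisson draw.

Lower injected activity (or shorter acquisition) is emulated by binomial
*count thinning*: every detected count is kept independently with
probability ``1 - r``, which maps Poisson(λ) voxels onto Poisson((1-r)·λ)
voxels exactly.

Penalized-likelihood reconstruction (BSREM-style, strength β) is emulated by
a documented surrogate: Gaussian post-smoothing whose width grows as
``σ(β) = σ_ref · sqrt(β / 300)``.  The surrogate reproduces the qualitative
behaviour that matters for the study design — noise (background variability)
falls and small-object contrast falls monotonically with β — but makes no
claim about any vendor algorithm.

No sinogram, attenuation, scatter or time-of-flight physics is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigError, GeometryError
from .grids import ActivityVolume, CountVolume, Grid

__all__ = [
    "GA68_HALF_LIFE_MIN",
    "FWHM_TO_SIGMA",
    "DEFAULT_BETAS",
    "DEFAULT_REDUCTIONS",
    "PhantomSpec",
    "AcquisitionConfig",
    "ReconParams",
    "Lesion",
    "PatientSpec",
    "build_nema_phantom",
    "build_patient_volume",
    "simulate_acquisition",
    "thin_counts",
    "beta_smooth",
    "decay_compensated_time",
    "default_phantom_shape",
    "default_patient_shape",
    "sphere_center_blur_fraction",
    "subcentimeter_fraction",
]

GA68_HALF_LIFE_MIN = 67.71
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

DEFAULT_BETAS = (150, 300, 450, 600)
DEFAULT_REDUCTIONS = (0.0, 0.17, 0.33, 0.50, 0.67)

#: sphere-to-background ratio presets: (sphere kBq/ml, background kBq/ml,
#: acquisition seconds per bed) at the start of each session
RATIO_PRESETS = {
    "10:1": (38.9, 4.0, 90.0),
    "4:1": (22.1, 5.2, 180.0),
    "2:1": (12.0, 5.4, 360.0),
}


def _validate_reduction(r: float) -> float:
    r = float(r)
    if not 0.0 <= r < 1.0:
        raise ConfigError(f"reduction fraction must lie in [0, 1), got {r}")
    return r


# ---------------------------------------------------------------------------
# phantom specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """NEMA IQ phantom geometry and compartment activities.

    Six fillable spheres sit on a ring in the central transaxial plane of an
    elliptical-cylinder body around a zero-activity lung insert.  Two 500 ml
    "arm" bottles rest against the body laterally.  All dimensions in mm,
    activities in kBq/ml.
    """

    sphere_diameters_mm: tuple[float, ...] = (37.0, 28.0, 22.0, 17.0, 13.0, 10.0)
    sphere_ring_radius_mm: float = 57.2
    body_semi_axes_mm: tuple[float, float] = (150.0, 115.0)
    body_height_mm: float = 180.0
    lung_diameter_mm: float = 50.0
    arm_bottle_diameter_mm: float = 80.0
    arm_bottle_volume_ml: float = 500.0
    sphere_activity_kBq_ml: float = 22.1
    background_activity_kBq_ml: float = 5.2
    bottle_activity_kBq_ml: float = 0.32
    ratio_label: str = "4:1"

    def __post_init__(self) -> None:
        self.validate()

    # -- derived geometry ---------------------------------------------------

    @property
    def sphere_centers_mm(self) -> tuple[tuple[float, float, float], ...]:
        """Sphere centres, equally spaced on the ring, largest sphere at 0°."""
        n = len(self.sphere_diameters_mm)
        out = []
        for i in range(n):
            ang = 2.0 * math.pi * i / n
            out.append(
                (
                    self.sphere_ring_radius_mm * math.cos(ang),
                    self.sphere_ring_radius_mm * math.sin(ang),
                    0.0,
                )
            )
        return tuple(out)

    @property
    def arm_bottle_height_mm(self) -> float:
        r = self.arm_bottle_diameter_mm / 2.0
        return self.arm_bottle_volume_ml * 1000.0 / (math.pi * r * r)

    @property
    def arm_bottle_centers_mm(self) -> tuple[tuple[float, float, float], ...]:
        """Bottles touch the body laterally at its widest point."""
        cx = self.body_semi_axes_mm[0] + self.arm_bottle_diameter_mm / 2.0
        return ((cx, 0.0, 0.0), (-cx, 0.0, 0.0))

    @property
    def true_ratio(self) -> float:
        return self.sphere_activity_kBq_ml / self.background_activity_kBq_ml

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for name in (
            "sphere_activity_kBq_ml",
            "background_activity_kBq_ml",
            "bottle_activity_kBq_ml",
        ):
            if getattr(self, name) < 0:
                raise GeometryError(f"{name} must be >= 0")
        if min(self.sphere_diameters_mm) <= 0:
            raise GeometryError("sphere diameters must be positive")
        a, b = self.body_semi_axes_mm
        centers = np.array(self.sphere_centers_mm)
        radii = np.array(self.sphere_diameters_mm) / 2.0
        # pairwise sphere overlap
        for i in range(len(radii)):
            for j in range(i + 1, len(radii)):
                d = float(np.linalg.norm(centers[i] - centers[j]))
                if d < radii[i] + radii[j]:
                    raise GeometryError(
                        f"spheres {i} and {j} overlap (centre distance {d:.1f} mm)"
                    )
        # lung insert clearance (lung is a full-height central cylinder)
        lung_r = self.lung_diameter_mm / 2.0
        inplane = np.hypot(centers[:, 0], centers[:, 1])
        if np.any(inplane - radii < lung_r):
            raise GeometryError("a sphere overlaps the lung insert")
        # containment in the body (conservative shrunken-ellipse test)
        for c, r in zip(centers, radii):
            if (c[0] / (a - r)) ** 2 + (c[1] / (b - r)) ** 2 > 1.0:
                raise GeometryError("a sphere protrudes through the body wall")
            if abs(c[2]) + r > self.body_height_mm / 2.0:
                raise GeometryError("a sphere protrudes through the end plates")

    @classmethod
    def for_ratio(cls, label: str, **overrides) -> "PhantomSpec":
        """Preset activities for the 10:1, 4:1 or 2:1 filling sessions."""
        if label not in RATIO_PRESETS:
            raise ConfigError(f"unknown ratio preset {label!r}; choose from {sorted(RATIO_PRESETS)}")
        hot, bg, _ = RATIO_PRESETS[label]
        return cls(
            sphere_activity_kBq_ml=hot,
            background_activity_kBq_ml=bg,
            ratio_label=label,
            **overrides,
        )


# ---------------------------------------------------------------------------
# acquisition / reconstruction parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionConfig:
    """Counting model of one PET acquisition.

    ``sensitivity_cps_per_kBq`` lumps all detection efficiency into a single
    factor so that expected counts per voxel are
    ``activity [kBq/ml] × voxel volume [ml] × sensitivity × time [s]``.
    Defaults mimic a digital PET/MR-like system (sensitivity 21 cps/kBq,
    PSF 4.2 mm FWHM, 256×256 matrix at 2.34×2.34×2.78 mm³); the PET/CT-like
    alternative uses 10 cps/kBq on a 200×200 matrix at 4.1×4.1×3.0 mm³.
    """

    time_per_bed_s: float = 180.0
    sensitivity_cps_per_kBq: float = 21.0
    psf_fwhm_mm: float = 4.2
    voxel_size_mm: tuple[float, float, float] = (2.34, 2.34, 2.78)
    matrix: tuple[int, int] = (256, 256)
    half_life_min: float = GA68_HALF_LIFE_MIN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.time_per_bed_s < 0:
            raise ConfigError("time_per_bed_s must be >= 0")
        if self.sensitivity_cps_per_kBq <= 0:
            raise ConfigError("sensitivity_cps_per_kBq must be > 0")
        if self.psf_fwhm_mm < 0:
            raise ConfigError("psf_fwhm_mm must be >= 0")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ConfigError("voxel_size_mm components must be > 0")
        if any(m <= 0 for m in self.matrix):
            raise ConfigError("matrix dimensions must be > 0")
        if self.half_life_min <= 0:
            raise ConfigError("half_life_min must be > 0")

    @classmethod
    def petct_like(cls, **overrides) -> "AcquisitionConfig":
        kw = dict(
            sensitivity_cps_per_kBq=10.0,
            voxel_size_mm=(4.1, 4.1, 3.0),
            matrix=(200, 200),
            psf_fwhm_mm=5.9,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class ReconParams:
    """β-parameterized noise-suppression surrogate.

    ``surrogate_sigma_ref_mm`` is the Gaussian smoothing width applied at the
    reference β = 300; other β values scale it by ``sqrt(β/300)``.
    """

    beta: float = 300.0
    surrogate_sigma_ref_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ConfigError("beta must be >= 0")
        if self.surrogate_sigma_ref_mm <= 0:
            raise ConfigError("surrogate_sigma_ref_mm must be > 0")

    @property
    def sigma_mm(self) -> float:
        return self.surrogate_sigma_ref_mm * math.sqrt(self.beta / 300.0)


# ---------------------------------------------------------------------------
# patient specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Lesion:
    center_mm: tuple[float, float, float]
    diameter_mm: float
    suvmax: float

    @property
    def volume_ml(self) -> float:
        return 4.0 / 3.0 * math.pi * (self.diameter_mm / 2.0) ** 3 / 1000.0


def _default_lesions() -> tuple[Lesion, ...]:
    # 10 lesions on an elliptical ring through the torso, alternating between
    # two axial planes; half have diameter <= 10 mm (volume <= the 10 mm
    # sphere's 0.52 ml), matching the subcentimeter-heavy clinical mix.
    diam = [10.0, 9.0, 8.0, 7.0, 6.0, 12.0, 17.0, 22.0, 28.0, 37.0]
    suv = [8.0, 5.0, 12.0, 4.0, 6.0, 10.0, 15.0, 20.0, 25.0, 40.0]
    # the two z-planes keep every lesion's 15 mm search window clear of the
    # liver so isocontour seeding cannot lock onto hepatic background
    ring_a, ring_b = 120.0, 80.0
    lesions = []
    for i, (d, s) in enumerate(zip(diam, suv)):
        ang = 2.0 * math.pi * i / len(diam)
        z = 55.0 if i % 2 == 0 else -55.0
        lesions.append(
            Lesion((ring_a * math.cos(ang), ring_b * math.sin(ang), z), d, s)
        )
    return tuple(lesions)


@dataclass(frozen=True)
class PatientSpec:
    """Synthetic patient: elliptical-cylinder body, ellipsoidal liver, lesions.

    Values are in SUV so they are directly comparable across injected
    activities; concentration is recovered via ``injected_MBq`` and
    ``weight_kg`` (default dose follows the 1.5 MBq/kg protocol).
    """

    weight_kg: float = 81.0
    injected_MBq: float | None = None
    body_semi_axes_mm: tuple[float, float] = (160.0, 110.0)
    body_height_mm: float = 200.0
    liver_center_mm: tuple[float, float, float] = (50.0, 20.0, 0.0)
    liver_semi_axes_mm: tuple[float, float, float] = (80.0, 60.0, 50.0)
    liver_suv: float = 6.0
    body_suv: float = 1.0
    lesions: tuple[Lesion, ...] = field(default_factory=_default_lesions)

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ConfigError("weight_kg must be > 0")
        if self.injected_MBq is not None and self.injected_MBq <= 0:
            raise ConfigError("injected_MBq must be > 0")
        if self.liver_suv < 0 or self.body_suv < 0:
            raise ConfigError("SUV values must be >= 0")
        self.validate_geometry()

    @property
    def dose_MBq(self) -> float:
        if self.injected_MBq is not None:
            return self.injected_MBq
        return 1.5 * self.weight_kg

    def in_liver(self, point) -> bool:
        c = np.asarray(self.liver_center_mm)
        s = np.asarray(self.liver_semi_axes_mm)
        p = np.asarray(point, dtype=float)
        return float(np.sum(((p - c) / s) ** 2)) <= 1.0

    def validate_geometry(self) -> None:
        a, b = self.body_semi_axes_mm
        for les in self.lesions:
            x, y, z = les.center_mm
            r = les.diameter_mm / 2.0
            if (x / (a - r)) ** 2 + (y / (b - r)) ** 2 > 1.0 or abs(z) + r > self.body_height_mm / 2.0:
                raise GeometryError(f"lesion at {les.center_mm} lies outside the body")
        centers = np.array([l.center_mm for l in self.lesions], dtype=float).reshape(-1, 3)
        radii = np.array([l.diameter_mm / 2.0 for l in self.lesions])
        for i in range(len(radii)):
            for j in range(i + 1, len(radii)):
                if np.linalg.norm(centers[i] - centers[j]) < radii[i] + radii[j]:
                    raise GeometryError(f"lesions {i} and {j} overlap")


def subcentimeter_fraction(spec: PatientSpec) -> float:
    """Fraction of lesions no larger than the 10 mm sphere (~0.52 ml)."""
    thr = 4.0 / 3.0 * math.pi * 5.0**3 / 1000.0
    if not spec.lesions:
        return 0.0
    return sum(l.volume_ml <= thr + 1e-12 for l in spec.lesions) / len(spec.lesions)


# ---------------------------------------------------------------------------
# volume builders
# ---------------------------------------------------------------------------


def default_phantom_shape(spec: PhantomSpec, voxel_size_mm, margin_mm: float = 10.0):
    """Smallest centred grid that holds the phantom, bottles and a margin."""
    sx, sy, sz = voxel_size_mm
    half_x = spec.body_semi_axes_mm[0] + spec.arm_bottle_diameter_mm + margin_mm
    half_y = spec.body_semi_axes_mm[1] + margin_mm
    half_z = spec.body_height_mm / 2.0 + margin_mm
    return (
        int(math.ceil(2 * half_x / sx)),
        int(math.ceil(2 * half_y / sy)),
        int(math.ceil(2 * half_z / sz)),
    )


def default_patient_shape(spec: PatientSpec, voxel_size_mm, margin_mm: float = 10.0):
    sx, sy, sz = voxel_size_mm
    return (
        int(math.ceil(2 * (spec.body_semi_axes_mm[0] + margin_mm) / sx)),
        int(math.ceil(2 * (spec.body_semi_axes_mm[1] + margin_mm) / sy)),
        int(math.ceil((spec.body_height_mm + 2 * margin_mm) / sz)),
    )


def build_nema_phantom(
    spec: PhantomSpec,
    voxel_size_mm,
    shape: tuple[int, int, int] | None = None,
) -> ActivityVolume:
    """Voxelize the phantom: each voxel takes the activity of the compartment
    containing its centre (air 0, background, lung 0, spheres, bottles)."""
    voxel_size_mm = tuple(float(v) for v in voxel_size_mm)
    if any(v <= 0 for v in voxel_size_mm):
        raise ConfigError(f"voxel size must be positive, got {voxel_size_mm}")
    spec.validate()
    if shape is None:
        shape = default_phantom_shape(spec, voxel_size_mm)
    grid = Grid.centered(shape, voxel_size_mm)
    X, Y, Z = grid.meshgrid()
    a, b = spec.body_semi_axes_mm
    data = np.zeros(grid.shape, dtype=np.float64)

    in_height = np.abs(Z) <= spec.body_height_mm / 2.0
    body = ((X / a) ** 2 + (Y / b) ** 2 <= 1.0) & in_height
    data[body] = spec.background_activity_kBq_ml

    lung = (X**2 + Y**2 <= (spec.lung_diameter_mm / 2.0) ** 2) & in_height
    data[lung] = 0.0

    for c, d in zip(spec.sphere_centers_mm, spec.sphere_diameters_mm):
        r2 = (d / 2.0) ** 2
        sph = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r2
        data[sph] = spec.sphere_activity_kBq_ml

    hb = spec.arm_bottle_height_mm / 2.0
    rb2 = (spec.arm_bottle_diameter_mm / 2.0) ** 2
    for c in spec.arm_bottle_centers_mm:
        bottle = ((X - c[0]) ** 2 + (Y - c[1]) ** 2 <= rb2) & (np.abs(Z - c[2]) <= hb)
        data[bottle] = spec.bottle_activity_kBq_ml

    return ActivityVolume(data, grid, "kBq/ml")


def sphere_center_blur_fraction(radius_mm: float, sigma_mm: float) -> float:
    """Central value of a unit ball after isotropic Gaussian blur.

    Closed form for a 3-D Gaussian of width ``sigma`` convolved with the
    indicator of a ball of radius ``R``, evaluated at the centre:
    ``erf(R/(σ√2)) − sqrt(2/π)·(R/σ)·exp(−R²/(2σ²))``.
    """
    if sigma_mm <= 0:
        return 1.0
    t = radius_mm / sigma_mm
    return math.erf(t / math.sqrt(2.0)) - math.sqrt(2.0 / math.pi) * t * math.exp(-t * t / 2.0)


def build_patient_volume(
    spec: PatientSpec,
    voxel_size_mm,
    shape: tuple[int, int, int] | None = None,
    calibrate_psf_fwhm_mm: float = 0.0,
) -> ActivityVolume:
    """Voxelize a synthetic patient as an SUV map.

    When ``calibrate_psf_fwhm_mm`` is positive, the uniform value written
    into each lesion is boosted so that after Gaussian blurring with that
    FWHM the lesion's peak equals its nominal ``suvmax`` (the correction is
    exact in the continuum; sub-voxel discretisation keeps it within a few
    per cent for lesions larger than about one FWHM).
    """
    voxel_size_mm = tuple(float(v) for v in voxel_size_mm)
    if any(v <= 0 for v in voxel_size_mm):
        raise ConfigError(f"voxel size must be positive, got {voxel_size_mm}")
    spec.validate_geometry()
    if shape is None:
        shape = default_patient_shape(spec, voxel_size_mm)
    grid = Grid.centered(shape, voxel_size_mm)
    X, Y, Z = grid.meshgrid()
    a, b = spec.body_semi_axes_mm
    data = np.zeros(grid.shape, dtype=np.float64)

    body = ((X / a) ** 2 + (Y / b) ** 2 <= 1.0) & (np.abs(Z) <= spec.body_height_mm / 2.0)
    data[body] = spec.body_suv

    lc = spec.liver_center_mm
    ls = spec.liver_semi_axes_mm
    liver = (
        ((X - lc[0]) / ls[0]) ** 2 + ((Y - lc[1]) / ls[1]) ** 2 + ((Z - lc[2]) / ls[2]) ** 2
    ) <= 1.0
    data[liver] = spec.liver_suv

    sigma = calibrate_psf_fwhm_mm * FWHM_TO_SIGMA
    for les in spec.lesions:
        local_bg = spec.liver_suv if spec.in_liver(les.center_mm) else spec.body_suv
        if sigma > 0:
            g = sphere_center_blur_fraction(les.diameter_mm / 2.0, sigma)
            g = max(g, 1e-6)
            amplitude = local_bg + (les.suvmax - local_bg) / g
        else:
            amplitude = les.suvmax
        c = les.center_mm
        r2 = (les.diameter_mm / 2.0) ** 2
        mask = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r2
        data[mask] = amplitude

    return ActivityVolume(data, grid, "SUV")


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def _gaussian_blur_mm(data: np.ndarray, fwhm_mm: float, spacing) -> np.ndarray:
    """Isotropic (in mm) Gaussian filter with a mean-preserving wrap boundary.

    Volumes are zero (air) near the grid edge, so circular wrapping carries no
    signal across the boundary yet keeps the kernel exactly normalised, which
    makes the global mean invariant to machine precision.
    """
    if fwhm_mm < 0:
        raise ConfigError("PSF FWHM must be >= 0")
    if fwhm_mm == 0:
        return data.copy()
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in spacing]
    return ndimage.gaussian_filter(data, sigma=sigma_vox, mode="wrap")


def simulate_acquisition(
    truth: ActivityVolume,
    acq: AcquisitionConfig,
    noiseless: bool = False,
) -> CountVolume:
    """Simulate a count image from a true activity map.

    Expected counts per voxel are the PSF-blurred activity times the
    deterministic scale ``voxel volume (ml) × sensitivity × time``; the
    realised image is an independent Poisson draw per voxel seeded from
    ``acq.seed`` (or the noise-free expectation itself if ``noiseless``).
    A zero acquisition time yields an all-zero count volume.
    """
    if acq.time_per_bed_s < 0:
        raise ConfigError("acquisition time must be >= 0")
    scale = truth.grid.voxel_volume_ml * acq.sensitivity_cps_per_kBq * acq.time_per_bed_s
    expectation = _gaussian_blur_mm(truth.data, acq.psf_fwhm_mm, truth.grid.spacing) * scale
    np.clip(expectation, 0.0, None, out=expectation)
    if noiseless:
        counts = expectation
    else:
        rng = np.random.default_rng(acq.seed)
        counts = rng.poisson(expectation).astype(np.int64)
    return CountVolume(counts, truth.grid, scale, truth.units)


def thin_counts(counts: CountVolume, reduction: float, seed: int) -> CountVolume:
    """Binomially thin counts with keep-probability ``1 - reduction``.

    This is the standard statistical emulation of a lower injected activity:
    thinning a Poisson(λ) field yields exactly Poisson((1-r)·λ).
    """
    r = _validate_reduction(reduction)
    data = np.asarray(counts.data)
    if not np.issubdtype(data.dtype, np.integer):
        raise ConfigError("thin_counts requires an integer count volume")
    if np.any(data < 0):
        raise ConfigError("counts must be non-negative")
    if r == 0.0:
        return CountVolume(data.copy(), counts.grid, counts.scale, counts.source_units)
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(data, 1.0 - r)
    return CountVolume(
        thinned.astype(np.int64), counts.grid, counts.scale * (1.0 - r), counts.source_units
    )


def beta_smooth(image: ActivityVolume, recon: ReconParams) -> ActivityVolume:
    """Apply the β-controlled noise-suppression surrogate (see module docs)."""
    if recon.beta == 0:
        return image.with_data(image.data.copy())
    sigma_vox = [recon.sigma_mm / s for s in image.grid.spacing]
    smoothed = ndimage.gaussian_filter(image.data, sigma=sigma_vox, mode="wrap")
    return image.with_data(smoothed)


def decay_compensated_time(
    t_ref_s: float, delay_min: float, half_life_min: float = GA68_HALF_LIFE_MIN
) -> float:
    """Acquisition time prolonged to offset radioactive decay after a delay."""
    if half_life_min <= 0:
        raise ConfigError("half_life_min must be > 0")
    if delay_min < 0:
        raise ConfigError("delay_min must be >= 0")
    return float(t_ref_s) * 2.0 ** (delay_min / half_life_min)
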