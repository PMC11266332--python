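"""Image-quality metrics for phantom and patient PET analyses.

Phantom metrics follow the NEMA-style convention: contrast recovery (CR)
normalises the measured hot-sphere/background contrast by the true activity
contrast; background variability (BV) is the relative noise (SD/mean) in
background cylinders; CNR = CR / BV.  Patient metrics normalise liver noise
by liver SUVmean and express lesion conspicuity as SUVmax over liver noise
(SNR) or over liver SUVmean (SBR).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, UndefinedMetricError
from .voi import VOIStats

__all__ = [
    "IQRecord",
    "contrast_recovery",
    "background_variability",
    "cnr",
    "liver_noise",
    "lesion_snr",
    "lesion_sbr",
    "suv_from_concentration",
]


@dataclass(frozen=True)
class IQRecord:
    """One (condition, reduction, β) row of image-quality metrics."""

    tag: str
    ratio: str
    reduction: float
    beta: float
    sphere_diameter_mm: float | None = None
    cr: float | None = None
    bv: float | None = None
    cnr: float | None = None
    liver_noise: float | None = None
    lesion_snr: float | None = None
    lesion_sbr: float | None = None
    lesion_suvmax: float | None = None


def contrast_recovery(ch: float, cb: float, ah: float, ab: float) -> float:
    """CR = (CH/CB − 1) / (aH/aB − 1).

    ``ch``/``cb`` are measured sphere and background VOI means; ``ah``/``ab``
    the true filled activities.  Units cancel in both ratios.
    """
    if cb <= 0:
        raise UndefinedMetricError("measured background mean must be > 0")
    if ab <= 0:
        raise UndefinedMetricError("true background activity must be > 0")
    if ah == ab:
        raise UndefinedMetricError("contrast undefined when aH equals aB")
    return (ch / cb - 1.0) / (ah / ab - 1.0)


def background_variability(
    bg_stats: Sequence[VOIStats], method: str = "per_voi"
) -> float:
    """Relative background noise over a set of background VOIs.

    ``per_voi`` (default) averages each VOI's SD/mean; ``pooled`` divides the
    mean of the SDs by the mean of the means.  Both use sample SDs.
    """
    if len(bg_stats) == 0:
        raise ConfigError("need at least one background VOI")
    means = np.array([s.mean for s in bg_stats], dtype=float)
    sds = np.array([s.sd for s in bg_stats], dtype=float)
    if np.any(means <= 0):
        raise UndefinedMetricError("background VOI mean must be > 0")
    if method == "per_voi":
        return float(np.mean(sds / means))
    if method == "pooled":
        return float(np.mean(sds) / np.mean(means))
    raise ConfigError(f"unknown BV method {method!r}")


def cnr(cr: float, bv: float) -> float:
    """Contrast-to-noise ratio CR / BV."""
    if bv <= 0:
        raise UndefinedMetricError("CNR undefined for zero background variability")
    return cr / bv


def liver_noise(liver_sd: float, liver_suvmean: float) -> float:
    """Liver SD normalised to liver SUVmean."""
    if liver_suvmean <= 0:
        raise UndefinedMetricError("liver SUVmean must be > 0")
    return liver_sd / liver_suvmean


def lesion_snr(lesion_suvmax: float, noise: float) -> float:
    """Lesion SUVmax over normalised liver noise."""
    if noise <= 0:
        raise UndefinedMetricError("lesion SNR undefined for zero liver noise")
    return lesion_suvmax / noise


def lesion_sbr(lesion_suvmax: float, liver_suvmean: float) -> float:
    """Lesion SUVmax over liver SUVmean."""
    if liver_suvmean <= 0:
        raise UndefinedMetricError("liver SUVmean must be > 0")
    return lesion_suvmax / liver_suvmean


def suv_from_concentration(
    conc_kBq_per_ml: float, injected_MBq: float, weight_kg: float
) -> float:
    """Standardised uptake value for unit tissue density (1 g/ml).

    SUV = concentration [Bq/ml] / (injected activity [Bq] / body mass [g]);
    equivalently ``conc_kBq_per_ml × weight_kg / injected_MBq``.
    """
    if injected_MBq <= 0 or weight_kg <= 0:
        raise ConfigError("injected activity and weight must be > 0")
    return conc_kBq_per_ml * weight_kg / injected_MBq
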