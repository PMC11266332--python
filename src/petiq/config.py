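"""YAML study configuration and report writing.

Configuration is schema-validated (unknown keys rejected) and every field
has a documented default, so an empty file is a valid configuration.  The
seed is part of the configuration: there is no silent nondeterminism.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigError
from .phantom import AcquisitionConfig, GA68_HALF_LIFE_MIN

__all__ = ["StudyConfig", "load_config", "write_report", "read_metrics_csv"]

CSV_FLOAT_FORMAT = "%.8g"


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AcquisitionSettings(_Strict):
    time_per_bed_s: float = Field(180.0, gt=0)
    sensitivity_cps_per_kBq: float = Field(21.0, gt=0)
    psf_fwhm_mm: float = Field(4.2, ge=0)
    voxel_size_mm: tuple[float, float, float] = (2.34, 2.34, 2.78)
    matrix: tuple[int, int] = (256, 256)
    half_life_min: float = Field(GA68_HALF_LIFE_MIN, gt=0)

    @field_validator("voxel_size_mm")
    @classmethod
    def _positive_voxels(cls, v):
        if any(x <= 0 for x in v):
            raise ValueError("voxel_size_mm components must be > 0")
        return v

    def to_acquisition(self, seed: int) -> AcquisitionConfig:
        return AcquisitionConfig(
            time_per_bed_s=self.time_per_bed_s,
            sensitivity_cps_per_kBq=self.sensitivity_cps_per_kBq,
            psf_fwhm_mm=self.psf_fwhm_mm,
            voxel_size_mm=self.voxel_size_mm,
            matrix=self.matrix,
            half_life_min=self.half_life_min,
            seed=seed,
        )


class GridSettings(_Strict):
    reductions: list[float] = [0.0, 0.17, 0.33, 0.50, 0.67]
    betas: list[int] = [150, 300, 450, 600]

    @field_validator("reductions")
    @classmethod
    def _valid_reductions(cls, v):
        if any(not 0.0 <= r < 1.0 for r in v):
            raise ValueError("reductions must lie in [0, 1)")
        return v


class ThresholdSettings(_Strict):
    min_visual_score: int = Field(2, ge=0, le=3)
    detectability_pct: float = Field(90.0, ge=0, le=100)


class StudyConfig(_Strict):
    ratio: str = "4:1"
    acquisition: AcquisitionSettings = AcquisitionSettings()
    grid: GridSettings = GridSettings()
    thresholds: ThresholdSettings = ThresholdSettings()
    surrogate_sigma_ref_mm: float = Field(3.0, gt=0)
    seed: int = Field(12345, ge=0, lt=2**31)
    output_dir: str = "results"


def load_config(path: str | Path | None = None) -> StudyConfig:
    """Load and validate a YAML study configuration.

    ``None`` or an empty file yields the documented defaults.  Schema
    violations raise :class:`ConfigError` naming the offending field.
    """
    raw = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        raw = yaml.safe_load(p.read_text()) or {}
    try:
        return StudyConfig.model_validate(raw)
    except ValidationError as exc:
        parts = []
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"]) or "<root>"
            parts.append(f"{loc}: {err['msg']}")
        raise ConfigError("invalid configuration — " + "; ".join(parts)) from exc


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT, lineterminator="\n")


def write_report(metrics: pd.DataFrame, selection, out_dir: str | Path) -> dict:
    """Write the study outputs: a long metrics CSV plus a JSON summary.

    Returns the paths written.  The CSV uses fixed numeric formatting so a
    write → read → write cycle is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    metrics_path = out / "metrics.csv"
    _write_csv(metrics, metrics_path)
    paths["metrics"] = metrics_path
    if selection is not None:
        sel_path = out / "selection.json"
        payload = {
            "per_reduction": {str(k): v for k, v in selection.per_reduction.items()},
            "reference_suvmax": selection.reference_suvmax,
            "score_threshold": selection.score_threshold,
            "detectability_threshold_pct": selection.detectability_threshold_pct,
        }
        sel_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        elig_path = out / "eligibility.csv"
        _write_csv(selection.eligibility, elig_path)
        paths["selection"] = sel_path
        paths["eligibility"] = elig_path
    return paths


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    """Read back a metrics CSV written by :func:`write_report`."""
    return pd.read_csv(path)
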