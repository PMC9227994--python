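"""Pipeline configuration: a single validated YAML-style document.

Every knob the analysis exposes lives here so a run is a pure function of
(input files, config, seed).  Unknown keys are rejected rather than ignored —
a typo in a config file should fail loudly, not silently fall back to a
default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .transport import TranswellGeometry

__all__ = ["PipelineConfig", "GeometryConfig", "FluxConfig",
           "CensoringConfig", "StatsConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    """Insert area and chamber/aliquot volumes (cm², mL)."""

    area_cm2: float = 1.12
    vol_a_ml: float = 0.4
    vol_b_ml: float = 1.2
    aliquot_a_ml: float = 0.2
    aliquot_b_ml: float = 0.6

    @model_validator(mode="after")
    def _check(self) -> "GeometryConfig":
        try:
            self.to_geometry()
        except ValueError as e:
            raise ConfigError(f"geometry: {e}") from e
        return self

    def to_geometry(self) -> TranswellGeometry:
        return TranswellGeometry(
            area=self.area_cm2,
            volume_apical=self.vol_a_ml,
            volume_basolateral=self.vol_b_ml,
            aliquot_apical=self.aliquot_a_ml,
            aliquot_basolateral=self.aliquot_b_ml,
        )


class FluxConfig(_Strict):
    """Steady-state flux regression options."""

    include_origin: bool = False
    #: restrict the regression to [t_min, t_max] minutes; null = all points
    window: Optional[tuple[float, float]] = None

    @field_validator("window")
    @classmethod
    def _ordered(cls, v):
        if v is not None and v[1] <= v[0]:
            raise ConfigError("flux.window must be (t_min, t_max) with t_min < t_max")
        return v


class CensoringConfig(_Strict):
    lloq: float = Field(default=0.025, gt=0)
    #: statistic of the blank responses used by the 5×-blank detection rule
    llod_policy: str = "mean_blank"

    @field_validator("llod_policy")
    @classmethod
    def _known(cls, v):
        if v not in ("mean_blank", "lloq"):
            raise ConfigError(f"unknown llod_policy {v!r}")
        return v


class StatsConfig(_Strict):
    welch: bool = False
    alpha_levels: tuple[float, float, float] = (0.05, 0.01, 0.001)

    @field_validator("alpha_levels")
    @classmethod
    def _decreasing(cls, v):
        if not all(b < a for a, b in zip(v, v[1:])):
            raise ConfigError("alpha_levels must be strictly decreasing")
        return v


class CalibrationConfig(_Strict):
    weighting: str = "none"

    @field_validator("weighting")
    @classmethod
    def _known(cls, v):
        if v not in ("none", "1/x", "1/x2"):
            raise ConfigError(f"unknown calibration weighting {v!r}")
        return v


class PipelineConfig(_Strict):
    """Complete analysis configuration with protocol defaults."""

    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    flux: FluxConfig = Field(default_factory=FluxConfig)
    censoring: CensoringConfig = Field(default_factory=CensoringConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    #: correct deconjugated concentrations for the 1:20 enzyme:sample mixing
    deconjugation_dilution_correction: bool = True
    times_min: tuple[float, ...] = (30.0, 60.0, 90.0, 120.0)
    output_dir: str = "results"
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        try:
            return cls.model_validate(data)
        except ConfigError:
            raise
        except Exception as e:  # pydantic ValidationError → ConfigError
            raise ConfigError(str(e)) from e


def load_config(path: "str | Path | None") -> PipelineConfig:
    """Load a config file; a missing/None path yields all defaults."""
    if path is None:
        return PipelineConfig()
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    return PipelineConfig.from_yaml(p.read_text())
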