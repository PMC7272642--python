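"""Validated run configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .classify import ClassifierSpec
from .synth import (
    DESK_DURATION,
    DESK_N_CHANNELS,
    DESK_N_VERTICES,
    DESK_SAMPLING_RATE,
)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    n_channels: int = DESK_N_CHANNELS
    n_vertices: int = DESK_N_VERTICES
    n_regions: int = 68
    sphere_radius_m: float = 0.09
    shell_fraction: float = 0.8
    sensor_radius_m: float = 0.12
    cortex_z_min: float = -0.35
    normal_radial_sd: float = 0.3


class AdEffect(_Strict):
    band: str
    region: str
    multiplier: float = 1.4


class CohortConfig(_Strict):
    n_ad: int = 20
    n_nc: int = 27
    sampling_rate_hz: float = DESK_SAMPLING_RATE
    duration_s: float = DESK_DURATION
    between_subject_cv: float = 0.2
    source_floor_rms_am: float = 0.3e-9
    sensor_noise_sd_t: float = 5e-14
    artifact_rate_per_min: float = 1.0
    artifact_amplitude_t: float = 12e-12
    ad_effects: list[AdEffect] | None = None


class PreprocConfig(_Strict):
    artifact_threshold_t: float = 10e-12
    epoch_length_s: float = 2.0


class InverseConfig(_Strict):
    snr: float = 3.0
    depth_exponent: float = 0.5


class StatsConfig(_Strict):
    alpha: float = 0.05
    test: Literal["welch", "student", "mannwhitney"] = "welch"


class ClassifierConfig(_Strict):
    degree: int = 2
    box_constraint: float = 1.0
    kernel_scale: float | Literal["auto"] = "auto"
    kernel_offset: float = 1.0
    standardize: bool = True
    n_folds: int = 6

    def to_spec(self, seed: int) -> ClassifierSpec:
        return ClassifierSpec(
            degree=self.degree,
            box_constraint=self.box_constraint,
            kernel_scale=self.kernel_scale,
            kernel_offset=self.kernel_offset,
            standardize=self.standardize,
            n_folds=self.n_folds,
            seed=seed,
        )


class RunConfig(_Strict):
    """Full pipeline configuration; ``scale: paper`` switches the geometry
    and recording sizes to the acquisition-scale setup (160 channels,
    15,000 vertices, 1000 Hz, 120 s)."""

    seed: int = 0
    output_dir: str = "megspect_out"
    scale: Literal["desk", "paper"] = "desk"
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    preproc: PreprocConfig = Field(default_factory=PreprocConfig)
    inverse: InverseConfig = Field(default_factory=InverseConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)

    @model_validator(mode="after")
    def _apply_scale(self) -> "RunConfig":
        if self.scale == "paper":
            if self.geometry == GeometryConfig():
                self.geometry = GeometryConfig(n_channels=160, n_vertices=15000)
            if (
                self.cohort.sampling_rate_hz == DESK_SAMPLING_RATE
                and self.cohort.duration_s == DESK_DURATION
            ):
                self.cohort.sampling_rate_hz = 1000.0
                self.cohort.duration_s = 120.0
        return self

    def config_hash(self) -> str:
        """Hash of the scientific settings (the output location excluded)."""
        payload = self.model_dump()
        payload.pop("output_dir", None)
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
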