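"""Run configuration: schema-validated YAML for end-to-end runs.

Unknown keys are rejected and every violation is reported at once, so a
mistyped parameter never silently falls back to a default.  Seeds are
mandatory (supplied at the top level); no stage seeds itself from the
wall clock.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

__all__ = ["RunConfig", "validate_config", "ConfigError"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StageToggles(_Strict):
    cohort: bool = True
    dnc: bool = True
    photometry: bool = True
    hplc: bool = True
    histology: bool = True


class PhotometryStageConfig(_Strict):
    frame_rate: float = Field(5.0, gt=0)
    duration: float = Field(900.0, gt=0)
    bleach_slope: float = 0.01
    transient_onset: float = Field(700.0, gt=0)
    transient_amplitude: float = 0.5
    transient_decay: float = Field(60.0, gt=0)
    noise_sd: float = Field(0.02, ge=0)
    fit_window_s: float = Field(600.0, gt=0)
    smoothing_s: float = Field(5.0, gt=0)


class HplcStageConfig(_Strict):
    curve_slope: float = Field(120.0, gt=0)  # true AUC per (ng/ml) of the simulated detector
    curve_noise_fraction: float = Field(0.02, ge=0)
    peak_width_s: float = Field(3.0, gt=0)
    noise_sd: float = Field(0.5, ge=0)


class HistologyImageConfig(_Strict):
    shape: tuple[int, int] = (256, 256)
    n_cells_control: int = Field(14, ge=0)
    n_cells_pd: int = Field(10, ge=0)
    cell_radius_range: tuple[float, float] = (8.0, 10.0)
    cell_intensity: float = Field(60.0, ge=0, le=255)
    background_level: float = Field(200.0, ge=0, le=255)
    texture_sd: float = Field(3.0, ge=0)

    @field_validator("cell_radius_range")
    @classmethod
    def _radii(cls, v):
        if v[0] <= 0 or v[0] > v[1]:
            raise ValueError("cell_radius_range must be positive and ordered")
        return v


class CountingConfig(_Strict):
    maxima_filter_size: int = Field(7, gt=0)
    blur_size: float = Field(7.0, gt=0)
    background_radius: int = Field(60, gt=0)
    min_particle_area: int = Field(100, ge=1)
    marker_min_distance: int = Field(7, gt=0)


class CohortStageConfig(_Strict):
    stages: list[str] = ["early", "ultra_early"]

    @field_validator("stages")
    @classmethod
    def _known(cls, v):
        from . import studyparams

        bad = [s for s in v if s not in studyparams.STAGES]
        if bad:
            raise ValueError(f"unknown disease stages {bad}; expected {studyparams.STAGES}")
        return v


class DncStageConfig(_Strict):
    state: str = "challenged"
    threshold_state: str = "challenged"

    @field_validator("state", "threshold_state")
    @classmethod
    def _state(cls, v):
        if v not in ("resting", "challenged"):
            raise ValueError(f"state must be resting or challenged, got {v!r}")
        return v


class RunConfig(_Strict):
    seed: int = Field(ge=0, lt=2**31)
    output_dir: str = "runs/demo"
    stages: StageToggles = StageToggles()
    cohort: CohortStageConfig = CohortStageConfig()
    dnc: DncStageConfig = DncStageConfig()
    photometry: PhotometryStageConfig = PhotometryStageConfig()
    hplc: HplcStageConfig = HplcStageConfig()
    histology_image: HistologyImageConfig = HistologyImageConfig()
    counting: CountingConfig = CountingConfig()


class ConfigError(ValueError):
    """Configuration invalid; ``violations`` lists every problem found."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid run config:\n" + "\n".join(f"  - {v}" for v in violations))


def validate_config(path) -> RunConfig:
    """Parse and schema-check a YAML config, reporting all violations."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        violations = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigError(violations) from exc
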