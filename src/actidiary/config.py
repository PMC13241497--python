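"""YAML-backed pipeline configuration, validated before any stage runs."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError
from .windows import DayWindow

__all__ = ["PipelineConfig", "load_config"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WindowSection(_StrictModel):
    start: str = "09:00"
    end: str = "18:00"
    slot_minutes: float = 15.0

    def build(self) -> DayWindow:
        try:
            return DayWindow.from_strings(self.start, self.end, self.slot_minutes)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc


class FilterSection(_StrictModel):
    order: int = 4
    cutoff_hz: float = 20.0
    placement: str = "post_norm"


class RulesSection(_StrictModel):
    min_simultaneous_slots: int = 4
    min_days: int = 3
    min_sensor_hours: float = 9.0
    require_window_span: bool = True
    sensor_hours_mode: str = "covered"


class OptimizerSection(_StrictModel):
    xatol: float | None = None
    fatol: float | None = None
    maxiter: int | None = None


class TremorSection(_StrictModel):
    include_ankle: bool = False


class PipelineConfig(_StrictModel):
    """All thresholds default to the quoted analysis values."""

    input_dir: str
    output_dir: str
    window: WindowSection = Field(default_factory=WindowSection)
    filter: FilterSection = Field(default_factory=FilterSection)
    min_coverage: float = 0.75
    rules: RulesSection = Field(default_factory=RulesSection)
    overlap_rule: str = "half"
    optimizer: OptimizerSection = Field(default_factory=OptimizerSection)
    tremor: TremorSection = Field(default_factory=TremorSection)
    subject_rmse_per_day_average: bool = False
    two_stage_profile: bool = True
    sampling_rate: float = 100.0
    plots: bool = False
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def load_config(path: str | Path) -> PipelineConfig:
    try:
        payload = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise ConfigError(f"config {path} must be a mapping")
    try:
        return PipelineConfig(**payload)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
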