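"""Run configuration: a single YAML/JSON document with explicit units.

Every length key carries ``_mm``, every time ``_s``, every frequency either
``_hz`` or ``cycles_per_min`` — no unit inference.  Unknown keys are
rejected.  ``build()`` methods turn validated configuration blocks into the
corresponding domain objects.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigurationError
from .geometry import TargetSpec, WindowGrid
from .motion import ConstantSpeedMotion, MotionModel, SampledMotion, SinusoidalMotion
from .simulate import ScanProtocol
from .synthetic import NoiseSpec


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TargetConfig(_Base):
    length_mm: float = Field(gt=0)
    level_hu: float = 700.0
    center_mm: float = 0.0
    lateral_mm: tuple[float, float] = (30.0, 50.0)
    label: str = ""

    def build(self) -> TargetSpec:
        return TargetSpec(
            length_y=self.length_mm, ct_level=self.level_hu,
            center_y0=self.center_mm, lateral_dims=self.lateral_mm,
            label=self.label,
        )


class MotionConfig(_Base):
    kind: Literal["sinusoidal", "constant_speed", "sampled"]
    amplitude_mm: float = 0.0
    frequency_hz: Optional[float] = None
    cycles_per_min: Optional[float] = None
    phase_rad: float = 0.0
    speed_mm_s: float = 0.0
    samples: Optional[list[tuple[float, float]]] = None

    @model_validator(mode="after")
    def _check(self) -> "MotionConfig":
        if self.kind == "sinusoidal":
            if (self.frequency_hz is None) == (self.cycles_per_min is None):
                raise ValueError(
                    "sinusoidal motion needs exactly one of frequency_hz / cycles_per_min"
                )
        if self.kind == "sampled" and not self.samples:
            raise ValueError("sampled motion needs a non-empty samples list")
        return self

    def build(self) -> MotionModel:
        if self.kind == "sinusoidal":
            f = self.frequency_hz if self.frequency_hz is not None else self.cycles_per_min / 60.0
            return SinusoidalMotion(amplitude=self.amplitude_mm, frequency=f,
                                    phase=self.phase_rad)
        if self.kind == "constant_speed":
            return ConstantSpeedMotion(speed=self.speed_mm_s)
        return SampledMotion.from_pairs(self.samples)


class ProtocolConfig(_Base):
    n_projections: Optional[int] = Field(default=None, ge=1)
    duration_s: float = Field(default=60.0, gt=0)
    fan_mode: Literal["half", "full"] = "half"

    def build(self) -> ScanProtocol:
        return ScanProtocol(n_projections=self.n_projections,
                            scan_duration=self.duration_s, fan_mode=self.fan_mode)


class GridConfig(_Base):
    origin_mm: float
    window_mm: float = Field(default=2.0, gt=0)
    n_windows: int = Field(ge=1)

    def build(self) -> WindowGrid:
        return WindowGrid(origin_y=self.origin_mm, window_width=self.window_mm,
                          n_windows=self.n_windows)


class AnalysisConfig(_Base):
    support_threshold: float = Field(default=0.05, gt=0, lt=1)
    split_dip_frac: float = Field(default=0.9, gt=0, lt=1)
    smooth_window: int = Field(default=3, ge=1)
    marker_length_mm: Optional[float] = Field(default=None, gt=0)


class NoiseConfig(_Base):
    gaussian_sd_hu: float = Field(default=0.0, ge=0)
    n_spikes: int = Field(default=0, ge=0)
    spike_amplitude_hu: float = 0.0
    spike_sign: Literal["positive", "negative", "both"] = "both"
    baseline_offset_hu: float = 0.0
    seed: Optional[int] = None

    def build(self, default_seed: int = 0) -> NoiseSpec:
        return NoiseSpec(
            gaussian_sd=self.gaussian_sd_hu, n_spikes=self.n_spikes,
            spike_amplitude=self.spike_amplitude_hu, spike_sign=self.spike_sign,
            baseline_offset=self.baseline_offset_hu,
            seed=self.seed if self.seed is not None else default_seed,
        )


class RunConfig(_Base):
    targets: list[TargetConfig] = Field(min_length=1)
    motion: MotionConfig
    grid: GridConfig
    protocol: ProtocolConfig = ProtocolConfig()
    deposition: Literal["center", "overlap"] = "overlap"
    analysis: AnalysisConfig = AnalysisConfig()
    noise: Optional[NoiseConfig] = None
    output_dir: str = "."
    seed: int = 0

    def build_targets(self) -> list[TargetSpec]:
        return [t.build() for t in self.targets]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"could not parse {path}: {exc}") from exc
    return parse_config(raw)


def parse_config(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration document must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigurationError(f"invalid configuration — {paths}") from exc
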