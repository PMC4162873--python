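"""Declarative run configuration, schema-validated.

One human-readable YAML file drives the CLI; unknown keys are rejected so
a typo never silently falls back to a default.  Command-line flags
override file values (documented precedence: flags > file > defaults).
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .circuit import FrequencyGrid
from .fixtures import DEFAULT_GRID, FixtureSpec
from .metrics import DEFAULT_BAND
from .nullmode import SweepWaveform

__all__ = [
    "GridConfig",
    "ScenarioConfig",
    "PrescreenConfig",
    "WaveformConfig",
    "RunConfig",
    "load_config",
    "config_hash",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    start_hz: float = DEFAULT_GRID.start
    stop_hz: float = DEFAULT_GRID.stop
    n_points: int = DEFAULT_GRID.n_points

    def to_grid(self) -> FrequencyGrid:
        return FrequencyGrid(self.start_hz, self.stop_hz, self.n_points)


class ScenarioConfig(_Strict):
    scenario: Literal[
        "empty_coil", "dielectric_load", "resonant_wire", "coiled_wire_weak", "detuned_port2"
    ] = "resonant_wire"
    wire_azimuth_deg: float = 0.0
    k: Optional[float] = Field(default=None, description="coupling coefficient; scenario preset when omitted")
    noise_floor: float = 0.0
    seed: int = 0
    grid: GridConfig = GridConfig()

    def to_fixture_spec(self) -> FixtureSpec:
        return FixtureSpec(
            scenario=self.scenario,
            wire_azimuth_deg=self.wire_azimuth_deg,
            k=self.k,
            noise_floor=self.noise_floor,
            seed=self.seed,
            grid=self.grid.to_grid(),
        )


class PrescreenConfig(_Strict):
    band_hz: Tuple[float, float] = DEFAULT_BAND
    noise_floor: float = 0.0
    prominence_factor: float = 3.0
    min_prominence: float = 1e-3
    coupling_max: float = 0.03
    wing_offset_hwhm: float = 5.0

    @model_validator(mode="after")
    def _check(self) -> "PrescreenConfig":
        lo, hi = self.band_hz
        if not lo < hi:
            raise ValueError(f"band must satisfy lo < hi, got {self.band_hz}")
        return self


class WaveformConfig(_Strict):
    duration_s: float = 0.05
    n_samples: int = 2000
    n_phase_cycles: float = 25.0
    total_power_w: float = 0.1

    def to_waveform(self) -> SweepWaveform:
        return SweepWaveform(
            duration_s=self.duration_s,
            n_samples=self.n_samples,
            n_phase_cycles=self.n_phase_cycles,
            total_power_w=self.total_power_w,
        )


class RunConfig(_Strict):
    model: ScenarioConfig = ScenarioConfig()
    prescreen: PrescreenConfig = PrescreenConfig()
    waveform: WaveformConfig = WaveformConfig()
    monitor_frequency_hz: Optional[float] = None
    compensation_exponent: float = 0.5


def load_config(path: Optional[str]) -> RunConfig:
    """Load and validate a YAML config; missing path gives all defaults."""
    if path is None:
        return RunConfig()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of the effective configuration, for run logs."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
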