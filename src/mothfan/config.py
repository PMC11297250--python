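"""Run configuration: one YAML file drives the whole pipeline.

Angles are degrees and lengths millimetres in the file (converted to SI
internally); all randomness flows through the single ``seed``.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from .sampling import TraceConfig
from .synthetic import AnalyticFlowSpec, KinematicsSpec


class KinematicsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    wing_length_mm: float = 17.3
    frequency_hz: float = 48.9
    amplitude_deg: float = 98.0
    stroke_plane_deg: float = 99.5
    body_angle_deg: float = -0.6
    mean_elevation_deg: float = -23.8
    elevation_amplitude_deg: float = 5.0
    n_cycles: int = 8
    frame_rate_hz: float = 2000.0
    noise_sd_mm: float = 0.0

    def to_spec(self) -> KinematicsSpec:
        return KinematicsSpec.from_degrees(
            wing_length=self.wing_length_mm * 1e-3,
            frequency=self.frequency_hz,
            amplitude_deg=self.amplitude_deg,
            stroke_plane_angle_deg=self.stroke_plane_deg,
            body_angle_deg=self.body_angle_deg,
            mean_elevation_deg=self.mean_elevation_deg,
            elevation_amplitude_deg=self.elevation_amplitude_deg,
            n_cycles=self.n_cycles,
            frame_rate=self.frame_rate_hz,
        )


class FlowSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    spacing_mm: float = 5.0
    snapshots_per_cycle: int = 50
    domain_lo_mm: tuple[float, float, float] = (-100.0, -100.0, 0.0)
    domain_hi_mm: tuple[float, float, float] = (200.0, 100.0, 150.0)
    efficiency: float = 0.13
    efficiency_osc: float = 0.13

    def to_spec(self, frequency_hz: float) -> AnalyticFlowSpec:
        return AnalyticFlowSpec(
            kind="flapping_dipole",
            spacing=self.spacing_mm * 1e-3,
            snapshots_per_cycle=self.snapshots_per_cycle,
            domain_lo=tuple(v * 1e-3 for v in self.domain_lo_mm),
            domain_hi=tuple(v * 1e-3 for v in self.domain_hi_mm),
            efficiency=self.efficiency,
            efficiency_osc=self.efficiency_osc,
            frequency=frequency_hz,
        )


class AntennaSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_stations: int = 21


class TraceSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_release_phases: int = 21
    steps_per_cycle: int = 500
    n_cycles: int = 40
    integrator: str = "euler"

    def to_config(self, n_stations: int) -> TraceConfig:
        return TraceConfig(
            n_stations=n_stations,
            n_release_phases=self.n_release_phases,
            steps_per_cycle=self.steps_per_cycle,
            n_cycles=self.n_cycles,
            integrator=self.integrator,
        )


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    log_level: str = "INFO"
    output_dir: str = "mothfan_out"
    kinematics: KinematicsSection = KinematicsSection()
    flow: FlowSection = FlowSection()
    antenna: AntennaSection = AntennaSection()
    trace: TraceSection = TraceSection()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the canonicalised configuration."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def provenance(self) -> dict:
        import mothfan
        import scipy

        return {
            "config_sha256": self.digest(),
            "seed": self.seed,
            "versions": {
                "mothfan": mothfan.__version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
            },
        }


def write_provenance(cfg: RunConfig, outdir) -> Path:
    path = Path(outdir) / "provenance.json"
    path.write_text(json.dumps(cfg.provenance(), indent=1, sort_keys=True))
    return path
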