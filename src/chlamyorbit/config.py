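"""Declarative pipeline configuration (YAML, validated with pydantic).

A config file is a nested key-value document with a mandatory ``seed``;
every physical quantity is validated positive before any stage runs. See
:class:`PipelineConfig` for the full schema and defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, PositiveFloat, PositiveInt


class SimulateConfig(BaseModel):
    """Synthetic population: counts, motion parameters, optional rendering."""

    n_revolving: int = Field(3, ge=0)
    n_translating: int = Field(2, ge=0)
    n_immotile: int = Field(1, ge=0)
    duration_s: PositiveFloat = 1.0
    frame_interval_s: PositiveFloat = 1e-3
    R_um: PositiveFloat = 1.16
    omega_rad_s: PositiveFloat = 22.75
    beat_freq_hz: float = 49.0
    beat_amp_um: float = Field(0.0, ge=0)
    noise_sigma_um: float = Field(0.05, ge=0)
    translator_speed_um_s: float = Field(150.0, ge=0)
    spacing_um: PositiveFloat = 20.0  # anchor grid spacing between cells
    render: bool = False
    pixel_size_um: PositiveFloat = 0.1
    cell_radius_um: PositiveFloat = 5.0
    blur_sigma_px: float = Field(1.0, ge=0)


class TrackingConfig(BaseModel):
    method: str = "otsu"
    polarity: str = "bright_cells"
    threshold: float | None = None
    min_area_px: PositiveInt = 9
    max_area_px: PositiveInt = 10_000_000
    max_disp_um: PositiveFloat = 5.0
    max_gap: int = Field(2, ge=0)


class KinematicsConfig(BaseModel):
    net_disp_thresh_um: PositiveFloat = 2.0
    circularity_thresh: PositiveFloat = 0.35
    beat_prominence: PositiveFloat = 10.0


class GeometryConfig(BaseModel):
    r_um: PositiveFloat = 5.0
    alpha_deg: float = Field(20.0, gt=0, lt=180)


class FluidConfig(BaseModel):
    eta_pa_s: PositiveFloat = 1.002e-3


class PipelineConfig(BaseModel):
    """Top-level pipeline configuration; ``seed`` drives all randomness."""

    seed: int
    out_dir: Path = Path("chlamyorbit_out")
    simulate: SimulateConfig = SimulateConfig()
    tracking: TrackingConfig = TrackingConfig()
    kinematics: KinematicsConfig = KinematicsConfig()
    geometry: GeometryConfig = GeometryConfig()
    fluid: FluidConfig = FluidConfig()

    def config_hash(self) -> str:
        """Stable hash of the validated config, for provenance blocks."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path, seed_override: int | None = None) -> PipelineConfig:
    """Load and validate a YAML config file; optionally override the seed."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if seed_override is not None:
        raw["seed"] = seed_override
    return PipelineConfig.model_validate(raw)
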