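"""Schema-validated pipeline configuration.

A single YAML file drives the CLI; unknown keys are rejected, and every run
writes the fully resolved configuration next to its outputs so results are
reproducible from the artefacts alone.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["ReconConfig", "FitConfig", "RoiConfig", "StatsConfig", "PipelineConfig"]


class ReconConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p_exponent: float = 0.5
    lambda_rel: float = 1e-4
    n_outer: int = 3
    n_inner_cg: int = 60
    n_pc_kept: int = 4
    merge_window: int = 2


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t2_grid_min_ms: float = 30.0
    t2_grid_max_ms: float = 3000.0
    t2_grid_points: int = 200
    b1_grid_min: float = 0.8
    b1_grid_max: float = 1.2
    b1_grid_step: float = 0.05
    t1_ms: float = 1500.0
    rician_correction: bool = True


class RoiConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_pixels: int = 10
    erode_px: int = 1


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 0.05


class PipelineConfig(BaseModel):
    """Top-level run configuration (strict schema)."""

    model_config = ConfigDict(extra="forbid")

    protocol: Literal["high_res", "bh"] = "bh"
    grid: int | None = None  # phantom grid size; None → protocol matrix
    lesion_subtype: str = "pRCC"
    lesion_diameter_mm: float = 56.0
    acceleration: float | None = None  # None → protocol nominal
    snr: float = 30.0
    seed: int = 0
    recon: ReconConfig = Field(default_factory=ReconConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    roi: RoiConfig = Field(default_factory=RoiConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    out_dir: str = "ktmese_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)

    def write_resolved(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        p = out / "resolved_config.yaml"
        p.write_text(self.resolved_yaml())
        return p
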