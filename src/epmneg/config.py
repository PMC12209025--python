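"""Run configuration (YAML) and deterministic seed fan-out."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field

from .geometry import MazeGeometry

__all__ = ["RunConfig", "load_config", "derive_seed"]


class MazeBlock(BaseModel):
    arm_length: float = 50.0
    arm_width: float = 10.0
    centre_size: float = 10.0
    grid_resolution: float = 1.0
    open_axis: str = "x"

    def build(self) -> MazeGeometry:
        return MazeGeometry(
            self.arm_length, self.arm_width, self.centre_size,
            self.grid_resolution, self.open_axis,
        )


class DiscretisationBlock(BaseModel):
    interpolate: bool = True
    speed_warn: float = 25.0


class SimulationBlock(BaseModel):
    phenotypes: list[str] = ["exploratory", "delayed", "avoidant"]
    n_subjects: int = 10
    duration: float = 300.0
    noise: bool = True


class SamplerBlock(BaseModel):
    walkers: int = 48
    steps: int = 2600
    burn: int = 900
    time_step: float = 10.0  # change-point fit grid spacing, s


class EffectsBlock(BaseModel):
    rope_scale: str = "response"
    hdi_mass: float = 0.95
    basis_size: int | None = None
    n_draws: int = 4000


class ClassificationBlock(BaseModel):
    open_floor: float = 5.0
    cutpoints: tuple[float, float, float] = (25.0, 50.0, 75.0)


class RunConfig(BaseModel):
    maze: MazeBlock = Field(default_factory=MazeBlock)
    discretisation: DiscretisationBlock = Field(default_factory=DiscretisationBlock)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    sampler: SamplerBlock = Field(default_factory=SamplerBlock)
    effects: EffectsBlock = Field(default_factory=EffectsBlock)
    classification: ClassificationBlock = Field(default_factory=ClassificationBlock)
    seed: int = 0
    output_dir: str = "epmneg-out"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def derive_seed(global_seed: int, stage: str) -> int:
    """Counter-free per-stage seed derived from the global seed.

    Stable across runs and below 2**31 so it can feed any RNG interface.
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
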