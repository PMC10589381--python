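"""Validated pipeline configuration (YAML or JSON).

One global seed fans out deterministically to per-module random streams via
``numpy.random.SeedSequence`` spawn keys, so reproducibility survives
pipeline reordering.  Unknown configuration keys are rejected on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .blob_world import SimConfig
from .counting_net import NetSpec, TrainConfig
from .lifespan_eval import StrainProfile
from .survival_sim import GridSpec

__all__ = ["PipelineConfig", "load_config", "module_rng", "module_seed"]

# fixed spawn indices per pipeline stage
_STREAMS = {"simulator": 0, "training": 1, "detection": 2, "evaluation": 3}


def module_seed(global_seed: int, module: str) -> int:
    """Derive a module-level integer seed (< 2**31) from the global seed."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(_STREAMS[module],))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def module_rng(global_seed: int, module: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(_STREAMS[module],))
    return np.random.default_rng(ss)


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridSection(_Section):
    n_objects: tuple[int, int] = (10, 15)
    mean_life: tuple[int, int] = (5, 57)
    slope: tuple[int, int] = (4, 20)
    perturb_magnitude: float = Field(0.05, ge=0)

    def to_spec(self) -> GridSpec:
        return GridSpec(tuple(self.n_objects), tuple(self.mean_life), tuple(self.slope))


class SimSection(_Section):
    image_size: int = Field(256, ge=8)
    seq_length: int = Field(57, ge=1)
    blob_radius: int = Field(3, ge=1)
    background_intensity: int = Field(255, ge=0, le=255)
    blob_intensity: int = Field(0, ge=0, le=255)
    plate_margin: int = Field(10, ge=0)
    occlusion_prob: float = Field(0.05, ge=0, lt=1)
    blank_days: list[int] | None = None
    max_rotation: float = Field(3.0, ge=0)
    max_translation: float = Field(4.0, ge=0)

    def to_config(self, perturb_magnitude: float = 0.05) -> SimConfig:
        return SimConfig(
            image_size=self.image_size, seq_length=self.seq_length,
            blob_radius=self.blob_radius,
            background_intensity=self.background_intensity,
            blob_intensity=self.blob_intensity, plate_margin=self.plate_margin,
            occlusion_prob=self.occlusion_prob,
            blank_day_schedule=None if self.blank_days is None else frozenset(self.blank_days),
            max_rotation=self.max_rotation, max_translation=self.max_translation,
            perturb_magnitude=perturb_magnitude)


class NetSection(_Section):
    variant: str = "lstm"
    seq_length: int = 57
    image_size: int = 256
    tiny: bool = False

    def to_spec(self) -> NetSpec:
        if self.tiny:
            return NetSpec.tiny(self.variant)
        return NetSpec(variant=self.variant, seq_length=self.seq_length,
                       image_size=self.image_size)


class TrainSection(_Section):
    epochs: int = 600
    lr: float = 0.001
    batch_size: int = 16
    momentum: float = 0.9
    weight_decay: float = 0.0
    batches_per_epoch: int = 4

    def to_config(self, seed: int) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, lr=self.lr,
                           batch_size=self.batch_size, momentum=self.momentum,
                           weight_decay=self.weight_decay,
                           batches_per_epoch=self.batches_per_epoch, seed=seed)


class DetectionSection(_Section):
    score_threshold: float = Field(0.85, ge=0, le=1)
    iou_threshold: float = Field(0.5, gt=0, le=1)


class StrainSection(_Section):
    name: str
    mean_life: int = Field(ge=1)

    def to_profile(self) -> StrainProfile:
        return StrainProfile(self.name, self.mean_life)


class PipelineConfig(_Section):
    seed: int = 0
    grid: GridSection = GridSection()
    sim: SimSection = SimSection()
    net: NetSection = NetSection()
    train: TrainSection = TrainSection()
    detection: DetectionSection = DetectionSection()
    strains: list[StrainSection] = Field(default_factory=lambda: [
        StrainSection(name="N2", mean_life=14),
        StrainSection(name="daf-2", mean_life=42),
    ])
    output_dir: str = "wormspan_out"

    def strain(self, name: str) -> StrainProfile:
        for s in self.strains:
            if s.name == name:
                return s.to_profile()
        raise KeyError(f"unknown strain {name!r}; configured: "
                       f"{[s.name for s in self.strains]}")

    def sim_config(self) -> SimConfig:
        return self.sim.to_config(self.grid.perturb_magnitude)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a pipeline config; defaults when ``path`` is None."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return PipelineConfig.model_validate(data or {})
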