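"""Schema-validated pipeline configuration (YAML) and run manifests.

A single config object carries every stage's parameters so cross-stage
constants (the 2.8 mm working spacing, the 70/50/1 mm crop margins) have one
source of truth. Unknown keys are rejected. Each CLI stage writes a JSON
manifest (inputs, config hash, seed, package version) next to its outputs so
any artifact can be re-run exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__

SCHEMA_VERSION = 1


class PhantomConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 2.8
    n_patients: int = 20
    grade_proportions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    counts_per_view: int = 1_000_000


class AugmentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_fraction: float = 0.05
    max_fraction: float = 1.50
    step: float = 0.05
    n_augmented_per_case: int = 28


class SegConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    backbone: str = "unet_small"
    epochs: int = 10
    batch_size: int = 2
    lr0: float = 1e-2
    n_train: int = 10
    n_val: int = 4
    overlap: float = 0.5


class ClsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    backbone: str = "cnn_small"
    epochs: int = 20
    batch_size: int = 4
    lr0: float = 5e-3
    input_spacing_mm: float = 2.8
    input_hw: tuple[int, int] = (96, 96)
    folds: int = 3


class LocalizationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    margins_mm: dict[str, float] = Field(
        default_factory=lambda: {"lv": 70.0, "whole_heart": 50.0, "ribcage": 1.0}
    )


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    workdir: str = "attrscint_run"
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    augment: AugmentConfig = Field(default_factory=AugmentConfig)
    segmentation: SegConfig = Field(default_factory=SegConfig)
    classification: ClsConfig = Field(default_factory=ClsConfig)
    localization: LocalizationConfig = Field(default_factory=LocalizationConfig)

    @model_validator(mode="after")
    def _check_consistency(self):
        margins = self.localization.margins_mm
        if set(margins) != {"lv", "whole_heart", "ribcage"}:
            raise ValueError("margins must cover lv, whole_heart, ribcage")
        if any(m < 0 for m in margins.values()):
            raise ValueError("margins must be >= 0")
        if self.classification.input_spacing_mm <= 0 or self.phantom.spacing_mm <= 0:
            raise ValueError("spacings must be positive")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir, stage: str, config: PipelineConfig, inputs: list[str]) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "inputs": sorted(str(i) for i in inputs),
        "config_hash": config.config_hash(),
        "config": config.model_dump(),
        "seed": config.seed,
        "version": __version__,
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
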