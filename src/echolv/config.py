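"""Run configuration: one YAML/JSON document drives the whole pipeline."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .phantom import PhantomConfig


class FeaturesConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    k_grid: list[int] = Field(default_factory=lambda: [2, 4, 8, 12])
    n_basis: int = Field(default=8, ge=4)
    periodic: bool = True


class AssistAnchorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    theta_deg: float = 90.0
    boundary: str = "endo"
    z_frac: float = 0.50


class ModelsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    variants: list[int] = Field(default_factory=lambda: [1, 2, 3])
    variant: int = 2  # variant used by the single-model fit/predict stages
    n_components: int = Field(default=8, ge=1)
    assist_anchor: AssistAnchorConfig = Field(default_factory=AssistAnchorConfig)


class EvaluationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_iter: int = Field(default=20, ge=1)
    seed: int = 0
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    metric_alpha: float = Field(default=0.001, gt=0.0, lt=1.0)


class IOConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cine_format: str = "tiff"


class RunConfig(BaseModel):
    """Top-level pipeline configuration; unknown keys are rejected by name."""

    model_config = ConfigDict(extra="forbid")

    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    features: FeaturesConfig = Field(default_factory=FeaturesConfig)
    models: ModelsConfig = Field(default_factory=ModelsConfig)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)
    io: IOConfig = Field(default_factory=IOConfig)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML (or JSON) run configuration; defaults when *path* is None."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(payload)
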