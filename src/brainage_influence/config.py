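"""Run configuration: YAML loading, strict validation, fully-echoed defaults.

Unknown keys are rejected (fail-fast, before any computation) and every
default is materialised into the loaded object so the run manifest records
the exact configuration in force.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration file violates the schema; message lists offending keys."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataConfig(_Strict):
    id_column: str = "subject_id"
    age_column: str = "age"
    label_column: str = "diagnosis"
    features: Optional[list[str]] = None  # None: all non-reserved columns
    labels: Optional[list[str]] = None  # None: labels found in the data
    control_label: str = "CN"


class ModelConfig(_Strict):
    regressor: str = "linear"
    hyperparams: dict = Field(default_factory=dict)
    n_folds: int = Field(5, ge=2)
    bias_correction: str = "predicted_on_age"


class MIConfig(_Strict):
    k_neighbors: int = Field(3, ge=1)


class ClassificationConfig(_Strict):
    n_folds: int = Field(5, ge=2)
    penalty_c: float = Field(1e6, gt=0)


class SeedsConfig(_Strict):
    master: int = Field(42, ge=0)
    n_repeats: int = Field(1, ge=1)


class OutputConfig(_Strict):
    directory: str = "."
    plots: bool = True


class ExperimentConfig(_Strict):
    ordering: str = "both"  # "age" | "discrimination" | "both"
    age_ranking_population: str = "all"  # "all" | "controls"


class RunConfig(_Strict):
    """Validated configuration for the two pipelines and the generator."""

    data: DataConfig = Field(default_factory=DataConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    mi: MIConfig = Field(default_factory=MIConfig)
    classification: ClassificationConfig = Field(default_factory=ClassificationConfig)
    seeds: SeedsConfig = Field(default_factory=SeedsConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)
    experiment: ExperimentConfig = Field(default_factory=ExperimentConfig)

    def to_dict(self) -> dict:
        return self.model_dump()

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    try:
        return RunConfig(**doc)
    except ValidationError as exc:
        offending = ", ".join(
            "/".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration ({offending}): {exc}") from exc
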