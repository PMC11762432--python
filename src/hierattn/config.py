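"""Run configuration: schema-validated YAML with explicit defaults for every
tunable, and a documented fan-out of the global seed into stage seeds."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

STAGES = ("simulate", "tensorize", "train", "evaluate", "baselines", "explain")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed so stages are independently replayable."""
    k = STAGES.index(stage)
    return (global_seed * 1000003 + 17 * (k + 1)) % (2 ** 31)


class SyntheticSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patients: int = 2000
    visit_rate_range: tuple[float, float] = (0.5, 6.0)
    outcome_base_rates: dict[str, float] = Field(
        default_factory=lambda: {"mortality": 0.12, "nursing_home": 0.06,
                                 "home_care": 0.10})
    planted_event_rate: float = 0.7
    in_migrant_fraction: float = 0.10
    exit_hazard: float = 0.02
    risk_spec: Optional[list[dict]] = None   # default: the generator's


class TrainingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    learning_rate: float = 1e-2
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 5
    grid_max_epochs: Optional[int] = None


class EvaluationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    threshold: float = 0.5
    n_bootstrap: int = 1000
    age_strata_edges: tuple[int, ...] = (65, 75, 85)


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rnn_type: str = "GRU"
    units: int = 64
    dense_before_output: int = 0
    embed_dim: int = 8
    attn_dim: int = 32


class RunConfig(BaseModel):
    """Validated end-to-end run configuration (unknown keys rejected)."""
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    outcome: str = "mortality"
    window: int = 1
    grid: Optional[list[dict]] = None        # None: single config, no search
    synthetic: SyntheticSection = Field(default_factory=SyntheticSection)
    model: ModelSection = Field(default_factory=ModelSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)

    @field_validator("outcome")
    @classmethod
    def _outcome_known(cls, v: str) -> str:
        if v not in ("mortality", "nursing_home", "home_care"):
            raise ValueError(f"unknown outcome {v!r}")
        return v

    @field_validator("window")
    @classmethod
    def _window_known(cls, v: int) -> int:
        if v not in (1, 5):
            raise ValueError("window must be 1 or 5")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json")))
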