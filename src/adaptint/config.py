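"""Run configuration: YAML file -> validated, fully defaulted settings.

Unknown keys are rejected, every range is validated, and the master seed is
mandatory.  The effective (post-default) configuration round-trips: dumping
it and reloading yields an identical object, and every CLI command echoes
it into its manifest.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .adjustment import AdjustmentConfig
from .rewards import RewardConfig
from .simulator import CohortConfig

__all__ = ["RunConfig", "load_config", "config_error_key"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Section):
    n_latent: int = Field(4, ge=1)
    n_cues: int = Field(6, ge=1)
    decay_c0: float = 0.0
    decay_c1: float = 1.0
    reg_lambda: float = Field(0.0, ge=0)
    attention_renorm: str = Field("none", pattern="^(none|max|sum_to_D)$")
    noise_scale: float = Field(0.05, ge=0)
    max_iter: int = Field(5000, ge=1)
    tol: float = Field(1e-8, gt=0)


class RewardSection(_Section):
    sensitivity_alpha: float = Field(1.0, ge=0)
    scale_gamma: float = Field(1.0, gt=0)
    discount_beta: float = Field(0.9, ge=0, le=1)
    penalty_lambda: float = Field(0.1, ge=0)
    improvement_threshold_delta: float = 0.0

    def to_dataclass(self) -> RewardConfig:
        return RewardConfig(**self.model_dump())


class PolicySection(_Section):
    n_bins: int = Field(10, ge=1)
    learn_rate_beta: float = Field(0.1, gt=0, le=1)
    discount_gamma: float = Field(0.9, ge=0, lt=1)
    epsilon_0: float = Field(0.3, ge=0, le=1)
    epsilon_decay: float = Field(0.999, gt=0, le=1)
    epsilon_min: float = Field(0.05, ge=0, le=1)
    default_q: float = 0.0
    n_sessions: int = Field(500, ge=1)
    n_interactions: int = Field(30, ge=1)


class AdjustmentSection(_Section):
    window_size: int = Field(5, ge=1)
    eta: float = Field(0.1, ge=0)
    smooth_lambda: float = Field(0.8, ge=0, le=1)
    p_min: float = Field(0.2, ge=0, le=1)
    p_max: float = Field(0.9, ge=0, le=1)
    phi_max: float = Field(2.0, gt=0)

    def to_dataclass(self) -> AdjustmentConfig:
        return AdjustmentConfig(**self.model_dump())


class SimulatorSection(_Section):
    n_children: int = Field(30, ge=1)
    n_interactions: int = Field(30, ge=1)
    n_cues: int = Field(6, ge=1)
    interventions: tuple[str, ...] = ("A", "B", "C")
    best_intervention: str = "A"
    best_effect: float = 0.3
    other_effect: float = 0.0
    baseline_range: tuple[float, float] = (0.3, 0.7)
    carryover_range: tuple[float, float] = (0.5, 0.9)
    loading_range: tuple[float, float] = (0.5, 1.0)
    noise_sd: float = Field(0.05, ge=0)
    cue_noise_sd: float = Field(0.05, ge=0)

    def to_dataclass(self, master_seed: int) -> CohortConfig:
        return CohortConfig(master_seed=master_seed, **self.model_dump())


class RunConfig(_Section):
    """Top-level run configuration; ``seed`` is the mandatory master seed."""

    seed: int
    model: ModelSection = ModelSection()
    reward: RewardSection = RewardSection()
    policy: PolicySection = PolicySection()
    adjustment: AdjustmentSection = AdjustmentSection()
    simulator: SimulatorSection = SimulatorSection()

    def effective(self) -> dict:
        return self.model_dump(mode="json")


def config_error_key(exc: ValidationError) -> str:
    """Dotted key of the first offending entry, e.g. 'reward.discount_beta'."""
    return ".".join(str(p) for p in exc.errors()[0]["loc"])


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; errors name the offending key."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(doc)
    except ValidationError as exc:
        key = config_error_key(exc)
        msg = exc.errors()[0]["msg"]
        raise ValueError(f"invalid config {path}: {key}: {msg}") from exc
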