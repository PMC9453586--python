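"""Experiment configuration: YAML loading, validation, seed derivation.

The configuration schema fails closed (unknown keys are errors) and injects
the protocol defaults everywhere: 4-hour grid step, window W=6, decision
threshold TH=0.5, 68/12/20 split fractions.  A single top-level seed
deterministically derives the per-stage seeds through
:class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

__all__ = ["ExperimentConfig", "ConfigError", "load_and_validate",
           "dump_config", "derive_stage_seeds"]


class ConfigError(ValueError):
    """Configuration failed to parse or validate."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class CohortShift(_Strict):
    """How cohort B differs from cohort A (second-hospital emulation)."""

    baseline_shift_sds: float = 1.0
    missing_prob_add: float = Field(default=0.10, ge=-1.0, le=1.0)


class GeneratorSettings(_Strict):
    n_stays: int = Field(default=200, ge=1)
    duration_low: int = Field(default=3, ge=3, le=18)
    duration_high: int = Field(default=18, ge=3, le=18)
    episode_rate: float | None = Field(default=None, ge=0.0, le=1.0)
    episode_persistence: float | None = Field(default=None, ge=0.0, le=1.0)
    cohort_b: CohortShift = CohortShift()


class PreprocessingSettings(_Strict):
    step_hours: float = Field(default=4.0, gt=0)
    coverage_threshold: float = Field(default=0.9, gt=0, le=1)
    tukey_k: float = Field(default=1.5, gt=0)
    knn_k: int = Field(default=5, ge=1)
    svd_rank: int | None = Field(default=None)
    use_svd: bool = True
    max_missing_fraction: float = Field(default=0.5, ge=0, le=1)


class WindowingSettings(_Strict):
    window: int = Field(default=6, ge=2)
    fractions: tuple[float, float, float] = (0.68, 0.12, 0.20)
    reference_ranges_path: str | None = None
    group_by_stay: bool = False

    @field_validator("fractions")
    @classmethod
    def _sum_to_one(cls, v):
        if any(f < 0 for f in v) or abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        return v


class TrainingSettings(_Strict):
    max_epochs: int = Field(default=40, ge=1)
    batch_size: int = Field(default=64, ge=1)
    learning_rate: float = Field(default=5e-3, gt=0)
    early_stopping_delta: float = Field(default=0.01, ge=0)
    patience: int = Field(default=10, ge=1)
    threshold: float = 0.5

    @field_validator("threshold")
    @classmethod
    def _th_open_interval(cls, v):
        if not 0 < v < 1:
            raise ValueError("threshold must lie strictly between 0 and 1")
        return v


class ExperimentConfig(_Strict):
    seed: int = 0
    output_dir: str = "labwatch_output"
    architectures: list[str] = ["lstm", "cnn", "mcnn", "transformer",
                                "tcn", "gbm"]
    generator: GeneratorSettings = GeneratorSettings()
    preprocessing: PreprocessingSettings = PreprocessingSettings()
    windowing: WindowingSettings = WindowingSettings()
    training: TrainingSettings = TrainingSettings()
    models: dict[str, dict] = {}  # per-architecture hyperparameter overrides


def load_and_validate(config_path: str | Path | None) -> ExperimentConfig:
    """Load YAML, inject defaults, validate every constraint.

    An empty (or absent) file yields the full default configuration.
    Referenced file paths must resolve at load time.
    """
    raw = {}
    if config_path is not None:
        path = Path(config_path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"config does not parse as YAML: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config top level must be a mapping")
    try:
        cfg = ExperimentConfig(**raw)
    except ValidationError as exc:
        msgs = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
            for e in exc.errors())
        raise ConfigError(f"invalid configuration: {msgs}") from exc
    rr = cfg.windowing.reference_ranges_path
    if rr is not None and not Path(rr).exists():
        raise ConfigError(f"reference_ranges_path does not resolve: {rr}")
    return cfg


def dump_config(cfg: ExperimentConfig) -> str:
    """Serialize the effective configuration back to YAML."""
    return yaml.safe_dump(cfg.model_dump(), sort_keys=False)


_STAGES = ("generator_a", "generator_b", "split", "train", "compare")


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Deterministically derive one sub-seed (< 2^31) per pipeline stage."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: int(c.generate_state(1)[0] % 2**31)
            for name, c in zip(_STAGES, children)}
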