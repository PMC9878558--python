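"""Run configuration: a single schema-validated JSON document.

Unknown keys are rejected so typos fail loudly; every pipeline command
writes the fully resolved configuration next to its outputs, making
each artifact reproducible from (config, seed) alone.
"""
from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict

from .containers import CohortSpec, NoiseSpec
from .experiments import ModelDef, SweepGrid

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortConfig(_Strict):
    n_subjects: int = 5
    minutes: int = 8
    channels: int = 64
    fs: float = 256.0
    block_s: float = 60.0
    n_runs: int = 2
    amp_sd: float = 0.2
    latency_jitter_ms: float = 20.0

    def spec(self, seed: int) -> CohortSpec:
        return CohortSpec(seed=seed, **self.model_dump())


class NoiseConfig(_Strict):
    snr: float = 0.2
    alpha: float = 1.0
    channel_corr: float = 0.3
    n_shared_sources: int = 8

    def spec(self) -> NoiseSpec:
        return NoiseSpec(**self.model_dump())


class ModelConfig(_Strict):
    name: str
    features: list[str]
    lag_window_ms: tuple[float, float]

    def model_def(self) -> ModelDef:
        return ModelDef(self.name, tuple(self.features), tuple(self.lag_window_ms))


class SweepConfig(_Strict):
    quantities_min: list[int] = [3, 4, 6, 8, 10, 14, 18, 24, 30, 36, 42]
    subject_counts: list[int] = [3, 4, 6, 8, 10, 14, 18, 24, 30, 36, 41]
    minutes_per_subject: list[int] = [2, 4, 8]
    n_resamples: int = 20

    def grid(self, seed: int) -> SweepGrid:
        return SweepGrid(
            quantities_min=tuple(self.quantities_min),
            subject_counts=tuple(self.subject_counts),
            minutes_per_subject=tuple(self.minutes_per_subject),
            n_resamples=self.n_resamples,
            seed=seed,
        )


class StatsConfig(_Strict):
    alphas: list[float] = [0.05, 0.01, 0.001]
    n_boot: int = 10_000
    criterion: float = 0.8
    pool_min: int = 2
    pool_max: int = 41


class RunConfig(_Strict):
    cohort: CohortConfig = CohortConfig()
    noise: NoiseConfig | None = NoiseConfig()
    models: list[ModelConfig] = [
        ModelConfig(name="dense", features=["envelope", "onset"], lag_window_ms=(-100, 350)),
        ModelConfig(
            name="sparse",
            features=["onset", "surprisal", "snr_word"],
            lag_window_ms=(-100, 800),
        ),
    ]
    lambda_grid: list[float] = [10.0**k for k in range(-2, 9)]
    sweep: SweepConfig = SweepConfig()
    stats: StatsConfig = StatsConfig()
    seed: int = 0

    def dump(self, path: Path) -> None:
        path.write_text(self.model_dump_json(indent=1))


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = json.loads(Path(path).read_text())
    return RunConfig.model_validate(raw)
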