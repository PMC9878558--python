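"""Core data containers shared across the pipeline.

The containers are deliberately thin: plain dataclasses wrapping numpy
arrays plus the metadata needed to keep the bookkeeping honest (sampling
rate, block boundaries, feature names, lag conventions).  All heavy
computation lives in the functional modules.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LagSpec",
    "EventList",
    "FeatureSet",
    "Recording",
    "KernelSet",
    "NoiseSpec",
    "CohortSpec",
    "TRFModel",
    "AccuracyRecord",
    "FoldResult",
    "CVResult",
]


@dataclass(frozen=True)
class LagSpec:
    """Lag window of a lagged regression model.

    The integer lag range is ``[floor(tmin_s * fs), ceil(tmax_s * fs)]``,
    inclusive at both ends.  At 256 Hz the window -100..350 ms maps to
    lags -26..90 (117 lags) and -100..800 ms to -26..205 (232 lags).
    """

    tmin_ms: float
    tmax_ms: float
    fs: float

    def __post_init__(self) -> None:
        if self.tmin_ms > self.tmax_ms:
            raise ValueError(f"tmin_ms ({self.tmin_ms}) > tmax_ms ({self.tmax_ms})")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def lmin(self) -> int:
        return math.floor(self.tmin_ms * self.fs / 1000.0)

    @property
    def lmax(self) -> int:
        return math.ceil(self.tmax_ms * self.fs / 1000.0)

    @property
    def n_lags(self) -> int:
        return self.lmax - self.lmin + 1

    @property
    def lags(self) -> np.ndarray:
        """Integer lags, ascending."""
        return np.arange(self.lmin, self.lmax + 1)

    @property
    def lag_times_ms(self) -> np.ndarray:
        return self.lags * 1000.0 / self.fs


@dataclass
class EventList:
    """Word-level events with per-event covariates.

    ``onsets`` are seconds from recording start, strictly increasing.
    ``surprisal`` is unitless and positive; ``snr_word`` is in dB.
    """

    onsets: np.ndarray
    surprisal: np.ndarray
    snr_word: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.surprisal = np.asarray(self.surprisal, dtype=float)
        self.snr_word = np.asarray(self.snr_word, dtype=float)
        n = self.onsets.size
        if self.surprisal.size != n or self.snr_word.size != n:
            raise ValueError("per-event value arrays must match onset count")
        if n and (np.any(self.onsets < 0) or np.any(self.onsets >= self.duration_s)):
            raise ValueError("onsets must lie in [0, duration)")
        if n > 1 and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return int(self.onsets.size)


@dataclass
class FeatureSet:
    """Regressor matrix (time x features) with metadata.

    ``block_bounds`` are half-open ``(start, stop)`` sample index pairs that
    partition the time axis into the 60-s presentation blocks; lagged
    designs are always built per block so no structure leaks across
    block boundaries.
    """

    data: np.ndarray  # time x features
    fs: float
    names: list[str]
    sparse_flags: list[bool]
    block_bounds: list[tuple[int, int]]
    lag_spec: LagSpec | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("feature data must be 2-D (time x features)")
        if len(self.names) != self.data.shape[1]:
            raise ValueError("one name per feature column required")
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"duplicate feature names: {self.names}")
        if len(self.sparse_flags) != len(self.names):
            raise ValueError("one sparsity flag per feature required")
        _check_blocks(self.block_bounds, self.data.shape[0])

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def select(self, names: Sequence[str]) -> "FeatureSet":
        """Column subset (used to build reduced models)."""
        idx = [self.names.index(n) for n in names]
        return FeatureSet(
            data=self.data[:, idx],
            fs=self.fs,
            names=list(names),
            sparse_flags=[self.sparse_flags[i] for i in idx],
            block_bounds=list(self.block_bounds),
            lag_spec=self.lag_spec,
        )


@dataclass
class Recording:
    """Multi-channel neural (or synthetic) recording, channels x time."""

    data: np.ndarray  # channels x time
    fs: float
    channel_names: list[str]
    block_bounds: list[tuple[int, int]]
    subject_id: str = "s00"
    run_ids: list[int] | None = None  # one run id per block

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (channels x time)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        _check_blocks(self.block_bounds, self.data.shape[1])
        if self.run_ids is None:
            self.run_ids = [0] * len(self.block_bounds)
        if len(self.run_ids) != len(self.block_bounds):
            raise ValueError("one run id per block required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class KernelSet:
    """Ground-truth impulse responses used by the forward simulator.

    ``kernels`` has shape (features, lags, channels) using the same lag
    convention as :class:`TRFModel`, so a perfect estimator recovers the
    array exactly.
    """

    kernels: np.ndarray  # features x lags x channels
    lag_spec: LagSpec
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=float)
        f, l, _c = self.kernels.shape
        if f != len(self.feature_names):
            raise ValueError("one kernel per feature required")
        if l != self.lag_spec.n_lags:
            raise ValueError("kernel lag axis inconsistent with lag_spec")


@dataclass(frozen=True)
class NoiseSpec:
    """Background-noise model for the simulator.

    ``alpha`` is the spectral exponent of the 1/f^alpha background,
    ``channel_corr`` in [0, 1] mixes a set of shared spatial sources into
    every channel, and ``snr`` is the per-channel variance ratio of the
    convolved signal to the noise.  ``band_hz`` restricts the noise
    spectrum to the analysis band (default 1-8 Hz), emulating recordings
    that have already passed the band-pass stage of the pipeline; ``snr``
    is then an in-band ratio.  Set ``band_hz=None`` for broadband noise.
    """

    snr: float = 0.2
    alpha: float = 1.0
    channel_corr: float = 0.3
    n_shared_sources: int = 8
    band_hz: tuple[float, float] | None = (1.0, 8.0)

    def __post_init__(self) -> None:
        if self.band_hz is not None and not 0 <= self.band_hz[0] < self.band_hz[1]:
            raise ValueError("band_hz must satisfy 0 <= lo < hi")
        if self.snr <= 0:
            raise ValueError("snr must be > 0 (use synthesize with zero kernels for pure noise)")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 <= self.channel_corr <= 1.0:
            raise ValueError("channel_corr must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Shape of a synthetic multi-subject cohort.

    ``minutes`` is the total recorded duration per subject, split into
    60-s blocks distributed over ``n_runs`` runs in acquisition order.
    Subject variability: multiplicative amplitude scale with log-normal
    spread ``amp_sd`` (log-scale SD) and latency jitter drawn uniformly
    from +-``latency_jitter_ms``.
    """

    n_subjects: int
    minutes: int
    channels: int = 64
    fs: float = 256.0
    block_s: float = 60.0
    n_runs: int = 2
    amp_sd: float = 0.2
    latency_jitter_ms: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs >= 2 subjects")
        total_s = self.minutes * 60.0
        n_blocks = total_s / self.block_s
        if abs(n_blocks - round(n_blocks)) > 1e-9:
            raise ValueError("minutes must divide into whole blocks")

    @property
    def n_blocks(self) -> int:
        return int(round(self.minutes * 60.0 / self.block_s))


@dataclass
class TRFModel:
    """Fitted temporal response function.

    ``beta`` has shape (features, lags, channels); the intercept is kept
    separate so that coefficient counts match the lagged-design size
    (features x lags per channel).
    """

    beta: np.ndarray
    intercept: np.ndarray
    lam: float
    lag_spec: LagSpec
    feature_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.intercept = np.asarray(self.intercept, dtype=float)
        f, l, c = self.beta.shape
        if f != len(self.feature_names) or l != self.lag_spec.n_lags:
            raise ValueError("beta shape inconsistent with lag_spec / features")
        if self.intercept.shape != (c,):
            raise ValueError("intercept must be per channel")
        if self.lam < 0:
            raise ValueError("ridge parameter must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.beta.shape[2]


@dataclass
class AccuracyRecord:
    """Per-channel prediction accuracies of one evaluation."""

    r: np.ndarray  # per channel
    fold_id: int
    unit_id: str
    floor_mean: np.ndarray | None = None  # per channel

    @property
    def corrected(self) -> np.ndarray:
        if self.floor_mean is None:
            raise ValueError("no noise floor attached")
        return self.r - self.floor_mean


@dataclass
class FoldResult:
    model: TRFModel
    accuracy: AccuracyRecord
    lam: float
    unit_id: str


@dataclass
class CVResult:
    """Leave-one-unit-out cross-validation output: one fold per unit."""

    folds: list[FoldResult]
    feature_names: list[str]
    lag_spec: LagSpec

    @property
    def accuracies(self) -> np.ndarray:
        """folds x channels array of raw Pearson accuracies."""
        return np.stack([f.accuracy.r for f in self.folds])

    @property
    def corrected_accuracies(self) -> np.ndarray:
        return np.stack([f.accuracy.corrected for f in self.folds])

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([f.lam for f in self.folds])

    def mean_beta(self) -> np.ndarray:
        return np.mean([f.model.beta for f in self.folds], axis=0)


def _check_blocks(bounds: list[tuple[int, int]], n: int) -> None:
    if not bounds:
        raise ValueError("at least one block required")
    pos = 0
    for start, stop in bounds:
        if start != pos or stop <= start:
            raise ValueError(f"block bounds {bounds} do not partition [0, {n})")
        pos = stop
    if pos != n:
        raise ValueError(f"block bounds {bounds} do not cover all {n} samples")
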