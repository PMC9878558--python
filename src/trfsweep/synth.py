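"""Synthetic EEG cohort generator with known ground-truth TRFs.

The generator realizes the forward model the estimator inverts: each
recording is the sum, over stimulus features, of the feature's
regressor convolved with a known impulse-response kernel, plus
1/f-type spatially correlated background noise.  Because the kernels
are known, estimator behavior (recovery, accuracy-vs-data trends,
noise floors) can be validated quantitatively — something impossible
with real EEG, where the true response is never observed.

Cohort structure emulates a typical continuous-speech listening study:
64 channels at 256 Hz, 60-s presentation blocks organized into runs,
word events at conversational rates, and multiplicative amplitude /
latency variability between subjects.
"""
from __future__ import annotations

import numpy as np
import scipy.signal

from . import features as feat
from .containers import (
    CohortSpec,
    EventList,
    FeatureSet,
    KernelSet,
    LagSpec,
    NoiseSpec,
    Recording,
)
from .montage import BIOSEMI64, FRONTAL_ROI, PARIETAL_ROI, default_channel_names
from .trf import build_design

__all__ = [
    "gen_word_events",
    "gen_dense_envelope",
    "gen_ground_truth_kernels",
    "default_topographies",
    "synthesize_recording",
    "synthesize_cohort",
    "make_feature_set",
]


def gen_word_events(
    duration_s: float,
    mean_interval_s: float = 0.32,
    min_interval_s: float = 0.12,
    seed: int | np.random.SeedSequence = 0,
    surprisal_lognorm: tuple[float, float] = (1.0, 0.5),
    snr_word_db: tuple[float, float] = (0.0, 4.0),
) -> EventList:
    """Word onsets from a renewal process with per-event covariates.

    Inter-onset intervals are ``min_interval_s`` plus a gamma variate
    (shape 2) with overall mean ``mean_interval_s``, matching
    conversational word rates (~3 words/s).  Surprisal is log-normal
    (right-skewed, positive); word SNR is normal in dB (symmetric).
    """
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    if not mean_interval_s > min_interval_s >= 0:
        raise ValueError("need mean_interval_s > min_interval_s >= 0")
    rng = np.random.default_rng(seed)
    onsets: list[float] = []
    t = 0.0
    scale = (mean_interval_s - min_interval_s) / 2.0  # gamma shape 2
    # draw in chunks to keep the RNG stream simple and reproducible
    while True:
        gaps = min_interval_s + rng.gamma(2.0, scale, size=256)
        for g in gaps:
            t += g
            if t >= duration_s:
                break
            onsets.append(t)
        if t >= duration_s:
            break
    n = len(onsets)
    mu, sig = surprisal_lognorm
    m_db, sd_db = snr_word_db
    return EventList(
        onsets=np.array(onsets),
        surprisal=rng.lognormal(mu, sig, size=n),
        snr_word=rng.normal(m_db, sd_db, size=n),
        duration_s=duration_s,
    )


def gen_dense_envelope(
    duration_s: float, fs: float, seed: int | np.random.SeedSequence = 0
) -> np.ndarray:
    """Speech-envelope surrogate: non-negative, power concentrated < 8 Hz.

    White noise is low-passed below 8 Hz, half-wave rectified and
    low-passed again; residual negative ringing is clipped at zero.
    """
    n = int(round(duration_s * fs))
    if n == 0:
        return np.zeros(0)
    if fs <= 16:
        raise ValueError("fs must exceed twice the 8 Hz envelope band")
    rng = np.random.default_rng(seed)
    sos = scipy.signal.butter(4, 8.0, btype="low", fs=fs, output="sos")
    x = scipy.signal.sosfiltfilt(sos, rng.standard_normal(n))
    x = np.maximum(x, 0.0)
    x = scipy.signal.sosfiltfilt(sos, x)
    return np.maximum(x, 0.0)


def _gabor(t_ms: np.ndarray, center_ms: float, width_ms: float, freq_hz: float) -> np.ndarray:
    env = np.exp(-0.5 * ((t_ms - center_ms) / width_ms) ** 2)
    return env * np.sin(2 * np.pi * freq_hz * (t_ms - center_ms) / 1000.0 + np.pi / 2)


# canonical deflection layouts (center ms, width ms, oscillation Hz, amplitude)
_COMPONENTS = {
    "envelope": [(70.0, 30.0, 4.0, 1.0), (160.0, 45.0, 3.0, -0.7), (250.0, 55.0, 2.0, 0.35)],
    "onset": [(90.0, 35.0, 3.5, 1.0), (200.0, 55.0, 2.5, -0.5)],
    "surprisal": [(120.0, 45.0, 3.0, 0.6), (400.0, 80.0, 1.5, -1.0)],
    "snr_word": [(140.0, 50.0, 2.5, 0.5), (380.0, 90.0, 1.5, -0.8)],
}


def default_topographies(feature_names: list[str], n_channels: int) -> dict[str, np.ndarray]:
    """Canonical fixed topographies: fronto-central weighting for the
    acoustic features, parietal weighting for the word-level features.

    With the 64-channel montage the weights peak on the frontal/parietal
    ROI electrodes; with other channel counts smooth index-based bumps
    are used."""
    out = {}
    for j, name in enumerate(feature_names):
        topo = np.full(n_channels, 0.2)
        if n_channels == len(BIOSEMI64):
            roi = FRONTAL_ROI if name in ("envelope", "onset") else PARIETAL_ROI
            idx = [BIOSEMI64.index(ch) for ch in roi]
            topo[idx] = 1.0
        else:
            center = (j + 1) * n_channels / (len(feature_names) + 1)
            topo += 0.8 * np.exp(-0.5 * ((np.arange(n_channels) - center) / (n_channels / 4)) ** 2)
        out[name] = topo
    return out


def gen_ground_truth_kernels(
    lag_spec: LagSpec,
    feature_names: list[str],
    topographies: dict[str, np.ndarray],
    seed: int | np.random.SeedSequence = 0,
    amplitude: float = 1.0,
    jitter: bool = True,
    zero_features: tuple[str, ...] = (),
) -> KernelSet:
    """Smooth multi-deflection ground-truth kernels, one per feature.

    Each kernel is a sum of Gabor-like deflections (canonical layouts
    per feature; word-level features carry a late ~380-420 ms
    deflection) times the feature's fixed channel topography, tapered
    to zero at the lag-window edges.  ``seed`` jitters deflection
    centers (+-15 ms) and amplitudes (~20%) so different cohorts have
    different but same-support kernels.  Features listed in
    ``zero_features`` (or a zero ``amplitude``) get all-zero kernels.
    """
    missing = [n for n in feature_names if n not in topographies]
    if missing:
        raise ValueError(f"no topography for feature(s) {missing}")
    rng = np.random.default_rng(seed)
    t_ms = lag_spec.lag_times_ms
    span = t_ms[-1] - t_ms[0]
    taper = np.sin(np.pi * np.clip((t_ms - t_ms[0]) / span, 0, 1)) ** 0.25
    ch = len(next(iter(topographies.values())))
    kernels = np.zeros((len(feature_names), lag_spec.n_lags, ch))
    for i, name in enumerate(feature_names):
        comps = _COMPONENTS.get(name, [(100.0, 40.0, 3.0, 1.0)])
        course = np.zeros_like(t_ms)
        for c_ms, w_ms, f_hz, a in comps:
            if c_ms > t_ms[-1] - 2 * w_ms:  # keep support inside the window
                continue
            dc = rng.uniform(-15.0, 15.0) if jitter else 0.0
            da = np.exp(rng.normal(0.0, 0.2)) if jitter else 1.0
            course += a * da * _gabor(t_ms, c_ms + dc, w_ms, f_hz)
        course *= taper
        amp = 0.0 if name in zero_features else amplitude
        kernels[i] = amp * np.outer(course, topographies[name])
    return KernelSet(kernels=kernels, lag_spec=lag_spec, feature_names=list(feature_names))


def _pink_noise(
    n_channels: int,
    n_samples: int,
    alpha: float,
    rng: np.random.Generator,
    fs: float = 1.0,
    band_hz: tuple[float, float] | None = None,
) -> np.ndarray:
    """Unit-variance 1/f^alpha noise, independent across channels,
    optionally restricted to ``band_hz`` (Hz at sampling rate ``fs``)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    if band_hz is not None:
        lo, hi = band_hz
        scale[(freqs < lo) | (freqs > hi)] = 0.0
        if not np.any(scale > 0):
            raise ValueError("noise band contains no FFT bins")
    spec = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _structured_noise(
    n_channels: int, n_samples: int, spec: NoiseSpec, rng: np.random.Generator, fs: float
) -> np.ndarray:
    """Spatially correlated 1/f^alpha background, unit variance per channel."""
    own = _pink_noise(n_channels, n_samples, spec.alpha, rng, fs, spec.band_hz)
    c = spec.channel_corr
    if c == 0 or spec.n_shared_sources == 0:
        return own
    sources = _pink_noise(spec.n_shared_sources, n_samples, spec.alpha, rng, fs, spec.band_hz)
    mix = rng.standard_normal((n_channels, spec.n_shared_sources))
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)
    shared = mix @ sources
    shared /= shared.std(axis=1, keepdims=True)
    noise = np.sqrt(1.0 - c) * own + np.sqrt(c) * shared
    return noise / noise.std(axis=1, keepdims=True)


def synthesize_recording(
    feature_set: FeatureSet,
    kernels: KernelSet,
    noise_spec: NoiseSpec | None,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "s00",
    channel_names: list[str] | None = None,
) -> Recording:
    """Forward model: recording = sum_f (regressor_f (*) kernel_f) + noise.

    The convolution uses the same per-block zero-padded lagged design
    the estimator builds, so with no noise a ridge fit at vanishing
    penalty recovers the kernels exactly.  Noise is scaled per channel
    so var(signal)/var(noise) equals ``noise_spec.snr`` (channels with
    zero signal get the median signal scale).  ``noise_spec=None``
    yields the noiseless convolution.
    """
    if list(feature_set.names) != list(kernels.feature_names):
        raise ValueError(
            f"feature mismatch: regressors {feature_set.names} vs kernels {kernels.feature_names}"
        )
    n_ch = kernels.kernels.shape[2]
    flat = kernels.kernels.reshape(-1, n_ch)
    sig = np.empty((feature_set.n_samples, n_ch))
    for a, b in feature_set.block_bounds:
        X = build_design(feature_set.data[a:b], kernels.lag_spec, intercept=False)
        sig[a:b] = X @ flat
    data = sig.T.copy()
    if noise_spec is not None:
        rng = np.random.default_rng(seed)
        noise = _structured_noise(n_ch, feature_set.n_samples, noise_spec, rng, feature_set.fs)
        sig_sd = data.std(axis=1)
        ref = np.median(sig_sd[sig_sd > 0]) if np.any(sig_sd > 0) else 1.0
        sig_sd = np.where(sig_sd > 0, sig_sd, ref)
        data = data + noise * (sig_sd / np.sqrt(noise_spec.snr))[:, None]
    return Recording(
        data=data,
        fs=feature_set.fs,
        channel_names=channel_names or default_channel_names(n_ch),
        block_bounds=list(feature_set.block_bounds),
        subject_id=subject_id,
    )


def make_feature_set(
    duration_s: float,
    fs: float,
    block_bounds: list[tuple[int, int]],
    seed: int | np.random.SeedSequence = 0,
    feature_names: list[str] | None = None,
    mean_interval_s: float = 0.32,
    min_interval_s: float = 0.12,
) -> FeatureSet:
    """Generate events + envelope and assemble the requested regressors
    (default: envelope, onset, surprisal, snr_word; RMS-1 normalized)."""
    names = feature_names or ["envelope", "onset", "surprisal", "snr_word"]
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    ev_seed, env_seed = ss.spawn(2)
    n = int(round(duration_s * fs))
    events = gen_word_events(duration_s, mean_interval_s, min_interval_s, seed=ev_seed)
    cols: dict[str, np.ndarray] = {}
    for name in names:
        if name == "envelope":
            raw = gen_dense_envelope(duration_s, fs, seed=env_seed)
            cols[name] = feat.log_envelope(raw, fs)
        elif name == "onset":
            cols[name] = feat.onset_regressor(events, fs, n)
        elif name == "surprisal":
            cols[name] = feat.value_regressor(events, events.surprisal, fs, n)
        elif name == "snr_word":
            cols[name] = feat.value_regressor(events, events.snr_word, fs, n)
        else:
            raise ValueError(f"unknown feature {name!r}")
    window = (-100.0, 800.0) if len(names) > 2 or "surprisal" in names else feat.DENSE_WINDOW_MS
    return assemble_with_bounds(cols, fs, block_bounds, window)


def assemble_with_bounds(cols, fs, block_bounds, window_ms) -> FeatureSet:
    return feat.assemble_model(
        cols, "custom", fs, block_bounds, lag_window_ms=window_ms
    )


def _shift_kernels(K: np.ndarray, shift: int) -> np.ndarray:
    """Shift kernels along the lag axis by ``shift`` samples, zero-filled."""
    if shift == 0:
        return K
    out = np.zeros_like(K)
    if shift > 0:
        out[:, shift:, :] = K[:, :-shift, :]
    else:
        out[:, :shift, :] = K[:, -shift:, :]
    return out


def synthesize_cohort(
    cohort_spec: CohortSpec,
    kernels: KernelSet,
    noise_spec: NoiseSpec | None,
) -> list[tuple[FeatureSet, Recording, KernelSet]]:
    """Generate one (FeatureSet, Recording, subject kernels) per subject.

    Every subject shares the cohort kernels up to a multiplicative
    amplitude scale (log-normal, log-SD ``amp_sd``) and a latency shift
    (uniform +-``latency_jitter_ms``); regressors and noise are drawn
    independently per subject.  Fully reproducible from the master seed.
    """
    ss = np.random.SeedSequence(cohort_spec.seed)
    subjects = []
    block_n = int(round(cohort_spec.block_s * cohort_spec.fs))
    bounds = [(i * block_n, (i + 1) * block_n) for i in range(cohort_spec.n_blocks)]
    duration_s = cohort_spec.n_blocks * cohort_spec.block_s
    per_run = max(1, int(np.ceil(cohort_spec.n_blocks / cohort_spec.n_runs)))
    run_ids = [min(i // per_run, cohort_spec.n_runs - 1) for i in range(cohort_spec.n_blocks)]
    for s, child in enumerate(ss.spawn(cohort_spec.n_subjects)):
        feat_seed, rec_seed, var_seed = child.spawn(3)
        rng = np.random.default_rng(var_seed)
        amp = float(np.exp(rng.normal(0.0, cohort_spec.amp_sd))) if cohort_spec.amp_sd > 0 else 1.0
        jit_ms = (
            rng.uniform(-cohort_spec.latency_jitter_ms, cohort_spec.latency_jitter_ms)
            if cohort_spec.latency_jitter_ms > 0
            else 0.0
        )
        shift = int(round(jit_ms * cohort_spec.fs / 1000.0))
        subj_K = KernelSet(
            kernels=_shift_kernels(amp * kernels.kernels, shift),
            lag_spec=kernels.lag_spec,
            feature_names=list(kernels.feature_names),
        )
        fset = make_feature_set(
            duration_s, cohort_spec.fs, bounds, seed=feat_seed,
            feature_names=list(kernels.feature_names),
        )
        rec = synthesize_recording(
            fset.select(kernels.feature_names),
            subj_K,
            noise_spec,
            seed=rec_seed,
            subject_id=f"s{s:02d}",
            channel_names=default_channel_names(kernels.kernels.shape[2]),
        )
        rec.run_ids = list(run_ids)
        subjects.append((fset, rec, subj_K))
    return subjects
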