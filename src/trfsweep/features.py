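"""Regressor construction for continuous-speech encoding models.

Two stimulus representations are supported, differing in sparseness:

* the *dense* model: a continuously varying log-transformed acoustic
  envelope plus a sparse word-onset impulse train (lag window -100 to
  350 ms);
* the *sparse* model: word-onset impulses plus word-level lexical
  surprisal and word-SNR value regressors sharing the onset timing
  (lag window -100 to 800 ms).

All columns are scaled so the RMS of their non-zero entries is 1, which
keeps the TRF amplitudes of dense and sparse features comparable and
lets a single ridge parameter regularize them jointly.
"""
from __future__ import annotations

import numpy as np
import scipy.signal

from .containers import EventList, FeatureSet, LagSpec

__all__ = [
    "onset_regressor",
    "value_regressor",
    "log_envelope",
    "rms_normalize_nonzero",
    "assemble_model",
    "DENSE_FEATURES",
    "SPARSE_FEATURES",
    "DENSE_WINDOW_MS",
    "SPARSE_WINDOW_MS",
]

DENSE_FEATURES = ["envelope", "onset"]
SPARSE_FEATURES = ["onset", "surprisal", "snr_word"]
DENSE_WINDOW_MS = (-100.0, 350.0)
SPARSE_WINDOW_MS = (-100.0, 800.0)


def _event_samples(event_list: EventList, fs: float, n_samples: int) -> np.ndarray:
    idx = np.round(event_list.onsets * fs).astype(int)
    # an onset within half a sample of the recording end rounds to
    # n_samples; clamp that boundary case to the last valid sample
    idx[idx == n_samples] = n_samples - 1
    if np.any(idx >= n_samples):
        raise ValueError("event onset beyond the end of the recording")
    return idx


def onset_regressor(event_list: EventList, fs: float, n_samples: int) -> np.ndarray:
    """Unit-amplitude impulse train aligned to word onsets.

    Events are mapped to ``round(onset * fs)``; if two events collide on
    one sample the amplitude stays 1.
    """
    col = np.zeros(n_samples)
    col[_event_samples(event_list, fs, n_samples)] = 1.0
    return col


def value_regressor(
    event_list: EventList, values: np.ndarray, fs: float, n_samples: int
) -> np.ndarray:
    """Sparse regressor carrying one value per event at the onset sample.

    Shares the word-onset timing; on a (rare) sample collision the last
    event's value wins.
    """
    values = np.asarray(values, dtype=float)
    if values.size != len(event_list):
        raise ValueError(
            f"{values.size} values for {len(event_list)} events"
        )
    col = np.zeros(n_samples)
    col[_event_samples(event_list, fs, n_samples)] = values
    return col


def log_envelope(
    raw_signal: np.ndarray,
    fs: float,
    cutoff_hz: float = 8.0,
    floor_eps: float | None = None,
) -> np.ndarray:
    """Low-frequency log envelope: rectify -> low-pass -> log.

    The raw signal is half-wave rectified, low-pass filtered below
    ``cutoff_hz`` with a zero-phase 4th-order Butterworth, floored at
    ``floor_eps`` (default ``1e-6 * max``) and log-transformed to
    approximate level encoding in the auditory system.
    """
    x = np.asarray(raw_signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("envelope input contains non-finite samples")
    if fs <= 2 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff")
    rect = np.maximum(x, 0.0)
    sos = scipy.signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    lp = scipy.signal.sosfiltfilt(sos, rect)
    if floor_eps is None:
        peak = lp.max()
        floor_eps = 1e-6 * peak if peak > 0 else 1e-12
    return np.log(np.maximum(lp, floor_eps))


def rms_normalize_nonzero(column: np.ndarray) -> np.ndarray:
    """Scale the non-zero entries of a column to RMS 1; zeros untouched."""
    col = np.asarray(column, dtype=float)
    nz = col != 0
    if not np.any(nz):
        raise ValueError("cannot RMS-normalize an all-zero column")
    rms = np.sqrt(np.mean(col[nz] ** 2))
    out = col.copy()
    out[nz] = col[nz] / rms
    return out


def assemble_model(
    columns: dict[str, np.ndarray],
    model_name: str,
    fs: float,
    block_bounds: list[tuple[int, int]],
    lag_window_ms: tuple[float, float] | None = None,
    normalize: bool = True,
) -> FeatureSet:
    """Stack named regressor columns into a :class:`FeatureSet`.

    ``model_name`` "dense" or "sparse" attaches the corresponding default
    lag window (-100..350 / -100..800 ms); any other name requires an
    explicit ``lag_window_ms``.  A column is flagged sparse when most of
    its samples are exactly zero.
    """
    names = list(columns)
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names")
    lengths = {len(c) for c in columns.values()}
    if len(lengths) != 1:
        raise ValueError("all regressor columns must have equal length")
    if lag_window_ms is None:
        try:
            lag_window_ms = {"dense": DENSE_WINDOW_MS, "sparse": SPARSE_WINDOW_MS}[model_name]
        except KeyError:
            raise ValueError(
                f"unknown model {model_name!r}: pass lag_window_ms explicitly"
            ) from None
    cols = []
    flags = []
    for name in names:
        col = np.asarray(columns[name], dtype=float)
        if normalize:
            col = rms_normalize_nonzero(col)
        cols.append(col)
        flags.append(np.mean(col == 0) > 0.5)
    return FeatureSet(
        data=np.stack(cols, axis=1),
        fs=fs,
        names=names,
        sparse_flags=flags,
        block_bounds=block_bounds,
        lag_spec=LagSpec(lag_window_ms[0], lag_window_ms[1], fs),
    )
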