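"""Synthetic cohort generator: event statistics, envelope spectrum,
ground-truth kernels, the forward convolution and noise scaling."""
import numpy as np
import pytest
import scipy.signal

from trfsweep.containers import CohortSpec, LagSpec, NoiseSpec
from trfsweep.synth import (
    _pink_noise,
    _structured_noise,
    default_topographies,
    gen_dense_envelope,
    gen_ground_truth_kernels,
    gen_word_events,
    make_feature_set,
    synthesize_cohort,
    synthesize_recording,
)

from conftest import make_cohort


def test_word_events_interval_statistics():
    ev = gen_word_events(600.0, seed=0)
    gaps = np.diff(np.concatenate([[0.0], ev.onsets]))
    assert gaps.min() >= 0.12
    assert np.mean(gaps) == pytest.approx(0.32, abs=0.02)  # ~3 words/s
    assert ev.onsets[-1] < 600.0
    assert np.all(np.diff(ev.onsets) > 0)


def test_word_events_covariates_and_determinism():
    a = gen_word_events(60.0, seed=5)
    b = gen_word_events(60.0, seed=5)
    c = gen_word_events(60.0, seed=6)
    assert np.array_equal(a.onsets, b.onsets)
    assert np.array_equal(a.surprisal, b.surprisal)
    assert not np.array_equal(a.onsets, c.onsets)
    assert np.all(a.surprisal > 0)  # log-normal support
    # surprisal is right-skewed: mean above median
    big = gen_word_events(600.0, seed=1)
    assert big.surprisal.mean() > np.median(big.surprisal)
    assert abs(big.snr_word.mean()) < 1.0  # centered near 0 dB


def test_word_events_empty_and_validation():
    assert gen_word_events(0.0).onsets.size == 0
    with pytest.raises(ValueError):
        gen_word_events(10.0, mean_interval_s=0.1, min_interval_s=0.2)


def test_envelope_nonnegative_and_lowpassed():
    fs = 128.0
    env = gen_dense_envelope(120.0, fs, seed=3)
    assert env.min() >= 0.0
    assert env.size == int(120 * fs)
    f, p = scipy.signal.periodogram(env - env.mean(), fs=fs)
    frac_low = p[f <= 8.0].sum() / p.sum()
    assert frac_low >= 0.95  # power concentrated in the analysis band
    assert np.array_equal(env, gen_dense_envelope(120.0, fs, seed=3))


def test_kernels_shape_support_and_zeroing():
    spec = LagSpec(-100.0, 350.0, 128.0)
    names = ["envelope", "onset"]
    topo = default_topographies(names, 6)
    K = gen_ground_truth_kernels(spec, names, topo, seed=0)
    assert K.kernels.shape == (2, spec.n_lags, 6)
    # edge taper: kernels vanish at both lag-window edges (to within the
    # taper's sin(pi)**0.25 ~ 1e-4 numerical residue)
    peak = np.abs(K.kernels).max()
    assert peak > 0.1
    assert np.abs(K.kernels[:, 0, :]).max() < 1e-3 * peak
    assert np.abs(K.kernels[:, -1, :]).max() < 1e-3 * peak
    Kz = gen_ground_truth_kernels(spec, names, topo, seed=0, zero_features=("onset",))
    assert np.allclose(Kz.kernels[1], 0.0)
    assert np.abs(Kz.kernels[0]).max() > 0.1


def test_kernels_seed_jitter_and_late_deflection():
    spec = LagSpec(-100.0, 800.0, 128.0)
    names = ["onset", "surprisal"]
    topo = default_topographies(names, 4)
    a = gen_ground_truth_kernels(spec, names, topo, seed=1)
    b = gen_ground_truth_kernels(spec, names, topo, seed=1)
    c = gen_ground_truth_kernels(spec, names, topo, seed=2)
    assert np.array_equal(a.kernels, b.kernels)
    assert not np.array_equal(a.kernels, c.kernels)
    # word-level feature carries energy in the late (>300 ms) window
    t_ms = spec.lag_times_ms
    late = np.abs(a.kernels[1][t_ms > 300.0]).max()
    assert late > 0.1


def test_pink_noise_band_restriction_and_variance():
    rng = np.random.default_rng(0)
    fs = 128.0
    x = _pink_noise(3, 8192, 1.0, rng, fs=fs, band_hz=(1.0, 8.0))
    assert np.allclose(x.std(axis=1), 1.0, atol=1e-9)
    f, p = scipy.signal.periodogram(x, fs=fs, axis=1)
    out_band = (f < 0.9) | (f > 8.2)
    assert p[:, out_band].sum() / p.sum() < 1e-3
    # broadband 1/f: more power below 4 Hz than above 32 Hz
    y = _pink_noise(1, 8192, 1.0, rng, fs=fs)
    f, p = scipy.signal.periodogram(y[0], fs=fs)
    assert p[(f > 0) & (f < 4)].sum() > 4 * p[f > 32].sum()


def test_structured_noise_channel_correlation():
    fs = 128.0
    spec_hi = NoiseSpec(snr=1.0, channel_corr=0.9)
    spec_lo = NoiseSpec(snr=1.0, channel_corr=0.0)

    def mean_abs_offdiag(spec):
        rng = np.random.default_rng(7)
        x = _structured_noise(8, 16384, spec, rng, fs)
        c = np.corrcoef(x)
        return np.abs(c[~np.eye(8, dtype=bool)]).mean()

    # random 8-source mixing caps pairwise correlation well below the
    # shared-variance fraction; a wide gap over the independent case is
    # the invariant worth pinning
    assert mean_abs_offdiag(spec_hi) > mean_abs_offdiag(spec_lo) + 0.15


def test_recording_matches_convolution_oracle():
    """Noiseless forward model equals an independent np.convolve oracle:
    y[t] = sum_f sum_l K[f,l,ch] x_f[t-l], zero-padded per block."""
    fs = 64.0
    names = ["envelope", "onset"]
    fset = make_feature_set(8.0, fs, [(0, 256), (256, 512)], seed=4, feature_names=names)
    spec = fset.lag_spec  # dense window (-100, 350) ms at 64 Hz
    topo = default_topographies(names, 3)
    K = gen_ground_truth_kernels(spec, names, topo, seed=2)
    rec = synthesize_recording(fset, K, None, seed=0)
    lmin = spec.lags[0]
    for a, b in fset.block_bounds:
        n = b - a
        for ch in range(3):
            y = np.zeros(n)
            for fi in range(2):
                full = np.convolve(fset.data[a:b, fi], K.kernels[fi, :, ch])
                idx = np.arange(n) - lmin
                y += full[idx]
            assert np.allclose(rec.data[ch, a:b], y, atol=1e-10)


def test_recording_snr_scaling_and_noise_band():
    fs = 128.0
    spec = LagSpec(-100.0, 350.0, fs)
    names = ["envelope", "onset"]
    topo = default_topographies(names, 4)
    K = gen_ground_truth_kernels(spec, names, topo, seed=0)
    bounds = [(0, 7680), (7680, 15360)]
    fset = make_feature_set(120.0, fs, bounds, seed=1, feature_names=names)
    clean = synthesize_recording(fset, K, None, seed=9)
    noisy = synthesize_recording(fset, K, NoiseSpec(snr=0.25), seed=9)
    noise = noisy.data - clean.data
    ratio = clean.data.var(axis=1) / noise.var(axis=1)
    assert np.allclose(ratio, 0.25, rtol=0.05)
    # default noise is confined to the 1-8 Hz analysis band
    f, p = scipy.signal.periodogram(noise, fs=fs, axis=1)
    assert p[:, (f < 0.9) | (f > 8.2)].sum() / p.sum() < 1e-3


def test_recording_zero_kernels_pure_noise():
    fs = 128.0
    spec = LagSpec(-100.0, 350.0, fs)
    names = ["envelope", "onset"]
    topo = default_topographies(names, 3)
    K = gen_ground_truth_kernels(spec, names, topo, seed=0, amplitude=0.0)
    fset = make_feature_set(60.0, fs, [(0, 7680)], seed=1, feature_names=names)
    assert np.allclose(synthesize_recording(fset, K, None, seed=0).data, 0.0)
    noisy = synthesize_recording(fset, K, NoiseSpec(snr=1.0), seed=0)
    assert noisy.data.std() > 0  # median fallback keeps noise finite


def test_recording_feature_name_mismatch():
    fs = 64.0
    spec = LagSpec(0.0, 100.0, fs)
    K = gen_ground_truth_kernels(spec, ["onset"], default_topographies(["onset"], 2))
    fset = make_feature_set(4.0, fs, [(0, 256)], feature_names=["envelope", "onset"])
    with pytest.raises(ValueError, match="mismatch"):
        synthesize_recording(fset, K, NoiseSpec(snr=1.0))


def test_cohort_structure_determinism_and_variability():
    (cohort_a, K) = make_cohort(n_subjects=3, minutes=2, seed=42)
    (cohort_b, _) = make_cohort(n_subjects=3, minutes=2, seed=42)
    assert len(cohort_a) == 3
    for (fa, ra, ka), (fb, rb, kb) in zip(cohort_a, cohort_b):
        assert np.array_equal(ra.data, rb.data)
        assert np.array_equal(fa.data, fb.data)
        assert np.array_equal(ka.kernels, kb.kernels)
    # subjects differ in regressors, data and kernel scaling/latency
    f0, r0, k0 = cohort_a[0]
    f1, r1, k1 = cohort_a[1]
    assert not np.array_equal(f0.data, f1.data)
    assert not np.array_equal(r0.data, r1.data)
    assert not np.array_equal(k0.kernels, k1.kernels)
    # subject kernels are amplitude/latency variants of the cohort kernels
    assert k0.kernels.shape == K.kernels.shape
    assert r0.subject_id == "s00" and r1.subject_id == "s01"
    assert len(r0.block_bounds) == 2  # 2 minutes -> 2 x 60 s blocks


def test_cohort_run_assignment():
    spec = CohortSpec(n_subjects=2, minutes=4, channels=3, fs=64.0, n_runs=2, seed=0)
    names = ["envelope", "onset"]
    K = gen_ground_truth_kernels(
        LagSpec(-100.0, 350.0, 64.0), names, default_topographies(names, 3), seed=0
    )
    cohort = synthesize_cohort(spec, K, None)
    _, rec, _ = cohort[0]
    assert rec.run_ids == [0, 0, 1, 1]


def test_cohort_no_variability_flags():
    (cohort, K) = make_cohort(n_subjects=2, minutes=2, amp_sd=0.0, jitter_ms=0.0, seed=3)
    for _, _, subj_K in cohort:
        assert np.array_equal(subj_K.kernels, K.kernels)
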