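import numpy as np
import pytest

from trfsweep.containers import CohortSpec, LagSpec, NoiseSpec
from trfsweep import synth


@pytest.fixture(scope="session")
def small_lag() -> LagSpec:
    # -100..350 ms at 128 Hz: 59 lags, cheap but realistic
    return LagSpec(-100.0, 350.0, 128.0)


def make_cohort(
    n_subjects=3,
    minutes=4,
    channels=6,
    fs=128.0,
    snr=0.2,
    seed=0,
    feature_names=("envelope", "onset"),
    lag=None,
    zero_features=(),
    noiseless=False,
    amp_sd=0.2,
    jitter_ms=10.0,
):
    """Small synthetic cohort used across the suite."""
    lag = lag or LagSpec(-100.0, 350.0, fs)
    spec = CohortSpec(
        n_subjects=n_subjects,
        minutes=minutes,
        channels=channels,
        fs=fs,
        n_runs=1,
        amp_sd=amp_sd,
        latency_jitter_ms=jitter_ms,
        seed=seed,
    )
    topo = synth.default_topographies(list(feature_names), channels)
    kernels = synth.gen_ground_truth_kernels(
        lag, list(feature_names), topo, seed=seed + 7919, zero_features=zero_features
    )
    noise = None if noiseless else NoiseSpec(snr=snr)
    return synth.synthesize_cohort(spec, kernels, noise), kernels


@pytest.fixture(scope="session")
def tiny_cohort():
    return make_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
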