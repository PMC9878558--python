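"""Statistical layer: significance of accuracies, minimum-data power
analysis, slope bootstraps and TRF similarity.

Prediction accuracies (Pearson r) are Fisher z-transformed (atanh)
before parametric testing.  The test family is gated by an
Anderson-Darling normality test: a one-sample t-test when normality is
not rejected, a Wilcoxon signed-rank test otherwise.  No
multiple-comparison correction is applied anywhere; each data quantity
is treated as a quasi-independent experiment (the correction-free
choice is recorded in output metadata).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .containers import TRFModel
from .trf import pearson_accuracy

__all__ = [
    "TestResult",
    "test_vs_zero",
    "PowerAnalysisResult",
    "min_data_power",
    "SlopeBootstrapResult",
    "slope_bootstrap",
    "trf_similarity",
    "fisher_z",
]

NOT_ACHIEVABLE = -1  # sentinel: no grid quantity met the power criterion


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh transform; |r| = 1 is rejected (infinite z)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| >= 1 cannot be Fisher z-transformed")
    return np.arctanh(r)


@dataclass
class TestResult:
    family: str  # "t" or "wilcoxon"
    statistic: float
    pvalue: float
    n: int
    normality_p: float


def _anderson_pvalue_gate(z: np.ndarray, alpha: float = 0.05) -> tuple[bool, float]:
    """Anderson-Darling normality gate.  Returns (is_normal, approx p).

    The p-value is interpolated from the tabulated critical values
    (saturating at the table's 0.15/0.01 ends), which is exact enough
    for a gate at conventional levels.
    """
    res = scipy.stats.anderson(z, dist="norm", method="interpolate")
    p = float(res.pvalue)
    return p > alpha, p


def test_vs_zero(accuracies: np.ndarray, gate_alpha: float = 0.05) -> TestResult:
    """Is the mean accuracy different from zero?

    Fisher z-transforms the correlations, gates on Anderson-Darling
    normality at ``gate_alpha`` and applies either a one-sample t-test
    or a Wilcoxon signed-rank test (both two-sided).
    """
    z = fisher_z(accuracies)
    if z.size < 3:
        raise ValueError("need >= 3 accuracies")
    if np.allclose(z, z[0]):
        raise ValueError("zero-variance sample: test statistic undefined")
    is_normal, norm_p = _anderson_pvalue_gate(z, gate_alpha)
    if is_normal:
        stat, p = scipy.stats.ttest_1samp(z, 0.0)
        family = "t"
    else:
        stat, p = scipy.stats.wilcoxon(z)
        family = "wilcoxon"
    return TestResult(
        family=family, statistic=float(stat), pvalue=float(p), n=int(z.size),
        normality_p=norm_p,
    )


@dataclass
class PowerAnalysisResult:
    """Minimum minutes-per-subject meeting the power criterion.

    ``min_minutes`` is a (pool size x alpha) table; the sentinel -1
    marks cells where no grid quantity reached the criterion.
    ``fractions`` holds the full (pool size x quantity x alpha)
    exceedance fractions.
    """

    min_minutes: pd.DataFrame
    fractions: np.ndarray
    pool_sizes: list[int]
    quantities: list[float]
    alphas: list[float]
    criterion: float
    n_boot: int
    meta: dict = field(default_factory=dict)


def min_data_power(
    accuracy_table: pd.DataFrame,
    pool_sizes=range(2, 42),
    alphas=(0.05, 0.01, 0.001),
    n_boot: int = 10_000,
    criterion: float = 0.8,
    seed: int = 0,
    two_sided: bool = True,
) -> PowerAnalysisResult:
    """Bootstrap power analysis over subject pool size and data quantity.

    ``accuracy_table`` is subjects x quantities (columns = minutes of
    data per subject).  For each pool size n, ``n_boot`` resamples of n
    subjects are drawn with replacement (one index draw per bootstrap,
    shared across quantities); a one-sample t statistic on the Fisher-z
    accuracies is compared against the t threshold for each alpha
    (``t > t_{1 - alpha/2, n-1}`` when ``two_sided``), and the minimum
    quantity is the smallest grid value whose exceedance fraction
    reaches ``criterion``.  Zero-variance draws count as
    non-significant.

    Reproducibility contract: a single ``default_rng(seed)`` stream is
    consumed by calling ``rng.integers(0, n_subjects, size=(n_boot,
    n))`` once per pool size, in the order the pool sizes are given.
    """
    pool_sizes = [int(n) for n in pool_sizes]
    if min(pool_sizes) < 2:
        raise ValueError("pool sizes must be >= 2")
    Z = fisher_z(accuracy_table.to_numpy(dtype=float))
    n_subj, n_q = Z.shape
    quantities = [float(c) for c in accuracy_table.columns]
    rng = np.random.default_rng(seed)
    fractions = np.zeros((len(pool_sizes), n_q, len(alphas)))
    for pi, n in enumerate(pool_sizes):
        idx = rng.integers(0, n_subj, size=(n_boot, n))
        samp = Z[idx]  # n_boot x n x n_q
        mean = samp.mean(axis=1)
        sd = samp.std(axis=1, ddof=1)
        # a draw of identical values yields sd ~ |mean| * eps (round-off
        # in the mean), not exactly 0; the relative threshold keeps such
        # degenerate draws non-significant
        degenerate = sd <= 1e-9 * np.maximum(1.0, np.abs(mean))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(~degenerate, mean / (sd / np.sqrt(n)), -np.inf)
        for ai, alpha in enumerate(alphas):
            q = 1 - alpha / 2 if two_sided else 1 - alpha
            thr = scipy.stats.t.ppf(q, df=n - 1)
            fractions[pi, :, ai] = np.mean(t > thr, axis=0)
    min_minutes = np.full((len(pool_sizes), len(alphas)), float(NOT_ACHIEVABLE))
    for pi in range(len(pool_sizes)):
        for ai in range(len(alphas)):
            ok = np.nonzero(fractions[pi, :, ai] >= criterion)[0]
            if ok.size:
                min_minutes[pi, ai] = quantities[ok[0]]
    return PowerAnalysisResult(
        min_minutes=pd.DataFrame(
            min_minutes, index=pool_sizes, columns=[str(a) for a in alphas]
        ),
        fractions=fractions,
        pool_sizes=pool_sizes,
        quantities=quantities,
        alphas=list(alphas),
        criterion=criterion,
        n_boot=n_boot,
        meta={"seed": seed, "two_sided": two_sided, "mc_correction": "none"},
    )


@dataclass
class SlopeBootstrapResult:
    slopes: np.ndarray
    fraction_positive: float
    significant: bool
    threshold: float


def slope_bootstrap(
    results_by_count: dict[int, np.ndarray],
    n_iter: int = 1000,
    threshold: float = 0.95,
    seed: int = 0,
) -> SlopeBootstrapResult:
    """Bootstrap test for a positive accuracy-vs-subject-count trend.

    Each iteration picks one result at random from the pool at every
    count and fits a two-parameter line (slope, intercept) by ordinary
    least squares; the trend is significant when more than
    ``threshold`` of the ``n_iter`` slopes are positive.
    """
    counts = sorted(results_by_count)
    if len(counts) < 2:
        raise ValueError("need >= 2 counts to fit a slope")
    pools = [np.atleast_1d(np.asarray(results_by_count[c], dtype=float)) for c in counts]
    if any(p.size == 0 for p in pools):
        raise ValueError("every count needs >= 1 result")
    rng = np.random.default_rng(seed)
    x = np.asarray(counts, dtype=float)
    slopes = np.empty(n_iter)
    for i in range(n_iter):
        y = np.array([p[rng.integers(0, p.size)] for p in pools])
        slopes[i] = np.polyfit(x, y, 1)[0]
    frac = float(np.mean(slopes > 0))
    return SlopeBootstrapResult(
        slopes=slopes,
        fraction_positive=frac,
        significant=frac > threshold,
        threshold=threshold,
    )


def trf_similarity(
    trf_a: TRFModel | np.ndarray,
    trf_b: TRFModel | np.ndarray,
    fs: float | None = None,
    trim_ms: float = 25.0,
) -> float:
    """Pearson correlation between two TRF time courses.

    ``floor(trim_ms * fs / 1000)`` samples are trimmed from each end of
    the lag axis before correlating (edge artifacts concentrate there),
    then the retained (features x lags x channels) coefficients are
    flattened.  Accepts fitted models or raw coefficient arrays
    (features x lags x channels; pass ``fs`` for arrays).
    """
    if isinstance(trf_a, TRFModel):
        if isinstance(trf_b, TRFModel) and (
            trf_a.lag_spec != trf_b.lag_spec
        ):
            raise ValueError("lag specifications differ")
        fs = trf_a.lag_spec.fs
        a = trf_a.beta
        b = trf_b.beta if isinstance(trf_b, TRFModel) else np.asarray(trf_b)
    else:
        a = np.asarray(trf_a)
        b = trf_b.beta if isinstance(trf_b, TRFModel) else np.asarray(trf_b)
        if fs is None:
            raise ValueError("fs required when passing raw arrays")
    if a.shape != b.shape:
        raise ValueError(f"TRF shapes differ: {a.shape} vs {b.shape}")
    trim = int(np.floor(trim_ms * fs / 1000.0))
    if 2 * trim >= a.shape[1]:
        raise ValueError("trim removes the entire lag axis")
    sl = slice(trim, a.shape[1] - trim) if trim else slice(None)
    return float(pearson_accuracy(a[:, sl, :].ravel(), b[:, sl, :].ravel()))
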