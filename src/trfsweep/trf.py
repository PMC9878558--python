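"""Lagged-design ridge regression: the TRF estimation engine.

A temporal response function (TRF) models a neural channel as a linear
convolution of stimulus feature time courses with per-feature impulse
responses.  Estimation regresses time-lagged copies of each feature
against the response; ridge regularization (penalty ``lam`` on all
coefficients except the intercept) controls the variance of the
estimate.

Two computational paths are provided and tested against each other:

* explicit design matrices (:func:`build_design`, :func:`ridge_solve`) —
  the reference path, simple and transparent;
* accumulated second-moment statistics (:class:`Moments`) — per-block
  Gram matrices that can be summed, sliced by feature and re-solved for
  many ridge parameters at once via a single eigendecomposition.  This
  is what makes nested leave-one-out cross-validation affordable.

Lag convention: for integer lag ``l`` the design column holds
``x[t - l]``, so positive lags describe the response *following* the
stimulus and negative lags the acausal window before it.  Lagged copies
are zero-padded at block edges and blocks are never concatenated, so no
structure leaks across block boundaries.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .containers import FeatureSet, LagSpec, TRFModel

__all__ = [
    "lag_indices",
    "build_design",
    "ridge_solve",
    "fit_ridge",
    "predict",
    "pearson_accuracy",
    "Moments",
    "ridge_from_moments",
    "accuracy_from_moments",
]


def lag_indices(tmin_ms: float, tmax_ms: float, fs: float) -> np.ndarray:
    """Inclusive integer lag range ``floor(tmin_s*fs) .. ceil(tmax_s*fs)``.

    At 256 Hz, (-100, 350) gives 117 lags and (-100, 800) gives 232.
    """
    return LagSpec(tmin_ms, tmax_ms, fs).lags


def _lagged_columns(x: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """time x lags matrix of zero-padded shifted copies of 1-D ``x``."""
    n = x.shape[0]
    out = np.zeros((n, lags.size))
    for k, l in enumerate(lags):
        if l >= 0:
            out[l:, k] = x[: n - l] if l < n else 0.0
        else:
            out[: n + l, k] = x[-l:]
    return out


def build_design(
    feature_matrix: np.ndarray, lag_spec: LagSpec, intercept: bool = True
) -> np.ndarray:
    """Lagged design matrix for one contiguous block.

    Columns are ordered feature-major, lag-minor (all lags of feature 0,
    then feature 1, ...), preceded by a constant column when
    ``intercept`` is set.  Samples shifted past the block edge are
    zero-padded.
    """
    F = np.atleast_2d(np.asarray(feature_matrix, dtype=float))
    if F.ndim != 2 or F.shape[1] == 0:
        raise ValueError("feature matrix must be 2-D with >= 1 feature column")
    if F.shape[0] < lag_spec.n_lags:
        raise ValueError("block shorter than the lag window")
    lags = lag_spec.lags
    cols = [_lagged_columns(F[:, j], lags) for j in range(F.shape[1])]
    X = np.concatenate(cols, axis=1)
    if intercept:
        X = np.concatenate([np.ones((F.shape[0], 1)), X], axis=1)
    return X


def ridge_solve(
    X: np.ndarray, Y: np.ndarray, lam: float, fit_intercept: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form ridge solution via the normal equations.

    Minimizes ``||Y - X beta - c||^2 + lam ||beta||^2`` with the
    intercept ``c`` unpenalized (implemented by centering, which is
    algebraically identical).  Returns ``(beta, intercept)`` where
    ``beta`` is coefficients x channels.
    """
    if lam < 0:
        raise ValueError("ridge parameter must be >= 0")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    y1d = Y.ndim == 1
    Y = Y.reshape(Y.shape[0], -1)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("design and response row counts differ")
    if fit_intercept:
        mx, my = X.mean(axis=0), Y.mean(axis=0)
        Xc, Yc = X - mx, Y - my
    else:
        mx = my = None
        Xc, Yc = X, Y
    A = Xc.T @ Xc + lam * np.eye(X.shape[1])
    b = Xc.T @ Yc
    try:
        beta = scipy.linalg.solve(A, b, assume_a="sym")
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as err:
        raise np.linalg.LinAlgError(
            "normal equations are singular; use lam > 0 to regularize"
        ) from err
    if not np.all(np.isfinite(beta)):
        raise np.linalg.LinAlgError(
            "normal equations are numerically singular; use lam > 0 to regularize"
        )
    if fit_intercept:
        c = my - mx @ beta
    else:
        c = np.zeros(Y.shape[1])
    if y1d:
        beta, c = beta[:, 0], c
    return beta, c


def fit_ridge(
    feature_set: FeatureSet,
    response_blocks: list[np.ndarray] | np.ndarray,
    lam: float,
    lag_spec: LagSpec | None = None,
) -> TRFModel:
    """Fit a TRF to one unit of data (blocks handled independently).

    ``response_blocks`` is either a single time x channels array (one
    block) or one array per block of the feature set.  The design is
    built per block and the normal equations are accumulated, which is
    exactly equivalent to fitting the stacked per-block designs.
    """
    lag_spec = lag_spec or feature_set.lag_spec
    if lag_spec is None:
        raise ValueError("a lag specification is required")
    if isinstance(response_blocks, np.ndarray):
        response_blocks = [response_blocks]
    F_blocks = [feature_set.data[a:b] for a, b in feature_set.block_bounds]
    if len(F_blocks) != len(response_blocks):
        raise ValueError("one response block per feature block required")
    m = Moments.from_blocks(F_blocks, response_blocks, lag_spec)
    betas, intercepts = ridge_from_moments(m, [lam])
    beta = betas[0].reshape(feature_set.n_features, lag_spec.n_lags, -1)
    return TRFModel(
        beta=beta,
        intercept=intercepts[0],
        lam=lam,
        lag_spec=lag_spec,
        feature_names=list(feature_set.names),
        meta={"n_train_samples": int(m.n)},
    )


def predict(model: TRFModel, feature_set: FeatureSet) -> np.ndarray:
    """Predicted response, time x channels, blocks handled independently."""
    if list(feature_set.names) != list(model.feature_names):
        raise ValueError(
            f"feature mismatch: model {model.feature_names} vs data {feature_set.names}"
        )
    flat = model.beta.reshape(-1, model.n_channels)
    out = np.empty((feature_set.n_samples, model.n_channels))
    for a, b in feature_set.block_bounds:
        X = build_design(feature_set.data[a:b], model.lag_spec, intercept=False)
        out[a:b] = X @ flat + model.intercept
    return out


def pearson_accuracy(predicted: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Per-channel Pearson correlation between prediction and data.

    Constant series yield r = 0 with a warning rather than NaN, so that
    degenerate folds stay finite and auditable.
    """
    P = np.asarray(predicted, dtype=float)
    A = np.asarray(actual, dtype=float)
    if P.shape != A.shape:
        raise ValueError("predicted and actual shapes differ")
    one_d = P.ndim == 1
    P = P.reshape(P.shape[0], -1)
    A = A.reshape(A.shape[0], -1)
    if P.shape[0] < 3:
        raise ValueError("need >= 3 samples for a correlation")
    Pc = P - P.mean(axis=0)
    Ac = A - A.mean(axis=0)
    num = np.einsum("tc,tc->c", Pc, Ac)
    den = np.sqrt(np.einsum("tc,tc->c", Pc, Pc) * np.einsum("tc,tc->c", Ac, Ac))
    r = np.zeros(P.shape[1])
    ok = den > 0
    if not np.all(ok):
        warnings.warn("constant series in correlation; returning r = 0", RuntimeWarning)
    r[ok] = num[ok] / den[ok]
    return float(r[0]) if one_d else r


# ---------------------------------------------------------------------------
# Second-moment machinery


@dataclass
class Moments:
    """Accumulated sufficient statistics of a lagged regression problem.

    Stores, for the intercept-free design ``X`` (p columns) and response
    ``Y`` (c channels): ``sxx = X'X``, ``sxy = X'Y``, the column sums
    ``sx``, ``sy``, the per-channel sum of squares ``syy`` and the
    sample count ``n``.  Moments of disjoint data add; ridge fits,
    predictions' correlation with the data and feature sub-models can
    all be computed from them without revisiting the raw samples.
    """

    sxx: np.ndarray
    sxy: np.ndarray
    sx: np.ndarray
    sy: np.ndarray
    syy: np.ndarray
    n: int
    n_lags: int

    @staticmethod
    def from_blocks(
        F_blocks: list[np.ndarray], Y_blocks: list[np.ndarray], lag_spec: LagSpec
    ) -> "Moments":
        first = True
        for F, Y in zip(F_blocks, Y_blocks, strict=True):
            X = build_design(F, lag_spec, intercept=False)
            Y = np.asarray(Y, dtype=float)
            if Y.shape[0] != X.shape[0]:
                raise ValueError("feature and response block lengths differ")
            if first:
                m = Moments(
                    sxx=X.T @ X,
                    sxy=X.T @ Y,
                    sx=X.sum(axis=0),
                    sy=Y.sum(axis=0),
                    syy=np.einsum("tc,tc->c", Y, Y),
                    n=X.shape[0],
                    n_lags=lag_spec.n_lags,
                )
                first = False
            else:
                m = m + Moments(
                    sxx=X.T @ X,
                    sxy=X.T @ Y,
                    sx=X.sum(axis=0),
                    sy=Y.sum(axis=0),
                    syy=np.einsum("tc,tc->c", Y, Y),
                    n=X.shape[0],
                    n_lags=lag_spec.n_lags,
                )
        if first:
            raise ValueError("no blocks given")
        return m

    def __add__(self, other: "Moments") -> "Moments":
        if self.n_lags != other.n_lags or self.sxx.shape != other.sxx.shape:
            raise ValueError("moment shapes differ")
        return Moments(
            sxx=self.sxx + other.sxx,
            sxy=self.sxy + other.sxy,
            sx=self.sx + other.sx,
            sy=self.sy + other.sy,
            syy=self.syy + other.syy,
            n=self.n + other.n,
            n_lags=self.n_lags,
        )

    @staticmethod
    def sum(moments: list["Moments"]) -> "Moments":
        total = moments[0]
        for m in moments[1:]:
            total = total + m
        return total

    def select_features(self, feature_idx: list[int]) -> "Moments":
        """Moments of the sub-design keeping only the given features.

        Valid because dropping feature columns of the design simply
        drops the corresponding rows/columns of the Gram matrices.
        """
        cols = np.concatenate(
            [np.arange(j * self.n_lags, (j + 1) * self.n_lags) for j in feature_idx]
        )
        return Moments(
            sxx=self.sxx[np.ix_(cols, cols)],
            sxy=self.sxy[cols],
            sx=self.sx[cols],
            sy=self.sy,
            syy=self.syy,
            n=self.n,
            n_lags=self.n_lags,
        )


def ridge_from_moments(
    m: Moments, lams: list[float] | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge solutions for every ``lam`` from one eigendecomposition.

    Centers the moments (unpenalized intercept), eigendecomposes the
    centered Gram matrix once and rescales in the eigenbasis per ridge
    parameter.  Returns ``(betas, intercepts)`` with shapes
    (n_lams, p, channels) and (n_lams, channels).
    """
    mx = m.sx / m.n
    my = m.sy / m.n
    A = m.sxx - m.n * np.outer(mx, mx)
    B = m.sxy - m.n * np.outer(mx, my)
    w, V = np.linalg.eigh(A)
    w = np.maximum(w, 0.0)  # clip tiny negative rounding of a PSD matrix
    Bt = V.T @ B
    betas = np.empty((len(lams), A.shape[0], B.shape[1]))
    intercepts = np.empty((len(lams), B.shape[1]))
    for i, lam in enumerate(lams):
        if lam < 0:
            raise ValueError("ridge parameter must be >= 0")
        denom = w + lam
        if np.any(denom <= 0):
            raise np.linalg.LinAlgError(
                "singular system at lam = 0; use lam > 0 to regularize"
            )
        betas[i] = V @ (Bt / denom[:, None])
        intercepts[i] = my - betas[i].T @ mx
    return betas, intercepts


def accuracy_from_moments(
    beta: np.ndarray, intercept: np.ndarray, m_val: Moments
) -> np.ndarray:
    """Per-channel Pearson r of the model's prediction on held-out data,
    computed from the held-out unit's moments only.

    Exactly equals correlating the concatenated per-block predictions
    with the data (verified in the test suite against the array path).
    """
    n = m_val.n
    sp = beta.T @ m_val.sx + n * intercept  # sum of predictions, per channel
    spy = np.einsum("pc,pc->c", beta, m_val.sxy) + intercept * m_val.sy
    M = m_val.sxx @ beta
    spp = (
        np.einsum("pc,pc->c", beta, M)
        + 2.0 * intercept * (beta.T @ m_val.sx)
        + n * intercept**2
    )
    cov = spy - sp * m_val.sy / n
    var_p = spp - sp**2 / n
    var_y = m_val.syy - m_val.sy**2 / n
    den = np.sqrt(np.maximum(var_p, 0.0) * np.maximum(var_y, 0.0))
    r = np.zeros_like(cov)
    ok = den > 0
    r[ok] = cov[ok] / den[ok]
    return np.clip(r, -1.0, 1.0)
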