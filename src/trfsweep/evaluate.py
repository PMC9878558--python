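"""Cross-validation, regularization selection, feature contributions
and mismatched-pairing noise floors.

The unit of cross-validation is either a trial (one 60-s block, for
subject-specific analyses) or a subject (all of their blocks, for
generic pooled analyses).  Leave-one-unit-out folds nest a second
leave-one-out loop over the *training* units only to select the ridge
parameter, so the held-out unit never influences training or
regularization.

Feature-specific model contributions are prediction-accuracy
differences between a full model and a reduced model with one feature
excluded, evaluated on identical folds.  Noise floors are built by
pairing each held-out 1-min data segment with every *other* segment's
regressors; the mean mismatched accuracy estimates what the raw
accuracy would be by chance and is subtracted from it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import (
    AccuracyRecord,
    CVResult,
    FeatureSet,
    FoldResult,
    LagSpec,
    Recording,
    TRFModel,
)
from .trf import (
    Moments,
    accuracy_from_moments,
    build_design,
    pearson_accuracy,
    ridge_from_moments,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "Unit",
    "units_from_blocks",
    "unit_from_subject",
    "select_lambda",
    "loo_crossval",
    "feature_contribution",
    "noise_floor",
    "attach_noise_floor",
    "attach_trial_noise_floor",
    "NoiseFloorResult",
    "ContributionRecord",
]

# decade grid spanning under- to over-regularization for z-scored data
# with RMS-1 regressors
DEFAULT_LAMBDA_GRID = tuple(10.0 ** np.arange(-2, 9))


@dataclass
class Unit:
    """One cross-validation unit: a list of (features, response) blocks."""

    unit_id: str
    blocks: list[tuple[np.ndarray, np.ndarray]]  # (time x feat, time x ch)
    feature_names: list[str]

    def moments(self, lag_spec: LagSpec) -> Moments:
        return Moments.from_blocks(
            [F for F, _ in self.blocks], [Y for _, Y in self.blocks], lag_spec
        )


def units_from_blocks(
    feature_set: FeatureSet, recording: Recording, block_indices: list[int] | None = None
) -> list[Unit]:
    """One unit per block (trial-level CV within a subject)."""
    idx = block_indices if block_indices is not None else range(len(feature_set.block_bounds))
    units = []
    for i in idx:
        a, b = feature_set.block_bounds[i]
        units.append(
            Unit(
                unit_id=f"{recording.subject_id}/b{i:02d}",
                blocks=[(feature_set.data[a:b], recording.data[:, a:b].T)],
                feature_names=list(feature_set.names),
            )
        )
    return units


def unit_from_subject(
    feature_set: FeatureSet,
    recording: Recording,
    block_indices: list[int] | None = None,
    unit_id: str | None = None,
) -> Unit:
    """One unit holding all (or the given) blocks of a subject."""
    idx = block_indices if block_indices is not None else range(len(feature_set.block_bounds))
    blocks = []
    for i in idx:
        a, b = feature_set.block_bounds[i]
        blocks.append((feature_set.data[a:b], recording.data[:, a:b].T))
    return Unit(
        unit_id=unit_id or recording.subject_id,
        blocks=blocks,
        feature_names=list(feature_set.names),
    )


def _check_grid(grid) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.size == 0:
        raise ValueError("empty ridge-parameter grid")
    if np.any(np.diff(g) <= 0):
        raise ValueError("ridge-parameter grid must be strictly ascending")
    return g


def _select_lambda_moments(train_moments: list[Moments], grid: np.ndarray) -> float:
    """Inner leave-one-out over training units; mean r over folds and
    channels per grid value; ties resolved toward the smallest value
    (ascending grid + first argmax)."""
    if len(train_moments) < 2:
        raise ValueError("ridge selection needs >= 2 training units")
    total = Moments.sum(train_moments)
    mean_r = np.zeros(grid.size)
    for m_val in train_moments:
        m_train = total + _neg(m_val)
        betas, intercepts = ridge_from_moments(m_train, grid)
        for i in range(grid.size):
            mean_r[i] += float(np.mean(accuracy_from_moments(betas[i], intercepts[i], m_val)))
    mean_r /= len(train_moments)
    return float(grid[int(np.argmax(mean_r))])


def _neg(m: Moments) -> Moments:
    return Moments(
        sxx=-m.sxx, sxy=-m.sxy, sx=-m.sx, sy=-m.sy, syy=-m.syy, n=-m.n, n_lags=m.n_lags
    )


def select_lambda(
    training_units: list[Unit], lag_spec: LagSpec, grid=DEFAULT_LAMBDA_GRID
) -> float:
    """Ridge parameter maximizing mean inner-CV accuracy on the training
    units only (the held-out test unit is never seen here)."""
    g = _check_grid(grid)
    if g.size == 1:
        return float(g[0])
    return _select_lambda_moments([u.moments(lag_spec) for u in training_units], g)


@dataclass
class SkippedFold:
    unit_id: str
    reason: str


def _constant_channels(m: Moments) -> bool:
    var = m.syy - m.sy**2 / m.n
    return bool(np.all(var <= 1e-12 * max(1.0, float(np.max(np.abs(m.syy))))))


def loo_crossval(
    units: list[Unit],
    lag_spec: LagSpec,
    grid=DEFAULT_LAMBDA_GRID,
    feature_names: list[str] | None = None,
    moments: list[Moments] | None = None,
) -> CVResult:
    """Leave-one-unit-out cross-validation with nested ridge selection.

    For each of the j folds: the ridge parameter is chosen by inner
    leave-one-out over the j-1 training units, the final model is fit
    on all training units at that parameter and evaluated on the
    held-out unit (per-channel Pearson r).  Units whose data are
    constant are skipped with a logged record rather than poisoning the
    whole run.

    ``moments`` may carry precomputed per-unit statistics (e.g. sliced
    from a larger feature set); otherwise they are built from the units.
    """
    if len(units) < 3:
        raise ValueError("leave-one-out needs >= 3 units")
    g = _check_grid(grid)
    names = feature_names or list(units[0].feature_names)
    if moments is None:
        moments = [u.moments(lag_spec) for u in units]
    folds: list[FoldResult] = []
    skipped: list[SkippedFold] = []
    bad = [k for k, m in enumerate(moments) if _constant_channels(m)]
    for k in bad:
        skipped.append(SkippedFold(units[k].unit_id, "all-constant data"))
        logger.warning("skipping unit %s: all-constant data", units[k].unit_id)
    keep = [k for k in range(len(units)) if k not in bad]
    total = Moments.sum([moments[k] for k in keep])
    for fold_id, k in enumerate(keep):
        train = [moments[i] for i in keep if i != k]
        if g.size == 1:
            lam = float(g[0])
        else:
            lam = _select_lambda_moments(train, g)
        m_train = total + _neg(moments[k])
        betas, intercepts = ridge_from_moments(m_train, [lam])
        r = accuracy_from_moments(betas[0], intercepts[0], moments[k])
        model = TRFModel(
            beta=betas[0].reshape(len(names), lag_spec.n_lags, -1),
            intercept=intercepts[0],
            lam=lam,
            lag_spec=lag_spec,
            feature_names=list(names),
            meta={"n_train_samples": int(m_train.n), "held_out": units[k].unit_id},
        )
        folds.append(
            FoldResult(
                model=model,
                accuracy=AccuracyRecord(r=r, fold_id=fold_id, unit_id=units[k].unit_id),
                lam=lam,
                unit_id=units[k].unit_id,
            )
        )
    result = CVResult(folds=folds, feature_names=list(names), lag_spec=lag_spec)
    result.skipped = skipped  # type: ignore[attr-defined]
    return result


@dataclass
class ContributionRecord:
    """Per-fold, per-channel accuracy difference full minus reduced."""

    delta: np.ndarray  # folds x channels
    excluded: str
    unit_ids: list[str] = field(default_factory=list)


def feature_contribution(cv_full: CVResult, cv_reduced: CVResult) -> ContributionRecord:
    """Contribution of the feature(s) absent from the reduced model.

    Both cross-validations must have been run on identical folds (same
    units, same order) under the same selection protocol.
    """
    full_ids = [f.unit_id for f in cv_full.folds]
    red_ids = [f.unit_id for f in cv_reduced.folds]
    if full_ids != red_ids:
        raise ValueError("fold structure differs between full and reduced models")
    excluded = [n for n in cv_full.feature_names if n not in cv_reduced.feature_names]
    if not excluded:
        excluded = ["<none>"]
    return ContributionRecord(
        delta=cv_full.accuracies - cv_reduced.accuracies,
        excluded="+".join(excluded),
        unit_ids=full_ids,
    )


@dataclass
class NoiseFloorResult:
    floor_mean: np.ndarray  # per channel
    matched: np.ndarray  # segments x channels
    mismatched: np.ndarray  # pairs x channels
    n_pairs: int


def noise_floor(unit: Unit, model: TRFModel) -> NoiseFloorResult:
    """Mismatched-pairing noise floor for one held-out unit.

    Every ordered pair (data segment i, regressor segment j), i != j,
    of the unit's 1-min blocks is evaluated: the model predicts from
    segment j's regressors and the prediction is correlated with
    segment i's data.  The mean over all k(k-1) mismatched pairs is the
    floor; subtracting it from the raw accuracy centers chance
    performance on zero.
    """
    k = len(unit.blocks)
    if k < 2:
        raise ValueError("noise floor needs >= 2 segments")
    lengths = {F.shape[0] for F, _ in unit.blocks}
    if len(lengths) != 1:
        raise ValueError("noise-floor segments must have equal length")
    flat = model.beta.reshape(-1, model.n_channels)
    preds = []
    for F, _ in unit.blocks:
        X = build_design(F, model.lag_spec, intercept=False)
        preds.append(X @ flat + model.intercept)
    matched = np.stack([pearson_accuracy(preds[i], unit.blocks[i][1]) for i in range(k)])
    mism = []
    for i in range(k):
        for j in range(k):
            if i != j:
                mism.append(pearson_accuracy(preds[j], unit.blocks[i][1]))
    mismatched = np.stack(mism)
    return NoiseFloorResult(
        floor_mean=mismatched.mean(axis=0),
        matched=matched,
        mismatched=mismatched,
        n_pairs=len(mism),
    )


def attach_trial_noise_floor(cv: CVResult, subject_unit: Unit) -> CVResult:
    """Noise floor for trial-level CV within one subject.

    Fold k's floor is the mean accuracy of fold k's model predicting the
    held-out block k's data from every *other* block's regressors
    (mismatched pairing restricted to the held-out segment).  Fold order
    must match the block order of ``subject_unit``.
    """
    k = len(subject_unit.blocks)
    if len(cv.folds) != k:
        raise ValueError(f"{len(cv.folds)} folds for {k} blocks")
    lengths = {F.shape[0] for F, _ in subject_unit.blocks}
    if len(lengths) != 1:
        raise ValueError("noise-floor segments must have equal length")
    for fi, fold in enumerate(cv.folds):
        flat = fold.model.beta.reshape(-1, fold.model.n_channels)
        _, Y_held = subject_unit.blocks[fi]
        mism = []
        for j, (F, _) in enumerate(subject_unit.blocks):
            if j == fi:
                continue
            pred = build_design(F, fold.model.lag_spec, intercept=False) @ flat
            mism.append(pearson_accuracy(pred + fold.model.intercept, Y_held))
        fold.accuracy.floor_mean = np.mean(mism, axis=0)
    return cv


def attach_noise_floor(cv: CVResult, units: list[Unit]) -> CVResult:
    """Compute a noise floor per fold and attach it to the accuracies."""
    by_id = {u.unit_id: u for u in units}
    for fold in cv.folds:
        nf = noise_floor(by_id[fold.unit_id], fold.model)
        fold.accuracy.floor_mean = nf.floor_mean
    return cv
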