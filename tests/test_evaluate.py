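"""Cross-validation: nested ridge selection, leave-one-out folds,
feature contributions and mismatched-pairing noise floors."""
import copy

import numpy as np
import pytest

from trfsweep.containers import LagSpec
from trfsweep.evaluate import (
    DEFAULT_LAMBDA_GRID,
    Unit,
    attach_noise_floor,
    attach_trial_noise_floor,
    feature_contribution,
    loo_crossval,
    noise_floor,
    select_lambda,
    unit_from_subject,
    units_from_blocks,
)
from trfsweep.trf import fit_ridge

from conftest import make_cohort


def _subject_units(cohort, subject=0):
    fset, rec, _ = cohort[subject]
    return units_from_blocks(fset, rec), fset.lag_spec


def test_default_grid_is_ascending_decades():
    g = np.array(DEFAULT_LAMBDA_GRID)
    assert g[0] == 1e-2 and g[-1] == 1e8 and g.size == 11
    assert np.all(np.diff(np.log10(g)) == pytest.approx(1.0))


def test_select_lambda_grid_validation(tiny_cohort):
    cohort, _ = tiny_cohort
    units, spec = _subject_units(cohort)
    with pytest.raises(ValueError, match="ascending"):
        select_lambda(units, spec, grid=[1.0, 1.0])
    with pytest.raises(ValueError, match="empty"):
        select_lambda(units, spec, grid=[])
    assert select_lambda(units, spec, grid=[3.5]) == 3.5
    with pytest.raises(ValueError, match=">= 2"):
        select_lambda(units[:1], spec, grid=[1.0, 10.0])


def test_select_lambda_noiseless_prefers_weak_penalty():
    cohort, _ = make_cohort(n_subjects=2, minutes=4, noiseless=True, seed=2)
    units, spec = _subject_units(cohort)
    lam = select_lambda(units, spec, grid=(1e-2, 1e2, 1e6))
    assert lam == 1e-2  # no noise: any shrinkage only hurts


def test_select_lambda_pure_noise_prefers_strong_penalty():
    cohort, _ = make_cohort(
        n_subjects=2, minutes=4, zero_features=("envelope", "onset"), snr=1.0, seed=3
    )
    units, spec = _subject_units(cohort)
    lam = select_lambda(units, spec, grid=(1e-2, 1e2, 1e6))
    assert lam == 1e6  # nothing to fit: shrink everything away


def test_loo_fold_structure(tiny_cohort):
    cohort, _ = tiny_cohort
    units, spec = _subject_units(cohort)
    cv = loo_crossval(units, spec, grid=(1.0, 100.0))
    assert len(cv.folds) == len(units)
    assert [f.unit_id for f in cv.folds] == [u.unit_id for u in units]
    assert cv.accuracies.shape == (len(units), 6)
    assert all(f.lam in (1.0, 100.0) for f in cv.folds)
    assert all(f.model.beta.shape == (2, spec.n_lags, 6) for f in cv.folds)
    assert cv.skipped == []


def test_loo_requires_three_units(tiny_cohort):
    cohort, _ = tiny_cohort
    units, spec = _subject_units(cohort)
    with pytest.raises(ValueError, match=">= 3"):
        loo_crossval(units[:2], spec)


def test_loo_signal_beats_noise():
    sig_cohort, _ = make_cohort(n_subjects=2, minutes=4, snr=0.3, seed=5)
    nul_cohort, _ = make_cohort(
        n_subjects=2, minutes=4, snr=0.3, seed=5, zero_features=("envelope", "onset")
    )
    u_sig, spec = _subject_units(sig_cohort)
    u_nul, _ = _subject_units(nul_cohort)
    r_sig = loo_crossval(u_sig, spec, grid=(1e0, 1e2, 1e4)).accuracies.mean()
    r_nul = loo_crossval(u_nul, spec, grid=(1e0, 1e2, 1e4)).accuracies.mean()
    assert r_sig > 0.3
    assert abs(r_nul) < 0.1
    assert r_sig > r_nul + 0.25


def test_loo_skips_constant_units(tiny_cohort):
    cohort, _ = tiny_cohort
    units, spec = _subject_units(cohort)
    bad = copy.deepcopy(units[1])
    bad.unit_id = "flat"
    bad.blocks = [(F, np.zeros_like(Y)) for F, Y in bad.blocks]
    cv = loo_crossval(units + [bad], spec, grid=(1.0, 100.0))
    assert len(cv.folds) == len(units)
    assert [s.unit_id for s in cv.skipped] == ["flat"]


def test_loo_precomputed_moments_match(tiny_cohort):
    cohort, _ = tiny_cohort
    units, spec = _subject_units(cohort)
    cv_a = loo_crossval(units, spec, grid=(1.0, 100.0))
    mom = [u.moments(spec) for u in units]
    cv_b = loo_crossval(units, spec, grid=(1.0, 100.0), moments=mom)
    assert np.allclose(cv_a.accuracies, cv_b.accuracies)
    assert [f.lam for f in cv_a.folds] == [f.lam for f in cv_b.folds]


def test_loo_lambda_ignores_held_out_unit(tiny_cohort):
    """Randomizing the held-out unit's response must not change the
    ridge parameter chosen for that fold (selection sees training only)."""
    cohort, _ = tiny_cohort
    units, spec = _subject_units(cohort)
    cv = loo_crossval(units, spec, grid=(1e0, 1e2, 1e4))
    rng = np.random.default_rng(0)
    tampered = copy.deepcopy(units)
    tampered[0].blocks = [(F, rng.normal(size=Y.shape)) for F, Y in tampered[0].blocks]
    cv_t = loo_crossval(tampered, spec, grid=(1e0, 1e2, 1e4))
    assert cv_t.folds[0].lam == cv.folds[0].lam


def test_contribution_identical_models_zero(tiny_cohort):
    cohort, _ = tiny_cohort
    units, spec = _subject_units(cohort)
    cv = loo_crossval(units, spec, grid=(100.0,))
    rec = feature_contribution(cv, cv)
    assert np.allclose(rec.delta, 0.0)
    assert rec.excluded == "<none>"
    assert rec.delta.shape == cv.accuracies.shape


def test_contribution_mismatched_folds_raise(tiny_cohort):
    cohort, _ = tiny_cohort
    units, spec = _subject_units(cohort)
    cv = loo_crossval(units, spec, grid=(100.0,))
    cv_other = loo_crossval(list(reversed(units)), spec, grid=(100.0,))
    with pytest.raises(ValueError, match="fold structure"):
        feature_contribution(cv, cv_other)


def test_contribution_detects_informative_feature():
    """With the onset kernel zeroed in the ground truth, dropping onset
    costs ~nothing; dropping the (active) envelope costs real accuracy."""
    cohort, _ = make_cohort(
        n_subjects=2, minutes=4, snr=0.3, seed=6, zero_features=("onset",)
    )
    fset, rec, _ = cohort[0]
    spec = fset.lag_spec
    grid = (1e0, 1e2, 1e4)
    full = loo_crossval(units_from_blocks(fset, rec), spec, grid=grid)

    def reduced(name):
        sub = fset.select([name])
        return loo_crossval(units_from_blocks(sub, rec), spec, grid=grid)

    d_onset = feature_contribution(full, reduced("envelope")).delta.mean()
    d_env = feature_contribution(full, reduced("onset")).delta.mean()
    assert abs(d_onset) < 0.05  # onset carries no true response
    assert d_env > 0.1  # envelope does
    assert d_env > d_onset


def test_noise_floor_arithmetic(tiny_cohort):
    cohort, _ = tiny_cohort
    fset, rec, _ = cohort[0]
    unit = unit_from_subject(fset, rec)
    model = fit_ridge(fset, [rec.data[:, a:b].T for a, b in fset.block_bounds], 100.0)
    nf = noise_floor(unit, model)
    k = len(unit.blocks)
    assert nf.n_pairs == k * (k - 1)
    assert nf.mismatched.shape == (k * (k - 1), 6)
    assert np.allclose(nf.floor_mean, nf.mismatched.mean(axis=0))
    # matched accuracy beats mismatched on true-signal data
    assert nf.matched.mean() > nf.floor_mean.mean()


def test_noise_floor_validation(tiny_cohort):
    cohort, _ = tiny_cohort
    fset, rec, _ = cohort[0]
    model = fit_ridge(fset, [rec.data[:, a:b].T for a, b in fset.block_bounds], 100.0)
    one = unit_from_subject(fset, rec, block_indices=[0])
    with pytest.raises(ValueError, match=">= 2"):
        noise_floor(one, model)
    unit = unit_from_subject(fset, rec)
    unit.blocks[0] = (unit.blocks[0][0][:-5], unit.blocks[0][1][:-5])
    with pytest.raises(ValueError, match="equal length"):
        noise_floor(unit, model)


def test_trial_noise_floor_matches_manual_pairing(tiny_cohort):
    """Fold k's floor equals the hand-computed mean accuracy of fold k's
    model predicting block k's data from the other blocks' regressors."""
    from trfsweep.trf import build_design, pearson_accuracy

    cohort, _ = tiny_cohort
    fset, rec, _ = cohort[0]
    spec = fset.lag_spec
    units = units_from_blocks(fset, rec)
    cv = loo_crossval(units, spec, grid=(1e2,))
    subj = unit_from_subject(fset, rec)
    cv = attach_trial_noise_floor(cv, subj)
    for fi, fold in enumerate(cv.folds):
        flat = fold.model.beta.reshape(-1, 6)
        mism = []
        for j, (F, _) in enumerate(subj.blocks):
            if j == fi:
                continue
            pred = build_design(F, spec, intercept=False) @ flat + fold.model.intercept
            mism.append(pearson_accuracy(pred, subj.blocks[fi][1]))
        assert np.allclose(fold.accuracy.floor_mean, np.mean(mism, axis=0))
    with pytest.raises(ValueError, match="folds for"):
        attach_trial_noise_floor(cv, unit_from_subject(fset, rec, block_indices=[0, 1]))


def test_noise_floor_centers_pure_noise_accuracy():
    """On null data (zero kernels) the corrected accuracy is centered
    much closer to zero than the raw accuracy is spread."""
    cohort, _ = make_cohort(
        n_subjects=3, minutes=4, snr=0.5, seed=8, zero_features=("envelope", "onset")
    )
    spec = cohort[0][0].lag_spec
    units = [unit_from_subject(f, r) for f, r, _ in cohort]
    cv = loo_crossval(units, spec, grid=(1e2,))
    cv = attach_noise_floor(cv, units)
    corrected = np.concatenate([f.accuracy.corrected for f in cv.folds])
    assert np.abs(np.mean(corrected)) < 0.05
    for f in cv.folds:
        assert f.accuracy.floor_mean is not None
        assert np.allclose(f.accuracy.corrected, f.accuracy.r - f.accuracy.floor_mean)
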