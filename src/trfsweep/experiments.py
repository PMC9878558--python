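"""Data-quantity sweep protocols and ROI averaging.

Two protocols probe how much data TRF analyses need:

* **subject-specific sweeps** refit each subject independently on the
  chronologically first q minutes of their retained blocks, for a grid
  of data quantities (default 3..42 min), with leave-one-trial-out CV
  over 1-min blocks;
* **generic resample sweeps** pool n subjects (drawn with replacement,
  default 20 resamples per cell) truncated to m minutes each (default
  m in {2, 4, 8}, n in 3..41, i.e. 33 configurations per model), fit
  with leave-one-subject-out CV and noise-floor-correct each held-out
  subject.  Full and reduced models consume identical resampling
  draws so their accuracy difference is a paired comparison.

Models are always fit to all channels; ROI averaging only pools the
*results* over the 13-electrode frontal and parietal sensor sets.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureSet, LagSpec, Recording
from .evaluate import (
    DEFAULT_LAMBDA_GRID,
    Unit,
    _check_grid,
    _neg,
    _select_lambda_moments,
    loo_crossval,
    noise_floor,
    unit_from_subject,
    units_from_blocks,
)
from .montage import FRONTAL_ROI, PARIETAL_ROI
from .trf import Moments, accuracy_from_moments, ridge_from_moments

__all__ = [
    "ModelDef",
    "DENSE_MODEL",
    "SPARSE_MODEL",
    "SweepGrid",
    "SweepResult",
    "ROIDefinition",
    "DEFAULT_ROIS",
    "subject_specific_sweep",
    "generic_resample_sweep",
    "roi_average",
]


@dataclass(frozen=True)
class ModelDef:
    """An encoding model: which features it uses and over which lags."""

    name: str
    feature_names: tuple[str, ...]
    lag_window_ms: tuple[float, float]

    def lag_spec(self, fs: float) -> LagSpec:
        return LagSpec(self.lag_window_ms[0], self.lag_window_ms[1], fs)


DENSE_MODEL = ModelDef("dense", ("envelope", "onset"), (-100.0, 350.0))
SPARSE_MODEL = ModelDef("sparse", ("onset", "surprisal", "snr_word"), (-100.0, 800.0))


@dataclass(frozen=True)
class SweepGrid:
    """Default grids of the sweep protocols."""

    quantities_min: tuple[int, ...] = (3, 4, 6, 8, 10, 14, 18, 24, 30, 36, 42)
    subject_counts: tuple[int, ...] = (3, 4, 6, 8, 10, 14, 18, 24, 30, 36, 41)
    minutes_per_subject: tuple[int, ...] = (2, 4, 8)
    n_resamples: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for g in (self.quantities_min, self.subject_counts, self.minutes_per_subject):
            if not g or list(g) != sorted(g):
                raise ValueError("grids must be non-empty and ascending")


@dataclass
class ROIDefinition:
    name: str
    channels: list[str]


DEFAULT_ROIS = [
    ROIDefinition("frontal", list(FRONTAL_ROI)),
    ROIDefinition("parietal", list(PARIETAL_ROI)),
]


@dataclass
class SweepResult:
    """Long-format result table plus companion TRF store.

    ``table`` has one row per (analysis, model, cell, fold/resample,
    channel); ``trf_store`` maps cell keys to mean TRF coefficient
    arrays (features x lags x channels); ``meta`` records grids, seeds
    and the logged resampling draws so runs are auditable.
    """

    table: pd.DataFrame
    trf_store: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)


def _strip(cohort):
    """Accept (FeatureSet, Recording) pairs or generator triples."""
    return [(c[0], c[1]) for c in cohort]


def subject_specific_sweep(
    cohort,
    grid: SweepGrid | None = None,
    models: list[ModelDef] = (DENSE_MODEL,),
    lambda_grid=DEFAULT_LAMBDA_GRID,
    block_indices: dict[str, list[int]] | None = None,
    compute_contributions: bool = False,
) -> SweepResult:
    """Per-subject chronological data-quantity sweep.

    For each subject, model and quantity q, the chronologically first q
    retained 1-min blocks are cross-validated leave-one-trial-out with
    nested ridge selection.  Per-block moment statistics are computed
    once per (subject, model) and shared across quantities and between
    full and reduced models, so the sweep scales with the largest
    quantity only.  Cells that fail (too little data, degenerate fits)
    are recorded in ``failures`` and skipped.
    """
    grid = grid or SweepGrid()
    cohort = _strip(cohort)
    rows = []
    trf_store = {}
    failures = []
    for fset, rec in cohort:
        sid = rec.subject_id
        keep = block_indices.get(sid) if block_indices else list(range(len(fset.block_bounds)))
        for model in models:
            spec = model.lag_spec(fset.fs)
            sub = fset.select(list(model.feature_names))
            units_all = units_from_blocks(sub, rec, keep)
            moments_all = [u.moments(spec) for u in units_all]
            variants = [("full", None, list(range(len(model.feature_names))))]
            if compute_contributions:
                for j, name in enumerate(model.feature_names):
                    kept_idx = [i for i in range(len(model.feature_names)) if i != j]
                    variants.append((f"reduced-{name}", name, kept_idx))
            for q in grid.quantities_min:
                if q > len(units_all):
                    failures.append((sid, model.name, q, "insufficient data"))
                    continue
                units = units_all[:q]
                cell = {}
                try:
                    for vname, excluded, keep_idx in variants:
                        moms = [m.select_features(keep_idx) for m in moments_all[:q]]
                        names = [model.feature_names[i] for i in keep_idx]
                        cv = loo_crossval(
                            units, spec, lambda_grid, feature_names=names, moments=moms
                        )
                        cell[vname] = cv
                except (ValueError, np.linalg.LinAlgError) as err:
                    failures.append((sid, model.name, q, str(err)))
                    continue
                cv = cell["full"]
                deltas = {
                    vname.removeprefix("reduced-"): cv.accuracies - cell[vname].accuracies
                    for vname in cell
                    if vname != "full"
                }
                for k, fold in enumerate(cv.folds):
                    for ci, ch in enumerate(rec.channel_names):
                        row = {
                            "analysis": "subject_specific",
                            "model": model.name,
                            "subject": sid,
                            "quantity_min": q,
                            "fold": k,
                            "unit": fold.unit_id,
                            "channel": ch,
                            "r": fold.accuracy.r[ci],
                            "lam": fold.lam,
                        }
                        for fname, d in deltas.items():
                            row[f"delta_{fname}"] = d[k, ci]
                        rows.append(row)
                trf_store[(model.name, sid, q)] = cv.mean_beta()
    return SweepResult(
        table=pd.DataFrame(rows),
        trf_store=trf_store,
        meta={"grid": grid, "models": [m.name for m in models]},
        failures=failures,
    )


def _draw_streams(grid: SweepGrid, n_cohort: int) -> dict:
    """Resampling index draws, fixed by the master seed and independent
    of which model consumes them (full and reduced models share them)."""
    rng = np.random.default_rng(grid.seed)
    draws = {}
    for n in grid.subject_counts:
        for m in grid.minutes_per_subject:
            for r in range(grid.n_resamples):
                draws[(n, m, r)] = rng.integers(0, n_cohort, size=n)
    return draws


def generic_resample_sweep(
    cohort,
    grid: SweepGrid | None = None,
    models: list[ModelDef] = (DENSE_MODEL,),
    lambda_grid=DEFAULT_LAMBDA_GRID,
    compute_contributions: bool = False,
    with_noise_floor: bool = True,
) -> SweepResult:
    """Generic (pooled-subject) sweep with resampling.

    For every cell (subject count n, minutes per subject m) and each of
    ``n_resamples`` draws of n subjects with replacement, the drawn
    data are fit with leave-one-subject-out CV: folds iterate over the
    *distinct* subjects in the draw and every copy of the held-out
    subject is removed from training, so duplicated subjects never leak
    into their own test fold.  Each held-out subject's accuracy is
    noise-floor corrected from its own mismatched 1-min segment
    pairings.  The stored rows are per-resample fold means.
    """
    grid = grid or SweepGrid()
    cohort = _strip(cohort)
    if max(grid.subject_counts) > len(cohort):
        raise ValueError(
            f"subject-count grid needs up to {max(grid.subject_counts)} subjects, "
            f"cohort has {len(cohort)}"
        )
    lambda_grid = _check_grid(lambda_grid)
    draws = _draw_streams(grid, len(cohort))
    rows = []
    trf_store = {}
    failures = []
    for model in models:
        fs = cohort[0][0].fs
        spec = model.lag_spec(fs)
        # per-subject moments at the largest minute count, sliced per cell
        subj_units: dict[int, dict[int, Unit]] = {}
        subj_moments: dict[tuple[int, int], Moments] = {}
        for si, (fset, rec) in enumerate(cohort):
            sub = fset.select(list(model.feature_names))
            subj_units[si] = {}
            for m in grid.minutes_per_subject:
                u = unit_from_subject(sub, rec, list(range(m)))
                subj_units[si][m] = u
                subj_moments[(si, m)] = u.moments(spec)
        variants = [("full", list(range(len(model.feature_names))))]
        if compute_contributions:
            for j, name in enumerate(model.feature_names):
                variants.append(
                    (f"reduced-{name}", [i for i in range(len(model.feature_names)) if i != j])
                )
        for n in grid.subject_counts:
            for m in grid.minutes_per_subject:
                for r_id in range(grid.n_resamples):
                    idx = draws[(n, m, r_id)]
                    per_variant = {}
                    try:
                        for vname, keep_idx in variants:
                            per_variant[vname] = _fit_resample(
                                idx, m, keep_idx, model, spec, subj_units,
                                subj_moments, lambda_grid, cohort,
                                with_noise_floor and vname == "full",
                            )
                    except (ValueError, np.linalg.LinAlgError) as err:
                        failures.append((model.name, n, m, r_id, str(err)))
                        continue
                    full = per_variant["full"]
                    for ci, ch in enumerate(cohort[0][1].channel_names):
                        row = {
                            "analysis": "generic",
                            "model": model.name,
                            "n_subjects": n,
                            "minutes": m,
                            "resample": r_id,
                            "channel": ch,
                            "r": full["r"][ci],
                            "r_corrected": full["r_corrected"][ci],
                            "lam": full["lam_median"],
                        }
                        for vname, res in per_variant.items():
                            if vname != "full":
                                row[f"delta_{vname.removeprefix('reduced-')}"] = (
                                    full["r"][ci] - res["r"][ci]
                                )
                        rows.append(row)
                    trf_store[(model.name, n, m, r_id)] = full["mean_beta"]
    return SweepResult(
        table=pd.DataFrame(rows),
        trf_store=trf_store,
        meta={
            "grid": grid,
            "models": [mo.name for mo in models],
            "draws": {k: v.tolist() for k, v in draws.items()},
        },
        failures=failures,
    )


def _fit_resample(
    idx, m, keep_idx, model, spec, subj_units, subj_moments, lambda_grid, cohort,
    with_floor,
):
    """Leave-one-subject-out CV over one resampling draw; returns fold
    means of raw and corrected accuracy plus the mean TRF."""
    moms = {si: subj_moments[(si, m)].select_features(keep_idx) for si in set(idx)}
    names = [model.feature_names[i] for i in keep_idx]
    distinct = sorted(set(idx))
    if len(distinct) < 2:
        raise ValueError("resampling draw contains a single distinct subject")
    r_folds, rc_folds, lams, betas = [], [], [], []
    for held in distinct:
        train = [moms[si] for si in idx if si != held]
        if len(train) < 2:
            raise ValueError("fewer than 2 training units after duplicate removal")
        lam = (
            float(lambda_grid[0])
            if lambda_grid.size == 1
            else _select_lambda_moments(train, lambda_grid)
        )
        bet, inter = ridge_from_moments(Moments.sum(train), [lam])
        r = accuracy_from_moments(bet[0], inter[0], moms[held])
        from .containers import TRFModel  # local import avoids cycle at module load

        trf = TRFModel(
            beta=bet[0].reshape(len(names), spec.n_lags, -1),
            intercept=inter[0],
            lam=lam,
            lag_spec=spec,
            feature_names=list(names),
        )
        if with_floor:
            u = subj_units[held][m]
            u_sub = Unit(u.unit_id, [(F[:, keep_idx], Y) for F, Y in u.blocks], names)
            nf = noise_floor(u_sub, trf)
            rc_folds.append(r - nf.floor_mean)
        else:
            rc_folds.append(r)
        r_folds.append(r)
        lams.append(lam)
        betas.append(trf.beta)
    return {
        "r": np.mean(r_folds, axis=0),
        "r_corrected": np.mean(rc_folds, axis=0),
        "lam_median": float(np.median(lams)),
        "mean_beta": np.mean(betas, axis=0),
    }


def roi_average(
    sweep: SweepResult, rois: list[ROIDefinition] = DEFAULT_ROIS
) -> SweepResult:
    """Average sweep results over ROI channel sets.

    Fitting stays all-channel; only the stored per-channel accuracies,
    contributions and TRF coefficients are averaged (unweighted) over
    each ROI's electrodes.  Unknown electrode labels raise.
    """
    table = sweep.table
    channels = list(table["channel"].unique())
    for roi in rois:
        unknown = [c for c in roi.channels if c not in channels]
        if unknown:
            raise ValueError(f"ROI {roi.name!r} references unknown channel(s) {unknown}")
    id_cols = [
        c
        for c in table.columns
        if c != "channel" and not pd.api.types.is_float_dtype(table[c])
    ]
    val_cols = [c for c in table.columns if c not in id_cols and c != "channel"]
    parts = []
    for roi in rois:
        sub = table[table["channel"].isin(roi.channels)]
        agg = sub.groupby(id_cols, as_index=False, sort=False)[val_cols].mean()
        agg.insert(len(id_cols), "roi", roi.name)
        parts.append(agg)
    roi_table = pd.concat(parts, ignore_index=True)
    # average stored TRFs over ROI channel indices
    ch_index = {c: i for i, c in enumerate(channels)}
    trf_store = {}
    for key, beta in sweep.trf_store.items():
        for roi in rois:
            sel = [ch_index[c] for c in roi.channels if c in ch_index]
            trf_store[key + (roi.name,)] = beta[:, :, sel].mean(axis=2, keepdims=True)
    return SweepResult(
        table=roi_table,
        trf_store=trf_store,
        meta={**sweep.meta, "rois": [r.name for r in rois]},
        failures=list(sweep.failures),
    )
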