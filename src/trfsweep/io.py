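"""On-disk layout: portable array containers plus JSON manifests.

A cohort is a directory with one ``subject_XX.npz`` per subject (named
arrays: regressor matrix, recording matrix, optional ground-truth
kernels) and a ``manifest.json`` recording the layout version,
sampling rate, block boundaries, feature names and channel labels.
Everything round-trips bit-identically; readers refuse layout versions
they do not know.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureSet, KernelSet, LagSpec, Recording, TRFModel

__all__ = [
    "LAYOUT_VERSION",
    "write_dataset",
    "read_dataset",
    "save_trf",
    "load_trf",
    "trf_to_tidy",
]

LAYOUT_VERSION = 1


class FormatError(ValueError):
    """Corrupt or incompatible on-disk data."""


def _lag_spec_meta(spec: LagSpec | None):
    if spec is None:
        return None
    return {"tmin_ms": spec.tmin_ms, "tmax_ms": spec.tmax_ms, "fs": spec.fs}


def _lag_spec_from(meta) -> LagSpec | None:
    return None if meta is None else LagSpec(meta["tmin_ms"], meta["tmax_ms"], meta["fs"])


def write_dataset(path, cohort, extra_meta: dict | None = None) -> None:
    """Write a cohort (triples or (FeatureSet, Recording) pairs) to ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "layout_version": LAYOUT_VERSION,
        "n_subjects": len(cohort),
        "subjects": [],
        **(extra_meta or {}),
    }
    for i, entry in enumerate(cohort):
        fset, rec = entry[0], entry[1]
        kernels = entry[2] if len(entry) > 2 else None
        arrays = {"features": fset.data, "recording": rec.data}
        if kernels is not None:
            arrays["kernels"] = kernels.kernels
        fname = f"subject_{i:02d}.npz"
        np.savez(path / fname, **arrays)
        manifest["subjects"].append(
            {
                "file": fname,
                "subject_id": rec.subject_id,
                "fs": float(fset.fs),
                "feature_names": list(fset.names),
                "sparse_flags": [bool(s) for s in fset.sparse_flags],
                "block_bounds": [[int(a), int(b)] for a, b in fset.block_bounds],
                "run_ids": [int(r) for r in rec.run_ids],
                "channel_names": list(rec.channel_names),
                "feature_lag_spec": _lag_spec_meta(fset.lag_spec),
                "kernel_lag_spec": _lag_spec_meta(kernels.lag_spec) if kernels else None,
                "kernel_features": kernels.feature_names if kernels else None,
            }
        )
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_dataset(path):
    """Read a cohort directory; returns (FeatureSet, Recording, KernelSet|None) triples."""
    path = Path(path)
    mf = path / "manifest.json"
    if not mf.exists():
        raise FormatError(f"no manifest.json in {path}")
    manifest = json.loads(mf.read_text())
    version = manifest.get("layout_version")
    if version != LAYOUT_VERSION:
        raise FormatError(
            f"unsupported layout version {version!r} (this reader supports {LAYOUT_VERSION})"
        )
    cohort = []
    for meta in manifest["subjects"]:
        f = path / meta["file"]
        if not f.exists():
            raise FormatError(f"missing array file {f}")
        with np.load(f) as z:
            for key in ("features", "recording"):
                if key not in z:
                    raise FormatError(f"array {key!r} missing from {f}")
            bounds = [tuple(b) for b in meta["block_bounds"]]
            fset = FeatureSet(
                data=z["features"],
                fs=meta["fs"],
                names=list(meta["feature_names"]),
                sparse_flags=list(meta["sparse_flags"]),
                block_bounds=bounds,
                lag_spec=_lag_spec_from(meta["feature_lag_spec"]),
            )
            rec = Recording(
                data=z["recording"],
                fs=meta["fs"],
                channel_names=list(meta["channel_names"]),
                block_bounds=bounds,
                subject_id=meta["subject_id"],
                run_ids=list(meta["run_ids"]),
            )
            kernels = None
            if "kernels" in z:
                kernels = KernelSet(
                    kernels=z["kernels"],
                    lag_spec=_lag_spec_from(meta["kernel_lag_spec"]),
                    feature_names=list(meta["kernel_features"]),
                )
        cohort.append((fset, rec, kernels))
    return cohort


def save_trf(path, model: TRFModel) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), beta=model.beta, intercept=model.intercept)
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "layout_version": LAYOUT_VERSION,
                "lam": model.lam,
                "lag_spec": _lag_spec_meta(model.lag_spec),
                "feature_names": model.feature_names,
                "meta": model.meta,
            },
            indent=1,
        )
    )


def load_trf(path) -> TRFModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta.get("layout_version") != LAYOUT_VERSION:
        raise FormatError(f"unsupported layout version {meta.get('layout_version')!r}")
    with np.load(path.with_suffix(".npz")) as z:
        return TRFModel(
            beta=z["beta"],
            intercept=z["intercept"],
            lam=meta["lam"],
            lag_spec=_lag_spec_from(meta["lag_spec"]),
            feature_names=list(meta["feature_names"]),
            meta=meta["meta"],
        )


def trf_to_tidy(model: TRFModel, channel_names: list[str] | None = None) -> pd.DataFrame:
    """Tidy TRF export: one row per (feature, lag_ms, channel)."""
    names = channel_names or [f"ch{i:02d}" for i in range(model.n_channels)]
    f_idx, l_idx, c_idx = np.meshgrid(
        np.arange(len(model.feature_names)),
        np.arange(model.lag_spec.n_lags),
        np.arange(model.n_channels),
        indexing="ij",
    )
    return pd.DataFrame(
        {
            "feature": np.asarray(model.feature_names)[f_idx.ravel()],
            "lag_ms": model.lag_spec.lag_times_ms[l_idx.ravel()],
            "channel": np.asarray(names)[c_idx.ravel()],
            "beta": model.beta.ravel(),
        }
    )
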