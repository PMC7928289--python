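"""Volume-series preprocessing: mask, crop, z-score, boxcar features.

The fixed pipeline order is mask/crop -> per-volume z-scoring -> boxcar
extraction -> (optional) averaging over the response window. Trials are
represented by the volumes acquired 5-8 s after stimulus onset (four
volumes at a 1 s sampling interval), either kept as a short time series
("boxcar" form, used by the spatiotemporal 3D CNN) or averaged into a
single volume ("averaged" form, used by everything else).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np
import pandas as pd

from .simulate import (
    CATEGORY_CODES,
    GroundTruth,
    SimConfig,
    VolumeSeries,
    _child_seeds,
    _seed_int,
    _window_time_indices,
    generate_events,
    generate_ground_truth,
    iter_runs,
)


class PreprocessError(ValueError):
    pass


@dataclass
class TrialDataset:
    """Per-trial features with aligned labels and provenance metadata.

    ``features`` is ``(n_trials, T, x, y, z)`` in boxcar form or
    ``(n_trials, x, y, z)`` in averaged form. ``labels`` uses the binary
    category encoding (mammal=0, tool=1). ``meta`` carries one row per
    trial with ``subject``, ``run``, ``trial`` columns in feature order.
    """

    features: np.ndarray
    labels: np.ndarray
    meta: pd.DataFrame
    mask: np.ndarray
    form: str  # "boxcar" | "averaged"
    window: Tuple[float, float] = (5.0, 8.0)
    tr: float = 1.0
    degenerate_volumes: int = 0  # zero-variance volumes zeroed during z-scoring

    def __post_init__(self) -> None:
        if self.form not in ("boxcar", "averaged"):
            raise PreprocessError(f"unknown form {self.form!r}")
        want_ndim = 5 if self.form == "boxcar" else 4
        if self.features.ndim != want_ndim:
            raise PreprocessError(
                f"{self.form} features must be {want_ndim}D, got {self.features.shape}"
            )
        n = self.features.shape[0]
        if not (len(self.labels) == n == len(self.meta)):
            raise PreprocessError("features, labels and meta are misaligned")
        if not np.isfinite(self.features).all():
            raise PreprocessError("non-finite feature values")
        if len(self.labels) and not np.isin(self.labels, [0, 1]).all():
            raise PreprocessError("labels must be binary 0/1")

    @property
    def n_trials(self) -> int:
        return self.features.shape[0]

    @property
    def spatial_shape(self) -> Tuple[int, ...]:
        return tuple(self.features.shape[2:] if self.form == "boxcar" else self.features.shape[1:])

    @property
    def n_boxcars(self) -> int:
        if self.form != "boxcar":
            raise PreprocessError("averaged dataset has no boxcar axis")
        return self.features.shape[1]

    def flat_features(self) -> np.ndarray:
        """(n_trials, n_features) view for linear models."""
        return self.features.reshape(self.n_trials, -1)

    def subset(self, idx: np.ndarray) -> "TrialDataset":
        idx = np.asarray(idx)
        return TrialDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            mask=self.mask,
            form=self.form,
            window=self.window,
            tr=self.tr,
            degenerate_volumes=self.degenerate_volumes,
        )

    def with_labels(self, labels: np.ndarray) -> "TrialDataset":
        """Same features/metadata under a replacement label vector."""
        out = TrialDataset(
            features=self.features,
            labels=np.asarray(labels),
            meta=self.meta,
            mask=self.mask,
            form=self.form,
            window=self.window,
            tr=self.tr,
            degenerate_volumes=self.degenerate_volumes,
        )
        return out


def mask_bounding_box(mask: np.ndarray) -> Tuple[slice, ...]:
    """Tight bounding-box slices of the True region of a 3D mask."""
    if mask.ndim != 3:
        raise PreprocessError(f"mask must be 3D, got shape {mask.shape}")
    if not mask.any():
        raise PreprocessError("mask is empty")
    slices = []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        profile = mask.any(axis=other)
        nz = np.flatnonzero(profile)
        slices.append(slice(int(nz[0]), int(nz[-1]) + 1))
    return tuple(slices)


def apply_mask_and_crop(
    volumes: np.ndarray, mask: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Zero voxels outside the mask and crop to the mask's bounding box.

    ``volumes`` may be a single 3D volume or any array whose trailing
    three axes are spatial. The same crop is applied to the mask, which
    is returned alongside so later stages agree on geometry.
    """
    volumes = np.asarray(volumes)
    if volumes.shape[-3:] != mask.shape:
        raise PreprocessError(
            f"spatial shape {volumes.shape[-3:]} does not match mask {mask.shape}"
        )
    box = mask_bounding_box(mask)
    cropped_mask = mask[box]
    cropped = volumes[(Ellipsis,) + box].copy()
    cropped[..., ~cropped_mask] = 0.0
    return cropped, cropped_mask


def zscore_volume(
    volume: np.ndarray, mask: np.ndarray | None = None
) -> Tuple[np.ndarray, bool]:
    """Z-score one image over its within-mask voxels (population sd).

    Returns ``(zscored, degenerate)``; a zero-variance image maps to all
    zeros with ``degenerate=True`` (and a warning) instead of erroring, so
    degenerate synthetic configurations still run.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.size == 0:
        raise PreprocessError("empty volume")
    sel = mask if mask is not None else np.ones(volume.shape, dtype=bool)
    vals = volume[sel]
    mu = vals.mean()
    sd = vals.std()  # ddof=0
    if sd == 0.0:
        warnings.warn("zero within-mask variance; volume z-scored to all zeros")
        return np.zeros_like(volume), True
    out = np.zeros_like(volume)
    out[sel] = (vals - mu) / sd
    return out, False


def extract_boxcars(
    series: VolumeSeries,
    events: pd.DataFrame,
    window: Tuple[float, float] = (5.0, 8.0),
    tr: float | None = None,
    mask: np.ndarray | None = None,
) -> TrialDataset:
    """Gather each trial's response-window volumes into boxcar features.

    A volume at grid time ``i*tr`` belongs to a trial when
    ``onset+start <= i*tr <= onset+end`` (closed interval on the sampling
    grid; four volumes for the default 5-8 s window at tr=1 s).
    """
    tr = series.tr if tr is None else tr
    ev = events
    if "subject" in ev.columns:
        ev = ev[(ev["subject"] == series.subject_id) & (ev["run"] == series.run_id)]
    n_time = series.data.shape[0]
    feats, labels, meta_rows = [], [], []
    t_count = None
    for _, row in ev.iterrows():
        try:
            t_idx = _window_time_indices(row["onset"], window, tr, n_time)
        except Exception as exc:
            raise PreprocessError(
                f"trial (subject={row.get('subject', series.subject_id)}, "
                f"run={row.get('run', series.run_id)}, trial={row['trial']}): {exc}"
            ) from exc
        if t_count is None:
            t_count = len(t_idx)
        elif len(t_idx) != t_count:
            raise PreprocessError(
                f"inconsistent boxcar count at trial {row['trial']}: "
                f"{len(t_idx)} != {t_count}"
            )
        feats.append(series.data[t_idx])
        labels.append(CATEGORY_CODES[row["category"]])
        meta_rows.append(
            {
                "subject": row.get("subject", series.subject_id),
                "run": row.get("run", series.run_id),
                "trial": row["trial"],
            }
        )
    features = np.stack(feats).astype(float)
    if mask is None:
        mask = np.ones(features.shape[2:], dtype=bool)
    return TrialDataset(
        features=features,
        labels=np.array(labels),
        meta=pd.DataFrame(meta_rows),
        mask=mask,
        form="boxcar",
        window=tuple(window),
        tr=tr,
    )


def average_boxcars(dataset: TrialDataset) -> TrialDataset:
    """Average the boxcar axis, producing one volume per trial."""
    if dataset.form != "boxcar":
        raise PreprocessError("dataset is already averaged")
    return TrialDataset(
        features=dataset.features.mean(axis=1),
        labels=dataset.labels,
        meta=dataset.meta,
        mask=dataset.mask,
        form="averaged",
        window=dataset.window,
        tr=dataset.tr,
        degenerate_volumes=dataset.degenerate_volumes,
    )


def preprocess_series(
    series: VolumeSeries,
    events: pd.DataFrame,
    mask: np.ndarray,
    window: Tuple[float, float] = (5.0, 8.0),
) -> TrialDataset:
    """Full per-run pipeline: mask/crop -> z-score each volume -> extract."""
    cropped, cmask = apply_mask_and_crop(series.data, mask)
    n_degenerate = 0
    for t in range(cropped.shape[0]):
        cropped[t], flag = zscore_volume(cropped[t], cmask)
        n_degenerate += int(flag)
    zs = VolumeSeries(
        data=cropped, tr=series.tr, subject_id=series.subject_id, run_id=series.run_id
    )
    ds = extract_boxcars(zs, events, window=window, tr=series.tr, mask=cmask)
    ds.degenerate_volumes = n_degenerate
    return ds


def concat_trial_datasets(datasets: Iterable[TrialDataset]) -> TrialDataset:
    """Stack per-run TrialDatasets (same geometry/form) into one."""
    datasets = list(datasets)
    if not datasets:
        raise PreprocessError("nothing to concatenate")
    first = datasets[0]
    for d in datasets[1:]:
        if d.form != first.form or d.features.shape[1:] != first.features.shape[1:]:
            raise PreprocessError("incompatible datasets")
    return TrialDataset(
        features=np.concatenate([d.features for d in datasets]),
        labels=np.concatenate([d.labels for d in datasets]),
        meta=pd.concat([d.meta for d in datasets], ignore_index=True),
        mask=first.mask,
        form=first.form,
        window=first.window,
        tr=first.tr,
        degenerate_volumes=sum(d.degenerate_volumes for d in datasets),
    )


def simulate_trial_dataset(
    config: SimConfig,
    seed: int | None = None,
    average: bool = True,
    window: Tuple[float, float] | None = None,
) -> Tuple[TrialDataset, GroundTruth]:
    """Simulate and preprocess a full dataset, one run at a time.

    Streams run by run so only a single 4D series is ever resident,
    which keeps the default design (30 runs of 400 volumes) cheap.
    Returns the trial features plus the generator's ground truth for
    recovery checks.
    """
    if seed is None:
        seed = config.seed
    if window is None:
        window = config.response_window
    ev_seed, gt_seed, run_seeds = _child_seeds(seed, config)
    events = generate_events(config, seed=_seed_int(ev_seed))
    truth = generate_ground_truth(config, seed=_seed_int(gt_seed))
    parts = [
        preprocess_series(vs, events, truth.gray_mask, window=window)
        for vs in iter_runs(config, truth, events, run_seeds)
    ]
    ds = concat_trial_datasets(parts)
    if average:
        ds = average_boxcars(ds)
    return ds, truth
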