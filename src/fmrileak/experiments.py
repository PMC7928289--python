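"""Canned experiments: the leakage-ordering and calibration studies.

These functions define the benchmark's study conditions in one place so
the analysis drivers, the test suite and the acceptance script all run
the identical experiment. Two regimes are used:

* ``leakage_regime`` — the default generator configuration: a shared
  category contrast that is an order of magnitude weaker per voxel than
  the between-subject variability, with temporally autocorrelated noise.
  Under it, decoding accuracy should rise from leave-one-subject-out
  (chance) through session shuffle to sample shuffle as splits admit more
  leakage.
* ``signal_regime`` — subject-exchangeable, strongly signaled, noise-light
  data on which every split should decode nearly perfectly; used for
  capacity and permutation-calibration checks.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np

from .evaluate import permutation_null, run_cv
from .models import ModelConfig
from .preprocess import TrialDataset, simulate_trial_dataset
from .simulate import SimConfig
from .splits import SPLIT_METHODS, plan_by_name


def leakage_regime(**overrides) -> SimConfig:
    """Default study conditions: subject variability dominates the signal."""
    return SimConfig(**overrides)


def signal_regime(**overrides) -> SimConfig:
    """Strong shared signal, exchangeable subjects, light noise."""
    params = dict(
        n_subjects=5,
        n_runs_per_subject=2,
        trials_per_run=20,
        volume_shape=(10, 10, 10),
        signal_amplitude=1.5,
        n_signal_voxels=40,
        sigma_subject=0.0,
        sigma_run=0.0,
        sigma_trial=0.5,
        ar1_rho=0.0,
    )
    params.update(overrides)
    return SimConfig(**params)


def calibration_regime(**overrides) -> SimConfig:
    """Small noisy dataset for permutation-null calibration runs."""
    params = dict(
        n_subjects=5,
        n_runs_per_subject=2,
        trials_per_run=20,
        volume_shape=(10, 10, 10),
        signal_amplitude=0.6,
        n_signal_voxels=40,
        sigma_subject=0.0,
        sigma_run=0.3,
        sigma_trial=1.0,
        ar1_rho=0.5,
    )
    params.update(overrides)
    return SimConfig(**params)


def leakage_ordering_experiment(
    seeds: Sequence[int],
    config: SimConfig | None = None,
    model_config: ModelConfig | None = None,
    splits: Sequence[str] = SPLIT_METHODS,
) -> Dict[str, List[float]]:
    """Mean PLR accuracy per split method, one value per simulation seed.

    Simulates the default design for each seed, builds the three split
    plans and runs the five-fold CV with the PLR baseline. Returns
    {split: [mean accuracy per seed]}.
    """
    if config is None:
        config = leakage_regime()
    if model_config is None:
        model_config = ModelConfig(family="plr")
    out: Dict[str, List[float]] = {s: [] for s in splits}
    for seed in seeds:
        ds, _ = simulate_trial_dataset(config, seed=seed)
        for split in splits:
            plan = plan_by_name(split, ds.meta, seed=seed)
            folds = run_cv(ds, plan, model_config, seed=seed)
            out[split].append(float(np.mean([f.accuracy for f in folds])))
    return out


def permutation_calibration_experiment(
    seed: int,
    n_perm: int = 20,
    config: SimConfig | None = None,
    model_config: ModelConfig | None = None,
    split: str = "sample",
) -> Dict[str, float]:
    """Null distribution on signaled data plus the true-label accuracy.

    Uses a small strongly-signaled dataset: the permutation null should
    center at chance while the true-label CV accuracy clears the null's
    maximum.
    """
    if config is None:
        config = signal_regime()
    if model_config is None:
        model_config = ModelConfig(family="plr", n_selected_voxels=200)
    ds, _ = simulate_trial_dataset(config, seed=seed)
    plan = plan_by_name(split, ds.meta, seed=seed)
    nulls = permutation_null(ds, plan, n_perm=n_perm, seed=seed, model_config=model_config)
    folds = run_cv(ds, plan, model_config, seed=seed)
    true_acc = float(np.mean([f.accuracy for f in folds]))
    return {
        "null_mean": float(np.mean(nulls)),
        "null_max": float(np.max(nulls)),
        "null_min": float(np.min(nulls)),
        "true_accuracy": true_acc,
        "n_perm": n_perm,
        "n_trials": ds.n_trials,
    }


def separable_trial_set(
    n_trials: int = 40,
    spatial_shape=(10, 10, 10),
    t_boxcars: int = 4,
    seed: int = 0,
    form: str = "averaged",
) -> TrialDataset:
    """A linearly separable toy set for capacity sanity checks.

    Two well-separated Gaussian blobs over a handful of voxels; labels
    balanced. Returned in averaged or boxcar form.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_half = n_trials // 2
    labels = np.array([0] * n_half + [1] * (n_trials - n_half))
    pattern = rng.standard_normal(spatial_shape)
    pattern /= np.linalg.norm(pattern)
    signs = np.where(labels == 0, 1.0, -1.0)
    vols = signs[:, None, None, None] * pattern[None] * 5.0
    vols = vols + 0.1 * rng.standard_normal(vols.shape)
    if form == "boxcar":
        feats = np.repeat(vols[:, None], t_boxcars, axis=1)
        feats = feats + 0.02 * rng.standard_normal(feats.shape)
    else:
        feats = vols
    meta = pd.DataFrame(
        {
            "subject": np.zeros(n_trials, dtype=int),
            "run": np.zeros(n_trials, dtype=int),
            "trial": np.arange(n_trials),
        }
    )
    return TrialDataset(
        features=feats,
        labels=labels,
        meta=meta,
        mask=np.ones(spatial_shape, dtype=bool),
        form=form,
    )
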