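import numpy as np
import pandas as pd
import pytest

from fmrileak.preprocess import TrialDataset
from fmrileak.simulate import SimConfig


@pytest.fixture
def tiny_config() -> SimConfig:
    """Five subjects, one short run each: enough for every split method."""
    return SimConfig(
        n_subjects=5,
        n_runs_per_subject=1,
        trials_per_run=8,
        volume_shape=(8, 8, 8),
        n_signal_voxels=10,
        signal_amplitude=1.0,
        sigma_subject=0.5,
        sigma_run=0.2,
        sigma_trial=0.3,
        ar1_rho=0.3,
        seed=7,
    )


@pytest.fixture
def small_multirun_config() -> SimConfig:
    """Five subjects x two runs: exercises run-level splitting."""
    return SimConfig(
        n_subjects=5,
        n_runs_per_subject=2,
        trials_per_run=10,
        volume_shape=(8, 8, 8),
        n_signal_voxels=10,
        signal_amplitude=1.0,
        sigma_subject=0.5,
        sigma_run=0.2,
        sigma_trial=0.3,
        ar1_rho=0.3,
        seed=7,
    )


def make_meta(n_subjects: int, n_runs: int, trials_per_run: int) -> pd.DataFrame:
    rows = [
        {"subject": s, "run": r, "trial": t}
        for s in range(n_subjects)
        for r in range(n_runs)
        for t in range(trials_per_run)
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def meta_240() -> pd.DataFrame:
    """240 trials: the worked sample-shuffle example (144/48/48)."""
    return make_meta(2, 6, 20)


@pytest.fixture
def meta_default() -> pd.DataFrame:
    """The full study design: 5 subjects x 6 runs x 40 trials = 1,200."""
    return make_meta(5, 6, 40)


def random_trial_dataset(
    n_trials: int = 30,
    shape=(5, 5, 5),
    form: str = "averaged",
    t_boxcars: int = 3,
    seed: int = 0,
    n_subjects: int = 5,
) -> TrialDataset:
    rng = np.random.default_rng(seed)
    if form == "averaged":
        feats = rng.standard_normal((n_trials,) + shape)
    else:
        feats = rng.standard_normal((n_trials, t_boxcars) + shape)
    labels = rng.integers(0, 2, n_trials)
    per_subject = n_trials // n_subjects
    meta = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subjects), per_subject)[:n_trials],
            "run": np.zeros(n_trials, dtype=int),
            "trial": np.arange(n_trials),
        }
    )
    return TrialDataset(
        features=feats,
        labels=labels,
        meta=meta,
        mask=np.ones(shape, dtype=bool),
        form=form,
    )
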