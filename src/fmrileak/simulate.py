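"""Synthetic event-related task-fMRI generator.

Emulates a small-sample category-decoding study: five subjects, six runs
each, forty trials per run (half "mammal", half "tool"), caption language
alternating run by run. Each trial evokes a boxcar-shaped response carried
by a category-contrast pattern that is shared across subjects, on top of a
variance hierarchy that makes the dataset hostile to cross-subject
decoding:

* a per-subject spatial offset pattern (largest component) — subjects look
  far more different from each other than from themselves,
* a per-run spatial offset (smaller) — runs of one subject differ,
* stationary AR(1) voxel noise — time points within a run are correlated,
  so trials of the same run are more alike than trials of different runs.

That structure is exactly what makes leave-one-subject-out, run-level and
trial-level cross-validation splits behave differently downstream, which is
the point of the benchmark. Everything is reproducible bit-for-bit from a
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Sequence, Tuple

import numpy as np
import pandas as pd

CATEGORIES: Tuple[str, str] = ("mammal", "tool")
LANGUAGES: Tuple[str, str] = ("korean", "chinese")

#: label encoding used everywhere downstream
CATEGORY_CODES: Dict[str, int] = {"mammal": 0, "tool": 1}
#: sign of the shared contrast pattern added for each category
CATEGORY_SIGNS: Dict[str, float] = {"mammal": 1.0, "tool": -1.0}


class DesignError(ValueError):
    """Raised when a simulation configuration violates the study design."""


@dataclass(frozen=True)
class SimConfig:
    """All generator parameters.

    Defaults encode the study design (5 subjects x 6 runs x 40 trials,
    boxcar response 5-8 s after onset) and a variance regime in which
    between-subject variability dominates the category signal while
    within-run temporal correlation exceeds between-run similarity.
    Units: seconds for times, arbitrary BOLD-like units for amplitudes
    (only ratios matter once images are z-scored).
    """

    n_subjects: int = 5
    n_runs_per_subject: int = 6
    trials_per_run: int = 40
    volume_shape: Tuple[int, int, int] = (16, 16, 16)
    tr: float = 1.0
    inter_trial_interval: float = 10.0
    response_window: Tuple[float, float] = (5.0, 8.0)
    signal_amplitude: float = 0.1
    n_signal_voxels: int = 60
    sigma_subject: float = 6.0
    sigma_run: float = 1.5
    sigma_trial: float = 1.0
    ar1_rho: float = 0.4
    language_by_run_parity: bool = True
    language_amplitude_modulation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_run <= 0 or self.trials_per_run % 2 != 0:
            raise DesignError(
                f"trials_per_run must be even and positive, got {self.trials_per_run}"
            )
        if self.n_subjects < 1 or self.n_runs_per_subject < 1:
            raise DesignError("need at least one subject and one run")
        lo, hi = self.response_window
        if not (0 <= lo <= hi):
            raise DesignError(f"invalid response window {self.response_window}")
        if hi > self.inter_trial_interval:
            raise DesignError(
                "response window must fit inside the inter-trial interval: "
                f"{hi} > {self.inter_trial_interval}"
            )
        if not (0.0 <= self.ar1_rho < 1.0):
            raise DesignError(f"ar1_rho must lie in [0, 1), got {self.ar1_rho}")
        for name in ("sigma_subject", "sigma_run", "sigma_trial", "signal_amplitude"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be non-negative")
        if len(self.volume_shape) != 3 or any(s < 1 for s in self.volume_shape):
            raise DesignError(f"volume_shape must be 3 positive ints, got {self.volume_shape}")
        if self.tr <= 0 or self.inter_trial_interval <= 0:
            raise DesignError("tr and inter_trial_interval must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_subjects * self.n_runs_per_subject * self.trials_per_run

    @property
    def n_timepoints_per_run(self) -> int:
        return math.ceil(self.trials_per_run * self.inter_trial_interval / self.tr)

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Recorded latent state of one simulated dataset.

    Kept so recovery tests (feature selection, saliency localization) can
    compare what a model found against what was actually planted.
    """

    gray_mask: np.ndarray  # bool volume
    signal_voxel_mask: np.ndarray  # bool volume, n_signal_voxels True inside gray
    shared_pattern: np.ndarray  # signed category-contrast volume
    per_subject_pattern: Dict[int, np.ndarray]
    realized_sigmas: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.signal_voxel_mask.any():
            raise DesignError("signal voxel mask is empty")
        if (self.signal_voxel_mask & ~self.gray_mask).any():
            raise DesignError("signal voxels must lie inside the gray mask")


@dataclass
class VolumeSeries:
    """One run's 4D time series (time, x, y, z) with its sampling rate."""

    data: np.ndarray
    tr: float
    subject_id: int
    run_id: int

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (time, x, y, z), got shape {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume series contains non-finite values")


def make_gray_mask(shape: Sequence[int]) -> np.ndarray:
    """Centered ellipsoid covering roughly half the volume.

    Serves as the stand-in gray-matter mask so the masking/cropping stages
    have nontrivial work; semi-axes are ~0.985 of each half-extent, which
    for an ellipsoid gives a ~50% fill fraction.
    """
    shape = tuple(int(s) for s in shape)
    axes = [np.arange(s, dtype=float) - (s - 1) / 2.0 for s in shape]
    semi = [0.985 * s / 2.0 for s in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    r2 = (xx / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (zz / semi[2]) ** 2
    return r2 <= 1.0


def generate_events(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Build the per-trial event table for the whole dataset.

    One row per trial with columns ``subject``, ``run``, ``trial``,
    ``onset`` (seconds from run start), ``category`` and ``language``.
    Category order is randomized independently within each run with exact
    half/half balance; onsets sit on a regular inter-trial grid; language
    alternates with run parity when enabled.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    half = config.trials_per_run // 2
    base = np.array([0] * half + [1] * half)
    rows = []
    for subject in range(config.n_subjects):
        for run in range(config.n_runs_per_subject):
            order = rng.permutation(base)
            if config.language_by_run_parity:
                language = LANGUAGES[run % 2]
            else:
                language = LANGUAGES[0]
            for trial in range(config.trials_per_run):
                rows.append(
                    {
                        "subject": subject,
                        "run": run,
                        "trial": trial,
                        "onset": trial * config.inter_trial_interval,
                        "category": CATEGORIES[order[trial]],
                        "language": language,
                    }
                )
    return pd.DataFrame(rows)


def generate_ground_truth(config: SimConfig, seed: int | None = None) -> GroundTruth:
    """Draw the latent spatial patterns: mask, signal voxels, contrasts."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gray = make_gray_mask(config.volume_shape)
    in_mask = np.flatnonzero(gray.ravel())
    if config.n_signal_voxels > in_mask.size:
        raise DesignError(
            f"n_signal_voxels={config.n_signal_voxels} exceeds {in_mask.size} gray voxels"
        )
    chosen = rng.choice(in_mask, size=config.n_signal_voxels, replace=False)
    signal_mask = np.zeros(gray.size, dtype=bool)
    signal_mask[chosen] = True
    signal_mask = signal_mask.reshape(gray.shape)

    shared = np.zeros(gray.shape, dtype=float)
    shared[signal_mask] = config.signal_amplitude * rng.standard_normal(
        config.n_signal_voxels
    )

    # Subject idiosyncrasy spans the whole gray mask: subjects differ
    # everywhere, not just at the informative voxels (keeping the
    # informative voxels from being selectively noisier than the rest).
    per_subject: Dict[int, np.ndarray] = {}
    for subject in range(config.n_subjects):
        pat = np.zeros(gray.shape, dtype=float)
        pat[gray] = config.sigma_subject * rng.standard_normal(int(gray.sum()))
        per_subject[subject] = pat

    realized = {
        "sigma_subject_realized": float(
            np.std([p[gray] for p in per_subject.values()]) if config.n_subjects else 0.0
        ),
        "shared_pattern_norm": float(np.linalg.norm(shared)),
    }
    return GroundTruth(
        gray_mask=gray,
        signal_voxel_mask=signal_mask,
        shared_pattern=shared,
        per_subject_pattern=per_subject,
        realized_sigmas=realized,
    )


def _ar1_noise(
    rng: np.random.Generator, n_time: int, n_voxels: int, sigma: float, rho: float
) -> np.ndarray:
    """Stationary AR(1) noise, marginal sd ``sigma``, lag-1 correlation ``rho``."""
    if sigma == 0.0:
        return np.zeros((n_time, n_voxels))
    eps = rng.standard_normal((n_time, n_voxels))
    out = np.empty((n_time, n_voxels))
    out[0] = sigma * eps[0]
    innov_sd = sigma * math.sqrt(1.0 - rho * rho)
    for t in range(1, n_time):
        out[t] = rho * out[t - 1] + innov_sd * eps[t]
    return out


def _window_time_indices(
    onset: float, window: Tuple[float, float], tr: float, n_time: int
) -> np.ndarray:
    """Volume indices i with onset+start <= i*tr <= onset+end (closed interval)."""
    lo, hi = onset + window[0], onset + window[1]
    eps = 1e-9 * max(1.0, abs(hi))
    first = math.ceil((lo - eps) / tr)
    last = math.floor((hi + eps) / tr)
    idx = np.arange(max(first, 0), min(last, n_time - 1) + 1)
    if first < 0 or last > n_time - 1:
        raise DesignError(
            f"response window [{lo}, {hi}] s falls outside the series "
            f"(0..{(n_time - 1) * tr} s)"
        )
    return idx


def simulate_subject_run(
    config: SimConfig,
    ground_truth: GroundTruth,
    subject_id: int,
    run_id: int,
    events: pd.DataFrame,
    seed: int | np.random.SeedSequence,
) -> VolumeSeries:
    """Simulate one run's 4D series for one subject.

    Per trial the volume gains ``shared_pattern * category_sign +
    subject_pattern`` during the response window (a boxcar), the whole run
    gains a run-level offset pattern, and stationary AR(1) noise is added
    per gray voxel. Voxels outside the gray mask stay exactly zero.
    """
    ev = events
    if "subject" in ev.columns:
        ev = ev[(ev["subject"] == subject_id) & (ev["run"] == run_id)]
    if len(ev) == 0:
        raise DesignError(f"no events for subject {subject_id} run {run_id}")
    rng = np.random.default_rng(seed)
    n_time = config.n_timepoints_per_run
    gray = ground_truth.gray_mask
    n_gray = int(gray.sum())
    flat = np.zeros((n_time, gray.size))

    run_offset = config.sigma_run * rng.standard_normal(n_gray)
    gray_idx = np.flatnonzero(gray.ravel())
    flat[:, gray_idx] += run_offset

    subj_pat = ground_truth.per_subject_pattern[subject_id].ravel()
    shared = ground_truth.shared_pattern.ravel()
    for _, row in ev.iterrows():
        sign = CATEGORY_SIGNS[row["category"]]
        amp = 1.0
        if config.language_amplitude_modulation and row["language"] == LANGUAGES[1]:
            amp = 1.0 + config.language_amplitude_modulation
        t_idx = _window_time_indices(row["onset"], config.response_window, config.tr, n_time)
        flat[np.ix_(t_idx, gray_idx)] += (
            amp * (shared[gray_idx] * sign + subj_pat[gray_idx])
        )

    noise = _ar1_noise(rng, n_time, n_gray, config.sigma_trial, config.ar1_rho)
    flat[:, gray_idx] += noise

    data = flat.reshape((n_time,) + tuple(config.volume_shape)).astype(np.float32)
    return VolumeSeries(data=data, tr=config.tr, subject_id=subject_id, run_id=run_id)


def _child_seeds(seed: int, config: SimConfig) -> tuple:
    """Split a master seed into (events, ground-truth, per-run) children."""
    ss = np.random.SeedSequence(seed)
    n_runs = config.n_subjects * config.n_runs_per_subject
    children = ss.spawn(2 + n_runs)
    return children[0], children[1], children[2:]


def iter_runs(
    config: SimConfig,
    ground_truth: GroundTruth,
    events: pd.DataFrame,
    run_seeds: Sequence[np.random.SeedSequence],
) -> Iterator[VolumeSeries]:
    """Yield one VolumeSeries per (subject, run), in subject-major order."""
    k = 0
    for subject in range(config.n_subjects):
        for run in range(config.n_runs_per_subject):
            yield simulate_subject_run(
                config, ground_truth, subject, run, events, run_seeds[k]
            )
            k += 1


def generate_dataset(
    config: SimConfig, seed: int | None = None
) -> Tuple[Dict[Tuple[int, int], VolumeSeries], pd.DataFrame, GroundTruth, np.ndarray]:
    """Materialize the full dataset in memory.

    Returns (volume series keyed by (subject, run), event table, ground
    truth, gray mask). For the default design this is 30 series of
    400 x 16^3 float32. Prefer :func:`iter_runs` when streaming.
    """
    if seed is None:
        seed = config.seed
    ev_seed, gt_seed, run_seeds = _child_seeds(seed, config)
    events = generate_events(config, seed=_seed_int(ev_seed))
    truth = generate_ground_truth(config, seed=_seed_int(gt_seed))
    series = {
        (vs.subject_id, vs.run_id): vs
        for vs in iter_runs(config, truth, events, run_seeds)
    }
    return series, events, truth, truth.gray_mask


def _seed_int(ss: np.random.SeedSequence) -> int:
    """Deterministic 31-bit integer derived from a SeedSequence."""
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
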