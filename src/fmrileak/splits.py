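"""Cross-validation split plans with three leakage regimes.

Three ways to carve 3:1:1 Train/Valid/Test folds out of a multi-subject,
multi-run trial set, ordered by how much statistical dependence they allow
between Train and Test:

* ``loso_folds`` — leave-one-subject-out: Test is one whole subject never
  seen in training (no subject-level leakage).
* ``session_shuffle_folds`` — whole runs assigned at random: Test subjects
  also appear in Train via other runs (within-subject leakage), but no run
  straddles subsets (no within-run temporal leakage).
* ``sample_shuffle_folds`` — individual trials assigned at random:
  within-subject and within-run dependence both leak into Test.

The shuffle-based plans are five independent random re-draws rather than a
partition, because a per-fold 3:1:1 ratio is incompatible with a 5-way
partition of the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Sequence

import numpy as np
import pandas as pd


class Fold(NamedTuple):
    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray


@dataclass
class SplitPlan:
    unit: str  # "subject" | "run" | "trial"
    folds: List[Fold]
    seed: int | None = None

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass
class SplitValidation:
    ok: bool
    violations: List[str]


class SplitDesignError(ValueError):
    pass


def _as_meta(meta) -> pd.DataFrame:
    if isinstance(meta, pd.DataFrame):
        return meta
    return meta.meta  # TrialDataset


def loso_folds(meta) -> SplitPlan:
    """Leave-one-subject-out plan: Test subject k, Valid subject k+1 (cyclic).

    Fully deterministic; n_folds equals the number of subjects, each
    subject serving as Test exactly once. The 3:1:1 subject design needs
    at least five subjects.
    """
    meta = _as_meta(meta)
    subjects = np.sort(meta["subject"].unique())
    if len(subjects) < 5:
        raise SplitDesignError(
            f"leave-one-subject-out with a 3:1:1 design needs >=5 subjects, "
            f"got {len(subjects)}"
        )
    folds = []
    subj = meta["subject"].to_numpy()
    for k, test_subject in enumerate(subjects):
        valid_subject = subjects[(k + 1) % len(subjects)]
        test = np.flatnonzero(subj == test_subject)
        valid = np.flatnonzero(subj == valid_subject)
        train = np.flatnonzero((subj != test_subject) & (subj != valid_subject))
        folds.append(Fold(train=train, valid=valid, test=test))
    return SplitPlan(unit="subject", folds=folds, seed=None)


def session_shuffle_folds(meta, n_folds: int = 5, seed: int = 0) -> SplitPlan:
    """Run-atomic shuffle plan: whole runs drawn 3:1:1 into Train/Valid/Test.

    Each fold is an independent shuffle of the (subject, run) blocks;
    Valid and Test each receive ``floor(n_runs/5)`` runs, the remainder
    going to Train (exactly 18/6/6 for 30 runs).
    """
    meta = _as_meta(meta)
    runs = meta[["subject", "run"]].drop_duplicates().sort_values(["subject", "run"])
    run_keys = list(runs.itertuples(index=False, name=None))
    if len(run_keys) < 5:
        raise SplitDesignError(f"session shuffle needs >=5 runs, got {len(run_keys)}")
    rng = np.random.default_rng(seed)
    key = list(zip(meta["subject"].to_numpy(), meta["run"].to_numpy()))
    run_of_trial = np.array([run_keys.index(k) for k in key])
    n_runs = len(run_keys)
    n_each = n_runs // 5
    folds = []
    for _ in range(n_folds):
        order = rng.permutation(n_runs)
        valid_runs, test_runs = order[:n_each], order[n_each : 2 * n_each]
        train_runs = order[2 * n_each :]
        folds.append(
            Fold(
                train=np.flatnonzero(np.isin(run_of_trial, train_runs)),
                valid=np.flatnonzero(np.isin(run_of_trial, valid_runs)),
                test=np.flatnonzero(np.isin(run_of_trial, test_runs)),
            )
        )
    return SplitPlan(unit="run", folds=folds, seed=seed)


def sample_shuffle_folds(meta, n_folds: int = 5, seed: int = 0) -> SplitPlan:
    """Trial-level shuffle plan: trials drawn 3:1:1 ignoring subject and run.

    240 trials yield 144/48/48; 1,200 trials yield 720/240/240. Each fold
    is an independent uniform draw.
    """
    meta = _as_meta(meta)
    n = len(meta)
    if n < 5:
        raise SplitDesignError(f"sample shuffle needs >=5 trials, got {n}")
    rng = np.random.default_rng(seed)
    n_each = n // 5
    folds = []
    for _ in range(n_folds):
        order = rng.permutation(n)
        folds.append(
            Fold(
                train=np.sort(order[2 * n_each :]),
                valid=np.sort(order[:n_each]),
                test=np.sort(order[n_each : 2 * n_each]),
            )
        )
    return SplitPlan(unit="trial", folds=folds, seed=seed)


def validate_split(plan: SplitPlan, meta) -> SplitValidation:
    """Check disjointness, coverage and unit atomicity of a plan.

    Violations are returned as human-readable strings rather than raised,
    so corrupted plans can be reported wholesale.
    """
    meta = _as_meta(meta)
    n = len(meta)
    all_idx = np.arange(n)
    violations: List[str] = []
    for f, fold in enumerate(plan.folds):
        parts = {"train": fold.train, "valid": fold.valid, "test": fold.test}
        for name, idx in parts.items():
            idx = np.asarray(idx)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                violations.append(f"fold {f}: {name} indices out of range")
        names = list(parts)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                overlap = np.intersect1d(parts[names[i]], parts[names[j]])
                if overlap.size:
                    violations.append(
                        f"fold {f}: trial(s) {overlap[:5].tolist()} appear in both "
                        f"{names[i]} and {names[j]}"
                    )
        union = np.union1d(np.union1d(fold.train, fold.valid), fold.test)
        if not np.array_equal(union, all_idx):
            violations.append(f"fold {f}: union of subsets does not cover all trials")
        if plan.unit in ("subject", "run"):
            cols = ["subject"] if plan.unit == "subject" else ["subject", "run"]
            unit_key = meta[cols].apply(tuple, axis=1).to_numpy()
            assignment = {}
            for name, idx in parts.items():
                for u in set(unit_key[np.asarray(idx, dtype=int)]):
                    if u in assignment and assignment[u] != name:
                        violations.append(
                            f"fold {f}: {plan.unit} {u} split across "
                            f"{assignment[u]} and {name}"
                        )
                    assignment[u] = name
    return SplitValidation(ok=not violations, violations=violations)


def plan_by_name(
    method: str, meta, n_folds: int = 5, seed: int = 0
) -> SplitPlan:
    """Dispatch on {"loso", "session", "sample"}."""
    builders = {
        "loso": lambda: loso_folds(meta),
        "session": lambda: session_shuffle_folds(meta, n_folds=n_folds, seed=seed),
        "sample": lambda: sample_shuffle_folds(meta, n_folds=n_folds, seed=seed),
    }
    if method not in builders:
        raise SplitDesignError(f"unknown split method {method!r}")
    return builders[method]()


SPLIT_METHODS: Sequence[str] = ("loso", "session", "sample")
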