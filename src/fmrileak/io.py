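"""Readers and writers: NIfTI volumes, BIDS-style events, bundles, plans.

Events follow the BIDS events convention (tab-separated, one header line,
onset in seconds) so real exports can be swapped in for the synthetic
tables. Trial features travel as a compressed ``.npz`` bundle with a JSON
sidecar recording form, window, tr and a mask checksum. Writers refuse to
overwrite unless ``force`` is passed, and a run manifest records every
output with its checksum.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import PreprocessError, TrialDataset
from .simulate import GroundTruth, SimConfig, VolumeSeries
from .splits import Fold, SplitPlan

EVENT_COLUMNS = ["subject", "run", "trial", "onset", "category", "language"]


class ParseError(ValueError):
    pass


@dataclass
class RunManifest:
    seeds: Dict[str, int] = field(default_factory=dict)
    config_checksum: str = ""
    outputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256
    package_version: str = ""
    created: str = ""

    def add(self, path: Path) -> None:
        self.outputs[str(path)] = sha256_file(path)

    def write(self, path: Path, force: bool = False) -> None:
        self.created = time.strftime("%Y-%m-%dT%H:%M:%S")
        _check_overwrite(path, force)
        path.write_text(json.dumps(asdict(self), indent=2))


def sha256_file(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def sha256_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _check_overwrite(path: Path, force: bool) -> None:
    if Path(path).exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")


def write_nifti(volume: np.ndarray, path: Path, force: bool = False) -> None:
    _check_overwrite(path, force)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine=np.eye(4))
    nib.save(img, str(path))


def read_nifti(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_events(events: pd.DataFrame, path: Path, force: bool = False) -> None:
    _check_overwrite(path, force)
    events.to_csv(path, sep="\t", index=False)


def read_events(path: Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ParseError(f"events file {path} missing column(s): {', '.join(missing)}")
    return events


def write_simulation(
    series: Dict[tuple, VolumeSeries],
    events: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
    outdir: Path,
    force: bool = False,
) -> RunManifest:
    """Write a simulated dataset: per-run NIfTI, mask, events, ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from fmrileak import __version__

    manifest = RunManifest(
        seeds={"master": config.seed}, package_version=__version__
    )
    for (subject, run), vs in sorted(series.items()):
        path = outdir / f"sub-{subject:02d}_run-{run:02d}_bold.nii.gz"
        _check_overwrite(path, force)
        # NIfTI stores (x, y, z, t); series use (t, x, y, z)
        img = nib.Nifti1Image(
            np.moveaxis(vs.data, 0, -1).astype(np.float32), affine=np.eye(4)
        )
        nib.save(img, str(path))
        manifest.add(path)
    mask_path = outdir / "gray_mask.nii.gz"
    write_nifti(truth.gray_mask.astype(np.float32), mask_path, force=force)
    manifest.add(mask_path)
    sig_path = outdir / "signal_mask.nii.gz"
    write_nifti(truth.signal_voxel_mask.astype(np.float32), sig_path, force=force)
    manifest.add(sig_path)
    ev_path = outdir / "events.tsv"
    write_events(events, ev_path, force=force)
    manifest.add(ev_path)
    gt_path = outdir / "ground_truth.json"
    _check_overwrite(gt_path, force)
    gt_path.write_text(
        json.dumps(
            {
                "realized_sigmas": truth.realized_sigmas,
                "n_signal_voxels": int(truth.signal_voxel_mask.sum()),
                "shared_pattern_checksum": sha256_array(truth.shared_pattern),
                "config": _config_dict(config),
            },
            indent=2,
        )
    )
    manifest.add(gt_path)
    manifest.config_checksum = hashlib.sha256(
        json.dumps(_config_dict(config), sort_keys=True).encode()
    ).hexdigest()
    manifest.write(outdir / "manifest.json", force=force)
    return manifest


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def read_simulation(indir: Path):
    """Load volumes + events + mask written by :func:`write_simulation`."""
    indir = Path(indir)
    events = read_events(indir / "events.tsv")
    mask = read_nifti(indir / "gray_mask.nii.gz") > 0.5
    tr = 1.0
    gt_path = indir / "ground_truth.json"
    if gt_path.exists():
        tr = float(json.loads(gt_path.read_text())["config"].get("tr", 1.0))
    series = {}
    for path in sorted(indir.glob("sub-*_run-*_bold.nii.gz")):
        parts = path.name.split("_")
        subject = int(parts[0].split("-")[1])
        run = int(parts[1].split("-")[1])
        data = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float32)
        if data.shape[:3] != mask.shape:
            raise PreprocessError(
                f"{path.name}: spatial shape {data.shape[:3]} != mask {mask.shape}"
            )
        # NIfTI stores (x, y, z, t); series use (t, x, y, z)
        series[(subject, run)] = VolumeSeries(
            data=np.moveaxis(data, -1, 0), tr=tr, subject_id=subject, run_id=run
        )
    return series, events, mask


def write_trial_dataset(dataset: TrialDataset, path: Path, force: bool = False) -> None:
    """Bundle features as .npz with a JSON sidecar (form, window, tr, mask)."""
    path = Path(path)
    _check_overwrite(path, force)
    sidecar = path.with_suffix(path.suffix + ".json")
    _check_overwrite(sidecar, force)
    np.savez_compressed(
        path,
        features=dataset.features,
        labels=dataset.labels,
        subject=dataset.meta["subject"].to_numpy(),
        run=dataset.meta["run"].to_numpy(),
        trial=dataset.meta["trial"].to_numpy(),
        mask=dataset.mask,
    )
    sidecar.write_text(
        json.dumps(
            {
                "form": dataset.form,
                "window": list(dataset.window),
                "tr": dataset.tr,
                "mask_checksum": sha256_array(dataset.mask.astype(np.uint8)),
                "n_trials": dataset.n_trials,
                "degenerate_volumes": dataset.degenerate_volumes,
            },
            indent=2,
        )
    )


def read_trial_dataset(path: Path) -> TrialDataset:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise ParseError(f"missing sidecar {sidecar}")
    meta_info = json.loads(sidecar.read_text())
    with np.load(path) as bundle:
        mask = bundle["mask"]
        if sha256_array(mask.astype(np.uint8)) != meta_info["mask_checksum"]:
            import warnings

            warnings.warn(f"mask checksum mismatch for {path}")
        ds = TrialDataset(
            features=bundle["features"],
            labels=bundle["labels"],
            meta=pd.DataFrame(
                {
                    "subject": bundle["subject"],
                    "run": bundle["run"],
                    "trial": bundle["trial"],
                }
            ),
            mask=mask.astype(bool),
            form=meta_info["form"],
            window=tuple(meta_info["window"]),
            tr=meta_info["tr"],
            degenerate_volumes=meta_info.get("degenerate_volumes", 0),
        )
    return ds


def write_split_plan(plan: SplitPlan, path: Path, force: bool = False) -> None:
    _check_overwrite(path, force)
    Path(path).write_text(
        json.dumps(
            {
                "unit": plan.unit,
                "seed": plan.seed,
                "folds": [
                    {
                        "train": f.train.tolist(),
                        "valid": f.valid.tolist(),
                        "test": f.test.tolist(),
                    }
                    for f in plan.folds
                ],
            }
        )
    )


def read_split_plan(path: Path) -> SplitPlan:
    d = json.loads(Path(path).read_text())
    folds = [
        Fold(
            train=np.array(f["train"], dtype=int),
            valid=np.array(f["valid"], dtype=int),
            test=np.array(f["test"], dtype=int),
        )
        for f in d["folds"]
    ]
    return SplitPlan(unit=d["unit"], folds=folds, seed=d["seed"])


def write_report(report: pd.DataFrame, path: Path, force: bool = False) -> None:
    """Accuracy/significance table as TSV plus a JSON with full vectors."""
    path = Path(path)
    _check_overwrite(path, force)
    cols = ["split", "classifier", "mean_accuracy", "p_value", "marker"]
    report[cols].to_csv(path, sep="\t", index=False, float_format="%.4f")
    json_path = path.with_suffix(".json")
    _check_overwrite(json_path, force)
    json_path.write_text(report.to_json(orient="records", indent=2))


def write_linear_model(model, path: Path, force: bool = False) -> None:
    """Serialize a fitted linear decoder as JSON.

    Stores family, selected voxel indices, the tuned regularization
    strength and the hyperplane (coefficients + intercept) — everything
    needed to rebuild the decision function.
    """
    from .models import LINEAR_FAMILIES, ModelError

    if model.family not in LINEAR_FAMILIES:
        raise ModelError(f"{model.family} is not a linear family")
    path = Path(path)
    _check_overwrite(path, force)
    est = model.estimator
    path.write_text(
        json.dumps(
            {
                "family": model.family,
                "selected_voxels": model.selected_voxels.tolist(),
                "C": model.best_param,
                "coef": est.coef_.tolist(),
                "intercept": est.intercept_.tolist(),
            }
        )
    )


def read_linear_model(path: Path):
    """Rebuild a serialized linear decoder (decision function only)."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.svm import LinearSVC

    from .models import TrainedModel

    d = json.loads(Path(path).read_text())
    est = LogisticRegression() if d["family"] == "plr" else LinearSVC()
    est.coef_ = np.array(d["coef"])
    est.intercept_ = np.array(d["intercept"])
    est.classes_ = np.array([0, 1])
    return TrainedModel(
        family=d["family"],
        estimator=est,
        selected_voxels=np.array(d["selected_voxels"], dtype=int),
        best_param=d["C"],
    )


def write_network_checkpoint(model, path: Path, force: bool = False) -> None:
    """Network weights as .npz plus a JSON sidecar with the history."""
    from .models import NETWORK_FAMILIES, ModelError

    if model.family not in NETWORK_FAMILIES:
        raise ModelError(f"{model.family} is not a network family")
    path = Path(path)
    _check_overwrite(path, force)
    sidecar = path.with_suffix(path.suffix + ".json")
    _check_overwrite(sidecar, force)
    params = model.estimator.parameters()
    np.savez_compressed(
        path, **{f"param_{i}": p.value for i, p in enumerate(params)}
    )
    sidecar.write_text(
        json.dumps({"family": model.family, "history": model.history})
    )


def load_network_checkpoint(model, path: Path) -> None:
    """Restore weights into a network of the same architecture, in place."""
    params = model.estimator.parameters()
    with np.load(Path(path)) as bundle:
        if len(bundle.files) != len(params):
            raise ParseError(
                f"checkpoint has {len(bundle.files)} arrays, "
                f"model expects {len(params)}"
            )
        for i, p in enumerate(params):
            p.value[...] = bundle[f"param_{i}"]
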