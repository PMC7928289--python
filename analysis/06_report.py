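"""Full split x classifier report at desk scale.

Evaluates all four decoder families (PLR, SVM, M2DCNN, 3DCNN) under the
three split strategies on one small simulated dataset, with a per-split
permutation chance level (PLR baseline, 20 relabelings), and writes the
twelve-row accuracy/significance table. The networks train with a
shortened schedule (60 epochs) appropriate to the 200-trial dataset;
the whole grid takes ~25 minutes on one core.
"""

from pathlib import Path

from fmrileak.evaluate import evaluate_grid
from fmrileak.experiments import calibration_regime
from fmrileak.io import write_report
from fmrileak.models import ModelConfig
from fmrileak.preprocess import simulate_trial_dataset
from fmrileak.splits import plan_by_name

ROOT = Path(__file__).resolve().parents[1]
SEED = 11


def main() -> None:
    config = calibration_regime()
    ds_box, _ = simulate_trial_dataset(config, seed=SEED, average=False)
    from fmrileak.preprocess import average_boxcars

    ds_avg = average_boxcars(ds_box)
    plans = {
        name: plan_by_name(name, ds_avg.meta, seed=SEED)
        for name in ("loso", "session", "sample")
    }
    configs = {
        "plr": ModelConfig(family="plr", n_selected_voxels=200),
        "svm": ModelConfig(family="svm", n_selected_voxels=200),
        "m2dcnn": ModelConfig(family="m2dcnn", epochs=60, batch_size=20),
        "cnn3d": ModelConfig(family="cnn3d", epochs=60, batch_size=20),
    }
    report = evaluate_grid(
        ds_avg, ds_box, plans, configs=configs, n_perm=20, seed=SEED
    )
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    write_report(report, results / "report.tsv", force=True)
    cols = ["split", "classifier", "mean_accuracy", "p_value", "marker"]
    print(report[cols].to_string(index=False,
                                 float_format=lambda v: f"{v:.4f}"))
    print(f"\nwrote {results / 'report.tsv'}")


if __name__ == "__main__":
    main()
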