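"""The central experiment: decoding accuracy versus split leakage.

Runs the PLR baseline under the three split strategies on three
independently simulated datasets (subject variability dominating the
category signal, temporally correlated noise) and tabulates the mean
accuracies. Finding to verify: accuracy rises monotonically from
leave-one-subject-out (chance) through session shuffle to sample shuffle,
i.e. apparent accuracy tracks the amount of train/test dependence, not
decoder quality.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fmrileak.experiments import leakage_ordering_experiment

ROOT = Path(__file__).resolve().parents[1]
SEEDS = [11, 12, 13]


def main() -> None:
    res = leakage_ordering_experiment(seeds=SEEDS)
    rows = [
        {
            "split": split,
            **{f"seed_{s}": acc for s, acc in zip(SEEDS, accs)},
            "mean_accuracy": float(np.mean(accs)),
        }
        for split, accs in res.items()
    ]
    table = pd.DataFrame(rows)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    table.to_csv(results / "leakage_ordering.tsv", sep="\t",
                 index=False, float_format="%.4f")

    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    means = {r["split"]: r["mean_accuracy"] for r in rows}
    ordered = means["loso"] <= means["session"] <= means["sample"]
    print(f"\nloso={means['loso']:.3f}  session={means['session']:.3f}  "
          f"sample={means['sample']:.3f}")
    print("finding:", "accuracy increases with allowed leakage "
          "(loso <= session <= sample)" if ordered else
          "ordering NOT observed — inspect per-seed table")


if __name__ == "__main__":
    main()
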