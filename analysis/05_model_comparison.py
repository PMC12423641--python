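"""Compare classification performance across model families over time.

Two-way repeated-measures ANOVA (model x time, subject = fold) on the
post-injection accuracy tables produced by script 03, with Tukey-adjusted
pairwise model contrasts when the model main effect is significant.
"""

import pickle
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np
import pandas as pd

from common import RESULTS, SCRATCH, study_config
from fusimap.evaluation import compare_models_over_time


def main() -> None:
    cfg = study_config()
    with open(SCRATCH / "fold_results.pkl", "rb") as fh:
        metrics = pickle.load(fh)
    if len(metrics) < 2:
        print("need at least two model families; run 03 (optionally --with-vit)")
        return

    inj_window = int(cfg.synth.injection_s) // cfg.window_frames
    common = set.intersection(
        *({m.window_index for m in folds[0]} for folds in metrics.values())
    )
    common = sorted(w for w in common if w >= inj_window)
    acc = {
        kind: np.array(
            [
                [next(m.accuracy for m in fold if m.window_index == w) for w in common]
                for fold in folds
            ]
        )
        for kind, folds in metrics.items()
    }
    res = compare_models_over_time(acc)
    rows = [
        {"effect": eff, "F": float(np.asarray(res[eff]["F"])), "p": float(np.asarray(res[eff]["p"]))}
        for eff in ("model", "time", "model:time")
    ]
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "model_comparison.csv", index=False)
    print(df.to_string(index=False))
    if res["tukey"]:
        for pair, vals in res["tukey"].items():
            print(f"{pair[0]} vs {pair[1]}: mean diff {100 * vals['mean_diff']:.2f}%, "
                  f"p = {vals['p']:.3g}")
    else:
        print("model main effect not significant; no post-hoc contrasts")


if __name__ == "__main__":
    main()
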