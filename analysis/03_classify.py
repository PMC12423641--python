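"""Train and evaluate the model families over sliding 1-minute windows.

For each of 3 random folds: the CNN (and optionally a reduced ViT) is
trained on the final 5 post-injection minutes and tested over the whole
session; the linear SVM is refit per 1-minute post-injection interval.
Writes tidy per-fold metrics and cross-fold summaries to results/, and
the per-fold mean saliency maps to scratch/ for script 04.

Usage: python analysis/03_classify.py [--with-vit]
"""

import argparse
import pickle
import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import RESULTS, SCRATCH, study_config
from fusimap import io as fio
from fusimap.evaluation import aggregate_folds, make_folds
from fusimap.pipeline import _metrics_tidy, run_fold, stage_seed


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--with-vit", action="store_true")
    args = parser.parse_args()
    models = ("cnn", "svm", "vit") if args.with_vit else ("cnn", "svm")

    cfg = study_config(models=models)
    cohort = fio.load_cohort(SCRATCH / "cohort_registered")
    by_id = {s.animal_id: s for s in cohort}
    folds = make_folds(cohort, n_folds=cfg.n_folds, seed=stage_seed(cfg.seed, 1))

    all_results = {}
    for kind in models:
        t0 = time.time()
        results = [
            run_fold(kind, f, by_id, cfg, seed=stage_seed(cfg.seed, 10 + f.fold_id))
            for f in folds
        ]
        all_results[kind] = results
        _metrics_tidy(kind, [r["metrics"] for r in results]).to_csv(
            RESULTS / f"metrics_{kind}.csv", index=False
        )
        summary = aggregate_folds([r["metrics"] for r in results])
        summary.to_csv(RESULTS / f"metrics_{kind}_summary.csv", index=False)
        for r in results:
            fio.save_map(r["mean_map"], SCRATCH / "maps" / f"{kind}_fold{r['fold_id']}.tif")
        peak = summary.loc[summary["accuracy_mean"].idxmax()]
        print(
            f"{kind}: {time.time() - t0:.0f}s; peak accuracy "
            f"{peak['accuracy_mean']:.3f} ± {peak['accuracy_sd']:.3f} "
            f"in window {int(peak['window_index'])} "
            f"(minute {int(peak['window_index'])}-{int(peak['window_index']) + 1})"
        )

    with open(SCRATCH / "fold_results.pkl", "wb") as fh:
        pickle.dump({k: [r["metrics"] for r in v] for k, v in all_results.items()}, fh)


if __name__ == "__main__":
    main()
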