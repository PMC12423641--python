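"""From mean saliency maps to data-driven regions and %CBV statistics.

Averages the per-fold maps of each method, upsamples to image size,
thresholds the top 15% of pixels, scores the resulting mask against the
planted ground truth (Dice), tracks %-change pD inside vs outside the
region for every animal, and runs the region x time repeated-measures
ANOVA separately for the drug and control groups.  Also runs the
threshold-fraction sensitivity sweep.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np
import pandas as pd
import tifffile

from common import RESULTS, SCRATCH, study_config
from fusimap import io as fio
from fusimap.containers import SaliencyMap
from fusimap.region_stats import (
    dice,
    percent_change_series,
    region_time_anova,
    sensitivity_sweep,
    threshold_top_fraction,
)
from fusimap.saliency import mean_map_over_time, upsample_bilinear


def main() -> None:
    cfg = study_config()
    cohort = fio.load_cohort(SCRATCH / "cohort_registered")
    truth_mask = tifffile.imread(SCRATCH / "truth" / "truth_mask.tif") > 0
    shape = cohort[0].shape

    anova_rows, cbv_rows, sweep_rows = [], [], []
    for kind in ("cnn", "svm"):
        fold_maps = []
        for p in sorted((SCRATCH / "maps").glob(f"{kind}_fold*.tif")):
            fold_maps.append(
                SaliencyMap(
                    "drug", tifffile.imread(p).astype(float),
                    "cam" if kind == "cnn" else "svm_weights",
                )
            )
        if not fold_maps:
            print(f"no maps for {kind}; run 03 first")
            continue
        mean_map = mean_map_over_time(fold_maps)
        if mean_map.grid.shape != shape:
            mean_map = upsample_bilinear(mean_map, shape)
        mask = threshold_top_fraction(mean_map, cfg.threshold_fraction)
        fio.save_mask(mask, SCRATCH / "maps" / f"mask_{kind}.tif")
        d = dice(mask.mask, truth_mask)
        chance = 2 * 0.15 * truth_mask.mean() / (0.15 + truth_mask.mean())
        print(f"{kind}: Dice vs planted truth {d:.3f} (chance {chance:.3f})")

        cbvs = [percent_change_series(s, mask) for s in cohort]
        for c in cbvs:
            cbv_rows.append(
                {
                    "model": kind,
                    "animal_id": c.animal_id,
                    "group": c.group,
                    "final_in_pct": float(c.in_region[-60:].mean()),
                    "final_out_pct": float(c.out_region[-60:].mean()),
                }
            )
        for group in ("drug", "control"):
            sub = [c for c in cbvs if c.group == group]
            res = region_time_anova(sub, window_frames=cfg.window_frames)
            for effect, vals in res.items():
                anova_rows.append({"model": kind, "group": group, "effect": effect, **vals})
            print(
                f"  {group}: region x time interaction "
                f"F={res['region:time']['F']:.2f}, p={res['region:time']['p']:.2g}"
            )

        drug = [s for s in cohort if s.group == "drug"]
        for entry in sensitivity_sweep(mean_map, drug, [0.05, 0.10, 0.15, 0.25, 0.35]):
            sweep_rows.append(
                {
                    "model": kind,
                    "fraction": entry["fraction"],
                    "final_in_pct": entry["final_in_pct"],
                    "final_out_pct": entry["final_out_pct"],
                    "divergence_pct": entry["divergence_pct"],
                }
            )

    pd.DataFrame(cbv_rows).to_csv(RESULTS / "cbv_endpoints.csv", index=False)
    pd.DataFrame(anova_rows).to_csv(RESULTS / "region_anova.csv", index=False)
    pd.DataFrame(sweep_rows).to_csv(RESULTS / "threshold_sensitivity.csv", index=False)
    drug_rows = [r for r in cbv_rows if r["group"] == "drug" and r["model"] == "cnn"]
    if drug_rows:
        fi = np.mean([r["final_in_pct"] for r in drug_rows])
        fo = np.mean([r["final_out_pct"] for r in drug_rows])
        print(f"cnn drug group, final minute: identified {fi:.2f}% vs non-identified {fo:.2f}%")


if __name__ == "__main__":
    main()
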