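"""End-to-end orchestration: simulate -> preprocess -> train -> evaluate
-> saliency -> regions, with seeded stages and a provenance manifest.

One root seed fans out to per-stage seeds through a counter scheme
(``stage_seed(root, i)``), so each stage is individually reproducible and
stages stay decoupled.  ``run_experiment`` executes the full chain for the
requested model families and writes tidy CSV metrics, mean saliency maps,
region masks, %CBV series, ANOVA tables and a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .classifiers import (
    DRUG_CLASS,
    final_minutes_window,
    normalized_frames,
    predict_scores,
    train_model,
    train_svm_per_window,
)
from .containers import PDFrameSeries, SaliencyMap
from .evaluation import (
    FoldSpec,
    aggregate_folds,
    compare_models_over_time,
    make_folds,
    window_metrics,
)
from .nn import CNNSpec, ViTSpec, build_cnn, build_vit
from .preprocess import build_reference, preprocess_series
from .region_stats import (
    percent_change_series,
    region_time_anova,
    threshold_top_fraction,
)
from .saliency import (
    mean_map_over_time,
    model_maps_over_session,
    svm_weight_map,
    upsample_bilinear,
)
from .synthdata import SynthConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "stage_seed", "run_experiment", "local_grid_search"]


def stage_seed(root: int, index: int) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    return int(np.random.SeedSequence([root, index]).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    """All knobs of one experiment run, seeded from a single root seed."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    models: Tuple[str, ...] = ("cnn", "svm", "vit")
    cnn: CNNSpec = field(default_factory=CNNSpec)
    vit: ViTSpec = field(default_factory=ViTSpec)
    n_folds: int = 10
    window_frames: int = 60
    threshold_fraction: float = 0.15
    train_minutes: float = 5.0
    train_stride: int = 1
    eval_stride: int = 1
    epochs: Optional[int] = None  # None -> per-spec default
    svm_C: float = 1.0
    reference_start_s: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.models:
            if m not in ("cnn", "svm", "vit"):
                raise ValueError(f"unknown model family {m!r}")
        if not (0 < self.threshold_fraction < 1):
            raise ValueError("threshold_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        cnn = CNNSpec(**raw.pop("cnn", {}))
        vit = ViTSpec(**raw.pop("vit", {}))
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(synth=synth, cnn=cnn, vit=vit, **raw)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        return d


def preprocess_cohort(
    cohort: Sequence[PDFrameSeries], cfg: RunConfig
) -> Tuple[List[PDFrameSeries], object]:
    """Register the whole cohort to a common reference (first animal)."""
    ref_series = cohort[0]
    start = int(round(cfg.reference_start_s * ref_series.frame_rate_hz))
    reference = build_reference(ref_series, start, min(10, ref_series.n_frames - start))
    processed = [preprocess_series(s, reference) for s in cohort]
    return processed, reference


def _build_model(kind: str, cfg: RunConfig, shape: Tuple[int, int], seed: int):
    if kind == "cnn":
        return build_cnn(cfg.cnn, shape, seed=seed)
    if kind == "vit":
        return build_vit(cfg.vit, shape, seed=seed)
    raise ValueError(kind)


def run_fold(
    kind: str,
    fold: FoldSpec,
    cohort: Dict[str, PDFrameSeries],
    cfg: RunConfig,
    seed: int,
) -> Dict[str, object]:
    """Train + evaluate + saliency for one model family on one fold.

    Returns per-window metrics over the evaluated span, the fold-mean raw
    saliency map (feature/patch resolution for cnn/vit, pixel resolution
    for svm), and the loss trace where applicable.
    """
    train = [cohort[a] for a in fold.train_animals]
    test = [cohort[a] for a in fold.test_animals]
    s0 = train[0]
    inj, n = s0.injection_index, s0.n_frames
    result: Dict[str, object] = {"fold_id": fold.fold_id, "kind": kind}

    if kind in ("cnn", "vit"):
        window = final_minutes_window(s0, cfg.train_minutes)
        model = _build_model(kind, cfg, s0.shape, seed=seed)
        model, trace = train_model(
            model, train, window, seed=seed, epochs=cfg.epochs, frame_stride=cfg.train_stride
        )
        result["loss_trace"] = trace
        idx_all, yt_all, yp_all, ys_all = [], [], [], []
        for s in test:
            frames = normalized_frames(s)[:: cfg.eval_stride]
            scores = predict_scores(model, frames)
            idx = np.arange(0, s.n_frames, cfg.eval_stride)
            idx_all.append(idx)
            yt_all.append(np.full(len(idx), 1 if s.group == "drug" else 0))
            yp_all.append(np.argmax(scores, axis=1))
            ys_all.append(scores[:, DRUG_CLASS] - scores[:, 1 - DRUG_CLASS])
        metrics = window_metrics(
            np.concatenate(idx_all),
            np.concatenate(yt_all),
            np.concatenate(yp_all),
            np.concatenate(ys_all),
            window_frames=cfg.window_frames,
            start=0,
            end=n,
        )
        saliency_kind = "cam" if kind == "cnn" else "attention"
        per_animal = [
            model_maps_over_session(
                model, s, saliency_kind, window_frames=cfg.window_frames, span=(inj, n)
            )
            for s in test
        ]
        # mean across test animals per window, then across windows
        window_means = [
            mean_map_over_time([maps[w] for maps in per_animal])
            for w in range(len(per_animal[0]))
        ]
        result["mean_map"] = mean_map_over_time(window_means)
    elif kind == "svm":
        models = train_svm_per_window(
            train,
            window_length_frames=cfg.window_frames,
            span=(inj, n),
            frame_stride=cfg.train_stride,
            C=cfg.svm_C,
        )
        idx_all, yt_all, yp_all, ys_all = [], [], [], []
        for m in models:
            for s in test:
                frames = normalized_frames(s)[m.start_frame : m.end_frame : cfg.eval_stride]
                dec = m.decision_function(frames.reshape(len(frames), -1))
                idx_all.append(np.arange(m.start_frame, m.end_frame, cfg.eval_stride))
                yt_all.append(np.full(len(dec), 1 if s.group == "drug" else 0))
                yp_all.append((dec > 0).astype(int))
                ys_all.append(dec)
        metrics = window_metrics(
            np.concatenate(idx_all),
            np.concatenate(yt_all),
            np.concatenate(yp_all),
            np.concatenate(ys_all),
            window_frames=cfg.window_frames,
            start=inj,
            end=n,
        )
        result["mean_map"] = mean_map_over_time(svm_weight_map(models))
    else:
        raise ValueError(kind)
    result["metrics"] = metrics
    return result


def _metrics_tidy(kind: str, per_fold: List[List]) -> pd.DataFrame:
    rows = []
    for fold_idx, fold in enumerate(per_fold):
        for m in fold:
            for name in ("accuracy", "precision", "recall", "f1", "auc"):
                rows.append(
                    {
                        "model": kind,
                        "fold": fold_idx,
                        "window": m.window_index,
                        "metric": name,
                        "value": getattr(m, name),
                    }
                )
    return pd.DataFrame(rows)


def run_experiment(cfg: RunConfig, outdir: Path) -> Dict[str, object]:
    """Execute the full analysis chain and persist all outputs.

    Stages: simulate, preprocess, folds, per-model train/evaluate/saliency,
    region statistics, model comparison.  Any stage failure aborts with
    the stage name; outputs of completed stages stay on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "config": cfg.to_dict(),
        "stages": [],
        "outputs": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def _done(stage: str, *files: Path) -> None:
        manifest["stages"].append(stage)
        manifest["outputs"].extend(str(f) for f in files)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    stage = "simulate"
    try:
        cohort, truth = simulate_cohort(
            dataclasses.replace(cfg.synth, seed=stage_seed(cfg.seed, 0))
        )
        fio.save_ground_truth(truth, outdir / "truth")
        _done(stage, outdir / "truth")

        stage = "preprocess"
        processed, reference = preprocess_cohort(cohort, cfg)
        by_id = {s.animal_id: s for s in processed}
        _done(stage)

        stage = "folds"
        folds = make_folds(processed, n_folds=cfg.n_folds, seed=stage_seed(cfg.seed, 1))
        _done(stage)

        stage = "train_evaluate"
        fold_results: Dict[str, List[Dict]] = {}
        for kind in cfg.models:
            fold_results[kind] = [
                run_fold(kind, f, by_id, cfg, seed=stage_seed(cfg.seed, 10 + f.fold_id))
                for f in folds
            ]
        metric_files = []
        for kind in cfg.models:
            df = _metrics_tidy(kind, [r["metrics"] for r in fold_results[kind]])
            p = outdir / f"metrics_{kind}.csv"
            df.to_csv(p, index=False)
            metric_files.append(p)
            summary = aggregate_folds([r["metrics"] for r in fold_results[kind]])
            sp = outdir / f"metrics_{kind}_summary.csv"
            summary.to_csv(sp, index=False)
            metric_files.append(sp)
        _done(stage, *metric_files)

        stage = "saliency"
        shape = processed[0].shape
        mean_maps: Dict[str, SaliencyMap] = {}
        map_files = []
        for kind in cfg.models:
            raw = mean_map_over_time([r["mean_map"] for r in fold_results[kind]])
            mean_maps[kind] = (
                raw if raw.grid.shape == shape else upsample_bilinear(raw, shape)
            )
            p = outdir / f"mean_map_{kind}.tif"
            fio.save_map(mean_maps[kind], p)
            map_files.append(p)
        _done(stage, *map_files)

        stage = "regions"
        region_rows = []
        anova_rows = []
        mask_files = []
        masks = {}
        for kind in cfg.models:
            mask = threshold_top_fraction(mean_maps[kind], cfg.threshold_fraction)
            masks[kind] = mask
            p = outdir / f"mask_{kind}.tif"
            fio.save_mask(mask, p)
            mask_files.append(p)
            cbvs = [percent_change_series(s, mask) for s in processed]
            for c in cbvs:
                for t, (vi, vo) in enumerate(zip(c.in_region, c.out_region)):
                    region_rows.append(
                        {
                            "model": kind,
                            "animal_id": c.animal_id,
                            "group": c.group,
                            "frame": t,
                            "in_pct": vi,
                            "out_pct": vo,
                        }
                    )
            for group in ("drug", "control"):
                sub = [c for c in cbvs if c.group == group]
                res = region_time_anova(sub, window_frames=cfg.window_frames)
                for effect, vals in res.items():
                    anova_rows.append(
                        {"model": kind, "group": group, "effect": effect, **vals}
                    )
        cbv_path = outdir / "cbv_series.csv"
        pd.DataFrame(region_rows).to_csv(cbv_path, index=False)
        anova_path = outdir / "region_anova.csv"
        pd.DataFrame(anova_rows).to_csv(anova_path, index=False)
        _done(stage, cbv_path, anova_path, *mask_files)

        stage = "compare_models"
        comparison = None
        if len(cfg.models) >= 2:
            # restrict to the post-injection window grid shared by all models
            common = set.intersection(
                *(
                    {m.window_index for m in fold_results[k][0]["metrics"]}
                    for k in cfg.models
                )
            )
            inj_window = processed[0].injection_index // cfg.window_frames
            common = sorted(w for w in common if w >= inj_window)
            acc = {}
            for kind in cfg.models:
                acc[kind] = np.array(
                    [
                        [
                            next(
                                m.accuracy
                                for m in r["metrics"]
                                if m.window_index == w
                            )
                            for w in common
                        ]
                        for r in fold_results[kind]
                    ]
                )
            comparison = compare_models_over_time(acc)
            rows = []
            for eff in ("model", "time", "model:time"):
                rows.append(
                    {
                        "effect": eff,
                        "F": float(np.asarray(comparison[eff]["F"])),
                        "p": float(np.asarray(comparison[eff]["p"])),
                    }
                )
            (outdir / "model_comparison.csv").write_text(
                pd.DataFrame(rows).to_csv(index=False)
            )
        _done(stage, outdir / "model_comparison.csv" if comparison else outdir)
    except Exception:
        logger.exception("stage %r failed; partial outputs persisted in %s", stage, outdir)
        raise

    return {
        "cohort": processed,
        "truth": truth,
        "reference": reference,
        "folds": folds,
        "fold_results": fold_results,
        "mean_maps": mean_maps,
        "masks": masks,
        "comparison": comparison,
        "manifest": manifest,
    }


def local_grid_search(
    grid: Dict[str, Sequence],
    evaluate: Callable[[Dict], float],
    evaluate_cv: Optional[Callable[[Dict], float]] = None,
    k_best: int = 15,
) -> Dict[str, object]:
    """Config-driven grid search replacing an external sweep service.

    ``evaluate`` scores one hyperparameter combination on a single
    held-out split (peak window accuracy); the ``k_best`` top combinations
    are re-scored with ``evaluate_cv`` (cross-validated peak accuracy,
    defaults to ``evaluate``) and the winner is the combination with the
    highest cross-validated peak accuracy.
    """
    names = sorted(grid)
    combos = [dict(zip(names, vals)) for vals in itertools.product(*(grid[n] for n in names))]
    if not combos:
        raise ValueError("empty grid")
    if k_best > len(combos):
        logger.warning("k_best=%d clipped to grid size %d", k_best, len(combos))
        k_best = len(combos)
    screened = sorted(
        ((evaluate(c), i) for i, c in enumerate(combos)), key=lambda t: (-t[0], t[1])
    )
    evaluate_cv = evaluate_cv or evaluate
    finalists = [(evaluate_cv(combos[i]), i) for _, i in screened[:k_best]]
    finalists.sort(key=lambda t: (-t[0], t[1]))
    best_score, best_idx = finalists[0]
    return {
        "ranked": [(combos[i], s) for s, i in screened],
        "finalists": [(combos[i], s) for s, i in finalists],
        "winner": combos[best_idx],
        "winner_score": best_score,
    }
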