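"""Cross-validated, sliding-window quantification of drug/control separation.

Folds are independent random animal-level splits at fixed per-class
training counts (ceil(n/2) per class: 5/10 drug and 7/13 control on the
standard cohort).  Within a fold, frame-level predictions from all test
animals are pooled into successive one-minute windows and the count-based
metrics (accuracy, precision, recall, F1, ROC-AUC) are computed per
window, then averaged pointwise across folds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .containers import PDFrameSeries, WindowMetrics
from .stats import rm_anova_two_way, tukey_pairwise

logger = logging.getLogger(__name__)

__all__ = [
    "FoldSpec",
    "make_folds",
    "window_metrics",
    "aggregate_folds",
    "compare_models_over_time",
]


@dataclass
class FoldSpec:
    fold_id: int
    train_animals: List[str]
    test_animals: List[str]

    def __post_init__(self) -> None:
        if set(self.train_animals) & set(self.test_animals):
            raise ValueError("train and test sets must be disjoint")


def make_folds(
    cohort: Sequence[PDFrameSeries],
    n_folds: int = 10,
    seed: int = 0,
    train_drug: int | None = None,
    train_control: int | None = None,
) -> List[FoldSpec]:
    """Independent random splits with fixed per-class training counts.

    Every animal lands in exactly one of train/test per fold; defaults put
    ceil(n/2) of each class in training.
    """
    drug = sorted(s.animal_id for s in cohort if s.group == "drug")
    control = sorted(s.animal_id for s in cohort if s.group == "control")
    if not drug or not control:
        raise ValueError("cohort must contain both classes")
    train_drug = train_drug if train_drug is not None else math.ceil(len(drug) / 2)
    train_control = (
        train_control if train_control is not None else math.ceil(len(control) / 2)
    )
    if not (0 < train_drug < len(drug)) or not (0 < train_control < len(control)):
        raise ValueError("training counts must leave at least one test animal per class")
    rng = np.random.default_rng(seed)
    folds = []
    for k in range(n_folds):
        tr_d = list(rng.choice(drug, size=train_drug, replace=False))
        tr_c = list(rng.choice(control, size=train_control, replace=False))
        train = sorted(tr_d + tr_c)
        test = sorted(set(drug + control) - set(train))
        folds.append(FoldSpec(fold_id=k, train_animals=train, test_animals=test))
    return folds


def _counts_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Tuple[float, float, float, float]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    acc = (tp + tn) / max(1, tp + tn + fp + fn)
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    rec = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return acc, prec, rec, f1


def window_metrics(
    frame_idx: np.ndarray,
    y_true: np.ndarray,
    y_pred: np.ndarray,
    y_score: np.ndarray,
    window_frames: int = 60,
    start: int = 0,
    end: int | None = None,
) -> List[WindowMetrics]:
    """Pool all frames of each successive window and score them.

    ``y_true``/``y_pred`` use 1 = drug, 0 = control; ``y_score`` is the
    continuous drug-class score used for the ROC-AUC.  Windows containing
    a single true class get AUC = NaN (recorded as missing, not 0.5).
    Window indices are absolute (``frame // window_frames``), so windows
    from evaluations over different spans line up on the session clock.
    """
    frame_idx = np.asarray(frame_idx)
    end = int(frame_idx.max()) + 1 if end is None else end
    out: List[WindowMetrics] = []
    for a in range(start, end - window_frames + 1, window_frames):
        w = a // window_frames
        sel = (frame_idx >= a) & (frame_idx < a + window_frames)
        if not sel.any():
            continue
        yt, yp, ys = y_true[sel], y_pred[sel], y_score[sel]
        acc, prec, rec, f1 = _counts_metrics(yt, yp)
        if len(np.unique(yt)) < 2:
            logger.info("window %d has a single class; AUC recorded missing", w)
            auc = float("nan")
        else:
            auc = float(roc_auc_score(yt, ys))
        out.append(
            WindowMetrics(
                window_index=w,
                accuracy=acc,
                precision=prec,
                recall=rec,
                f1=f1,
                auc=auc,
                n_frames=int(sel.sum()),
            )
        )
    return out


def aggregate_folds(per_fold: Sequence[Sequence[WindowMetrics]]) -> pd.DataFrame:
    """Pointwise mean and SD of each metric across folds.

    Missing AUCs are excluded pairwise; ``auc_n`` reports how many folds
    contributed per window.  With a single fold the SD columns are NaN.
    """
    if not per_fold:
        raise ValueError("no folds")
    grids = [tuple(m.window_index for m in fold) for fold in per_fold]
    if len(set(grids)) != 1:
        raise ValueError("inconsistent window grids across folds")
    rows = []
    names = ("accuracy", "precision", "recall", "f1", "auc")
    for j, widx in enumerate(grids[0]):
        row: Dict[str, float] = {"window_index": widx}
        for name in names:
            vals = np.array([getattr(fold[j], name) for fold in per_fold], dtype=float)
            ok = ~np.isnan(vals)
            row[f"{name}_mean"] = float(vals[ok].mean()) if ok.any() else float("nan")
            row[f"{name}_sd"] = (
                float(vals[ok].std(ddof=1)) if ok.sum() > 1 else float("nan")
            )
            if name == "auc":
                row["auc_n"] = int(ok.sum())
        row["n_frames"] = int(np.sum([fold[j].n_frames for fold in per_fold]))
        rows.append(row)
    return pd.DataFrame(rows)


def compare_models_over_time(
    accuracy: Dict[str, np.ndarray], alpha: float = 0.05
) -> Dict[str, object]:
    """Two-way repeated-measures comparison of model accuracies over time.

    ``accuracy`` maps model name to a (folds, windows) table restricted to
    the post-injection period; the fold is the repeated-measures subject.
    Returns the ANOVA effects (``model``, ``time``, ``model:time``) and,
    when the model main effect is significant, Tukey-adjusted pairwise
    differences of fold-level mean accuracies.
    """
    names = sorted(accuracy)
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    tables = [np.asarray(accuracy[n], dtype=float) for n in names]
    shape = tables[0].shape
    if any(t.shape != shape for t in tables):
        raise ValueError("all models must share the (folds, windows) grid")
    data = np.stack(tables, axis=1)  # (folds, models, windows)
    res = rm_anova_two_way(data)
    out: Dict[str, object] = {
        "model": res["A"],
        "time": res["B"],
        "model:time": res["A:B"],
        "models": names,
    }
    fold_means = np.stack([t.mean(axis=1) for t in tables], axis=1)
    if float(res["A"]["p"]) < alpha:
        out["tukey"] = tukey_pairwise(fold_means, names)
    else:
        out["tukey"] = None
    return out
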