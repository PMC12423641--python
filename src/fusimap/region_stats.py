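"""Data-driven regions and %CBV divergence statistics.

A mean saliency map is turned into an "identified region" by selecting
exactly the top ``round(fraction * n_pixels)`` pixels (fraction 0.15 by
default).  Per animal, the %-change pD signal relative to the minutes-3-5
baseline is tracked inside and outside that region, binned to one-minute
windows, and tested with a two-way repeated-measures ANOVA (region x
time, subject = animal) separately per group.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Sequence

import numpy as np

from .containers import CBVSeries, PDFrameSeries, RegionMask, SaliencyMap
from .stats import rm_anova_two_way

logger = logging.getLogger(__name__)

__all__ = [
    "threshold_top_fraction",
    "percent_change_series",
    "bin_cbv",
    "region_time_anova",
    "sensitivity_sweep",
    "dice",
]


def threshold_top_fraction(map_: SaliencyMap, fraction: float = 0.15) -> RegionMask:
    """Exactly the ``round(fraction * P)`` largest-valued pixels.

    Ties at the cutoff are broken by ascending flat index (stable sort),
    so the mask is deterministic; a constant map therefore selects the
    first k flat indices (warned).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    grid = map_.grid
    k = int(round(fraction * grid.size))
    if np.ptp(grid) == 0:
        logger.warning("constant saliency map: selecting the first %d pixels", k)
    order = np.argsort(-grid, axis=None, kind="stable")
    mask = np.zeros(grid.size, dtype=bool)
    mask[order[:k]] = True
    return RegionMask(mask=mask.reshape(grid.shape), fraction=fraction, source=map_.source)


def percent_change_series(series: PDFrameSeries, mask: RegionMask) -> CBVSeries:
    """Baseline-anchored %-change pD inside and outside the mask.

    ``in_region(t) = 100 * (m(t) - B) / B`` where ``m(t)`` is the
    mask-mean intensity and ``B`` its mean over the baseline window;
    analogously for the complement.
    """
    m = mask.mask
    if m.shape != series.shape:
        raise ValueError("mask shape must match frames")
    if not m.any() or m.all():
        raise ValueError("mask must be neither empty nor full")
    flat = series.frames.reshape(series.n_frames, -1)
    mean_in = flat[:, m.ravel()].mean(axis=1, dtype=np.float64)
    mean_out = flat[:, ~m.ravel()].mean(axis=1, dtype=np.float64)
    start, end = series.baseline_window
    out = []
    for mt in (mean_in, mean_out):
        b = float(mt[start:end].mean())
        if b == 0:
            raise ValueError("degenerate (zero) baseline")
        out.append(100.0 * (mt - b) / b)
    return CBVSeries(
        animal_id=series.animal_id,
        in_region=out[0],
        out_region=out[1],
        baseline_window=series.baseline_window,
        group=series.group,
    )


def bin_cbv(
    cbv: CBVSeries, window_frames: int = 60, start: int | None = None, end: int | None = None
) -> np.ndarray:
    """(2, n_bins) window means of the in/out series; trailing partial dropped."""
    n = len(cbv.in_region)
    start = 0 if start is None else start
    end = n if end is None else end
    n_bins = (end - start) // window_frames
    if n_bins < 1:
        raise ValueError("span shorter than one window")
    sl = slice(start, start + n_bins * window_frames)
    binned_in = cbv.in_region[sl].reshape(n_bins, window_frames).mean(axis=1)
    binned_out = cbv.out_region[sl].reshape(n_bins, window_frames).mean(axis=1)
    return np.stack([binned_in, binned_out])


def region_time_anova(
    cbv_list: Sequence[CBVSeries],
    window_frames: int = 60,
    start: int | None = None,
    end: int | None = None,
) -> Dict[str, Dict[str, float]]:
    """Two-way RM ANOVA (region x time, subject = animal) on binned %CBV.

    ``start``/``end`` default to the post-injection span (baseline end to
    series end).  Returns F/p/df for ``region``, ``time`` and
    ``region:time``.
    """
    if len(cbv_list) < 3:
        raise ValueError("need at least 3 animals for the repeated-measures ANOVA")
    s0 = cbv_list[0]
    start = s0.baseline_window[1] if start is None else start
    data = np.stack([bin_cbv(c, window_frames, start, end) for c in cbv_list])
    if np.any(~np.isfinite(data)):
        raise ValueError("missing cells in the region x time table")
    res = rm_anova_two_way(data)  # (animals, region, time)
    return {
        "region": {k: float(np.asarray(v)) for k, v in res["A"].items()},
        "time": {k: float(np.asarray(v)) for k, v in res["B"].items()},
        "region:time": {k: float(np.asarray(v)) for k, v in res["A:B"].items()},
    }


def sensitivity_sweep(
    mean_map: SaliencyMap,
    cohort: Sequence[PDFrameSeries],
    fractions: Sequence[float],
    window_frames: int = 60,
) -> List[Dict[str, object]]:
    """Repeat the threshold -> %CBV analysis for each threshold fraction.

    Per fraction, reports the mask and the end-of-session in/out %CBV
    divergence averaged over the given animals (typically one group).
    """
    out: List[Dict[str, object]] = []
    for f in fractions:
        mask = threshold_top_fraction(mean_map, f)
        cbvs = [percent_change_series(s, mask) for s in cohort]
        final_in = float(np.mean([c.in_region[-window_frames:].mean() for c in cbvs]))
        final_out = float(np.mean([c.out_region[-window_frames:].mean() for c in cbvs]))
        out.append(
            {
                "fraction": float(f),
                "mask": mask,
                "final_in_pct": final_in,
                "final_out_pct": final_out,
                "divergence_pct": final_in - final_out,
            }
        )
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom) if denom else 0.0
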