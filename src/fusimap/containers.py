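"""Core in-memory containers shared by every stage of the pipeline.

All image stacks are ``(T, rows, cols)`` float arrays of nonnegative
power-Doppler (pD) intensities in arbitrary units, acquired at a fixed
frame rate (1 frame/s by default).  Time is stored in frames; seconds are
derived through ``frame_rate_hz``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

GROUPS = ("drug", "control")


@dataclass
class PDFrameSeries:
    """One animal's pD stack with its group label and session timing.

    Parameters
    ----------
    animal_id : str
        Unique identifier within a cohort.
    group : {"drug", "control"}
        Pharmacological condition.
    frames : ndarray, shape (T, rows, cols)
        Nonnegative pD intensities.
    frame_rate_hz : float
        Acquisition rate; 1.0 for the standard protocol.
    injection_index : int
        Frame ordinal of the (saline or drug) injection.
    baseline_window : (int, int)
        Half-open frame interval ``[start, end)`` used as the %-change
        baseline; must end at or before the injection.
    """

    animal_id: str
    group: str
    frames: np.ndarray
    frame_rate_hz: float
    injection_index: int
    baseline_window: Tuple[int, int]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, rows, cols) stack")
        if self.frames.size and float(self.frames.min()) < 0:
            raise ValueError("pD intensities must be nonnegative")
        start, end = self.baseline_window
        if not (0 <= start < end <= self.injection_index):
            raise ValueError("baseline_window must lie inside the pre-injection period")
        if not self.injection_index < self.frames.shape[0]:
            raise ValueError("injection_index must fall inside the session")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> Tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    def with_frames(self, frames: np.ndarray) -> "PDFrameSeries":
        """Copy of this series with a replacement stack (same metadata)."""
        return PDFrameSeries(
            animal_id=self.animal_id,
            group=self.group,
            frames=frames,
            frame_rate_hz=self.frame_rate_hz,
            injection_index=self.injection_index,
            baseline_window=self.baseline_window,
        )


@dataclass
class ReferenceImage:
    """Fixed image every animal is registered to (mean of a short window)."""

    image: np.ndarray
    source_animal: str
    n_frames_averaged: int

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.n_frames_averaged < 1:
            raise ValueError("n_frames_averaged must be >= 1")
        if self.image.size and float(self.image.min()) < 0:
            raise ValueError("reference image must be nonnegative")


@dataclass
class SaliencyMap:
    """Nonnegative per-pixel (or per-cell) importance grid for one class."""

    class_label: str
    grid: np.ndarray
    source: str  # "cam" | "svm_weights" | "attention"
    window_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("saliency grid must be finite")
        if self.grid.size and float(self.grid.min()) < -1e-12:
            raise ValueError("saliency grid must be nonnegative")
        self.grid = np.clip(self.grid, 0.0, None)


@dataclass
class RegionMask:
    """Boolean pixel mask from top-fraction thresholding of a saliency map."""

    mask: np.ndarray
    fraction: float
    source: str = "cam"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (0.0 < self.fraction < 1.0):
            raise ValueError("fraction must lie in (0, 1)")

    @property
    def n_true(self) -> int:
        return int(self.mask.sum())


@dataclass
class GroundTruth:
    """Planted truth of a synthetic cohort: where and how strongly the drug acts."""

    effect_mask: np.ndarray
    effect_curve: np.ndarray  # per-frame multiplicative factor in (0, 1]

    def __post_init__(self) -> None:
        self.effect_mask = np.asarray(self.effect_mask, dtype=bool)
        self.effect_curve = np.asarray(self.effect_curve, dtype=float)
        if self.effect_curve.ndim != 1:
            raise ValueError("effect_curve must be 1-D (per frame)")
        if np.any(self.effect_curve <= 0) or np.any(self.effect_curve > 1 + 1e-12):
            raise ValueError("effect_curve values must lie in (0, 1]")
        frac = self.effect_mask.mean()
        if not (0.0 < frac < 1.0):
            raise ValueError("effect mask must be neither empty nor full")


@dataclass
class CBVSeries:
    """Baseline-anchored %-change pD trajectories inside/outside a mask."""

    animal_id: str
    in_region: np.ndarray
    out_region: np.ndarray
    baseline_window: Tuple[int, int]
    group: str = "drug"

    def __post_init__(self) -> None:
        self.in_region = np.asarray(self.in_region, dtype=float)
        self.out_region = np.asarray(self.out_region, dtype=float)
        if self.in_region.shape != self.out_region.shape:
            raise ValueError("in/out series must share a time axis")
        if not (np.all(np.isfinite(self.in_region)) and np.all(np.isfinite(self.out_region))):
            raise ValueError("CBV series must be finite")


@dataclass
class WindowMetrics:
    """Frame-level classification metrics pooled over one 1-minute window."""

    window_index: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float  # NaN when only one class is present in the window
    n_frames: int = 0

    def __post_init__(self) -> None:
        for name in ("accuracy", "precision", "recall", "f1"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (np.isnan(self.auc) or 0.0 <= self.auc <= 1.0):
            raise ValueError("auc must lie in [0, 1] or be NaN")
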