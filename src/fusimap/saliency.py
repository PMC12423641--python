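"""Importance maps: XGrad-CAM, attention rollout, SVM weight maps.

All three methods reduce a trained model to a nonnegative per-pixel (or
per-cell) importance grid for the drug class:

* **XGrad-CAM** weights each final-conv feature map ``A_k`` by
  ``w_k = sum_ij [dY_c/dA_k(i,j) * A_k(i,j) / sum_mn A_k(m,n)]`` and takes
  ``ReLU(sum_k w_k A_k)`` — the axiom-derived, activation-normalized
  gradient weighting.
* **Attention rollout** fuses each layer's head attentions (elementwise
  max by default), discards the weakest entries (discard ratio 0.9,
  sparing the class-token column), adds the residual identity, row-
  normalizes, and multiplies the processed matrices across layers; the
  class-token row, reshaped to the patch grid, is the map.
* **SVM weight maps** keep only the weight entries whose sign pushes
  toward the drug class (negative under the fitted drug = -1 convention),
  inverted to positive importance.

Raw CAM / rollout grids live at feature-map or patch resolution; they are
averaged at that resolution and bilinearly upsampled to image size last.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np
from skimage.transform import resize

from .containers import PDFrameSeries, SaliencyMap
from .classifiers import DRUG_CLASS, Model, WindowSVM, normalized_frames

EPS = 1e-8

__all__ = [
    "FeatureActivations",
    "xgrad_cam",
    "upsample_bilinear",
    "attention_rollout",
    "svm_weight_map",
    "mean_map_over_time",
    "model_maps_over_session",
]


@dataclass
class FeatureActivations:
    """Target-layer activations, their class-score gradients, and the score."""

    maps: np.ndarray  # (K, h, w)
    gradients: np.ndarray  # (K, h, w), dY_c/dA_k(i,j)
    class_score: float
    class_label: str = "drug"

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.gradients = np.asarray(self.gradients, dtype=float)
        if self.maps.shape != self.gradients.shape:
            raise ValueError("maps and gradients must be shape-aligned")
        if self.maps.ndim != 3 or self.maps[0].size == 0:
            raise ValueError("expected (K, h, w) activations with h*w > 0")


def xgrad_cam(acts: FeatureActivations) -> SaliencyMap:
    """Raw (h x w) XGrad-CAM localization map, before any upsampling.

    Channels whose activations sum to (numerically) zero get weight 0
    rather than a 0/0; the map is clamped at zero by the final ReLU.
    """
    A, g = acts.maps, acts.gradients
    denom = A.sum(axis=(1, 2))
    safe = np.where(np.abs(denom) < EPS, 1.0, denom)
    w = np.where(
        np.abs(denom) < EPS, 0.0, (g * A).sum(axis=(1, 2)) / safe
    )
    grid = np.maximum(0.0, np.tensordot(w, A, axes=(0, 0)))
    return SaliencyMap(class_label=acts.class_label, grid=grid, source="cam")


def upsample_bilinear(map_: SaliencyMap, target: Tuple[int, int]) -> SaliencyMap:
    """Bilinear upsampling to ``target`` (rows, cols).

    Uses half-pixel-center sampling (the resampling grid treats pixels as
    cells, not corner-aligned points).  Interpolation cannot leave the
    input's [min, max] range.
    """
    src = map_.grid
    if target[0] < src.shape[0] or target[1] < src.shape[1]:
        raise ValueError("target must be at least the source size")
    up = resize(src, target, order=1, mode="edge", anti_aliasing=False)
    up = np.clip(up, src.min(), src.max())
    return SaliencyMap(
        class_label=map_.class_label,
        grid=up,
        source=map_.source,
        window_index=map_.window_index,
    )


def _fuse_heads(mat: np.ndarray, fusion: str) -> np.ndarray:
    if mat.ndim == 2:
        return mat
    if mat.ndim != 3:
        raise ValueError("attention matrix must be (N, N) or (heads, N, N)")
    if fusion == "max":
        return mat.max(axis=0)
    if fusion == "mean":
        return mat.mean(axis=0)
    raise ValueError(f"unknown head fusion {fusion!r}")


def _process_layer(fused: np.ndarray, discard_ratio: float) -> np.ndarray:
    n = fused.shape[0]
    flat = fused.flatten()
    k = int(discard_ratio * flat.size)
    if k > 0:
        order = np.argsort(flat, kind="stable")  # ascending; ties by flat index
        drop = order[:k]
        drop = drop[drop % n != 0]  # spare the class-token column
        flat = flat.copy()
        flat[drop] = 0.0
        fused = flat.reshape(n, n)
    a = fused + np.eye(n)
    return a / a.sum(axis=1, keepdims=True)


def attention_rollout(
    attn_stack: Sequence[np.ndarray],
    discard_ratio: float = 0.9,
    fusion: str = "max",
    grid: Tuple[int, int] | None = None,
) -> SaliencyMap:
    """Roll per-layer attentions into a class-token-to-patch importance map.

    ``attn_stack`` holds one matrix per layer, either already head-fused
    (N, N) or per-head (heads, N, N); N counts the class token plus the
    patches.  Matrices must be row-stochastic.  The result is the class-
    token row over patch tokens, reshaped to ``grid`` when given (else
    returned as a flat (1, N-1) grid).
    """
    if not (0.0 <= discard_ratio < 1.0):
        raise ValueError("discard_ratio must lie in [0, 1)")
    if not len(attn_stack):
        raise ValueError("empty attention stack")
    rollout: np.ndarray | None = None
    n = None
    for mat in attn_stack:
        mat = np.asarray(mat, dtype=float)
        if mat.shape[-1] != mat.shape[-2]:
            raise ValueError("attention matrices must be square")
        if np.any(mat < -1e-9) or not np.allclose(mat.sum(axis=-1), 1.0, atol=1e-4):
            raise ValueError("attention matrices must be row-stochastic")
        fused = _fuse_heads(mat, fusion)
        if n is None:
            n = fused.shape[0]
        elif fused.shape[0] != n:
            raise ValueError("all layers must share the token count")
        a = _process_layer(fused, discard_ratio)
        rollout = a if rollout is None else a @ rollout
    row = rollout[0, 1:]
    if grid is not None:
        row = row.reshape(grid)
    else:
        row = row[None, :]
    return SaliencyMap(class_label="drug", grid=np.clip(row, 0.0, None), source="attention")


def svm_weight_map(
    models: Sequence[Union[WindowSVM, np.ndarray]],
    image_shape: Tuple[int, int] | None = None,
    toward_label: int = -1,
) -> List[SaliencyMap]:
    """Per-window drug-driving weight maps, order preserved.

    Weights whose sign pushes toward the drug class (negative under the
    fitted convention) are kept and inverted to positive importance; all
    other entries are zeroed.
    """
    out: List[SaliencyMap] = []
    for idx, m in enumerate(models):
        if isinstance(m, WindowSVM):
            w, shape, widx = m.weights, m.image_shape, m.window_index
        else:
            w = np.asarray(m, dtype=float).ravel()
            if image_shape is None:
                raise ValueError("image_shape required for raw weight vectors")
            shape, widx = image_shape, idx
        if w.size != shape[0] * shape[1]:
            raise ValueError("weight vector length must equal rows*cols")
        if toward_label < 0:
            grid = np.where(w < 0, -w, 0.0)
        else:
            grid = np.where(w > 0, w, 0.0)
        out.append(
            SaliencyMap(
                class_label="drug",
                grid=grid.reshape(shape),
                source="svm_weights",
                window_index=widx,
            )
        )
    return out


def mean_map_over_time(maps: Sequence[SaliencyMap]) -> SaliencyMap:
    """Pixelwise mean of a list of same-shape maps (e.g. across windows)."""
    if not len(maps):
        raise ValueError("need at least one map")
    shape = maps[0].grid.shape
    if any(m.grid.shape != shape for m in maps):
        raise ValueError("maps must share a shape")
    grid = np.mean([m.grid for m in maps], axis=0)
    return SaliencyMap(class_label=maps[0].class_label, grid=grid, source=maps[0].source)


def model_maps_over_session(
    model: Model,
    series: PDFrameSeries,
    kind: str,
    window_frames: int = 60,
    span: Tuple[int, int] | None = None,
    class_idx: int = DRUG_CLASS,
    discard_ratio: float = 0.9,
    fusion: str = "max",
) -> List[SaliencyMap]:
    """Sliding one-window saliency maps for one animal.

    For each successive window the window-mean frame (baseline-normalized)
    is fed to the model and one map is produced: XGrad-CAM for ``kind ==
    "cam"`` (at feature-map resolution) or attention rollout for ``kind ==
    "attention"`` (at patch-grid resolution).
    """
    start, end = span if span is not None else (series.injection_index, series.n_frames)
    frames = normalized_frames(series)
    n_windows = (end - start) // window_frames
    maps: List[SaliencyMap] = []
    for w in range(n_windows):
        a, b = start + w * window_frames, start + (w + 1) * window_frames
        mean_frame = frames[a:b].mean(axis=0)
        if kind == "cam":
            A, g, score = model.feature_activations(mean_frame, class_idx)
            m = xgrad_cam(FeatureActivations(maps=A, gradients=g, class_score=score))
        elif kind == "attention":
            model.forward(mean_frame[None], record_attn=True)
            stack = [att[0] for att in model.attention_stack()]  # (heads, N, N)
            m = attention_rollout(
                stack, discard_ratio=discard_ratio, fusion=fusion, grid=model.grid
            )
        else:
            raise ValueError("kind must be 'cam' or 'attention'")
        m.window_index = w
        maps.append(m)
    return maps
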