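"""Training the three model families on registered pD frames.

The CNN and ViT are trained once per fold on frames from a fixed training
window (the final five post-injection minutes under the standard protocol)
and then evaluated over the whole session; the linear SVM is refit on each
successive one-minute interval so its weight map can track the evolving
drug effect.

Frames are normalized per animal by the baseline-window mean before any
model sees them, pixelwise: model inputs are fractional deviations from
the animal's own pre-injection baseline image (the per-pixel %-change
map, divided by 100).  This anchors every animal to its own pre-injection
state, so residual anatomy — and most registration error — divides out
and the models see the hemodynamic change itself, which is the quantity
of interest throughout.

Label conventions: for the CNN/ViT the drug class has index 1 (class
scores are ``[control, drug]``).  The SVM is fit on labels drug = +1,
control = -1: since the drug *lowers* pD at affected pixels, correctly
classifying drug frames requires *negative* weights at those pixels, so
"negative weights identify drug-driven regions" holds at the pixels that
matter — which is how the weight maps are read downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np
from sklearn.svm import LinearSVC

from .containers import PDFrameSeries
from .nn import Adam, ConvNet, VisionTransformer, cross_entropy

logger = logging.getLogger(__name__)

DRUG_CLASS = 1  # CNN/ViT class index of the drug condition
SVM_DRUG_LABEL = 1  # SVM side of the drug class; control is -1

__all__ = [
    "TrainWindow",
    "DRUG_CLASS",
    "SVM_DRUG_LABEL",
    "normalized_frames",
    "make_dataset",
    "train_model",
    "predict_scores",
    "train_svm_per_window",
]

Model = Union[ConvNet, VisionTransformer]


@dataclass
class TrainWindow:
    """Half-open frame interval the static models are trained on."""

    start_frame: int
    end_frame: int
    description: str = ""

    def __post_init__(self) -> None:
        if not self.end_frame > self.start_frame:
            raise ValueError("window must have positive length")


def final_minutes_window(series: PDFrameSeries, minutes: float = 5.0) -> TrainWindow:
    n = series.n_frames
    length = int(round(minutes * 60 * series.frame_rate_hz))
    return TrainWindow(max(0, n - length), n, f"final {minutes:g} minutes post-injection")


def normalized_frames(series: PDFrameSeries) -> np.ndarray:
    """Per-pixel fractional change from the animal's baseline mean image.

    ``(frame / baseline) - 1`` where ``baseline`` is the pixelwise mean
    over the baseline window — i.e. the per-pixel %-change map / 100, the
    standard relative-CBV representation.  Dead pixels (baseline at or
    near zero) are guarded by an epsilon floor.
    """
    start, end = series.baseline_window
    b = series.frames[start:end].mean(axis=0, dtype=np.float64)
    peak = float(b.max())
    if peak <= 0:
        raise ValueError(f"degenerate baseline for {series.animal_id}")
    b = np.clip(b, 1e-6 * peak, None)
    return (series.frames / b - 1.0).astype(np.float32)


def make_dataset(
    train_series: Sequence[PDFrameSeries],
    window: TrainWindow,
    frame_stride: int = 1,
) -> Tuple[np.ndarray, np.ndarray]:
    """(image, label) pairs from all frames of the window, all train animals."""
    xs, ys = [], []
    for s in train_series:
        if window.end_frame > s.n_frames:
            raise ValueError("training window exceeds session length")
        frames = normalized_frames(s)[window.start_frame : window.end_frame : frame_stride]
        xs.append(frames)
        ys.append(np.full(frames.shape[0], 1 if s.group == "drug" else 0, dtype=np.int64))
    X = np.concatenate(xs, axis=0).astype(np.float32)
    y = np.concatenate(ys)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    return X, y


def train_model(
    model: Model,
    train_series: Sequence[PDFrameSeries],
    window: TrainWindow,
    seed: int = 0,
    epochs: int | None = None,
    frame_stride: int = 1,
) -> Tuple[Model, List[float]]:
    """Fit a CNN or ViT with Adam + cross-entropy; returns (model, loss trace).

    Deterministic given ``seed``: the same shuffling, batching and
    initialization-independent updates reproduce the loss trace exactly.
    """
    X, y = make_dataset(train_series, window, frame_stride)
    spec = model.spec
    epochs = epochs if epochs is not None else spec.epochs
    opt = Adam(model.all_layers(), lr=spec.learning_rate)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    trace: List[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, spec.batch_size):
            idx = order[i : i + spec.batch_size]
            opt.zero_grad()
            logits = model.forward(X[idx])
            loss, dlogits = cross_entropy(logits, y[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
        trace.append(float(np.sum(losses) / n))
    return model, trace


def predict_scores(model: Model, frames: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Per-frame class scores ``[control, drug]``; argmax is the prediction."""
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[1:] != model.input_shape:
        raise ValueError(
            f"frames of shape {frames.shape[1:]} do not match model input {model.input_shape}"
        )
    out = np.empty((frames.shape[0], 2), dtype=np.float64)
    for i in range(0, frames.shape[0], batch_size):
        out[i : i + batch_size] = model.forward(frames[i : i + batch_size])
    return out


@dataclass
class WindowSVM:
    """Linear SVM fit on one interval; weights are per-pixel features."""

    window_index: int
    start_frame: int
    end_frame: int
    weights: np.ndarray  # flat, length rows*cols; positive decision = drug
    intercept: float
    image_shape: Tuple[int, int]

    def decision_function(self, frames: np.ndarray) -> np.ndarray:
        flat = np.asarray(frames, dtype=float).reshape(len(frames), -1)
        return flat @ self.weights + self.intercept


def train_svm_per_window(
    train_series: Sequence[PDFrameSeries],
    window_length_frames: int = 60,
    span: Tuple[int, int] | None = None,
    frame_stride: int = 1,
    C: float = 1.0,
) -> List[WindowSVM]:
    """One linear SVM per successive interval of ``window_length_frames``.

    ``span`` defaults to the whole post-injection period.  A trailing
    partial window is dropped (logged).  Each model is fit on the flattened
    pixels of that interval's frames from the training animals, labels
    drug = +1 / control = -1 (drug frames sit on the positive decision
    side; drug-informative pixels, where intensity falls, carry negative
    weights).
    """
    if not train_series:
        raise ValueError("empty training set")
    groups = {s.group for s in train_series}
    if len(groups) < 2:
        raise ValueError("training set must contain both classes")
    s0 = train_series[0]
    start, end = span if span is not None else (s0.injection_index, s0.n_frames)
    n_windows = (end - start) // window_length_frames
    if (end - start) % window_length_frames:
        logger.info(
            "dropping trailing partial window of %d frames",
            (end - start) % window_length_frames,
        )
    shape = s0.shape
    norm = {s.animal_id: normalized_frames(s) for s in train_series}
    models: List[WindowSVM] = []
    for w in range(n_windows):
        a, b = start + w * window_length_frames, start + (w + 1) * window_length_frames
        X, y = [], []
        for s in train_series:
            frames = norm[s.animal_id][a:b:frame_stride]
            X.append(frames.reshape(frames.shape[0], -1))
            y.append(
                np.full(frames.shape[0], SVM_DRUG_LABEL if s.group == "drug" else -1)
            )
        clf = LinearSVC(C=C, random_state=0, max_iter=5000)
        clf.fit(np.concatenate(X), np.concatenate(y))
        # coef_ is oriented toward classes_[1] == +1 (drug): positive
        # decision values mean drug, and pixels whose intensity drop marks
        # the drug get negative weights.
        models.append(
            WindowSVM(
                window_index=w,
                start_frame=a,
                end_frame=b,
                weights=clf.coef_.ravel().astype(float),
                intercept=float(clf.intercept_[0]),
                image_shape=shape,
            )
        )
    return models
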