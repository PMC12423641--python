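"""CAM-compatible convolutional classifier.

The default architecture follows the selected configuration for 91 x 128
pD frames: four 3x3 convolutional layers (channels 32, 64, 128, 128) with
ELU activations, the first three with stride 2 (91 -> 46 -> 23 -> 12 rows,
128 -> 64 -> 32 -> 16 columns), then global average pooling and a single
linear layer producing two class scores.  The single-linear-GAP head is
what makes the final conv layer a valid class-activation-mapping target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .ops import ELU, F32, Conv2D, Layer, Linear

__all__ = ["CNNSpec", "ConvNet", "build_cnn"]


@dataclass
class CNNSpec:
    """Architecture + training hyperparameters of the convolutional model."""

    n_conv_layers: int = 4
    channels: Tuple[int, ...] = (32, 64, 128, 128)
    n_downsample: int = 3
    kernel: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 30

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if len(self.channels) != self.n_conv_layers:
            raise ValueError("channels must list one width per conv layer")
        if self.n_downsample > self.n_conv_layers:
            raise ValueError("cannot downsample more often than there are layers")


class _GAP(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, K, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape).astype(dout.dtype) / (
            h * w
        )


class ConvNet:
    """Feed-forward conv stack + GAP + linear head, with manual backprop."""

    def __init__(self, spec: CNNSpec, input_shape: Tuple[int, int], seed: int = 0) -> None:
        rows, cols = input_shape
        r, c = rows, cols
        rng = np.random.default_rng(seed)
        if min(rows, cols) < 2**spec.n_downsample:
            raise ValueError(
                f"input {input_shape} too small for {spec.n_downsample} stride-2 stages"
            )
        self.spec = spec
        self.input_shape = (rows, cols)
        self.layers: List[Layer] = []
        in_ch = 1
        for i, out_ch in enumerate(spec.channels):
            stride = 2 if i < spec.n_downsample else 1
            self.layers.append(
                Conv2D(in_ch, out_ch, kernel=spec.kernel, stride=stride, pad=1, rng=rng)
            )
            self.layers.append(ELU())
            if stride == 2:
                r = (r + 2 - spec.kernel) // 2 + 1
                c = (c + 2 - spec.kernel) // 2 + 1
            if r < 1 or c < 1:
                raise ValueError(
                    f"input {input_shape} too small for {spec.n_downsample} stride-2 stages"
                )
            in_ch = out_ch
        self.feature_grid = (r, c)
        self.gap = _GAP()
        self.head = Linear(spec.channels[-1], 2, rng=rng)

    # ------------------------------------------------------------------ core
    @staticmethod
    def _as_batch(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        return x

    def forward_features(self, x: np.ndarray) -> np.ndarray:
        """Final-conv-layer activations A, shape (B, K, h, w)."""
        out = self._as_batch(x)
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def head_scores(self, feats: np.ndarray) -> np.ndarray:
        """Class scores from target-layer activations: linear(GAP(A))."""
        return self.head.forward(self.gap.forward(np.asarray(feats, dtype=F32)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head_scores(self.forward_features(x))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.head.backward(dlogits)
        d = self.gap.backward(d)
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def all_layers(self) -> List[Layer]:
        return [*self.layers, self.head]

    # -------------------------------------------------------------- saliency
    def feature_activations(self, image: np.ndarray, class_idx: int):
        """Target-layer activations and dY_c/dA for one image.

        Returns ``(maps, grads, score)`` with maps and grads of shape
        (K, h, w).  The gradient is taken of the raw class score (before
        softmax) with respect to the final conv layer's activations; for
        the GAP + linear head this is the head weight spread uniformly over
        the h*w positions.
        """
        feats = self.forward_features(image)
        scores = self.head_scores(feats)
        h, w = feats.shape[2:]
        grads = np.broadcast_to(
            self.head.P["w"][:, class_idx][None, :, None, None], feats.shape
        ) / (h * w)
        return feats[0], np.ascontiguousarray(grads[0], dtype=float), float(
            scores[0, class_idx]
        )


def build_cnn(
    spec: CNNSpec | None = None, input_shape: Tuple[int, int] = (91, 128), seed: int = 0
) -> ConvNet:
    """Instantiate the convolutional model for a given input shape."""
    return ConvNet(spec or CNNSpec(), input_shape, seed=seed)
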