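"""Synthetic fUSI cohorts with a planted, known drug-effect region.

Real power-Doppler recordings of drug sessions are not publicly
distributable, so every downstream stage (filtering, registration,
classification, saliency, region statistics) is exercised on cohorts
generated here.  The generative model is deliberately simple but keeps the
features the pipeline has to cope with:

* a shared template vascular map (curvilinear bright vessels on a dim
  background) deformed smoothly per animal — the inter-animal anatomical
  variability that registration must undo;
* slow multiplicative "breathing" oscillation plus per-pixel high-frequency
  noise — what the temporal lowpass filter removes;
* for drug animals, a multiplicative CBV decrease confined to a planted
  mask, ramping up after the injection with a saturating exponential —
  the signal the classifiers and saliency maps must find.

Each frame is ``deform(template) * (1 + breathing(t) + noise) * effect(t)``
with ``effect(t) = 1 - amplitude * ramp(t)`` inside the mask for drug
animals and 1 everywhere otherwise.  Multiplicative modulation keeps pD
intensities positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .containers import GROUPS, GroundTruth, PDFrameSeries, RegionMask

__all__ = [
    "SynthConfig",
    "make_vascular_map",
    "plant_effect_mask",
    "deformation_field",
    "effect_ramp",
    "simulate_animal",
    "simulate_cohort",
]


@dataclass
class SynthConfig:
    """Study-design and noise parameters of a synthetic cohort.

    Defaults mirror the standard protocol: 91 x 128 pixel sagittal frames at
    1 frame/s, 60-minute sessions with the injection at minute 5, 10 drug
    and 13 control animals, and a drug effect plateauing near a 14% regional
    CBV drop.
    """

    image_rows: int = 91
    image_cols: int = 128
    frame_rate_hz: float = 1.0
    session_s: float = 3600.0
    injection_s: float = 300.0
    n_drug: int = 10
    n_control: int = 13
    effect_amplitude: float = 0.14
    effect_tau_s: float = 1200.0
    effect_fraction: float = 0.15
    breathing_amp: float = 0.03
    breathing_freq_hz: float = 0.2
    noise_sd: float = 0.02
    deform_sd_px: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_rows, self.image_cols) <= 0:
            raise ValueError("image shape must be positive")
        if not self.injection_s < self.session_s:
            raise ValueError("injection must precede session end")
        if not self.breathing_freq_hz < self.frame_rate_hz / 2:
            raise ValueError("breathing frequency must be below Nyquist")
        for name in ("effect_amplitude", "breathing_amp", "noise_sd", "deform_sd_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.n_drug, self.n_control) < 1:
            raise ValueError("both groups need at least one animal")
        if not (0.0 < self.effect_fraction < 1.0):
            raise ValueError("effect_fraction must lie in (0, 1)")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.image_rows, self.image_cols

    @property
    def n_frames(self) -> int:
        return int(round(self.session_s * self.frame_rate_hz))

    @property
    def injection_index(self) -> int:
        return int(round(self.injection_s * self.frame_rate_hz))

    @property
    def baseline_window(self) -> Tuple[int, int]:
        # last 2 minutes of the pre-injection period (minutes 3-5 under the
        # standard 5-minute pre-injection protocol)
        start = max(0, self.injection_index - int(round(120 * self.frame_rate_hz)))
        return start, self.injection_index


def make_vascular_map(seed: int, shape: Tuple[int, int] = (91, 128)) -> np.ndarray:
    """Strictly positive template image with curvilinear vessel-like structures.

    Random smooth paths are rasterised with Gaussian cross-sections onto a
    dim, slowly varying background.  Deterministic in ``seed``.
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError("shape must be positive")
    rng = np.random.default_rng(seed)
    canvas = np.zeros((rows, cols), dtype=float)
    n_vessels = 10 + rng.integers(0, 5)
    for _ in range(n_vessels):
        r = rng.uniform(0, rows)
        c = rng.uniform(0, cols)
        ang = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.5)
        n_steps = int(rng.integers(30, 80))
        for _ in range(n_steps):
            ang += rng.normal(0.0, 0.25)
            r = np.clip(r + np.sin(ang), 0, rows - 1)
            c = np.clip(c + np.cos(ang), 0, cols - 1)
            canvas[int(r), int(c)] += amp
    canvas = ndimage.gaussian_filter(canvas, sigma=1.2)
    background = 0.15 + 0.1 * ndimage.gaussian_filter(rng.random((rows, cols)), sigma=6)
    image = background + canvas
    assert image.min() > 0
    return image


def plant_effect_mask(
    shape: Tuple[int, int], fraction: float, seed: int
) -> RegionMask:
    """Connected blob-like boolean mask covering ~``fraction`` of the pixels.

    A smooth random potential is superposed on a radial bowl around a random
    centre; the top ``round(fraction * n_pixels)`` pixels of that potential
    form the mask, so the pixel count is exact and the blob stays connected
    (the bowl dominates at the chosen noise scale).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    rows, cols = shape
    rng = np.random.default_rng(seed)
    centre = (rng.uniform(0.25 * rows, 0.75 * rows), rng.uniform(0.25 * cols, 0.75 * cols))
    rr, cc = np.mgrid[0:rows, 0:cols]
    dist = np.hypot(rr - centre[0], cc - centre[1])
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=6)
    noise = noise / (np.abs(noise).max() + 1e-12)
    potential = -dist / max(rows, cols) + 0.15 * noise
    k = int(round(fraction * rows * cols))
    if k == 0:
        mask = np.zeros(shape, dtype=bool)
        mask[int(centre[0]), int(centre[1])] = True
        return RegionMask(mask=mask, fraction=fraction, source="planted")
    order = np.argsort(-potential, axis=None, kind="stable")
    mask = np.zeros(rows * cols, dtype=bool)
    mask[order[:k]] = True
    return RegionMask(mask=mask.reshape(shape), fraction=fraction, source="planted")


def deformation_field(
    shape: Tuple[int, int], sd_px: float, seed: int, smooth_sigma: float = 8.0
) -> np.ndarray:
    """Smooth random displacement field, RMS magnitude ``sd_px`` per axis.

    Returns an array of shape (2, rows, cols): row and column displacements.
    """
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(
        rng.standard_normal((2,) + tuple(shape)), sigma=(0, smooth_sigma, smooth_sigma)
    )
    rms = np.sqrt(np.mean(field**2)) + 1e-12
    return field * (sd_px / rms)


def warp_image(image: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Pull-back warp of ``image`` by a (2, rows, cols) displacement field."""
    rows, cols = image.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    coords = np.stack([rr + field[0], cc + field[1]])
    return ndimage.map_coordinates(image, coords, order=1, mode="nearest")


def effect_ramp(t_s: np.ndarray, injection_s: float, tau_s: float) -> np.ndarray:
    """Saturating post-injection ramp: 0 before injection, ``1 - exp(-dt/tau)`` after."""
    dt = np.asarray(t_s, dtype=float) - injection_s
    return np.where(dt > 0, 1.0 - np.exp(-np.clip(dt, 0, None) / tau_s), 0.0)


def _animal_series(
    cfg: SynthConfig,
    group: str,
    anatomy_seed: int,
    truth: GroundTruth,
    template: np.ndarray,
    animal_id: str,
) -> PDFrameSeries:
    rng = np.random.default_rng(anatomy_seed)
    field = deformation_field(cfg.shape, cfg.deform_sd_px, int(rng.integers(2**31)))
    baseline = warp_image(template, field)

    n = cfg.n_frames
    t = np.arange(n, dtype=float) / cfg.frame_rate_hz
    phase = rng.uniform(0, 2 * np.pi)
    breathing = cfg.breathing_amp * np.sin(2 * np.pi * cfg.breathing_freq_hz * t + phase)

    ramp = effect_ramp(t, cfg.injection_s, cfg.effect_tau_s)
    frames = np.empty((n, cfg.image_rows, cfg.image_cols), dtype=np.float32)
    mask = truth.effect_mask
    for i in range(n):
        frame = baseline * (1.0 + breathing[i])
        if cfg.noise_sd > 0:
            frame = frame * (1.0 + cfg.noise_sd * rng.standard_normal(cfg.shape))
        if group == "drug" and ramp[i] > 0:
            frame = frame * np.where(mask, 1.0 - cfg.effect_amplitude * ramp[i], 1.0)
        frames[i] = np.clip(frame, 0.0, None)

    return PDFrameSeries(
        animal_id=animal_id,
        group=group,
        frames=frames,
        frame_rate_hz=cfg.frame_rate_hz,
        injection_index=cfg.injection_index,
        baseline_window=cfg.baseline_window,
    )


def simulate_animal(
    cfg: SynthConfig, group: str, anatomy_seed: int, truth: GroundTruth
) -> PDFrameSeries:
    """Simulate one animal's session from the shared template and planted truth."""
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    if truth.effect_mask.shape != cfg.shape:
        raise ValueError("ground-truth mask shape must match the configured image shape")
    template = make_vascular_map(cfg.seed, cfg.shape)
    return _animal_series(cfg, group, anatomy_seed, truth, template, f"{group}_{anatomy_seed}")


def make_ground_truth(cfg: SynthConfig) -> GroundTruth:
    mask = plant_effect_mask(cfg.shape, cfg.effect_fraction, seed=cfg.seed + 1)
    t = np.arange(cfg.n_frames, dtype=float) / cfg.frame_rate_hz
    curve = 1.0 - cfg.effect_amplitude * effect_ramp(t, cfg.injection_s, cfg.effect_tau_s)
    return GroundTruth(effect_mask=mask.mask, effect_curve=curve)


def simulate_cohort(cfg: SynthConfig) -> Tuple[List[PDFrameSeries], GroundTruth]:
    """Full cohort: ``n_drug`` drug + ``n_control`` control animals, shared truth.

    Anatomy seeds are spawned from ``cfg.seed`` so the cohort is bit-identical
    across runs with the same config; anatomy assignment is independent of
    group.
    """
    truth = make_ground_truth(cfg)
    template = make_vascular_map(cfg.seed, cfg.shape)
    n_total = cfg.n_drug + cfg.n_control
    seeds = np.random.SeedSequence(cfg.seed).generate_state(n_total) & 0x7FFFFFFF
    cohort: List[PDFrameSeries] = []
    for i in range(n_total):
        group = "drug" if i < cfg.n_drug else "control"
        idx = i if i < cfg.n_drug else i - cfg.n_drug
        series = _animal_series(
            cfg, group, int(seeds[i]), truth, template, f"{group}{idx:02d}"
        )
        cohort.append(series)
    return cohort, truth
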