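"""Temporal denoising and spatial registration of pD stacks.

Stage order is fixed and logged: per-frame rigid motion correction (phase
correlation against the animal's own reference), zero-phase temporal
lowpass filtering, then a single non-rigid registration of the whole stack
to the common reference (one smooth displacement field per animal,
estimated on the animal's baseline mean).  Rigid correction handles
within-session motion; the non-rigid stage handles inter-animal anatomy.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, signal
from skimage.registration import optical_flow_tvl1, phase_cross_correlation

from .containers import PDFrameSeries, ReferenceImage

logger = logging.getLogger(__name__)

__all__ = [
    "lowpass_zero_phase",
    "build_reference",
    "rigid_correct",
    "register_nonrigid",
    "preprocess_series",
]


def _design_lowpass(passband_norm: float, stopband_atten_db: float) -> np.ndarray:
    """Kaiser-window FIR lowpass for forward-backward (zero-phase) use.

    ``passband_norm`` is a fraction of Nyquist.  The transition band is four
    passband widths wide (a narrow passband needs some transition room to
    keep the filter length practical for 1 Hz data).  Designed single-pass
    attenuation already meets the requested stopband floor; the
    forward-backward application doubles it in dB.
    """
    if not (0.0 < passband_norm < 1.0):
        raise ValueError("passband_norm must lie in (0, 1) (fraction of Nyquist)")
    width = min(4.0 * passband_norm, 0.9 - passband_norm)
    numtaps, beta = signal.kaiserord(stopband_atten_db + 5.0, width)
    numtaps |= 1  # odd length, symmetric
    cutoff = passband_norm + width / 2.0
    return signal.firwin(numtaps, cutoff, window=("kaiser", beta))


def lowpass_zero_phase(
    series: PDFrameSeries,
    passband_norm: float = 0.02,
    stopband_atten_db: float = 60.0,
) -> PDFrameSeries:
    """Per-pixel zero-phase temporal lowpass.

    The filter is applied forward and backward (``filtfilt``), which cancels
    the group delay exactly and preserves the DC component; stopband
    sinusoids are attenuated by at least ``stopband_atten_db``.
    """
    taps = _design_lowpass(passband_norm, stopband_atten_db)
    padlen = 3 * (len(taps) - 1)
    if series.n_frames <= padlen:
        raise ValueError(
            f"series of {series.n_frames} frames is shorter than the filter "
            f"warm-up length ({padlen + 1} frames); record longer or widen the passband"
        )
    flat = series.frames.reshape(series.n_frames, -1).astype(float)
    filtered = signal.filtfilt(taps, [1.0], flat, axis=0)
    filtered = filtered.reshape(series.frames.shape)
    assert filtered.min() > -1e-9 * max(1.0, abs(float(series.frames.max())))
    filtered = np.clip(filtered, 0.0, None)
    return series.with_frames(filtered.astype(np.float32))


def build_reference(
    series: PDFrameSeries, start_frame: int, n_frames: int = 10
) -> ReferenceImage:
    """Pixelwise mean of ``n_frames`` frames starting at ``start_frame``."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not (0 <= start_frame and start_frame + n_frames <= series.n_frames):
        raise ValueError("reference window out of range")
    image = series.frames[start_frame : start_frame + n_frames].mean(axis=0)
    return ReferenceImage(
        image=np.asarray(image, dtype=float),
        source_animal=series.animal_id,
        n_frames_averaged=n_frames,
    )


def _estimate_shift(frame: np.ndarray, reference: np.ndarray) -> Tuple[float, float]:
    """Integer-pixel translation estimate via phase correlation.

    Whole-pixel precision keeps untranslated frames bit-identical (no
    resampling) and is what within-session head-fixed motion needs.
    """
    if float(frame.std()) == 0.0 or float(reference.std()) == 0.0:
        return 0.0, 0.0  # deterministic fallback for degenerate frames
    shift, _, _ = phase_cross_correlation(reference, frame, upsample_factor=1)
    return float(shift[0]), float(shift[1])


def rigid_correct(
    series: PDFrameSeries, reference: ReferenceImage
) -> Tuple[PDFrameSeries, np.ndarray]:
    """Translate each frame to maximise cross-correlation with the reference.

    Returns the corrected series and the estimated per-frame (row, col)
    displacements of each frame relative to the reference (the applied
    correction is their negative).  All-constant frames fall back
    deterministically to zero shift.
    """
    if reference.image.shape != series.frames.shape[1:]:
        raise ValueError("reference and frames must share a shape")
    if series.n_frames == 0:
        raise ValueError("empty series")
    out = np.empty_like(series.frames)
    shifts = np.zeros((series.n_frames, 2))
    for i in range(series.n_frames):
        dr, dc = _estimate_shift(series.frames[i], reference.image)
        shifts[i] = (-dr, -dc)  # displacement of the frame w.r.t. the reference
        if dr == 0.0 and dc == 0.0:
            out[i] = series.frames[i]
        else:
            out[i] = ndimage.shift(
                series.frames[i].astype(float), (dr, dc), order=1, mode="nearest"
            )
    out = np.clip(out, 0.0, None)
    return series.with_frames(out), shifts


def _warp_stack(frames: np.ndarray, field: np.ndarray) -> np.ndarray:
    rows, cols = frames.shape[1:]
    rr, cc = np.mgrid[0:rows, 0:cols]
    coords = np.stack([rr + field[0], cc + field[1]])
    out = np.empty_like(frames)
    for i in range(frames.shape[0]):
        out[i] = ndimage.map_coordinates(
            frames[i].astype(float), coords, order=1, mode="nearest"
        )
    return out


def register_nonrigid(
    series: PDFrameSeries,
    reference: ReferenceImage,
    attachment: float = 40.0,
) -> Tuple[PDFrameSeries, np.ndarray]:
    """Warp the whole stack onto the common reference.

    One smooth displacement field per animal is estimated with TV-regularized
    optical flow between the animal's baseline mean and the reference, then
    applied to every frame.  If warping does not decrease the mean squared
    difference of the baseline mean to the reference, the input is returned
    unchanged with a logged warning (non-convergence guard).

    Returns the registered series and the (2, rows, cols) displacement field
    actually applied (zeros when registration was rejected).
    """
    if reference.image.shape != series.frames.shape[1:]:
        raise ValueError("reference and frames must share a shape")
    start, end = series.baseline_window
    moving = series.frames[start:end].mean(axis=0).astype(float)
    ref = reference.image.astype(float)
    scale = ref.max() + 1e-12
    flow = optical_flow_tvl1(ref / scale, moving / scale, attachment=attachment)
    warped = _warp_stack(moving[None], flow)[0]
    mse_before = float(np.mean((moving - ref) ** 2))
    mse_after = float(np.mean((warped - ref) ** 2))
    if mse_after > mse_before:
        logger.warning(
            "non-rigid registration rejected for %s (MSE %.4g -> %.4g); returning input",
            series.animal_id,
            mse_before,
            mse_after,
        )
        return series, np.zeros((2,) + moving.shape)
    out = np.clip(_warp_stack(series.frames, flow), 0.0, None)
    return series.with_frames(out.astype(series.frames.dtype)), flow


def preprocess_series(
    series: PDFrameSeries,
    reference: Optional[ReferenceImage] = None,
    passband_norm: float = 0.02,
    stopband_atten_db: float = 60.0,
    rigid: bool = True,
    nonrigid: bool = True,
) -> PDFrameSeries:
    """Full per-animal pipeline: rigid correction -> lowpass -> non-rigid.

    ``reference`` is the cohort-common reference; when None, only the
    animal-internal stages (rigid correction against the animal's own
    baseline mean, filtering) run.
    """
    out = series
    if rigid:
        start, _ = series.baseline_window
        n_ref = min(10, series.n_frames - start)
        own_ref = build_reference(series, start, n_ref)
        logger.info("rigid motion correction: %s", series.animal_id)
        out, _ = rigid_correct(out, own_ref)
    logger.info("zero-phase lowpass: %s", series.animal_id)
    out = lowpass_zero_phase(out, passband_norm, stopband_atten_db)
    if nonrigid and reference is not None:
        logger.info("non-rigid registration to %s: %s", reference.source_animal, series.animal_id)
        out, _ = register_nonrigid(out, reference)
    return out
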