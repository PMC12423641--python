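"""Filtering and registration contracts, checked against planted truths."""

import numpy as np
import pytest
from scipy import signal

from fusimap.containers import ReferenceImage
from fusimap.preprocess import (
    build_reference,
    lowpass_zero_phase,
    preprocess_series,
    register_nonrigid,
    rigid_correct,
)
from fusimap.synthdata import (
    SynthConfig,
    deformation_field,
    make_ground_truth,
    make_vascular_map,
    simulate_animal,
    warp_image,
)

from conftest import constant_series, series_from_frames


class TestLowpass:
    def test_dc_preserved_exactly(self):
        s = constant_series(7.0, n_frames=900, injection=800)
        out = lowpass_zero_phase(s)
        assert np.allclose(out.frames, 7.0, atol=1e-6)

    def test_stopband_attenuation_60db(self):
        """A sinusoid at 0.4 of Nyquist must come out ~1000x smaller."""
        t = np.arange(900)
        x = 5.0 + np.sin(2 * np.pi * 0.2 * t)  # 0.2 Hz at fs = 1 Hz
        frames = np.tile(x[:, None, None], (1, 3, 4))
        out = lowpass_zero_phase(series_from_frames(frames, injection=800))
        resid = out.frames[300:600, 0, 0] - 5.0
        assert np.abs(resid).max() <= 1e-3

    def test_passband_zero_phase(self):
        """In-passband content is not delayed: peak cross-correlation at lag 0."""
        t = np.arange(2000, dtype=float)
        x = 10.0 + np.sin(2 * np.pi * 0.004 * t)  # within the passband
        frames = np.tile(x[:, None, None], (1, 2, 2))
        out = lowpass_zero_phase(series_from_frames(frames, injection=1900))
        a = x[300:1700] - x[300:1700].mean()
        b = out.frames[300:1700, 0, 0] - out.frames[300:1700, 0, 0].mean()
        lags = signal.correlation_lags(len(a), len(b))
        xc = signal.correlate(a, b)
        assert lags[np.argmax(xc)] == 0

    def test_too_short_series_rejected_with_message(self):
        s = constant_series(1.0, n_frames=40, injection=30)
        with pytest.raises(ValueError, match="warm-up"):
            lowpass_zero_phase(s)

    def test_never_negative(self):
        rng = np.random.default_rng(0)
        frames = np.abs(rng.normal(1, 0.5, (900, 4, 4)))
        out = lowpass_zero_phase(series_from_frames(frames, injection=850))
        assert out.frames.min() >= 0


class TestReference:
    def test_single_frame_is_identity(self):
        rng = np.random.default_rng(1)
        frames = rng.random((20, 5, 6)).astype(np.float32)
        s = series_from_frames(frames, injection=15)
        ref = build_reference(s, 3, 1)
        assert np.allclose(ref.image, frames[3])

    def test_mean_of_two_frames(self):
        frames = np.stack([np.zeros((2, 2)), np.full((2, 2), 2.0)] + [np.ones((2, 2))] * 5)
        s = series_from_frames(frames, injection=6)
        ref = build_reference(s, 0, 2)
        assert np.allclose(ref.image, 1.0)

    def test_window_out_of_range_rejected(self):
        s = constant_series(1.0, n_frames=20, injection=15)
        with pytest.raises(ValueError):
            build_reference(s, 15, 10)


class TestRigid:
    def test_planted_integer_shift_recovered(self):
        img = make_vascular_map(1, (64, 80))
        ref = ReferenceImage(img, "r", 1)
        moved = np.roll(np.roll(img, 3, axis=0), -2, axis=1)
        s = series_from_frames(np.stack([moved] * 3), injection=2, baseline=(0, 1))
        out, shifts = rigid_correct(s, ref)
        assert shifts[0] == pytest.approx((3, -2))
        # central region restored
        assert np.abs(out.frames[0][10:-10, 10:-10] - img[10:-10, 10:-10]).max() < 1e-3

    def test_identity_gives_zero_shift(self):
        img = make_vascular_map(2, (32, 40))
        s = series_from_frames(np.stack([img] * 2), injection=1, baseline=(0, 1))
        _, shifts = rigid_correct(s, ReferenceImage(img, "r", 1))
        assert np.allclose(shifts, 0)

    def test_constant_frame_deterministic_fallback(self):
        img = make_vascular_map(2, (32, 40))
        s = constant_series(3.0, n_frames=2, shape=(32, 40), injection=1)
        out, shifts = rigid_correct(s, ReferenceImage(img, "r", 1))
        assert np.allclose(shifts, 0)
        assert np.array_equal(out.frames, s.frames)


class TestNonrigid:
    def test_fixed_point_zero_displacement(self):
        img = make_vascular_map(3, (64, 80))
        s = series_from_frames(np.stack([img] * 5), injection=4, baseline=(0, 3))
        out, flow = register_nonrigid(s, ReferenceImage(img, "r", 1))
        assert np.abs(flow).max() < 0.1

    def test_planted_smooth_deformation_mostly_recovered(self):
        """A smooth ~2 px-magnitude planted field is undone to < 1 px residual."""
        img = make_vascular_map(3, (64, 80))
        field = deformation_field((64, 80), 1.5, seed=5)
        warped = warp_image(img, field)
        s = series_from_frames(np.stack([warped] * 5), injection=4, baseline=(0, 3))
        out, flow = register_nonrigid(s, ReferenceImage(img, "r", 1))
        before = np.mean((warped - img) ** 2)
        after = np.mean((out.frames[0] - img) ** 2)
        assert after < 0.5 * before
        # estimated flow cancels the planted field (residual < 1 px on average)
        resid = np.sqrt(((flow + field) ** 2).sum(axis=0))
        assert resid.mean() < 1.0

    def test_idempotent_up_to_tolerance(self):
        img = make_vascular_map(3, (64, 80))
        field = deformation_field((64, 80), 1.5, seed=6)
        warped = warp_image(img, field)
        s = series_from_frames(np.stack([warped] * 5), injection=4, baseline=(0, 3))
        ref = ReferenceImage(img, "r", 1)
        once, _ = register_nonrigid(s, ref)
        twice, _ = register_nonrigid(once, ref)
        mse1 = np.mean((once.frames[0] - img) ** 2)
        mse2 = np.mean((twice.frames[0] - img) ** 2)
        assert mse2 <= mse1 * 1.05 + 1e-12


class TestPipelineOrderAndAmplitude:
    def test_effect_amplitude_survives_preprocessing(self):
        """Noise-free planted effect passes through filtering + registration
        within ~1% (its timescale is far below the passband edge)."""
        cfg = SynthConfig(
            session_s=900.0,
            injection_s=150.0,
            effect_tau_s=100.0,
            effect_amplitude=0.2,
            noise_sd=0.0,
            breathing_amp=0.0,
            deform_sd_px=1.0,
            n_drug=1,
            n_control=1,
            seed=21,
        )
        truth = make_ground_truth(cfg)
        s = simulate_animal(cfg, "drug", 5, truth)
        ref = build_reference(s, cfg.baseline_window[0], 10)
        out = preprocess_series(s, ref)
        m = truth.effect_mask
        start, end = s.baseline_window
        raw_drop = 1 - s.frames[-1][m].mean() / s.frames[start:end][:, m].mean()
        proc_drop = 1 - out.frames[-1][m].mean() / out.frames[start:end][:, m].mean()
        assert proc_drop == pytest.approx(raw_drop, abs=0.01)
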