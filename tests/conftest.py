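"""Shared fixtures: tiny synthetic series and cohorts, reduced model specs.

Everything is generated programmatically at test time; sizes are kept far
below the full experimental protocol so the unit tests stay fast, while
the statistical and end-to-end checks in test_acceptance.py use the
reduced cohort scale documented in docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pytest

from fusimap.containers import PDFrameSeries
from fusimap.synthdata import SynthConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """Short low-noise cohort on the full 91x128 grid."""
    return SynthConfig(
        session_s=420.0,
        injection_s=120.0,
        n_drug=2,
        n_control=2,
        effect_amplitude=0.3,
        effect_tau_s=60.0,
        noise_sd=0.01,
        breathing_amp=0.02,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    cohort, truth = simulate_cohort(small_cfg)
    return cohort, truth


def constant_series(
    value: float = 1.0,
    n_frames: int = 40,
    shape=(6, 8),
    group: str = "control",
    injection: int = 30,
) -> PDFrameSeries:
    frames = np.full((n_frames,) + shape, value, dtype=np.float32)
    return PDFrameSeries(
        animal_id=f"const_{group}",
        group=group,
        frames=frames,
        frame_rate_hz=1.0,
        injection_index=injection,
        baseline_window=(max(0, injection - 10), injection),
    )


def series_from_frames(frames, group="control", injection=None, baseline=None, animal_id=None):
    frames = np.asarray(frames, dtype=np.float32)
    n = frames.shape[0]
    injection = injection if injection is not None else n - 1
    baseline = baseline if baseline is not None else (max(0, injection - 10), injection)
    return PDFrameSeries(
        animal_id=animal_id or f"{group}_x",
        group=group,
        frames=frames,
        frame_rate_hz=1.0,
        injection_index=injection,
        baseline_window=baseline,
    )
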