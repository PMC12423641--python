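"""Shared scale, paths and seeds for the numbered analysis scripts.

The study conditions mirror the acquisition protocol (91 x 128 frames at
1 frame/s, injection after 5 minutes, ~15% regional CBV drop building up
with a 20-minute time constant) at a desk-scale cohort: 6 drug + 6
control animals, 20-minute sessions, 3 cross-validation folds.  Frame
subsampling strides keep the NumPy training loops tractable on one CPU.
"""

from pathlib import Path

from fusimap.nn import ViTSpec
from fusimap.pipeline import RunConfig
from fusimap.synthdata import SynthConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 20250920


def study_config(models=("cnn", "svm"), seed: int = SEED) -> RunConfig:
    return RunConfig(
        synth=SynthConfig(
            session_s=1200.0,
            injection_s=300.0,
            n_drug=6,
            n_control=6,
            effect_amplitude=0.15,
            seed=seed,
        ),
        models=tuple(models),
        # ViT at analysis scale: 4 layers / 64-dim embedding (full-protocol
        # defaults are far heavier than one CPU core can train in minutes)
        vit=ViTSpec(depth=4, embed_dim=64, heads=4),
        n_folds=3,
        epochs=6,
        train_stride=5,
        eval_stride=6,
        seed=seed,
    )
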