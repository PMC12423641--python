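# Methods

`fusimap` implements an ROI-free analysis of drug-induced hemodynamic
change in functional-ultrasound (fUSI) power-Doppler (pD) image time
series: cohorts of 2-D pD stacks (drug vs saline control) are registered
to a common reference, classified over sliding one-minute windows by
three model families, reduced to per-method saliency maps, and the maps
are turned into data-driven regions whose %CBV trajectories are tested
with repeated-measures statistics.  This note records the models, the
parameter choices that matter, and the design decisions taken where the
design was genuinely open.

## Synthetic cohorts

Real pD recordings of pharmacological sessions are not publicly
distributable, so the package ships a generator whose planted ground
truth makes every downstream claim testable.

One shared template vascular map (curvilinear bright vessels over a dim
background, strictly positive) is deformed per animal by a smooth random
displacement field — this is the inter-animal anatomical variability that
registration must undo.  Each frame is

```
frame(t) = deform(template) * (1 + breathing(t) + noise(t)) * effect(t)
```

with `effect(t) = 1 − A·ramp(t)` inside a planted connected mask for drug
animals and 1 elsewhere; `ramp(t) = 1 − exp(−(t − t_inj)/τ)` after the
injection and 0 before.  All modulation is multiplicative, preserving the
positivity of pD intensities.

Defaults mirror the acquisition protocol: 91 × 128 pixels at 1 frame/s,
60-minute sessions with injection at minute 5, 10 drug + 13 control
animals, baseline window = the last two pre-injection minutes.  Remaining
parameters (units in parentheses):

| parameter | default | why |
|---|---|---|
| `effect_amplitude` (fraction) | 0.14 | plateau regional CBV drop of the order reported for NMDA-antagonist challenges (−10 to −15%) |
| `effect_tau_s` (s) | 1200 | effect still strengthening 30–40 min post-injection, matching when classification peaks |
| `effect_fraction` (fraction of pixels) | 0.15 | affected region of the same size as the analysis threshold |
| `breathing_amp`, `breathing_freq_hz` | 0.03, 0.2 | a single sub-Nyquist sinusoid; the true breathing band aliases at 1 Hz, this gives the lowpass filter something concrete to remove |
| `noise_sd` (fraction) | 0.02 | per-pixel multiplicative noise; chosen for testability — real pD noise magnitudes are not published |
| `deform_sd_px` (px) | 1.5 | small smooth inter-animal deformation; real variability is not quantified |

What the generator does **not** emulate: acoustic physics, within-session
motion beyond what rigid correction removes, heterogeneous effect
topographies, vigilance/anesthesia drift.  Passing tests therefore show
the pipeline recovers *this* class of planted effects; they are not a
claim about real-data accuracy.

## Preprocessing

Fixed, logged order per animal: (1) rigid motion correction — per-frame
integer-pixel phase correlation against the animal's own baseline mean
(subpixel refinement would force a resampling of every frame for no
benefit with head-fixed data; still frames pass through bit-identical);
(2) zero-phase temporal lowpass — Kaiser-window FIR applied
forward–backward (`filtfilt`), passband 0.02 × Nyquist (0.01 Hz at 1 Hz
sampling), ≥ 60 dB stopband, DC preserved exactly; the forward–backward
pass doubles the design attenuation in dB and cancels the group delay;
(3) non-rigid registration to the cohort reference — one TV-regularized
optical-flow field per animal, estimated between the animal's baseline
mean and the reference (the mean of ten frames from the start of the
third minute of the reference animal), applied to every frame.  If the
warp does not reduce the baseline's MSE to the reference the animal is
passed through unchanged with a warning.

The displacement field is per-animal, not per-frame: inter-animal
anatomy, not motion, is what this stage addresses; within-session motion
is the rigid stage's job.  Whether filtering preceded registration in the
original workflow is not documented; the order above is a logged choice.

## Classifiers and input representation

Three families, trained per cross-validation fold on frames labelled by
group:

* **CNN** — four 3×3 conv layers (channels 32, 64, 128, 128), ELU, the
  first three with stride 2 (feature grid 91×128 → 46×64 → 23×32 →
  12×16), then global average pooling and one linear layer to two class
  scores.  Adam, lr 1e-3, batch 32, cross-entropy.  The GAP + single-
  linear head makes the final conv layer a valid CAM target, and the 128
  final feature maps at 12 × 16 are what the CAM is computed on.
* **ViT** — patch size (7, 8) → 13 × 16 = 208 patch tokens + class token,
  pre-norm blocks, GELU MLPs, learnable positional embedding; default
  depth 16, 4 heads, embedding 256, Adam lr 1e-4, batch 16.  Attention
  probabilities of every layer are recorded for rollout.
* **Linear SVM** — every pixel is a feature; one model per successive
  one-minute interval, so the weight map can track the evolving effect.
  Labels are drug = +1 / control = −1: the drug *lowers* pD at affected
  pixels, so under this orientation those pixels carry negative weights,
  and extracting-and-inverting the negative weights selects the
  drug-driven region.

CNN and ViT train on the final five post-injection minutes and are tested
over the whole session in one-minute windows; the SVM is refit per
window.

**Input representation.** Models see per-pixel *fractional change from
baseline*: `frame / baseline_image − 1`, where `baseline_image` is the
animal's pixelwise mean over the baseline window.  This is the standard
relative-CBV quantity, and it is load-bearing: in raw (even globally
rescaled) intensity units, residual anatomy after registration is ~2× the
drug effect at vessel edges, and with few animals per class every model
family memorizes training-animal identity instead of the drug effect.
Dividing by the animal's own baseline image cancels anatomy and most
registration error, after which all three families generalize across
animals.  Region %CBV statistics are computed from intensity stacks
directly and are unaffected by this choice.

The CNN and ViT are implemented as a compact NumPy module with explicit
backward passes (`fusimap.nn`); gradients are verified against central
differences in the test suite, and training is bit-deterministic given a
seed.

## Saliency and regions

* **XGrad-CAM** on the final conv layer: per-channel weights
  `w_k = Σ_ij [∂Y_c/∂A_k(i,j) · A_k(i,j) / Σ_mn A_k(m,n)]`, map
  `ReLU(Σ_k w_k A_k)` at 12 × 16, bilinearly upsampled (half-pixel-center
  convention) to 91 × 128.  Channels with zero activation sum get weight
  0 (ε-guard), never NaN.  For the GAP + linear head the gradient is
  exactly `θ_kc/(h·w)`, giving a closed form the tests assert against.
* **Attention rollout**: per layer, heads fused by elementwise max, the
  lowest 90% of entries zeroed (never the class-token column; ties broken
  by flat index for determinism), identity added, rows renormalized, then
  multiplied across layers; the class-token row reshaped to the 13 × 16
  patch grid is the map.
* **SVM weight maps**: negative-signed weights (the drug-driving side)
  inverted to positive importance, per window.

Per-window maps are averaged across test animals within a fold, across
folds, and across windows — all at native (feature/patch) resolution —
and upsampled last.  The window input for CNN/ViT maps is the window-mean
frame (computing maps per frame and averaging is the other defensible
choice; the mean-frame variant costs 60× less and the window is
quasi-stationary after the 0.01 Hz lowpass).

**Regions**: the top `round(0.15 · n_pixels)` map pixels, selected by
exact count with ties broken by ascending flat index (a count-based
reading of "top 15% of pixels"; a percentile-value cut is not
deterministic under ties).  A sensitivity sweep repeats the analysis over
a list of fractions.

## Statistics

%CBV inside/outside a mask is `100·(m(t) − B)/B` with `m(t)` the
mask-mean intensity and `B` its baseline-window mean, binned to
one-minute windows for inference.  Two-way repeated-measures ANOVAs:
region × time with animal as subject (per group), and model × time with
fold as subject for the model comparison, followed by Tukey-adjusted
pairwise contrasts on fold-level mean accuracies when the model main
effect is significant.  The classical balanced within-subject
decomposition is implemented directly (no sphericity correction, matching
the original analysis description) and vectorized over replicates so that
null calibration with hundreds of simulated datasets is cheap; it is
cross-checked against statsmodels `AnovaRM` in the tests.  The exact-null
degenerate case (zero effect *and* zero error variance) is defined as
F = 0, p = 1.

Windowed classification metrics (accuracy, precision, recall, F1,
ROC-AUC) are computed from pooled frame-level counts per window; windows
containing a single true class record AUC as missing, excluded pairwise
when averaging across folds.  Undefined 0/0 precision or recall is
reported as 0.

## Problem sizes

The test suite and the worked examples run a reduced study: 6 drug + 6
control animals, 20-minute sessions (injection at minute 5), 3 folds,
effect amplitude 0.15, training frames subsampled 5×, evaluation frames
6×, 8 training epochs.  These are the package's own desk-scale choices;
the full-protocol defaults (23 animals, 60-minute sessions, 10 folds,
30 epochs) remain the configured defaults.  At analysis scale the ViT
runs with depth 4 and embedding 64 (the full 16-layer, 256-dim
configuration is the configured default but is disproportionately slow to
train in pure NumPy).

## Known limitations

* The generator's effect is spatially uniform inside one connected mask;
  graded or multi-focal effects are untested.
* Non-rigid registration leaves vessel-edge residuals of roughly half a
  pixel; the baseline-ratio input representation, not registration
  quality, is what makes classification robust.
* Attention rollout is less spatially specific than the CAM on these
  cohorts (Dice vs the planted region roughly 2× chance, against ~5× for
  the CAM) — consistent with rollout's known checkerboard/diffuseness
  artifacts.
* The repeated-measures ANOVA assumes sphericity; a Greenhouse–Geisser
  option is not currently wired in.
* One displacement field per animal means residual within-session
  non-rigid motion (absent in the generator) would go uncorrected.
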