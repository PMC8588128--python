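# Methods

## Signal model of the synthetic generator

Each simulated trial is, per channel, a sum of two sinusoids — mu centred
at 10 Hz (drawn uniformly in 9–11 Hz per trial) and beta centred at 22 Hz
(20–24 Hz) — with independent random phases, plus Gaussian white noise.
Amplitudes default to 10 µV (mu), 5 µV (beta) and noise_sd 3 µV at
250 Hz, a plausible scalp-EEG scale. During the post-cue MI window the
oscillation amplitude on each channel is multiplied by a class- and
channel-specific attenuation factor in [0, 1]; the pre-cue segment and
the separate rest baseline carry the unattenuated rhythms. The default
montage is three channels read as C3-like, Cz-like and C4-like, with
imagined left hand attenuating C4 and imagined right hand attenuating
C3 (contralateral ERD).

This model was chosen because its band-power statistics are analytic: a
sinusoid of amplitude A carries band power A²/2, so a configured
attenuation a is recoverable as √(P_MI/P_rest) — which the tests verify
with an independent Welch periodogram. What the generator does *not*
emulate: volume conduction and channel correlations, 1/f background
spectra, EOG/EMG artifacts, inter-session nonstationarity, and
trial-to-trial amplitude drift. Passing tests therefore demonstrate that
the pipeline's mechanics and statistics are correct, not that the
classifier's absolute accuracies transfer to recorded EEG.

Two named conditions recur in the tests: *strongly separable*
(attenuation 0.2, noise_sd 2) where a trained network should approach
perfect held-out accuracy, and *class overlap* (attenuation 0.7,
noise_sd 10) where errors occur and the uncertainty machinery has
something to reject.

## Preprocessing

Band-pass 4–38 Hz with an order-3 Butterworth filter applied
forward–backward (zero phase, via second-order sections); zero phase
avoids group delay shifting the cue alignment, and the order is
configurable. Standardization is electrode-wise exponential moving with
decay 0.999: μ and σ² are updated recurrently per sample, initialised
from the mean/variance of the pre-trial rest baseline (default 2 s,
configurable — the baseline length genuinely matters only through how
stable the initial statistics are). Outliers are clipped to μ ± 6σ.
Whether clipping uses the statistics *before* or *after* the update is
ambiguous in principle; the default clips against the previous sample's
statistics so the recurrences see the clipped value and the update stays
explicit and causal, and `clip_mode="post_update"` switches to the
alternative. A zero-variance baseline raises rather than standardizing
by 0.

Crops of 4 s are slid every 8 ms (2 samples at 250 Hz) across the
window −0.5 … 4 s around the cue; the crop count is
floor((window − crop)/stride) + 1 (63 for the default geometry), the
standard sliding-window convention for a non-integer number of strides.
All second-valued windows convert to samples by round(sec × fs).

## Network and training

Layer order: temporal conv (45×1, 40 filters, stride 2) → spatial conv
(1×n_channels, 40 filters) → batch norm → square → average pool (45,
stride 1) → max pool (window 8, stride 8) → log(u + 1e-6) → dropout →
dense softmax. Batch norm sits after the spatial convolution and before
the squaring, with momentum 0.99 and ε=1e-3; placing it after the square
is a switchable variant in principle but the chosen order matches the
shallow-ConvNet lineage this head derives from. The max-pool window
equals its stride (8): that is the only reading of an "8×1 stride"
pooling that yields 2160 dense-input features from 1000-sample input
(1000 → 478 conv positions → 434 pooled → 54 max-pooled × 40 filters).
Dropout rate defaults to 0.5, placed directly before the dense layer —
which is also what makes the cached-activation MCD exact.

The forward and backward passes are explicit NumPy; the backward pass is
validated against central-difference numerical gradients to ~1e-9
relative error. Training uses Adam (lr 1e-3), categorical cross-entropy
on crop labels, max-norm constraints re-applied after every update
(2.0 per conv filter, 0.5 per dense class column — constants are
conventional for this architecture family and configurable), learning
rate halved after 10 epochs without validation-loss improvement, early
stopping with patience 20 and best-weight restoration. Ties in argmax
resolve toward the lowest class index everywhere.

## Monte Carlo dropout and ensembles

T=50 passes by default. One seeded generator drives all masks, drawn in
(pass, member, crop) order, so fast and reference paths consume the same
stream: the fast path computes the conv-stack activations once per input
and re-applies fresh masks only to the dropout/dense head; the naive
reference re-runs the full network per pass. Equality to 1e-12 is
asserted. Trial-level prediction averages the softmax outputs of a
trial's crops within each pass (the passes stay distinct so that
between-pass variability — the uncertainty signal — is preserved).
Ensembles average member outputs within each pass, each member drawing
independent masks; the repeated-holdout models provide the members.

## Uncertainty statistics

Entropies are in bits with 0·log 0 := 0 and entropy returned
non-negative; the normalized entropy divides by log₂C. The variation
ratio is 1 − f_c*/T with per-pass argmax and mode ties toward the lowest
index; its attainable range is [0, 1 − 1/C]. Mutual information is
clamped to 0 below 1e-9 (it is non-negative by Jensen but finite-T
floating point can dip marginally). Total variance uses the
population (1/T) convention. The margin of confidence fixes
c = argmax p* and computes d_t against that same c in every pass, so
individual d_t can be negative; σ_d is the sample (ddof 1) standard
deviation, defined 0 at T=1 — with the consequence, accepted and
documented, that T=1 predictions are always "certain" (the threshold
degenerates to M > 0 only when σ_d = 0).

The rejection threshold M̂ = σ_d·z_{1−α/2}/√T implements "certain iff the
CI of M excludes zero"; the boundary M = M̂ counts as uncertain. Because
σ_d is a sample standard deviation, the exact null certainty rate is
P(t_{T−1} > z_{1−α/2}) ≈ 0.0278 at T=50, α=0.05 — close enough to α/2
that the coverage test's 3-SE band absorbs the difference, and the
z-form is kept as the definition.

Histogram separation (Bhattacharyya) uses 20 equal-width bins over the
pooled min–max by default, with an ε=1e-12 guard inside the log so that
disjoint supports give a large finite distance. The threshold sweep
varies the multiplier z in M̂ = σ_d·z/√T over 100 log-spaced points in
[0.1, 10], reporting the UA-optimal point and the UA at z=1.96 and
z=2.576 (confidence levels 0.95 / 0.99), which lie on that axis.

Undefined ratios (e.g. Riu with no incorrect predictions) are reported
as NaN and excluded from means.

## Experiment design

Repeated holdout: the training pool is split at random n_repeats=16
times into train/validation parts (validation fraction 1/6 for the
22-channel 4-class geometry, 1/5 for the 3-channel 2-class one, both
overridable); one network per split; a fixed test set for evaluation.
Subject-specific splits draw within one subject's trials,
non-subject-specific from the pooled set. All randomness derives from
one master seed expanded per repeat and stage. Test accuracy is
trial-level (argmax of p* from crop-averaged passes) by default;
crop-level evaluation is available. The co-adaptation check reports
ACC(T=1, dropout on) − ACC(deterministic) per model: systematically
negative values mean neurons co-adapted during training and test-time
dropout hurts.

## Problem sizes in tests

The suite and end-to-end checks run a scaled-down geometry chosen as
this package's desk-scale condition: 3 channels, 2 classes, 2 s MI
window, 2 s / 500-sample crops with a coarse 500 ms crop stride, 30
trials per class (70/30 session split), up to 40 epochs with patience
10. One training run takes a few seconds; the ten-seed end-to-end block
runs in about a minute. The full-scale geometry (22 channels, 4 s crops,
8 ms stride, 16 repeats) is exercised for architecture correctness and
is available through the same configuration objects.

## Known limitations

* No GPU path and no concurrency; determinism is prioritised over speed.
* The GDF adapter is code-complete but not validated against real
  BCI Competition IV recordings.
* Batch-norm running statistics are updated with momentum 0.99, so very
  short trainings leave them close to their initialisation; validation
  and test evaluation share this inference path, keeping early stopping
  consistent with final evaluation.
* Calibration methods (temperature scaling), conformal prediction and
  aleatoric/epistemic decompositions beyond mutual information are out
  of scope.
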