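# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind `opmclean`.  It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Pipeline model

The package assumes the standard instantaneous linear mixing model of
MEG artifact correction: the sensor array `X(t) ∈ R^{C}` is an unknown
invertible mixture of statistically independent sources, some neural,
some ocular/cardiac.  FastICA recovers an unmixing matrix per 10-s epoch;
artifact source time courses are identified by their dependence on the
magnetic reference sensors, and removal is reconstruction with those
source rows zeroed.  Stationarity is assumed *within* an epoch only —
that is the reason ICA is fit per epoch rather than on the concatenated
recording (the classifier also consumes fixed-length 10,000-sample
component waveforms, which per-epoch decomposition yields directly).
Whole-recording ICA remains possible by passing a longer "epoch" length.

## Randomized dependence coefficient

`rdc(x, y)` = median over `n_repeats = 5` draws of the largest canonical
correlation between random sinusoidal feature maps of the
copula-transformed inputs.

* **Copula transform**: `u[m] = #{j : x[j] ≤ x[m]} / (n + 1)`; the n+1
  denominator keeps values strictly inside (0, 1).  Ties share ranks
  (the ≤ count), so the transform — and hence the score — is exactly
  invariant under strictly increasing marginal maps.
* **Features**: `φ(u) = sin(u W + b)`, `W ∈ R^{1×k}` with entries
  `N(0, s²)`, `b ~ U(0, 2π)`; defaults `k = 20`, `s = 1/6` (s is the
  *standard deviation* of the projection weights).
* **Shared projections**: within a repeat, both inputs receive the same
  `(W, b)` draw.  Each feature map keeps the prescribed law, but the
  coupling makes the estimator exactly symmetric in its arguments —
  with independent per-side draws the symmetry error of a median of
  five repeats reaches ≈ 0.04 even at n = 10,000.
* **Regularization**: the CCA covariance blocks receive a *relative*
  ridge, `ridge · mean(diag(C))·I` with dimensionless `ridge = 1e-3`.
  At `s = 1/6` the feature variance is ≈ 1e-3, so an absolute ridge of
  the same magnitude would halve the self-dependence score
  (`rdc(x, x) ≈ 0.88` instead of ≥ 0.99); the relative form makes the
  regularization scale-free.  The eigenproblem is solved by Cholesky
  whitening plus SVD; eigenvalues nudged above 1 by floating point are
  clipped to 1.  `ridge = 0` on a singular block raises with advice.
* **Batched scorer**: `rdc_against_references` computes the same
  estimator for many components against a fixed reference pair, sharing
  copula transforms and feature maps across pairings (float32 blocked
  GEMMs internally — ample for a score quoted to two decimals, and it
  reproduces `rdc()` to < 1e-3).

The null level of the RDC is a positive bias floor that shrinks with n
(≈ 0.03 at n = 10,000, k = 20); thresholds δ = 0.3 / λ = 0.2 sit far
above it.

## Synthetic sessions

The generator emulates the acquisition protocol the pipeline targets:
32 MEG channels + MOG + MCG + trigger at 1 kHz; 1 kHz tone pips of
200–300 ms every 2 s; 10-s analysis epochs.

* **Neural background**: white noise band-passed to 1.5–40 Hz and scaled
  to unit RMS per channel, plus an alpha rhythm of 8–13 Hz band-filtered
  noise at RMS 0.5 per channel.  The alpha rhythm is deliberately *not* a
  fixed-phase sinusoid: a pure 10 Hz tone is exactly periodic in the 2-s
  inter-stimulus interval, i.e. phase-locked to every trial, and would
  sit in the trial average forever (measured: a 0.5-RMS pre-stimulus ERF
  floor that no amount of averaging or artifact removal reduces).
  Band-filtered noise waxes, wanes and drifts in phase like real alpha
  and averages out across trials.  The background is *not* a biophysical
  forward model (no head geometry, no lead fields, no sensor noise
  spectra).
* **Blink train**: homogeneous Poisson events (exponential gaps), rate
  0.3/s in "normal" mode and 2/s in "rapid" mode (band 1–3/s); event
  waveform is an asymmetric bump — half-Gaussian rise ≈ 100 ms, slower
  ≈ 200 ms decay — with a small negative rebound (biphasic).  A 10-s
  epoch at the natural rate has ≈ 5% probability of containing no blink
  at all; such epochs genuinely carry no blink component, and evaluation
  conditions on event presence.
* **Cardiac train**: three-lobe piecewise-Gaussian Q–R–S template
  (total width ≈ 100 ms, R positive, Q/S negative) repeated with
  inter-beat intervals drawn uniformly from 900–1000 ms.
* **Evoked response**: an M100-like Gaussian bump peaking 100 ms
  post-onset with a smaller opposite-sign deflection at 200 ms, confined
  to [onset, onset + 0.5 s].
* **Mixing**: each source enters the array through a fixed unit-norm
  random topography.  Base peak amplitudes relative to the unit-RMS
  background: blink 25, cardiac 15, evoked 4 (array-wide; per channel
  ≈ 4.4, 2.6 and 0.7 after the 1/√32 topography factor).  Blink and
  cardiac fields at the scalp dwarf cortical activity, while the evoked
  response only emerges after trial averaging — these ratios reproduce
  that regime.
* **References**: source plus independent Gaussian noise at 5% of source
  RMS (near-source sensors are high-SNR).
* All draws descend from one seed; sessions are bit-reproducible.

What passing tests on this generator do **not** show: robustness to
sensor motion, non-stationary mixing, overlapping artifact classes on a
single component, realistic OPM noise floors, or inter-subject topography
variability beyond random re-draws.

## Dataset construction

Scores are thresholded per epoch: one blink (highest `rdc_mog` > δ) and
one cardiac (highest `rdc_mcg` > δ) component at most; non-artifacts need
*both* scores < λ; the [λ, δ] gap is discarded rather than treated as
negative (negatives are defined strictly by λ).  If one component tops
both references it takes the class of its larger score, ties going to
cardiac (the more stereotyped morphology).  Classes are subsampled to
blink : cardiac : non-artifact = 1 : 1 : 4, doubled by sign inversion,
and split 4 : 1 stratified by class — with an inverted twin always in the
same partition as its original, a leakage guard stricter than plain
stratification.  Waveforms inherit the unit-variance ICA convention.

For the scaled-down study, component waveforms are stride-subsampled from
10,000 to 2,000 points.  The pipeline band-limits everything to 40 Hz at
a 1 kHz rate, so keeping every 5th sample (effective 200 Hz, Nyquist
100 Hz) is alias-free.

## CA-SeqNet

Implemented from scratch in NumPy (forward and backward passes written
out, validated against central finite differences to < 1e-3 relative
error in float64).  Channels-last memory layout makes each convolution an
im2col reshape plus one GEMM with no transposes.

* Backbone: 7 × [Conv1d(kernel 3, same padding) → BatchNorm1d → ReLU →
  MaxPool1d(2)] with widths (64, 64, 128, 128, 256, 256, 256) — the
  seven convolutions of the first three blocks of the classic 16-layer
  deep CNN, which reconciles "seven repeated units" with that lineage.
* Channel attention: `A = σ(W·[GAP(F), GMP(F)] + b)` with a single
  linear map 2C → C (mathematically identical to the 1×1 convolution of
  the pooled descriptor, bias included), applied multiplicatively per
  channel.
* Head: FC(256) → ReLU → Dropout(0.5) → FC(64) → ReLU → Dropout(0.5) →
  FC(3) → softmax.  Hidden sizes and dropout are sized to the ~10³-sample
  training regime.
* Inputs are standardized per waveform (zero mean, unit variance) —
  required for stable convergence and consistent with the scale-free ICA
  convention.
* Training: Adam, lr 1e-3 × 0.1^(epoch div 10), batch 16, mean
  multiclass cross-entropy, 100 epochs at full scale (20 in the
  scaled-down study).  Weight init is fan-in-scaled uniform
  (U(±1/√fan_in)); one master seed (42) drives init, shuffling and
  dropout, and computation is single-device deterministic, so histories
  are bit-reproducible.  A NaN loss aborts with a diagnostic.
* Inference runs with dropout off and batch-norm running statistics, so
  `forward` is a pure function.

## Preprocessing numerics

* Filter: 4th-order Butterworth band-pass (second-order sections),
  applied forward-backward (`sosfiltfilt`) — zero phase, so ERF peak
  latencies are preserved.  The designed zero-phase response at 60 Hz is
  |H|² ≈ 0.03.  The trigger line is never filtered.
* FastICA: per epoch on MEG channels only, `n_components` = channel
  count, unit-variance sources (scale absorbed into mixing columns),
  `max_iter = 200`, `tol = 1e-3`.  On realistic epochs the strict
  fixed-point criterion is rarely met even at generous tolerances while
  the non-Gaussian artifact components stabilize within tens of
  iterations; a run that stops at `max_iter` is therefore returned
  flagged (`converged=False`) rather than retried by default — retrying
  with fresh seeds was observed never to change the outcome, only the
  runtime.  Optional `retries`/`strict` arguments restore the stricter
  policy.  Reconstruction error with no exclusions is < 1e-6 relative
  RMS.
* Epoching: non-overlapping, trailing partial epoch discarded; the
  pipeline order is fixed as filter → epoch.

## Evaluation

* Metrics are one-vs-rest per class: precision TP/(TP+FP), recall
  TP/(TP+FN), F1 the harmonic mean, accuracy (TP+TN)/total (the standard
  form), macro figures unweighted class means, all in percent.  Zero
  denominators report 0 with a warning.
* ERF: per-channel trial average over [−0.2, 0.5] s (the post window
  chosen to display the M100), baseline-corrected by the pre-stimulus
  mean; trials clipped by recording edges are dropped.
* SNR: `20·log₁₀(RMS post / RMS pre)` with pre = [−0.2, 0) s and post =
  [0, 0.2] s (half-open at onset), RMS pooled over all MEG channels —
  the per-channel/aggregate choice was open and the aggregate is the
  more stable statistic.
* Cleaning re-runs filter → epoch → ICA → classify → reconstruct per
  epoch and passes reference and trigger rows through untouched
  (truncated to whole epochs).

## Scaled-down study conditions

The self-contained study executed by the test suite and the acceptance
script uses 12 synthetic subjects × 50 s (five 10-s epochs each,
alternating natural/rapid blinking), yielding ≈ 700 samples after
balancing and inversion; 2,000-point waveforms; 20 training epochs.
These sizes were chosen so the whole study runs in minutes on one CPU
while leaving the training recipe itself untouched.

Cleaning efficacy is evaluated on fresh 120-s sessions under natural
blinking — the condition of an evoked-response recording; instructed
rapid blinking is an acquisition protocol for enriching the artifact
dataset, not something one does during an ERF experiment.  Two opposing
small effects set the SNR margin at this scale.  Removing an ICA
component deletes a whole spatial direction, taking with it the slice of
evoked signal that projects onto it (≈ 1/n_channels per flagged
component on average, more when a random artifact topography happens to
align with the evoked topography).  Conversely the blink residual, being
~400 ms wide, is nearly constant across the ±0.2-s SNR windows and is
largely absorbed by baseline correction, so its removal buys less SNR
than its amplitude suggests.  The net improvement is therefore a fraction
of a dB per session on this generator — cleanly positive in most
sessions, occasionally negative when topographies align adversarially —
far smaller than on real recordings, where slow physiological noise does
not average down with 1/√trials.

## Worked-run outcomes

Everything quantitative is recomputed by the tests and
`scripts/acceptance.py`; typical magnitudes at the sizes above: held-out
classification accuracy and macro-F1 in the high nineties, RDC
identification rates ≥ 95%, and pre-stimulus ERF amplitude reduced in
essentially every cleaned session.  The per-session SNR comparison is the
one quantity that does not transfer to this generator: for the reasons in
the previous section its margin is ~0 ± 0.4 dB here, so cleaned beats raw
in only roughly half to three-quarters of sessions depending on the seed
draw, even though ground-truth artifact removal is near its ceiling.

## Known limitations

* No time-lagged dependence: the RDC compares simultaneous samples, so a
  reference delayed against its artifact component under-scores.
* Single-axis (radial) sensor model; no multi-axis OPM support.
* One artifact component per reference per epoch in the labeler; real
  decompositions occasionally split an artifact across two components
  (the classifier may still flag both at removal time).
* The non-convergence flag is informational; downstream stages do not
  currently branch on it.
* Synthetic validation only, within this package; performance figures on
  the generator do not transfer verbatim to recorded OPM data.
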