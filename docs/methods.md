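# Methods

`eegvigil` implements an EEG-based inattention detection and alerting
pipeline for UAV operators, together with the synthetic world needed to
exercise it end to end.  This note records the models, the defaults and why
they were chosen, the numerical decisions, and the limits of what the
synthetic benchmark can show.

## The detection problem

An operator's attention state is modelled as a hidden two-state process
(attention / inattention).  The observable consequences are:

* **EEG**: the amplitude of the theta band (4–8 Hz) is elevated during
  inattention; the other conventional bands (delta 2–4, alpha 8–13,
  beta 13–30 Hz) carry no consistent direction of change.
* **Flight performance**: the variance of altitude and velocity around the
  commanded targets (6500 ft, 250 kn) grows when the operator stops
  correcting deviations.

Telemetry is used only to *label* training data; at run time the detector
sees EEG features alone.

## Synthetic sessions

No public recordings exist for this task, so the simulator is a first-class
component rather than a test fixture.

**State process.** A two-state Markov chain at the 6 Hz frame rate with
geometric dwell times, mean 100 s (attention) and 25 s (inattention).  The
20 % long-run inattention fraction mirrors the ~20 % inattention ratio that
operator studies report for comparable monotonous flight tasks.

**EEG.** Each of the 14 channels (AF3 … O2, 10–20 montage) is an
independent sum of four AR(2) oscillators — one per band, poles tuned to the
band centre with bandwidth-matched radius — plus white noise, sampled at
120 Hz.  Default stationary SDs are 10/8/6/4 µV for delta/theta/alpha/beta
with 2 µV white noise.  During inattention frames the theta oscillator is
multiplied by `theta_gain` (default 3).  120 Hz was chosen over a
consumer-headset 128 Hz so the 6 Hz frame rate divides the raw rate exactly
(hop = 20 samples, no resampling).

**Telemetry.** Altitude and velocity follow discrete-time
Ornstein–Uhlenbeck dynamics around the targets,
`x_{t+1} = m + φ(x_t − m) + σ_state ε`, with φ = exp(−Δt/τ) and τ = 2 s —
a stick-correction timescale comfortably inside the 10 s labelling window.
Innovation SDs are (5 ft, 1 kn) in attention and (25 ft, 5 kn) in
inattention (ratio 5); the constructor rejects configurations in which
inattention is not noisier than attention.

**What the simulator does not model**: eye-blink/EMG artifacts, 1/f
spectral background, inter-channel correlation, realistic flight dynamics,
or operator idiosyncrasy.  Passing tests therefore demonstrate that the
pipeline recovers the *modelled* regularities, not that it would reach the
same numbers on human data.

**Responsive simulant.** For recovery studies the state path can be
post-processed so that every inattention episode is truncated
`detect_delay + response_latency` frames after onset (defaults: one 1 s
monitor step + 2 s latency), emulating an operator who reacts to the alert.

## Signal processing

* Band-pass: zero-phase 4th-order Butterworth, 2–42 Hz (`sosfiltfilt`).
* Band decomposition: sliding rectangular 1 s FFT window (120 samples),
  hop 20; per band the amplitude is the mean single-sided FFT magnitude
  over the bins inside the band's range, in µV.  This reconstructs the
  opaque headset-API output as the simplest STFT-magnitude equivalent.
  A record of N samples yields `floor((N − 120)/20) + 1` frames, so the
  band series is 5 frames shorter than the nominal 6 Hz frame count;
  telemetry and ground truth are truncated to match (frame *t* covers raw
  time [t/6, t/6 + 1) s).
* Channel averaging: arithmetic mean of the 14 channels → 4 values per
  frame (56 properties reduce to 4).
* Normalization: per-band z-score with mean and *sample* SD estimated on
  training data only and reused verbatim on held-out or streaming data.
  A zero-variance band is an error, not a silent NaN.
* Start trim: the first 60 s are dropped from EEG, telemetry and labels
  alike — early-flight fluctuations are uninformative about attention.

## Features

**AAR via RLS.**  Each normalized band series is tracked by a recursive
least-squares AR(`n_c = 10`) estimator with forgetting factor λ = 0.95 and
initial covariance `1000·I`.  The effective memory `(1+λ)/(1−λ) ≈ 39`
frames (6.5 s) sits deliberately between the 1 s frame spacing (smoothing
FFT-frame noise) and the shortest typical episode dwell (so coefficients
can follow regime switches); a λ of 0.99 (memory ≈ 33 s) was measured to
blur state transitions and degrade every downstream classifier.  The first
`n_c` frames carry the zero initialization, preserving label alignment.
Numerics: the covariance update divides by λ each step, so floating-point
asymmetry in P compounds geometrically; P is re-symmetrized every update,
after which RLS agrees with direct exponentially-weighted least squares to
machine precision, and its time-averaged stationary estimate agrees with
batch OLS on stationary AR(2) data to ±0.05 over 10⁴ frames (the
instantaneous coefficient wobbles with the ~200-frame effective memory).  A non-finite update resets the covariance and logs a
warning.

**PCA.**  The 4×10 coefficients are flattened band-major (delta c₁…c₁₀,
theta c₁…c₁₀, …) and reduced to `n_p = 10` components fitted on training
frames only.  Component signs are fixed (largest-magnitude loading
positive) so serialized models are reproducible; a training matrix of rank
below `n_p` is an explicit error.

## Labelling

Windows of `w = 60` frames (10 s) advance by 6 frames (1 s).  A window is
labelled INATTENTION iff its altitude variance *and* velocity variance both
exceed the respective session medians (strict inequality; ties and
all-identical variances fall to attention).  The conjunction was chosen
over a disjunction because it is the reading that keeps the inattention
fraction well below 50 %; it is configurable (`label_rule: both|either`).
Labels are a training-time construct; percentiles are computed over the
whole session, not streamed.

A structural property worth knowing: the median rule places exactly half
of all windows above each channel median.  When only a fraction q ≈ 0.23
of windows are truly degraded, about (0.5 − q)/(1 − q) ≈ 35 % of genuinely
attentive windows must exceed each median, and with independent channels
the conjunction mislabels ≈ 12 % of them.  This caps pure-window agreement
with ground truth near 0.88 *regardless of how well separated the noise
SDs are* (degraded windows already exceed the medians ~99 % of the time).
The label noise is shared by every downstream classifier and is an
inherent cost of the rank-based rule, not an implementation artifact.

Training sets double every inattention window (`oversample_factor = 2`);
the operation refuses to run on a test split.  Splits are random at 8:2 by
window, oversampling strictly after splitting.

## Detection

Two Gaussian-emission HMMs (3 hidden states each) are trained
subject-dependently: the attention HMM on attention-labelled windows'
feature sequences, the inattention HMM on the (oversampled)
inattention-labelled ones.  A 60-frame window is classified by comparing
forward log-likelihoods; ties go to inattention because a missed lapse is
costlier than a spurious alert.

* Fitting: Baum–Welch (hmmlearn) with 5 seeded random restarts, best final
  log-likelihood wins; the full per-iteration trace is retained and is
  non-decreasing on every run.  The practical convergence tolerance is 0.1
  on the absolute log-likelihood (traces plateau within a few dozen
  iterations at session scale).
* Emissions: **full** covariance by default (`hmm_covariance` also accepts
  `diag`).  With tens of thousands of training frames per class the full
  model is well conditioned and measurably improves the generative fit and
  held-out accuracy; the diagonal variant remains for small-data regimes.
  Covariances are floored at 10⁻⁶.
* The forward log-likelihood is computed in log space in-package and is
  verified in the tests against exhaustive path enumeration (all ≤3-state
  models, sequences ≤6) and against the hmmlearn scorer.
* Baseline: an RBF-kernel SVM with library-default hyperparameters on the
  per-window mean feature vector, kept solely for the sequential-vs-static
  comparison.

On synthetic sessions the SVM baseline is a harder opponent than on real
recordings, for a structural reason: consecutive windows overlap by 90 %,
so a randomly split test window shares most of its frames with training
windows, and a high-capacity discriminative model can partially reproduce
even the *noise* component of the median-rule labels from its memorized
neighbours.  The generative two-HMM detector cannot and should not learn
label noise, so its accuracy against the noisy labels trails by several
points under the random split even when its agreement with the *true*
state is equal or better; with a blocked (contiguous, non-overlapping)
split the two models are statistically tied, with the sequential detector
slightly ahead on average.

## Alerting and monitoring

Detection results map to two commands (INATTENTION → ALERT,
ATTENTION → STAY).  An ALERT dispatches one event with both stimuli
(visual + auditory) to every registered sink; sinks are pluggable (an
in-memory log sink and a terminal bell/inverse-video sink ship with the
package) and a failing sink never interrupts monitoring.  Each 1 s cycle
checks the acquisition-device connection first; POOR logs a
manual-adjustment request and skips classification, and a missing status
feed is treated as POOR.  The default refractory period is 0 (every
inattention window alerts); the monitor never mutates the detector.

## Evaluation

Confusion counts take inattention as the positive class;
accuracy = (TP+TN)/total, precision = TP/(TP+FP), recall = TP/(TP+FN),
with zero denominators reported as an explicit `undefined` marker.  The
label-ratio report gives the inattention fraction over the whole
maneuvering and after the start trim, plus a per-minute curve.  The band
diagnostic reports per-band class means and standardized differences and
flags the most elevated band (theta, on sessions with the built-in
signature).  Attention recovery compares the mean telemetry variance in
the 60 frames after each detection between alert-enabled and
alert-disabled paired sessions.

## Problem sizes

Default study sessions are 1800 s (10 795 band frames, ~1730 windows);
unit tests use 300–900 s sessions, and the acceptance script runs three
1800 s end-to-end replicates with 3 HMM restarts and ≤50 EM iterations,
plus 50 paired 300 s recovery replicates.  These sizes were chosen so the
full suite runs comfortably on a single CPU while leaving the statistical
checks well-powered.

## Known limitations

* The simulator's independence assumptions (channels, bands, telemetry
  axes) are stronger than reality; correlated artifacts would stress the
  PCA and the labelling rule in ways these tests do not probe.
* The median-conjunction label rule has the irreducible false-alarm floor
  described above.
* Subject-dependence is emulated only through per-session training; there
  is no between-subject variability model.
* The alerting path renders stimuli as events, not hardware signals.
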