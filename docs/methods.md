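# Methods

`neurobrake` implements an EEG-based detector of emergency-braking
intention for simulated driving: a 1-s, 8-channel EEG window is
classified every step (62.5–250 ms) as *normal driving* or *braking
intention*, with executed braking events detected automatically from a
co-recorded 6-axis IMU and used to label training data.  Because no
recording of the original driving experiment is distributable, the
package ships a synthetic-session generator that reproduces the
statistical structure the pipeline assumes; everything downstream of
the generator treats a session identically whether it is synthetic or
recorded.

## Synthetic driving sessions

A session is a pair of time-aligned streams on a shared 128 Hz clock:
8 EEG channels (µV; 10–20 labels F3…O2) and 6 IMU channels
(3-axis accelerometer + 3-axis gyroscope, in raw counts).

**Event process.**  Executed-braking times are drawn with
shifted-exponential inter-event gaps: a hard minimum of 6 s (so the 5-s
post-event discard zone of one event can never touch the next event's
1-s pre-braking window) plus an exponential excess, giving a
configurable mean interval of 23 s — the mean spacing observed between
emergency stimuli in the driving experiments this pipeline targets.
Each event carries a reaction time drawn from N(876 ms, 150 ms),
defining the stimulus time recorded in `truth_events`.

**EEG.**  Each channel is an AR(10) process driven by independent unit
white noise, with poles at: 0.97 (real; 1/f-like roll-off), 0.40
(real), 9.5 Hz radius 0.90 (alpha rhythm), 6 Hz radius 0.55, 20 Hz
radius 0.60, 45 Hz radius 0.30.  Band-averaged power decreases
monotonically from delta through gamma, as in resting EEG.  During the
`pre_braking_signature_ms` interval (default 600 ms) before each
braking time, the alpha pole glides up by 3.75 Hz × `signature_strength`
(clamped inside the alpha band), and the theta- and beta-pole radii are
re-solved numerically so that the theta- and beta-band *integrated*
powers match the baseline spectrum.  The signature is therefore almost
invisible to band-integrated power but directly visible to an
autoregressive fit, which resolves pole positions — this is what makes
AR features outperform band-power features on these sessions by
construction, the same ordering reported for recorded data.  Setting
`signature_strength = 0` makes braking and normal windows statistically
identical (the null model used to guard against label leakage).  The
default strength of 1.0 was calibrated once, at design time, so that
the cross-validated accuracy of the AR pipeline falls in the 0.8-0.9
band observed for recorded sessions (0.82-0.91 across seeds here).

Coefficient switches are implemented with filter-state continuation
(`lfiltic`), so segment boundaries introduce no transients.  The whole
EEG array is scaled to an RMS of `eeg_scale_uv` (default 10 µV); the
amplitude scale after analog-to-digital conversion is not specified by
any reference, and every feature downstream is scale-invariant after
z-scoring, so this is cosmetic.

**IMU.**  Per-axis Gaussian baseline noise (accelerometer SD 3 counts,
gyroscope SD 30 counts) keeps the within-window magnitude SD far below
the 12/120-count detection thresholds during normal driving.  At each
braking time a 300-ms raised-cosine burst is added to the longitudinal
accelerometer axis and the pitch gyroscope axis, with amplitude
calibrated analytically so the magnitude SD inside a 1-s window equals
twice the threshold — events are detectable by construction,
emulating the unambiguous pedal transients in the recordings.

**What the generator does not model:** volume conduction between EEG
channels (channels are independent), eye-blink/EMG contamination
(injected explicitly only in artifact-rejection tests), soft braking,
non-stationary background drift, and any stimulus-locked evoked
potential.  Passing tests therefore demonstrate that the *pipeline*
behaves correctly under its stated assumptions, not that those
assumptions hold for any particular headset or subject.

## Labeling

A 1-s window is event-positive when the SD of the 3-axis gyroscope
magnitude exceeds 120 counts or the accelerometer magnitude SD exceeds
12 counts (either sensor suffices).  Runs of positive windows within
5 s collapse to one event, timestamped at the first sample whose
deviation from the window median exceeds the triggering threshold —
the earliest causal anchor available in a streaming setting.

Windows *ending* in `(e − P, e]` are braking-intention samples for
pre-braking period P ∈ {200, …, 1000} ms; the half-open convention
makes the count per event exactly P/step when P is a multiple of the
step (8 windows for 1000 ms / 125 ms).  Windows overlapping `(e, e+5 s]`
are discarded (post-event instability).  Normal windows must keep 5 s
distance from every event on both sides and be IMU-quiet, and are
subsampled (seeded) to at most twice the braking count, matching the
~1.9:1 imbalance of recorded datasets.

## Preprocessing and artifact rejection

Windows are band-pass filtered 1–60 Hz with a 4th-order Butterworth
applied forward–backward (zero phase; no latency distortion inside a
1-s window).  Artifact rejection decomposes a stretch of EEG with
extended infomax ICA and zeroes components whose approximate entropy
falls below a threshold — blinks and head movements are high-amplitude
and *regular*, hence low-ApEn — then reconstructs the channels; if all
components would be removed, the input is returned with a warning.

The infomax implementation is a deterministic full-batch
natural-gradient iteration (`W ← W + η (I − φ(y)yᵀ/n) W`,
φ(y) = K·tanh(y) + y, K the kurtosis-sign diagonal refreshed every 10
sweeps) on PCA-whitened data, with eigenvalues below 10⁻⁴ of the
largest treated as a rank deficiency (the decomposition then proceeds
in the significant subspace with a warning and pseudo-inverse
reconstruction).  Two numerical choices matter on short data:

* For subspaces of dimension k > 3 with fewer than 50·k samples, the
  learning rate is annealed once the relative update falls below 2×10⁻²
  (scaled with the current rate).  The rotation in a k-dim whitened
  space has k(k−1)/2 free parameters; on a 128-sample window a fully
  converged sample-optimal rotation demonstrably *overfits* — it mixes
  a perfectly isolated artifact direction back into the noise subspace
  (sklearn FastICA, which converges exactly, shows the same failure).
  Bounding the travel keeps genuinely identifiable structure while
  preventing that drift.
* Artifact cleaning is performed on multi-second blocks (the tests use
  8 s) rather than single 1-s windows: the flagged component carries an
  irreducible ~√k/√n fraction of clean signal, so removal at n = 128
  cannot reconstruct contaminated channels faithfully, while at
  n ≈ 1000 the cleaned channels correlate > 0.9 with the clean truth.
  Per-1-s-window decomposition remains fully supported (and is what the
  reconstruction/determinism tests exercise).

ApEn uses the standard m = 2, r = 0.2 × SD; with r proportional to SD
the statistic is amplitude-invariant.  The default artifact threshold
of 0.30 sits between the 1st percentile of clean-component ApEn on 1-s
windows (≈0.24) and on 8-s blocks (≈0.45), computed from seeded clean
simulations; blink-like components score ≈0.1–0.25 at either length.

## Features

**Relative band power.**  512-point periodogram of each 128-sample
channel (zero-padded, boxcar window by default, Hann available),
0.25 Hz bins; absolute band power is the PSD sum over half-open bands
delta [1,4), theta [4,8), alpha [8,14), beta [14,30), gamma [30,60) Hz,
normalized per channel to relative powers.  40 features (5 × 8),
channel-major.  An all-zero channel gets uniform 0.2 per band and is
flagged.  Half-open edges resolve the ambiguity of shared band
boundaries without double-counting bins.

**Burg AR.**  Channels are mean-centered (the mean is the recorded
intercept, excluded from the feature because the input-size arithmetic
8 × p admits no intercept) and fit with the Burg recursion: reflection
coefficients minimize summed forward/backward prediction error
(|k| ≤ 1 by construction, keeping fits on or inside the stationarity
boundary) with Levinson updates of the coefficient polynomial.  The
implementation agrees with `statsmodels`' Burg to machine precision and
with a least-squares AR fit to < 0.02 at length 4096.  The feature vector holds, per channel, the p
coefficients plus the innovation variance — 8 × (p+1) values,
channel-major, matching classifier input sizes 32…168 for p ∈ [3, 20]
(order 10 default).

## Classifier

A three-layer perceptron: D inputs (40 or 8(p+1)), sigmoid hidden layer
(default 50 units), 2-unit softmax output, mean cross-entropy loss.
Features are z-scored with constants fit on training data only.
Training is full-batch gradient descent with a bold-driver step
(grow 5 % on improvement, halve and retry on worsening), which makes
runs deterministic per seed and the recorded training-loss history
non-increasing; early stopping monitors validation cross-entropy
(patience 10) and restores the best weights.  Class indices are fixed:
0 = normal, 1 = braking; exact probability ties resolve to 0.
Analytic gradients are verified against central finite differences to
10⁻⁶ relative error in the tests.

## Evaluation

Braking intention is the positive class: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP); zero-denominator metrics are reported as
`None`, never NaN.  ROC/AUC uses the full threshold sweep
(trapezoidal AUC = normalized Mann–Whitney U with ties at ½).

Cross-validation is stratified, shuffled 5-fold.  When a feature table
carries provenance groups (it does when built from a session), folds
additionally keep all windows of one braking event — and all windows of
one quiet segment — together.  This matters: overlapping windows
(87.5 % overlap at the 125-ms step) are strongly correlated, and plain
sample-level shuffling lets that correlation leak between train and
validation — on null sessions (no EEG signature at all) plain shuffling
produced AUC ≈ 0.65 where grouped folds correctly give ≈ 0.5.  Both
the mean of per-fold metrics and pooled-prediction metrics are
reported, since the aggregation convention is ambiguous in common
usage.  Parameter sweeps (`ar_order` 3–20, `step_ms` {62.5, 125, 250},
`pre_braking_ms` {200…1000}, `n_hidden` {10…1000}) re-run labeling from
the session whenever the parameter changes the label structure, so
training data are always collected exactly as in online testing.

## Online detection

A rolling 1-s buffer advances by the step size; each step runs the
identical band-pass → featurize → standardize → predict path used in
training, so streaming output is bit-identical to batch segmentation
(asserted in the tests).  Per-step labels are the plain argmax.  A
*detection event* requires confidence: it fires on the 3rd consecutive
step whose braking probability exceeds 0.95, and at most once per
braking episode.  These defaults were measured at design time on
synthetic sessions: an unconfident 2-step rule produced ≈18 false
alarms/min, while 3 steps at 0.95 gives event recall 1.0 with ≈0.2
false alarms/min and a mean lead of ≈180 ms before the executed
braking.  Both knobs are exposed (`smoothing_n`,
`detection_threshold`).  Lead time is measured to the IMU-detected
braking onset.

## Problem sizes

The test suite and the acceptance script use 10-minute sessions
(~25 events, ~350–580 labeled samples at the default step), 5-fold CV,
and 10 minutes of streaming at 62.5-ms steps — the same session length
as the online evaluation the pipeline targets, and large enough that
the qualitative orderings (AR > band power; short pre-braking periods >
1000 ms; order 10 ≥ order 3) are stable across seeds.

## Known limitations

* Independent-channel EEG means ICA has no volume-conduction mixing to
  undo in pipeline data; artifact rejection is validated on explicitly
  constructed mixtures instead, and is off by default in the feature
  path (`use_ica=True` enables it).
* The per-window ICA regime (n = 128, k = 8) is at the edge of
  identifiability; the travel-gated schedule is a pragmatic
  regularizer, not an optimality guarantee.
* The IMU event detector is threshold-based and tuned to unambiguous
  emergency transients; soft braking is out of scope.
* Detection lead times are bounded above by the signature onset
  (600 ms) minus the debounce span, and shrink as the confidence
  threshold rises.
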