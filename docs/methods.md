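# Methods

`handpilot` models two residual-function control interfaces for people with
high spinal cord injury who retain voluntary control of a few supra-lesional
muscles or small shoulder/arm movements.  Either interface drives the same
three-command state machine — at-rest (RS), hand-open (HO), hand-close (HC)
— which in turn drives a simulated robotic hand or a two-channel functional
electrical stimulation (FES) device.  This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Command state machine

Three states, four edges: RS→HO, RS→HC, HO→RS, HC→RS.  Direct HO↔HC
transitions do not exist; changing gesture passes through rest.  Conditions
are *triggers*: when none holds, the machine keeps its state.  Per modality:

| edge      | EMG condition                      | IMU condition      |
|-----------|------------------------------------|--------------------|
| RS→HC     | Env1 > RH1 **and** Env2 < RL2      | movement ∈ class 2 |
| RS→HO     | Env2 > RH2 **and** Env1 < RL1      | movement ∈ class 1 |
| HO/HC→RS  | Env1 < RL1 **and** Env2 < RL2      | any movement       |

The two-sided EMG entry condition is a co-contraction guard: a command fires
only when one muscle is clearly active *and* the other clearly relaxed.  The
low/high pair per muscle (RL < RH) provides hysteresis — entry requires
crossing the high threshold, release requires dropping below the low one —
so envelope chatter inside the band cannot toggle the command.

There is no minimum dwell or debounce time by default (a configurable
refractory exists in `run_session`).  The EMG machine is evaluated on the
envelope decimated to a 100 Hz decision tick: the envelope is band-limited
to 4 Hz, so evaluating at the raw 5 kHz rate would add cost and no
information.

## EMG pipeline

Raw two-channel surface EMG (nominally 5 kHz) passes through a 4th-order
Butterworth high-pass at 20 Hz, full-wave rectification, and a 4th-order
Butterworth low-pass at 4 Hz.  Decoding uses causal (`sosfilt`) filtering,
matching online use and the system's latency behavior; zero-phase
(`sosfiltfilt`) is available for offline inspection only.  Filter state is
initialized to the first sample's steady state, and the first 0.5 s are
treated as a settling window excluded from triggering.

Calibration records each muscle at rest and during a strong voluntary
contraction (VC) held for 4 s.  The VC reference statistic is the mean
envelope over the central part of the contraction plateau (the contiguous
region above half the peak, trimmed 12.5% per side — the central 3 s of a
4 s hold).  The mean-over-plateau was chosen over the peak because the peak
of a noisy envelope is biased upward and unstable across recordings;
`peak` and `p95` variants are available.  Calibration is rejected when the
VC reference does not exceed 3× the rest level — the contraction is "not
clearly visible" and should be re-recorded.

Threshold ratios default to RL = 0.2 and RH = 0.6 of VC.  A second, manual
fine-tuning phase (raising RH for comfort, lowering RL for easier release,
asymmetric per-muscle settings for habitual co-contractors) has no
algorithm; it is exposed purely as per-muscle ratio overrides.

Muscle→command polarity follows the state-machine conditions (muscle 1
closes, muscle 2 opens) and is configurable; clinical descriptions of which
muscle should open the hand vary and the mapping is a deployment choice.

## IMU pipeline

The 6-axis stream (3-axis accelerometer + 3-axis gyroscope, nominal
~47 Hz, irregular timestamps, dropped samples) is first-differenced per
sample, **without** dividing by dt.  Differencing removes the constant
gravity offset and converts short movements into large excursions; skipping
dt normalization keeps thresholds, features and classification in one
consistent unit system, and the realized-rate bookkeeping below absorbs
rate variation.  The magnetometer and Euler angles are not used
(environment-dependent calibration).

*Activation thresholds.*  α_i = max_k |X_{i,k}| / 2 over a calibration
segment containing the instructed movements.  The absolute value makes the
threshold symmetric — movements produce signed excursions in either
direction, and a one-sided max would miss negative-going movements.

*Onset detection.*  An onset fires when **any** axis exceeds its threshold.
Requiring all six simultaneously would almost never fire, since each α_i
derives from that axis's own maximum; the all-axes variant remains
available (`mode="all"`).  A 1 s refractory window after each onset
prevents one movement from triggering twice (calibration movements are
spaced by ~1 s rests).

*Features.*  Around onset k, θ_i = RMS of X_i over a 1 s window centered on
k.  The window length in samples is N = round(f · 1 s), where f is the
number of timestamps in the trailing second — recomputed at every onset
because wireless links drop samples, so N tracks the realized local rate
(≈42 at 10% drops).  The centered window means the decision can only be
emitted at the window's trailing edge, ≈0.5 s after the movement; this
latency is a structural property of the feature, not an implementation
artifact, and is measured by the acceptance script.

*Classifier.*  Calibration features are mean-centered; the top two
principal directions (SVD, sign fixed by making each component's
largest-magnitude loading positive) form the 2×6 projection P.  Class
centroids are the per-class means of the projected calibration points.  A
new movement is projected (M = P·(θ − mean)) and labelled by the nearest
centroid in Euclidean distance, ties to class 1.  Every movement receives a
label — there is no reject class by default; a reject radius can be layered
on but widens the interface's failure modes in a different direction
(missed commands instead of wrong ones).  Mean-centering is standard
practice; because the same mean is subtracted at fit and classify time, the
point-to-centroid geometry is identical to the uncentered variant up to
component orientation.

## Synthetic signals

The generator exists because no recordings ship with the package; its
defaults are the study conditions the rest of the suite assumes.

*EMG.*  Each channel is baseline Gaussian noise (σ = 0.01 raw units) plus
unit-variance 20–450 Hz band-limited Gaussian noise amplitude-modulated by
a trapezoidal activation profile (0.2 s ramps) — the standard
phenomenological surface-EMG model.  The VC calibration contraction has
amplitude 1.0; task contractions default to 0.8 of VC.  A fraction κ
(default 0) of each activation leaks into the opposite channel to emulate
co-contraction.

*IMU.*  Timestamps are a 47 Hz grid with 2 ms Gaussian jitter and
per-sample drop probability (default 5%; trials use 10%).  Each movement is
a 0.4 s Gaussian-windowed 8 Hz oscillation of amplitude 8 sensor units,
distributed over the six axes by a unit "axis-energy signature" per class
(defaults: accel-x+gyro-x vs accel-y+gyro-y — two orthogonal movement
directions), on top of a constant 9.81 accel-z gravity offset and
σ = 0.05 sensor noise.  Every burst additionally carries a
class-independent common-mode component (fraction 0.4, renormalized):
a real limb movement shakes all axes somewhat, and without it four axes
would carry pure noise, putting their thresholds at half the noise maximum
— a level noise itself crosses.  Class identity lives entirely in the
signature part.  A per-movement signature rotation by ~`signature_angle_noise`
radians (default 0) models inconsistent movement execution.

What the generator does **not** emulate: biomechanically realistic limb
kinematics, fatigue and electrode-lift drift, FES-evoked EMG artifacts
(sensors sit contralateral to stimulation), and real inter-subject
variability.  Passing tests therefore show that the algorithms implement
their definitions and are robust to the modeled noise, jitter, drops and
leakage — not that clinical performance figures transfer.

*Simulated user.*  Maps an instructed transition to an executed action;
with probability `confusion_rate` an activation uses the wrong
muscle/movement.  Releases always succeed by construction (relaxation for
EMG, either movement for IMU) — mirroring the interface design, where
release is deliberately the easy direction.  Reaction latency defaults to
0.3 s.

## Validation protocol

A validation sequence is a uniform shuffle of 5 hand-open and 5 hand-close
trials, each expanded to its activation and release instruction — 20
instructions, exactly 5 per transition type, always feasible from rest.
An instruction is correct when the first achieved state change within its
response window (default timeout 10 s, truncated at the next instruction)
reaches the instructed target; performance = correct / desired.  All 20
instructions are scored by default; `activations_only` restricts the
denominator to the 10 RS→X instructions, since whether releases count in
the human protocol's denominator is not fully determined.  Simulated
trials schedule instructions every 6 s (EMG — the contraction is held
between activation and release) or 4 s (IMU — one burst per instruction).

## Numerical choices and degenerate inputs

- Causal filters initialized with `sosfilt_zi` scaled to the first sample;
  0.5 s settling exclusion.
- Envelope clipped at 0 (the low-pass can undershoot on sharp edges).
- Decimation by plain striding (envelope band-limited far below the tick
  Nyquist).
- All-zero IMU calibration channel ⇒ threshold 0 plus a degenerate-channel
  warning; rank-deficient feature matrices warn that the second component
  is arbitrary within the null space.
- Feature windows that overrun the stream are deferred online and clipped
  with a warning offline.
- PCA sign fixed by the largest-|loading|-positive convention; classifier
  ties break to class 1.
- Random generation uses `numpy.random.default_rng` seeded per config;
  identical seeds give bit-identical sessions.

## Problem sizes

The test suite and acceptance script run entirely on generated data:
calibration sessions of 10 movements per class (IMU) or one 4 s VC per
muscle (EMG), validation trials of 20 instructions (≈126 s of 5 kHz EMG or
≈85 s of 47 Hz IMU per trial), latency measured over 5 movements, and
statistical properties over 10–12 seeds or trials per condition.  These
sizes give binomial/rank statistics comfortable margins while keeping any
single check in the seconds range.

## Known limitations

- The second-phase threshold fine-tuning is config-only; no adaptation
  algorithm is provided.
- Proportional (contraction-intensity) control and >2 movement classes are
  out of scope.
- The stimulator model is command-level (channel on/off with parameters);
  no pulse-train waveform synthesis and no safety interlocks — real FES
  hardware drivers are explicitly not part of this package.
- Latency is reported for the IMU path; EMG latency is set by the 4 Hz
  low-pass group delay and envelope rise time and is not separately
  calibrated.
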