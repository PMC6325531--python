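# Methods

This note documents the models, signal-processing choices and numerical
conventions behind `trackadapt`, and states what the synthetic-data
generator does and does not emulate.

## Screen geometry and units

All positions are screen centimetres with the origin at the screen centre,
+x rightward and +y upward. At the 57 cm viewing distance assumed
throughout, 1 cm on the screen subtends 1.00° of visual angle (to within
0.01°), so centimetres and degrees are used interchangeably at a 1:1 ratio
(`DEG_PER_CM = 1`). Signals are sampled at 1000 Hz and trials last 10 s
(10,000 samples) unless configured otherwise.

## Target synthesis

**Tabulated patterns.** Externally moved targets combine two sinusoids per
axis — a fundamental plus a second or third harmonic with an axis-specific
phase — giving smooth, pseudo-random-looking closed paths. Five parameter
rows ship with the package (`data/target_patterns.tsv`). The fundamental
angular frequency is not part of that table; the package default is
ω = 2π·0.2 rad/s, i.e. two fundamental cycles per 10-s trial. This value is
a documented assumption, chosen because (a) a closed path requires an
integer number of fundamental cycles per trial, and (b) it reproduces the
nominal 160 cm arc length of all five patterns (158.3–160.7 cm). Because
arc length over a fixed duration is strictly increasing in ω,
`calibrate_fundamental` can re-derive ω from any nominal length by
bracketed root finding; on the shipped table it recovers the default to
0.1%.

**Self-moved-style targets.** `make_random_trajectory` models instructed
"as unpredictable as possible" joystick wiggling: Gaussian white velocity
noise, band-pass filtered to 0.1–2 Hz (zero phase, generated with padding
so filter edge transients never enter the trial), integrated to position,
folded into a ±15 cm box (the joystick's 25° excursion maps to 15 cm), and
iteratively rescaled so the mean tangential speed equals the 16 cm/s
set-point exactly (the fold is an isometry except at fold points, so a few
rescale–refold passes converge). The band matters: purely low-passed
velocity noise yields positions *smoother* (by approximate entropy) than
the sinusoidal patterns, the opposite of what self-generated wiggling looks
like; the 0.1 Hz lower edge contributes slow screen-covering sweeps and the
2 Hz upper edge the irregular wiggle, making generated paths robustly less
regular than the tabulated ones at matched length while keeping pursuit-
scale accelerations (~400°/s²) far below the saccade-detection threshold.

## The adaptive participant

No mechanistic participant model exists for this paradigm; the simulator
is the simplest generator that reproduces the qualitative dynamics, with
every knob exposed in `SimConfig`.

**Learning.** Each channel (hand, eye) carries an internal estimate
`theta_hat` of the applied rotation, updated once per trial by the
single-rate state-space rule

    theta <- retention * theta + alpha * (mapping - theta_effective)

with `retention = 0.999`, `alpha_hand = 0.12`, `alpha_eye = 0.5`. With
full retention and no noise the residual error after n trials is exactly
`90·(1−alpha)^n`, which the tests check against the simulation. The eye
rate brings eye tracking back to baseline within roughly ten trials; the
hand rate converges the *estimate* almost fully within 40 trials while
hand *performance* stays above baseline (next paragraph).

**Execution difficulty.** Hand motor noise scales with the magnitude of
the counter-rotation being executed
(`sd · (1 + rotation_difficulty·|theta|/90)`, `rotation_difficulty = 1.5`).
This separates prediction from control: the internal estimate can converge
(which is what transfers to the eye task) while executing the unfamiliar
counter-rotated mapping remains noisy, so hand-task error never returns to
baseline within the rotation block. Without this term a single-rate
learner cannot show both phenomena at once.

**Transfer.** Tasks read each other's estimates through directional
weights: the eye channel sees
`theta_hat_eye + transfer_hand_to_eye·theta_hat_hand` (default weight 1),
the hand channel sees
`theta_hat_hand + transfer_eye_to_hand·theta_hat_eye` (default 0). This
generates the asymmetric-transfer phenomenon; it deliberately does not
adjudicate *why* transfer is asymmetric.

**Oculomotor model.** Between saccades the eye follows an internal goal
with a pure tracking delay plus smoothed gaze jitter. For a self-moved
target the goal is the target position predicted from the efference copy
of the hand command rotated by the eye channel's estimate; prediction also
compensates `prediction_lead_ms = 30` of the `pursuit_lag_ms = 50` reactive
delay, leaving an effective self-moved lag of ~20 ms. Catch-up saccades
trigger when the eye–target distance exceeds 1.5 cm, execute after a
120 ms latency as minimum-jerk gaze shifts landing on the target, and add
a persistent position offset (error then re-accumulates at the rate the
goal drifts from the target, which is what makes saccade rate grow with
rotation mismatch). Saccade duration follows a main-sequence-like rule
(30 ms + 2 ms/°), shortened when necessary so the peak acceleration reaches
at least `saccade_peak_acc = 6000°/s²` — comfortably above the 1500°/s²
detection threshold at any amplitude (the minimum-jerk peak acceleration
is (10/√3)·A/T²).

**Playback trials** emulate watching one's own previously generated target
with the hand at rest: no efference copy, so the tracking delay is
`playback_lag_multiplier = 2` times the *effective* self-moved lag
(2 × 20 = 40 ms), and saccades are purely reactive. Because a reactive
saccade that lands on the current target would cancel the very lag being
modelled, reactive triggering is conservative
(`playback_trigger_multiplier = 2` on the trigger distance) — a stand-in
for deciding on degraded, delayed sensory error. The modelled playback/self
lag ratio of ≈2 and the increased playback distance are the quantities the
tests assert; absolute millisecond values are not fitted to human data.

**Blinks** are Poisson events (3.6/min, 150 ms) that zero the pupil trace
and clear the validity flag, giving ≈0.9% invalid samples per trial.

**Protocol.** Two groups × 12 participants by default; per participant,
baseline (10 trials), rotation (40, 90° CCW), washout (2) in both tasks,
with the hand-first group doing hand before eye within each phase and the
eye-first group the reverse. Hand-task patterns are drawn balanced (each
block contains each of the five patterns equally often, shuffled).
Per-participant RNG streams are split from the run seed with a stable
spawn key (seed, group hash, participant index), so adding participants
never perturbs existing ones; learning rates get mild lognormal
between-participant jitter (sd 0.1, an arbitrary but documented
variability knob — real inter-participant structure is unknown).

## Preprocessing

Gaze calibration is a least-squares affine map fitted to nine fixation
means (rank checked; residual RMS reported). All position signals are
low-pass filtered with a 4th-order Butterworth at 25 Hz; **zero-phase**
(forward–backward) filtering is the default because lag estimation must
not be biased by filter group delay — a causal mode is retained for
sensitivity analysis. The kinematic chain mirrors standard oculomotor
practice: position → filter → central-difference velocity → filter →
tangential speed → central-difference → filtered tangential acceleration.
Blinks are masked (pupil ≤ threshold, dilated ±50 ms), never interpolated,
and masked samples are excluded from every downstream mean. The first
second of every trial is discarded from all metrics.

## Metrics

**Interleaved cross-correlation lag.** To use both axes in a single lag
estimate, the x and y samples of each signal are interleaved and the
normalized cross-correlation is evaluated only at shifts that are
multiples of two interleaved samples (whole physical samples). At such
shifts the interleaved product sum equals the sum of per-axis product
sums, which is how the scan is evaluated (FFT-based, per-lag normalized,
validity-weighted). Positive lag means the first signal trails the second;
lags up to ±500 ms are searched by default. The estimator recovers
constructed integer-millisecond shifts exactly and agrees with the mean of
per-axis lags within 2 ms on pursuit-like data.

**Saccade detection.** An event is a tangential-acceleration peak paired
with the first deceleration trough within 120 ms, both exceeding
1500°/s²; the event spans the surrounding acceleration zero-crossings,
and amplitude is the eye displacement over that span. A secondary velocity
criterion (speed peak > 30°/s with matching prominence, transient width
< 100 ms, and at least a third-of-threshold acceleration spike) recovers
small saccades that the acceleration criterion alone misses — the
package's replacement for the manual identification of sub-1° saccades.
Events closer than 20 ms are merged; events overlapping blink-masked
samples are discarded. Note the 25 Hz filtering attenuates the raw
acceleration transient of a saccade by roughly 2–4×, which the default
simulator saccade kinematics leave ample headroom for.

**Approximate entropy.** Standard ApEn(m, r) = Φ_m − Φ_{m+1} with
self-matches included (the original convention), m = 2 and
r = 0.2·SD(signal); a zero-variance series returns 0 by convention.
Because template counting is O(n²), per-trial metrics decimate the
joystick signal to 100 Hz before ApEn (configurable); the implementation
shares one pairwise-distance matrix between the two embeddings for small
n and falls back to a memory-chunked scan for large n, and matches a
brute-force template-count oracle to 1e-10.

**Dispatch.** Hand trials yield cursor–target, eye–target and eye–cursor
distances; eye/playback trials yield eye–target distance, interleaved lag
and per-axis joystick ApEn; saccade statistics (rate over the analyzed
9 s, mean amplitude) are computed for every trial with an eye channel.

## Learning statistics

Per-trial error series are fitted with `error = a·e^(b·trial) + c`
constrained to a ≥ 0, b ≤ 0, c ≥ 0 (the unconstrained problem is not
identifiable on noisy short series), by bounded trust-region least squares
with a multi-start over b ∈ {−1, −0.3, −0.1, −0.03}; the best SSE wins.
Goodness of fit is the Pearson correlation R between fitted and observed
values, normalized by the Fisher z (arctanh) transform — the standard
log-based normalization of correlation coefficients, adopted here as the
interpretation of "logarithmic (z-score) normalization". Flat fits or flat
data leave R undefined (flagged NaN).

The group analysis is a balanced two-way mixed ANOVA — between-subject
factor GROUP, within-subject factor TIME, where TIME bins are the means of
trial pairs (1–2), (19–20), (39–40) — decomposed into GROUP,
subjects-within-group, TIME, GROUP×TIME and TIME×subjects-within-group,
with F ratios against the matching error terms (a 2×12×3 design gives the
F(1,22)/F(2,44) layout). Unbalanced designs are rejected rather than
approximated. Post-hoc comparisons use the Newman–Keuls stepwise procedure
with studentized-range criticals computed numerically from
`scipy.stats.studentized_range` (validated against published table values
in the tests); a non-significant stretch blocks all nested comparisons.
The significance threshold is 0.05. Aftereffects are reported as
100·(mean(post) − mean(late))/mean(late); the transfer index is
(naive early − experienced early)/(naive early − naive baseline), i.e. 1
for complete transfer and 0 for none.

## What the generator does and does not show

The simulator reproduces the *qualitative* phenomena: ≥3× error increase
at rotation onset in hand tracking, eye tracking back to baseline within
~10 trials while hand tracking stays elevated through trial 40, aftereffects
in both tasks at washout, near-complete hand→eye transfer and near-zero
eye→hand transfer, doubled lag and degraded accuracy during playback, and
self-moved targets more entropic than the tabulated ones. It is *not*
fitted to the human group means (e.g. exact percent changes or
millisecond lags), carries no biomechanics, no saccadic suppression and no
realistic inter-participant covariance structure. Passing tests therefore
demonstrate that the analysis chain measures these phenomena correctly
when they are present — not that human data would yield the same numbers.

## Problem sizes and numerical conventions

The end-to-end checks run the full protocol at the study's size
(12 participants per group, 2496 trials at 1000 Hz); unit tests use 1–2
participants or single trials. Root finding uses Brent's method on a
bracketed interval ([1e-3, 1e2] rad/s for ω). Correlation denominators of
zero yield r = 0 rather than NaN. Degenerate ANOVA variance follows the
convention: zero effect over zero error is F = 0; a real effect over zero
error is an error. Saccade events must span at least 8 samples. All
randomness flows from `numpy.random.Generator` instances seeded explicitly;
every public entry point is deterministic given its seed.
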