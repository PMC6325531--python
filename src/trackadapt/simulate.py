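"""Adaptive-participant simulator for eye-hand tracking under rotated feedback.

The experiment this generator emulates has two tracking tasks performed under
a visuomotor rotation of the joystick-to-screen mapping:

* **hand tracking** — the participant moves a joystick to keep a cursor on an
  externally moved target (sum-of-sinusoids path);
* **eye tracking** — the participant wiggles a self-moved target with the
  joystick while keeping gaze on it, which probes the ability to *predict*
  the visual consequences of one's own hand movement.

Adaptation is modelled with a single-rate state-space learner per channel:
an internal rotation estimate ``theta_hat`` is updated once per trial by
``theta <- retention * theta + alpha * (mapping - theta)``.  Transfer between
tasks is modelled as weighted read access to the other channel's estimate
(defaults: hand adaptation is fully visible to the eye channel, eye
adaptation is invisible to the hand channel), which generates the
asymmetric-transfer phenomenon without committing to a mechanistic account.

The oculomotor model combines delayed smooth pursuit of an internal goal
(the predicted target position when the target is self-moved) with catch-up
saccades: whenever the eye-target distance exceeds a trigger threshold, a
minimum-jerk gaze shift to the target is executed after a latency.  Blinks
are injected as Poisson events that zero the pupil trace.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .trajectory import (
    PointSeries,
    SamplingSpec,
    load_target_patterns,
    make_random_trajectory,
    make_trajectory,
    rotate_xy,
)

__all__ = [
    "LearnerState",
    "SimConfig",
    "TrialRecording",
    "simulate_hand_trial",
    "simulate_eye_trial",
    "simulate_playback_trial",
    "inject_blinks",
    "run_experiment",
    "GROUP_HAND_FIRST",
    "GROUP_EYE_FIRST",
    "DEFAULT_PROTOCOL",
]

GROUP_HAND_FIRST = "hand_first"
GROUP_EYE_FIRST = "eye_first"

#: (phase, mapping_deg, n_trials) protocol blocks, per task.
DEFAULT_PROTOCOL = (
    ("baseline", 0.0, 10),
    ("rotation", 90.0, 40),
    ("washout", 0.0, 2),
)

# peak acceleration of a minimum-jerk displacement A over duration T is
# 10/sqrt(3) * A / T^2
_MINJERK_ACC = 10.0 / math.sqrt(3.0)


@dataclass
class LearnerState:
    """Per-channel internal estimates of the applied rotation (deg)."""

    theta_hat_hand: float = 0.0
    theta_hat_eye: float = 0.0

    def copy(self) -> "LearnerState":
        return LearnerState(self.theta_hat_hand, self.theta_hat_eye)


@dataclass(frozen=True)
class SimConfig:
    """Simulator parameters.

    Learning: ``alpha_hand``/``alpha_eye`` are per-trial error-driven update
    rates, ``retention`` the per-trial retention factor.  The hand rate is
    slow enough that hand tracking does not return to baseline within a
    40-trial rotation block, while the eye rate brings eye tracking back to
    baseline within roughly ten trials.

    Oculomotor: ``pursuit_lag_ms`` is the reactive pursuit delay;
    ``prediction_lead_ms`` is how much of that delay efference-copy-based
    prediction compensates when the target is self-moved.  Catch-up saccades
    fire when the eye-target distance exceeds ``saccade_trigger_cm``, execute
    after ``saccade_latency_ms`` with a minimum-jerk profile whose duration
    follows a main-sequence-like rule (30 ms + 2 ms/deg), shortened if needed
    so the peak acceleration reaches at least ``saccade_peak_acc`` deg/s^2
    (kept well above the 1500 deg/s^2 detector threshold).
    """

    alpha_hand: float = 0.12
    alpha_eye: float = 0.5
    retention: float = 0.999
    transfer_hand_to_eye: float = 1.0
    transfer_eye_to_hand: float = 0.0

    motor_noise_sd: float = 0.4        # cm, smoothed additive hand noise
    #: executing a counter-rotated mapping is harder than the intuitive one:
    #: hand motor noise grows by this factor at a full 90 deg counter-rotation,
    #: so hand tracking stays above baseline even once the rotation estimate
    #: has converged (control remains imperfect while prediction is updated)
    rotation_difficulty: float = 1.5
    eye_noise_sd: float = 0.15         # cm, smoothed gaze jitter
    noise_cutoff_hz: float = 5.0

    feedback_delay_ms: float = 30.0    # residual hand-tracking loop delay
    pursuit_lag_ms: float = 50.0
    prediction_lead_ms: float = 30.0
    pursuit_gain: float = 1.0
    playback_lag_multiplier: float = 2.0

    saccade_trigger_cm: float = 1.5
    saccade_latency_ms: float = 120.0
    saccade_peak_acc: float = 6000.0   # deg/s^2
    saccade_refractory_ms: float = 50.0
    #: without an efference copy the sensed tracking error is itself delayed
    #: and uncertain, so reactive (playback) saccades trigger conservatively
    playback_trigger_multiplier: float = 2.0

    blink_rate_per_min: float = 3.6
    blink_duration_ms: float = 150.0

    hand_speed_setpoint: float = 16.0  # cm/s mean tangential target speed
    participant_sd: float = 0.1        # lognormal jitter of learning rates

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_hand", "alpha_eye", "retention",
                     "transfer_hand_to_eye", "transfer_eye_to_hand"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.saccade_peak_acc > 1500.0:
            raise ValueError("saccade_peak_acc must exceed the 1500 deg/s^2 "
                             "detection threshold")

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass
class TrialRecording:
    """One simulated (or loaded) trial: sample streams plus metadata."""

    t_ms: np.ndarray
    target_xy: np.ndarray
    eye_xy: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray
    cursor_xy: np.ndarray | None = None
    hand_xy: np.ndarray | None = None
    task: str = "hand"               # hand | eye | playback
    mapping_deg: float = 0.0
    group: str = ""
    phase: str = ""
    trial_index: int = 0
    pattern_id: int = 0
    participant: str = ""

    @property
    def fs(self) -> float:
        return 1000.0 / float(self.t_ms[1] - self.t_ms[0])

    @property
    def duration_s(self) -> float:
        return (float(self.t_ms[-1] - self.t_ms[0]) + 1000.0 / self.fs) / 1000.0

    @property
    def n_samples(self) -> int:
        return len(self.t_ms)

    def meta(self) -> dict:
        return {
            "task": self.task,
            "mapping_deg": self.mapping_deg,
            "group": self.group,
            "phase": self.phase,
            "trial_index": self.trial_index,
            "pattern_id": self.pattern_id,
            "participant": self.participant,
            "n_samples": self.n_samples,
        }

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "t_ms": self.t_ms,
            "target_x_cm": self.target_xy[:, 0],
            "target_y_cm": self.target_xy[:, 1],
            "eye_x_cm": self.eye_xy[:, 0],
            "eye_y_cm": self.eye_xy[:, 1],
            "pupil": self.pupil,
            "valid": self.valid.astype(int),
        })
        if self.cursor_xy is not None:
            df["cursor_x_cm"] = self.cursor_xy[:, 0]
            df["cursor_y_cm"] = self.cursor_xy[:, 1]
        if self.hand_xy is not None:
            df["hand_x_cm"] = self.hand_xy[:, 0]
            df["hand_y_cm"] = self.hand_xy[:, 1]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **meta) -> "TrialRecording":
        def _xy(prefix: str) -> np.ndarray | None:
            cols = [f"{prefix}_x_cm", f"{prefix}_y_cm"]
            if not all(c in df.columns for c in cols):
                return None
            return df[cols].to_numpy(dtype=float)

        return cls(
            t_ms=df["t_ms"].to_numpy(dtype=float),
            target_xy=_xy("target"),
            eye_xy=_xy("eye"),
            pupil=df["pupil"].to_numpy(dtype=float),
            valid=df["valid"].to_numpy().astype(bool),
            cursor_xy=_xy("cursor"),
            hand_xy=_xy("hand"),
            **meta,
        )


# ---------------------------------------------------------------------------
# low-level building blocks


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, sd: float,
                  cutoff_hz: float) -> np.ndarray:
    """(n, 2) low-pass filtered Gaussian noise with per-axis SD ``sd``."""
    if sd == 0.0:
        return np.zeros((n, 2))
    raw = rng.standard_normal((n, 2))
    sos = _signal.butter(2, cutoff_hz, fs=fs, output="sos")
    sm = _signal.sosfiltfilt(sos, raw, axis=0)
    sm *= sd / sm.std(axis=0, keepdims=True)
    return sm


def _delay(xy: np.ndarray, n_samples: int) -> np.ndarray:
    """Shift a signal later in time, padding with the initial sample."""
    if n_samples <= 0:
        return xy.copy()
    out = np.empty_like(xy)
    out[:n_samples] = xy[0]
    out[n_samples:] = xy[:-n_samples]
    return out


def _advance(xy: np.ndarray, n_samples: int) -> np.ndarray:
    """Shift a signal earlier in time (look-ahead), padding the tail."""
    if n_samples <= 0:
        return xy.copy()
    out = np.empty_like(xy)
    out[:-n_samples] = xy[n_samples:]
    out[-n_samples:] = xy[-1]
    return out


def _minjerk_profile(n: int) -> np.ndarray:
    """Normalized minimum-jerk position profile s(tau), s(0)=0, s(1)=1."""
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _saccade_duration_s(amp_deg: float, peak_acc: float, fs: float) -> float:
    """Main-sequence duration, shortened so peak acceleration >= peak_acc."""
    t_main = 0.030 + 0.002 * amp_deg
    if amp_deg > 0:
        t_cap = math.sqrt(_MINJERK_ACC * amp_deg / peak_acc)
        t = min(t_main, t_cap)
    else:
        t = t_main
    return max(t, 8.0 / fs)


def _pursue_with_saccades(
    goal_xy: np.ndarray,
    target_xy: np.ndarray,
    fs: float,
    delay_ms: float,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Delayed pursuit of an internal goal plus catch-up saccades to the target.

    Between saccades the eye follows ``goal`` (delayed by ``delay_ms``) plus
    a constant positional offset; each saccade resets that offset so that the
    eye lands on the *actual* target, after which error re-accumulates at the
    rate the goal drifts away from the target.
    """
    n = len(goal_xy)
    base = cfg.pursuit_gain * _delay(goal_xy, int(round(delay_ms * fs / 1000.0)))
    base = base + _smooth_noise(rng, n, fs, cfg.eye_noise_sd, cfg.noise_cutoff_hz)

    eye = base.copy()
    offset = np.zeros(2)
    latency = int(round(cfg.saccade_latency_ms * fs / 1000.0))
    refractory = int(round(cfg.saccade_refractory_ms * fs / 1000.0))
    i = 0
    for _ in range(200):  # saccade budget per trial
        err = np.linalg.norm(target_xy[i:] - (base[i:] + offset), axis=1)
        over = np.nonzero(err > cfg.saccade_trigger_cm)[0]
        if over.size == 0:
            break
        t0 = i + int(over[0])
        onset = t0 + latency
        if onset >= n - 2:
            break
        jump = target_xy[onset] - (base[onset] + offset)
        amp = float(np.linalg.norm(jump))
        dur = _saccade_duration_s(amp, cfg.saccade_peak_acc, fs)
        m = min(int(round(dur * fs)), n - onset)
        prof = _minjerk_profile(m)
        eye[i:onset] = base[i:onset] + offset
        eye[onset: onset + m] = base[onset: onset + m] + offset + jump * prof[:, None]
        offset = offset + jump
        i = onset + m + refractory
        if i >= n:
            break
    else:
        i = n
    if i < n:
        eye[i:] = base[i:] + offset
    return eye


def _effective_theta(state: LearnerState, cfg: SimConfig, channel: str) -> float:
    if channel == "hand":
        return state.theta_hat_hand + cfg.transfer_eye_to_hand * state.theta_hat_eye
    return state.theta_hat_eye + cfg.transfer_hand_to_eye * state.theta_hat_hand


def _update_state(state: LearnerState, cfg: SimConfig, channel: str,
                  mapping_deg: float) -> LearnerState:
    new = state.copy()
    if channel == "hand":
        err = mapping_deg - _effective_theta(state, cfg, "hand")
        new.theta_hat_hand = cfg.retention * state.theta_hat_hand + cfg.alpha_hand * err
    else:
        err = mapping_deg - _effective_theta(state, cfg, "eye")
        new.theta_hat_eye = cfg.retention * state.theta_hat_eye + cfg.alpha_eye * err
    return new


def _base_recording(t_ms, target, eye, cursor, hand, n, **meta) -> TrialRecording:
    return TrialRecording(
        t_ms=t_ms,
        target_xy=target,
        eye_xy=eye,
        cursor_xy=cursor,
        hand_xy=hand,
        pupil=np.full(n, 1000.0),
        valid=np.ones(n, dtype=bool),
        **meta,
    )


# ---------------------------------------------------------------------------
# trial-level simulation


def simulate_hand_trial(
    state: LearnerState,
    target: PointSeries,
    cfg: SimConfig,
    mapping_deg: float,
    rng: np.random.Generator | None = None,
    **meta,
) -> tuple[TrialRecording, LearnerState]:
    """Simulate one hand-tracking trial of an externally moved target.

    The hand command pursues the target (with a residual loop delay) while
    counter-rotating by the current internal rotation estimate; the cursor is
    the hand rotated by the applied mapping, so cursor error reflects the
    mismatch between the estimate and the mapping.  Gaze pursues the target,
    not the cursor.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    fs = 1.0 / (target.t[1] - target.t[0])
    n = len(target)
    tgt = target.xy

    theta = _effective_theta(state, cfg, "hand")
    desired = _delay(tgt, int(round(cfg.feedback_delay_ms * fs / 1000.0)))
    noise_sd = cfg.motor_noise_sd * (
        1.0 + cfg.rotation_difficulty * min(abs(theta), 90.0) / 90.0)
    noise = _smooth_noise(rng, n, fs, noise_sd, cfg.noise_cutoff_hz)
    hand = rotate_xy(desired, -theta) + noise
    cursor = rotate_xy(hand, mapping_deg)

    eye = _pursue_with_saccades(tgt, tgt, fs, cfg.pursuit_lag_ms, cfg, rng)

    rec = _base_recording(target.t * 1000.0, tgt, eye, cursor, hand, n,
                          task="hand", mapping_deg=mapping_deg, **meta)
    rec = inject_blinks(rec, cfg, rng)
    return rec, _update_state(state, cfg, "hand", mapping_deg)


def simulate_eye_trial(
    state: LearnerState,
    cfg: SimConfig,
    mapping_deg: float,
    rng: np.random.Generator | None = None,
    timing: SamplingSpec | None = None,
    **meta,
) -> tuple[TrialRecording, LearnerState]:
    """Simulate one eye-tracking trial of a self-moved target.

    The hand generates a random smooth trajectory; the on-screen target is
    the hand rotated by the mapping.  The eye pursues the target position
    *predicted* from the efference copy of the hand command rotated by the
    current eye-channel rotation estimate; prediction also compensates part
    of the pursuit delay (``prediction_lead_ms``).  When the estimate
    mismatches the mapping the predicted goal diverges from the true target
    and catch-up saccades correct the accumulating error.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    timing = timing or SamplingSpec()
    fs = timing.rate
    n = timing.n_samples

    hand_cmd = make_random_trajectory(rng, timing, cfg.hand_speed_setpoint).xy
    noise = _smooth_noise(rng, n, fs, cfg.motor_noise_sd, cfg.noise_cutoff_hz)
    hand = hand_cmd + noise
    target = rotate_xy(hand, mapping_deg)

    theta = _effective_theta(state, cfg, "eye")
    lead = int(round(cfg.prediction_lead_ms * fs / 1000.0))
    predicted = _advance(rotate_xy(hand_cmd, theta), lead)
    eye = _pursue_with_saccades(predicted, target, fs, cfg.pursuit_lag_ms, cfg, rng)

    rec = _base_recording(timing.times() * 1000.0, target, eye, None, hand, n,
                          task="eye", mapping_deg=mapping_deg, **meta)
    rec = inject_blinks(rec, cfg, rng)
    return rec, _update_state(state, cfg, "eye", mapping_deg)


def simulate_playback_trial(
    target: PointSeries,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    **meta,
) -> TrialRecording:
    """Simulate eye tracking of a played-back (externally moved) target.

    With no efference copy available, pursuit is purely reactive: the
    tracking delay is ``playback_lag_multiplier`` times the effective
    self-moved delay, and saccades are reactive corrections only.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    fs = 1.0 / (target.t[1] - target.t[0])
    n = len(target)
    tgt = target.xy
    self_delay = max(cfg.pursuit_lag_ms - cfg.prediction_lead_ms, 0.0)
    delay = cfg.playback_lag_multiplier * self_delay
    pb_cfg = cfg.replace(
        saccade_trigger_cm=cfg.saccade_trigger_cm * cfg.playback_trigger_multiplier)
    eye = _pursue_with_saccades(tgt, tgt, fs, delay, pb_cfg, rng)
    rec = _base_recording(target.t * 1000.0, tgt, eye, None, None, n,
                          task="playback", mapping_deg=0.0, **meta)
    return inject_blinks(rec, cfg, rng)


def inject_blinks(rec: TrialRecording, cfg: SimConfig,
                  rng: np.random.Generator) -> TrialRecording:
    """Insert Poisson-placed blinks: pupil drops to 0, samples marked invalid."""
    if cfg.blink_rate_per_min <= 0:
        return rec
    fs = rec.fs
    n = rec.n_samples
    dur = int(round(cfg.blink_duration_ms * fs / 1000.0))
    expected = cfg.blink_rate_per_min * rec.duration_s / 60.0
    n_blinks = rng.poisson(expected)
    for _ in range(n_blinks):
        start = int(rng.integers(0, max(1, n - dur)))
        rec.pupil[start: start + dur] = 0.0
        rec.valid[start: start + dur] = False
    return rec


# ---------------------------------------------------------------------------
# protocol-level simulation


def _participant_rng(seed: int, group: str, index: int) -> np.random.Generator:
    # spawn-key style stream split: adding participants never perturbs others
    # (zlib.crc32 is stable across processes, unlike built-in str hashing)
    return np.random.default_rng([seed, zlib.crc32(group.encode()) % (2**31), index])


def _jitter_cfg(cfg: SimConfig, rng: np.random.Generator) -> SimConfig:
    if cfg.participant_sd <= 0:
        return cfg
    j = lambda v: float(np.clip(v * rng.lognormal(0.0, cfg.participant_sd), 0.0, 1.0))
    return cfg.replace(alpha_hand=j(cfg.alpha_hand), alpha_eye=j(cfg.alpha_eye))


def _balanced_patterns(n_trials: int, rng: np.random.Generator) -> list[int]:
    """Pattern ids 1-5 drawn so each block contains a similar number of each."""
    ids = np.tile(np.arange(1, 6), math.ceil(n_trials / 5))[:n_trials]
    rng.shuffle(ids)
    return [int(i) for i in ids]


def run_experiment(
    cfg: SimConfig | None = None,
    seed: int | None = None,
    participants_per_group: int = 12,
    timing: SamplingSpec | None = None,
    protocol: tuple = DEFAULT_PROTOCOL,
    groups: tuple[str, str] = (GROUP_HAND_FIRST, GROUP_EYE_FIRST),
) -> list[TrialRecording]:
    """Simulate the full two-group transfer protocol.

    Each participant runs baseline (10 trials), rotation (40 trials) and
    washout (2 trials) blocks in both tasks; the ``hand_first`` group does
    the hand block before the eye block within every phase and the
    ``eye_first`` group the reverse.  Per-participant RNG streams are derived
    from the seed, so datasets are reproducible and adding participants never
    perturbs existing ones.
    """
    cfg = cfg or SimConfig()
    if seed is not None:
        cfg = cfg.replace(seed=seed)
    timing = timing or SamplingSpec()
    patterns = load_target_patterns()

    dataset: list[TrialRecording] = []
    for group in groups:
        task_order = ("hand", "eye") if group == GROUP_HAND_FIRST else ("eye", "hand")
        for p_idx in range(participants_per_group):
            rng = _participant_rng(cfg.seed, group, p_idx)
            p_cfg = _jitter_cfg(cfg, rng)
            pid = f"{group}_p{p_idx:02d}"
            state = LearnerState()
            for phase, mapping, n_trials in protocol:
                for task in task_order:
                    pattern_ids = _balanced_patterns(n_trials, rng)
                    for k in range(n_trials):
                        meta = dict(group=group, phase=phase,
                                    trial_index=k + 1, participant=pid)
                        if task == "hand":
                            pat = pattern_ids[k]
                            target = make_trajectory(patterns[pat], timing)
                            rec, state = simulate_hand_trial(
                                state, target, p_cfg, mapping, rng,
                                pattern_id=pat, **meta)
                        else:
                            rec, state = simulate_eye_trial(
                                state, p_cfg, mapping, rng, timing, **meta)
                        dataset.append(rec)
    return dataset
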