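"""Per-trial tracking performance measures.

Implements the four families of measures used to quantify eye-hand tracking:

* mean Euclidean distances between effector pairs (cursor-target, eye-target,
  eye-cursor), discarding the first second of each trial;
* the temporal lag between two planar signals, estimated by cross-correlating
  the *interleaved* x/y sequences shifted by multiples of two interleaved
  samples, so both axes contribute to a single lag estimate;
* catch-up saccade detection from tangential-acceleration peaks above a
  threshold (1500 deg/s^2 by default), with rate and mean amplitude summaries;
* approximate entropy (ApEn) of scalar signals as an unpredictability index
  (embedding dimension 2, tolerance 0.2 x SD by default, self-matches
  included as in Pincus' original definition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as _signal

from .preprocess import FilterConfig, analysis_mask, kinematics, mask_blinks
from .trajectory import DEG_PER_CM

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import TrialRecording

__all__ = [
    "SaccadeDetectorConfig",
    "SaccadeEvent",
    "ApEnSettings",
    "TrialMetrics",
    "mean_distance",
    "xcorr_lag_2d",
    "xcorr_lag_1d",
    "detect_saccades",
    "saccade_stats",
    "approximate_entropy",
    "compute_trial_metrics",
]


@dataclass(frozen=True)
class SaccadeDetectorConfig:
    """Catch-up saccade detector settings.

    ``acc_threshold`` is the tangential-acceleration magnitude (deg/s^2) a
    peak/trough pair must exceed.  ``vel_threshold`` is a secondary criterion
    (deg/s) that recovers small saccades whose acceleration stays below the
    main threshold, standing in for manual identification of sub-1-degree
    saccades.  Events with onsets closer than ``min_separation_ms`` are
    merged.
    """

    acc_threshold: float = 1500.0
    vel_threshold: float = 30.0
    min_separation_ms: float = 20.0
    min_amplitude_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.acc_threshold > 0:
            raise ValueError("acc_threshold must be positive")


@dataclass(frozen=True)
class SaccadeEvent:
    """One detected saccade: sample span, amplitude and peak acceleration."""

    onset: int
    offset: int
    amplitude_deg: float
    peak_acceleration: float

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("saccade onset must precede offset")
        if self.amplitude_deg < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class ApEnSettings:
    """Approximate-entropy settings: embedding dimension and tolerance factor."""

    m: int = 2
    r_factor: float = 0.2
    #: decimation factor applied before ApEn on high-rate trial signals;
    #: template counting is O(n^2), and regularity of smooth hand motion is
    #: preserved at 100 Hz.
    decimate: int = 10

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension must be >= 1")
        if not self.r_factor > 0:
            raise ValueError("tolerance factor must be positive")


@dataclass
class TrialMetrics:
    """Per-trial scalar summaries (NaN where not applicable for the task)."""

    cursor_target_cm: float = np.nan
    eye_target_cm: float = np.nan
    eye_cursor_cm: float = np.nan
    eye_target_lag_ms: float = np.nan
    saccade_rate_hz: float = np.nan
    saccade_amplitude_deg: float = np.nan
    apen_x: float = np.nan
    apen_y: float = np.nan


# ---------------------------------------------------------------------------
# distances


def mean_distance(
    a_xy: np.ndarray,
    b_xy: np.ndarray,
    fs: float,
    valid: np.ndarray | None = None,
    discard_s: float = 1.0,
) -> float:
    """Mean Euclidean distance between two aligned planar signals.

    The first ``discard_s`` seconds and any invalid (blink) samples are
    excluded from the mean.
    """
    a_xy = np.asarray(a_xy, dtype=float)
    b_xy = np.asarray(b_xy, dtype=float)
    if a_xy.shape != b_xy.shape:
        raise ValueError("series must be aligned and equally long")
    mask = analysis_mask(len(a_xy), fs, valid, discard_s)
    if not mask.any():
        raise ValueError("no valid samples left after discard/blink masking")
    d = np.linalg.norm(a_xy[mask] - b_xy[mask], axis=1)
    return float(d.mean())


# ---------------------------------------------------------------------------
# interleaved cross-correlation lag


def _lag_scan(
    a_cols: list[np.ndarray],
    b_cols: list[np.ndarray],
    w: np.ndarray,
    win_start: int,
    win_len: int,
    k_max: int,
) -> tuple[int, float]:
    """Shared engine for normalized cross-correlation over integer lags.

    ``a_cols``/``b_cols`` are per-axis 1-D signals; the correlation at lag k
    sums products over all axes, which is exactly the interleaved-sequence
    correlation evaluated at shifts that are multiples of (number of axes)
    interleaved samples.  ``w`` is a 0/1 validity weight over the window for
    ``a``.  Lags run from -k_max to +k_max; positive lag means ``a`` trails
    ``b``.  Implemented with strided windows so the scan is a handful of
    matrix-vector products.
    """
    w_sum = w.sum()
    if w_sum < 2:
        raise ValueError("no valid samples in the correlation window")
    lags = np.arange(-k_max, k_max + 1)

    num = np.zeros(lags.size)
    var_b = np.zeros(lags.size)
    norm_a_sq = 0.0
    for a_col, b_col in zip(a_cols, b_cols):
        aw = a_col[win_start: win_start + win_len] * w
        aw -= (aw.sum() / w_sum) * w
        norm_a_sq += float(np.sum(aw**2))
        # window for lag k starts at win_start - k; 'valid' correlation of the
        # padded b segment against the window kernels yields, for every lag at
        # once, the product sums and the windowed first/second moments of b
        b_seg = b_col[win_start - k_max: win_start + win_len + k_max]
        num += _signal.correlate(b_seg, aw, mode="valid", method="fft")[::-1]
        sb = _signal.correlate(b_seg, w, mode="valid", method="fft")[::-1]
        sb2 = _signal.correlate(b_seg**2, w, mode="valid", method="fft")[::-1]
        var_b += sb2 - sb**2 / w_sum
    denom = np.sqrt(norm_a_sq) * np.sqrt(np.maximum(var_b, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, 0.0)
    best = int(np.argmax(r))
    return int(lags[best]), float(r[best])


def xcorr_lag_2d(
    a_xy: np.ndarray,
    b_xy: np.ndarray,
    fs: float,
    max_lag_ms: float = 500.0,
    valid: np.ndarray | None = None,
    discard_s: float = 1.0,
) -> tuple[float, float]:
    """Lag between two planar signals via interleaved cross-correlation.

    The x and y samples of each signal are interleaved into a single sequence
    and the normalized cross-correlation is evaluated only at shifts that are
    multiples of two interleaved samples, i.e. whole physical samples, so the
    horizontal and vertical axes contribute to a single lag estimate.  (At
    such shifts the interleaved product sum is identically the sum of the
    per-axis product sums, which is how the scan is evaluated.)

    Returns ``(lag_ms, peak_correlation)``.  Positive lag means ``a`` trails
    ``b`` (e.g. ``xcorr_lag_2d(eye, target) > 0`` when the eye lags the
    target).  Lags from ``-max_lag_ms`` to ``+max_lag_ms`` are searched.
    """
    a_xy = np.asarray(a_xy, dtype=float)
    b_xy = np.asarray(b_xy, dtype=float)
    if a_xy.shape != b_xy.shape:
        raise ValueError("series must be aligned and equally long")
    n = len(a_xy)
    k_max = int(round(max_lag_ms * fs / 1000.0))
    start = int(round(discard_s * fs))
    win_start = max(start, k_max)
    win_len = n - k_max - win_start
    if win_len < 2 * k_max or win_len < 2:
        raise ValueError("analysis window shorter than twice the maximum lag")
    mask = analysis_mask(n, fs, valid, discard_s)
    w = mask[win_start: win_start + win_len].astype(float)
    k, r = _lag_scan(
        [a_xy[:, 0], a_xy[:, 1]], [b_xy[:, 0], b_xy[:, 1]],
        w, win_start, win_len, k_max,
    )
    return k * 1000.0 / fs, r


def xcorr_lag_1d(
    a: np.ndarray,
    b: np.ndarray,
    fs: float,
    max_lag_ms: float = 500.0,
    discard_s: float = 1.0,
) -> tuple[float, float]:
    """Single-axis cross-correlation lag (same conventions as the 2-D form)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must be aligned and equally long")
    n = len(a)
    k_max = int(round(max_lag_ms * fs / 1000.0))
    start = int(round(discard_s * fs))
    win_start = max(start, k_max)
    win_len = n - k_max - win_start
    if win_len < 2 * k_max or win_len < 2:
        raise ValueError("analysis window shorter than twice the maximum lag")
    w = np.ones(win_len)
    k, r = _lag_scan([a], [b], w, win_start, win_len, k_max)
    return k * 1000.0 / fs, r


# ---------------------------------------------------------------------------
# saccade detection


def detect_saccades(
    acceleration: np.ndarray,
    eye_xy: np.ndarray,
    fs: float,
    cfg: SaccadeDetectorConfig | None = None,
    speed: np.ndarray | None = None,
    valid: np.ndarray | None = None,
) -> list[SaccadeEvent]:
    """Detect catch-up saccades from tangential eye kinematics.

    A saccade is a paired supra-threshold acceleration peak and deceleration
    trough in the signed tangential acceleration.  The event spans from the
    acceleration zero-crossing preceding the peak to the zero-crossing
    following the trough; amplitude is the Euclidean eye displacement over
    that span (deg, at the 1 cm = 1 deg screen geometry).  Events overlapping
    invalid (blink) samples are discarded; events closer than the minimum
    separation are merged.
    """
    cfg = cfg or SaccadeDetectorConfig()
    acc = np.asarray(acceleration, dtype=float)
    eye_xy = np.asarray(eye_xy, dtype=float)
    n = len(acc)

    peaks, _ = _signal.find_peaks(acc, height=cfg.acc_threshold)
    troughs, _ = _signal.find_peaks(-acc, height=cfg.acc_threshold)

    # pair each acceleration peak with the first deceleration trough that
    # follows within a saccade-scale window
    max_pair = int(round(0.12 * fs))
    events: list[tuple[int, int]] = []
    ti = 0
    for p in peaks:
        while ti < len(troughs) and troughs[ti] <= p:
            ti += 1
        if ti >= len(troughs) or troughs[ti] - p > max_pair:
            continue
        q = int(troughs[ti])
        events.append((_zero_cross_before(acc, int(p)), _zero_cross_after(acc, q, n)))

    if speed is not None and cfg.vel_threshold > 0:
        # secondary criterion, standing in for manual identification of small
        # saccades: a brief, prominent speed transient with a (possibly
        # sub-threshold) acceleration spike.  Width gating separates saccadic
        # transients from slow pursuit-speed modulation.
        sp = np.asarray(speed, dtype=float)
        vel_peaks, props = _signal.find_peaks(
            sp, height=cfg.vel_threshold, prominence=cfg.vel_threshold,
            width=(None, 0.1 * fs), rel_height=0.5,
        )
        for p, lo, hi in zip(vel_peaks, props["left_ips"], props["right_ips"]):
            lo, hi = int(lo), min(int(hi) + 1, n - 1)
            if any(on <= p <= off for on, off in events):
                continue
            if np.max(np.abs(acc[lo: hi + 1])) > cfg.acc_threshold / 3:
                events.append((lo, hi))

    events = _merge_close(events, int(round(cfg.min_separation_ms * fs / 1000.0)))

    out: list[SaccadeEvent] = []
    for onset, offset in events:
        if valid is not None and not np.all(valid[onset: offset + 1]):
            continue
        amp = float(np.linalg.norm(eye_xy[offset] - eye_xy[onset])) * DEG_PER_CM
        if amp < cfg.min_amplitude_deg:
            continue
        peak_acc = float(np.max(np.abs(acc[onset: offset + 1])))
        out.append(SaccadeEvent(onset, offset, amp, peak_acc))
    return out


def _zero_cross_before(acc: np.ndarray, idx: int) -> int:
    i = idx
    while i > 0 and acc[i] > 0:
        i -= 1
    return i


def _zero_cross_after(acc: np.ndarray, idx: int, n: int) -> int:
    i = idx
    while i < n - 1 and acc[i] < 0:
        i += 1
    return i


def _merge_close(events: list[tuple[int, int]], min_gap: int) -> list[tuple[int, int]]:
    if not events:
        return []
    events = sorted(events)
    merged = [events[0]]
    for onset, offset in events[1:]:
        last_on, last_off = merged[-1]
        if onset - last_off < min_gap:
            merged[-1] = (last_on, max(last_off, offset))
        else:
            merged.append((onset, offset))
    return merged


def saccade_stats(events: list[SaccadeEvent], analyzed_duration_s: float) -> tuple[float, float]:
    """Saccade rate (/s) and mean amplitude (deg; NaN when no events)."""
    if not analyzed_duration_s > 0:
        raise ValueError("analyzed duration must be positive")
    rate = len(events) / analyzed_duration_s
    amp = float(np.mean([e.amplitude_deg for e in events])) if events else float("nan")
    return rate, amp


# ---------------------------------------------------------------------------
# approximate entropy


def approximate_entropy(
    x: np.ndarray,
    settings: ApEnSettings | None = None,
    r: float | None = None,
) -> float:
    """Approximate entropy ApEn(m, r) of a scalar series.

    ApEn = Phi_m - Phi_{m+1}, where Phi_m is the mean over template positions
    of the log fraction of m-length templates within Chebyshev distance r
    (self-matches included).  By default r = r_factor * SD(x); a
    zero-variance series returns 0 by convention.  No decimation is applied
    here — callers decimate beforehand if desired.
    """
    settings = settings or ApEnSettings()
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < settings.m + 2:
        raise ValueError("series too short for the requested embedding")
    if r is None:
        sd = float(np.std(x))
        if sd == 0.0:
            return 0.0
        r = settings.r_factor * sd

    if n <= 3000:
        # share one pairwise scalar-distance matrix between both embeddings;
        # the Chebyshev distance of m-templates is the running max along its
        # shifted diagonals
        d0 = np.abs(x[:, None] - x[None, :])

        def phi(m: int) -> float:
            big_n = n - m + 1
            dm = d0[:big_n, :big_n].copy()
            for k in range(1, m):
                np.maximum(dm, d0[k: k + big_n, k: k + big_n], out=dm)
            counts = (dm <= r).sum(axis=1)
            return float(np.mean(np.log(counts / big_n)))
    else:
        def phi(m: int) -> float:
            templates = sliding_window_view(x, m)
            big_n = templates.shape[0]
            counts = np.empty(big_n)
            chunk = max(1, int(2**22 // max(1, big_n * m)))
            for i0 in range(0, big_n, chunk):
                block = templates[i0: i0 + chunk]
                d = np.abs(block[:, None, :] - templates[None, :, :]).max(axis=2)
                counts[i0: i0 + chunk] = (d <= r).sum(axis=1)
            return float(np.mean(np.log(counts / big_n)))

    return phi(settings.m) - phi(settings.m + 1)


# ---------------------------------------------------------------------------
# per-trial dispatch


def compute_trial_metrics(
    rec: "TrialRecording",
    filter_cfg: FilterConfig | None = None,
    detector_cfg: SaccadeDetectorConfig | None = None,
    apen_settings: ApEnSettings | None = None,
    max_lag_ms: float = 500.0,
    discard_s: float = 1.0,
) -> TrialMetrics:
    """Compute the task-appropriate scalar metrics for one trial.

    Hand trials yield cursor-target, eye-target and eye-cursor distances;
    eye and playback trials yield the eye-target distance, interleaved-lag
    estimate and joystick ApEn.  Saccade statistics are computed for every
    trial with an eye channel.
    """
    filter_cfg = filter_cfg or FilterConfig()
    detector_cfg = detector_cfg or SaccadeDetectorConfig()
    apen_settings = apen_settings or ApEnSettings()

    fs = rec.fs
    valid = mask_blinks(rec.pupil, fs, rec.valid)
    target = lowpass_xy(rec.target_xy, fs, filter_cfg)
    eye = lowpass_xy(rec.eye_xy, fs, filter_cfg)
    cursor = lowpass_xy(rec.cursor_xy, fs, filter_cfg) if rec.cursor_xy is not None else None

    m = TrialMetrics()
    m.eye_target_cm = mean_distance(eye, target, fs, valid, discard_s)
    m.eye_target_lag_ms, _ = xcorr_lag_2d(eye, target, fs, max_lag_ms, valid, discard_s)

    if rec.task == "hand":
        m.cursor_target_cm = mean_distance(cursor, target, fs, valid, discard_s)
        m.eye_cursor_cm = mean_distance(eye, cursor, fs, valid, discard_s)
    else:
        # joystick (hand-space) motion unpredictability, per axis
        hand = rec.hand_xy if rec.hand_xy is not None else rec.target_xy
        step = max(1, apen_settings.decimate)
        m.apen_x = approximate_entropy(hand[::step, 0], apen_settings)
        m.apen_y = approximate_entropy(hand[::step, 1], apen_settings)

    kin = kinematics(rec.eye_xy, fs, filter_cfg)
    events = detect_saccades(
        kin["acceleration"], kin["position"], fs, detector_cfg,
        speed=kin["speed"], valid=valid,
    )
    first = int(round(discard_s * fs))
    events = [e for e in events if e.onset >= first]
    duration = rec.duration_s - discard_s
    m.saccade_rate_hz, m.saccade_amplitude_deg = saccade_stats(events, duration)
    return m


def lowpass_xy(xy: np.ndarray, fs: float, cfg: FilterConfig) -> np.ndarray:
    """Low-pass filter each axis of a planar signal."""
    from .preprocess import lowpass

    return lowpass(np.asarray(xy, dtype=float), fs, cfg)
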