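"""Target trajectory synthesis for 2-D tracking experiments.

Externally moved targets are sums of two sinusoids per axis (a fundamental
plus a second or third harmonic), which yields pseudo-random looking but
smooth closed paths.  Self-moved-style targets are generated from low-pass
filtered Gaussian velocity noise with closed-loop control of the mean
tangential speed.  Screen coordinates are centimetres with the origin at the
screen centre, +x rightward, +y upward; at a 57 cm viewing distance 1 cm on
the screen subtends 1 degree of visual angle, so cm and deg are used
interchangeably at a 1:1 ratio throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import brentq

__all__ = [
    "DEG_PER_CM",
    "TrajectorySpec",
    "SamplingSpec",
    "PointSeries",
    "load_target_patterns",
    "make_trajectory",
    "path_length",
    "calibrate_fundamental",
    "make_random_trajectory",
    "apply_rotation",
    "DEFAULT_OMEGA",
]

#: Visual angle subtended by 1 cm on the screen at the 57 cm viewing distance.
DEG_PER_CM = 1.0

#: Default fundamental angular frequency: two cycles per 10-s trial (0.2 Hz).
#: With the built-in amplitude/harmonic table this reproduces the nominal
#: 160 cm path length; see :func:`calibrate_fundamental` for the principled
#: re-derivation.
DEFAULT_OMEGA = 2.0 * np.pi * 0.2


@dataclass(frozen=True)
class TrajectorySpec:
    """Amplitudes, harmonic multipliers and phases of one target pattern.

    The target path is ``x(t) = a1x*cos(w t) + a2x*cos(hx*w t - phix)`` and
    ``y(t) = a1y*sin(w t) + a2y*sin(hy*w t - phiy)``.  Phases are stored in
    degrees (as tabulated) and converted to radians at evaluation time.
    """

    a1x: float
    a2x: float
    hx: int
    phix_deg: float
    a1y: float
    a2y: float
    hy: int
    phiy_deg: float
    omega: float = DEFAULT_OMEGA

    def __post_init__(self) -> None:
        if min(self.a1x, self.a2x, self.a1y, self.a2y) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.hx not in (2, 3) or self.hy not in (2, 3):
            raise ValueError("harmonic multipliers must be 2 or 3")
        if not self.omega > 0:
            raise ValueError("fundamental angular frequency must be positive")

    def with_omega(self, omega: float) -> "TrajectorySpec":
        return TrajectorySpec(
            self.a1x, self.a2x, self.hx, self.phix_deg,
            self.a1y, self.a2y, self.hy, self.phiy_deg, omega,
        )


@dataclass(frozen=True)
class SamplingSpec:
    """Uniform sampling grid: rate in samples/s, duration in seconds."""

    rate: float = 1000.0
    duration: float = 10.0

    def __post_init__(self) -> None:
        if not (self.rate > 0 and self.duration > 0):
            raise ValueError("rate and duration must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.rate * self.duration))

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass
class PointSeries:
    """A uniformly sampled planar path: time (s) plus x/y position (cm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have equal lengths")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.x))
                and np.all(np.isfinite(self.y))):
            raise ValueError("PointSeries values must be finite")

    def __len__(self) -> int:
        return self.t.size

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) position array."""
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "x_cm": self.x, "y_cm": self.y})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PointSeries":
        return cls(df["t_s"].to_numpy(), df["x_cm"].to_numpy(), df["y_cm"].to_numpy())


def load_target_patterns(omega: float = DEFAULT_OMEGA) -> dict[int, TrajectorySpec]:
    """Load the five built-in hand-tracking target patterns.

    Returns a mapping from pattern id to :class:`TrajectorySpec`, all sharing
    the given fundamental frequency.
    """
    with resources.files("trackadapt.data").joinpath("target_patterns.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return {
        int(row.id): TrajectorySpec(
            row.a1x, row.a2x, int(row.hx), row.phix_deg,
            row.a1y, row.a2y, int(row.hy), row.phiy_deg, omega,
        )
        for row in table.itertuples()
    }


def make_trajectory(spec: TrajectorySpec, timing: SamplingSpec | None = None) -> PointSeries:
    """Evaluate a two-sinusoid-per-axis target path on a uniform grid."""
    timing = timing or SamplingSpec()
    t = timing.times()
    w = spec.omega
    phix = np.radians(spec.phix_deg)
    phiy = np.radians(spec.phiy_deg)
    x = spec.a1x * np.cos(w * t) + spec.a2x * np.cos(spec.hx * w * t - phix)
    y = spec.a1y * np.sin(w * t) + spec.a2y * np.sin(spec.hy * w * t - phiy)
    return PointSeries(t, x, y)


def path_length(series: PointSeries) -> float:
    """Arc length: sum of Euclidean distances between consecutive samples."""
    if len(series) < 2:
        raise ValueError("path_length needs at least 2 samples")
    return float(np.hypot(np.diff(series.x), np.diff(series.y)).sum())


def calibrate_fundamental(
    specs: list[TrajectorySpec],
    timing: SamplingSpec | None = None,
    nominal_length: float = 160.0,
    bracket: tuple[float, float] = (1e-3, 1e2),
) -> float:
    """Solve for the shared fundamental frequency giving a target arc length.

    Arc length over a fixed duration is strictly increasing in omega, so the
    root of ``mean arc length - nominal_length`` is found by bracketed root
    finding.  Returns omega in rad/s.
    """
    if not nominal_length > 0:
        raise ValueError("nominal_length must be positive")
    if not specs:
        raise ValueError("need at least one TrajectorySpec")
    timing = timing or SamplingSpec()

    def mean_length(omega: float) -> float:
        return float(np.mean([
            path_length(make_trajectory(s.with_omega(omega), timing)) for s in specs
        ]))

    lo, hi = bracket
    f_lo = mean_length(lo) - nominal_length
    f_hi = mean_length(hi) - nominal_length
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no omega in [{lo}, {hi}] rad/s yields mean arc length {nominal_length} cm"
        )
    return float(brentq(lambda w: mean_length(w) - nominal_length, lo, hi, xtol=1e-10))


def make_random_trajectory(
    seed: int | np.random.Generator,
    timing: SamplingSpec | None = None,
    speed_setpoint: float = 16.0,
    half_extent: float = 15.0,
    noise_band_hz: tuple[float, float] = (0.1, 2.0),
) -> PointSeries:
    """Generate a smooth unpredictable path with controlled mean speed.

    Gaussian white velocity noise is band-pass filtered (Butterworth, zero
    phase) to ``noise_band_hz``, integrated to position, folded back into
    the ``±half_extent`` box (emulating the limited joystick excursion), and
    iteratively rescaled so that the mean tangential speed equals
    ``speed_setpoint`` cm/s.  The band combines slow screen-covering sweeps
    (lower edge) with faster wiggling (upper edge), giving motion that is
    markedly less regular than the sum-of-sinusoids patterns while staying
    smooth at pursuit timescales.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if not speed_setpoint > 0:
        raise ValueError("speed_setpoint must be positive")
    timing = timing or SamplingSpec()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = timing.n_samples
    dt = timing.dt
    # pad by two noise-correlation lengths so zero-phase filter edge
    # transients never reach the trial window
    pad = int(round(2.0 * timing.rate / noise_band_hz[0]))
    v = rng.standard_normal((n + 2 * pad, 2))
    sos = signal.butter(2, noise_band_hz, btype="bandpass", fs=timing.rate,
                        output="sos")
    v = signal.sosfiltfilt(sos, v, axis=0)[pad: pad + n]

    t = timing.times()
    mean_speed = float(np.linalg.norm(v, axis=1).mean())
    if mean_speed == 0:
        raise ValueError("degenerate zero-velocity noise draw")
    v *= speed_setpoint / mean_speed
    xy = np.zeros((n, 2))
    # Folding the integrated path into the box is an isometry except at the
    # fold points, so a few rescale-and-refold passes pin the mean tangential
    # speed to the set-point.
    for _ in range(6):
        pos = np.cumsum(v * dt, axis=0)
        pos -= pos.mean(axis=0)
        xy = _fold_into_box(pos, half_extent)
        achieved = np.hypot(*np.diff(xy, axis=0).T).sum() / (dt * (n - 1))
        if abs(achieved - speed_setpoint) < 1e-9:
            break
        v *= speed_setpoint / achieved
    return PointSeries(t, xy[:, 0], xy[:, 1])


def _fold_into_box(pos: np.ndarray, half_extent: float) -> np.ndarray:
    """Reflect positions into [-half_extent, half_extent] (triangle-wave fold)."""
    period = 4.0 * half_extent
    shifted = np.mod(pos + half_extent, period)
    return np.where(shifted <= 2 * half_extent,
                    shifted - half_extent,
                    3 * half_extent - shifted)


def apply_rotation(series: PointSeries, angle_deg: float) -> PointSeries:
    """Rotate a path counterclockwise about the screen centre."""
    if not np.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    c, s = np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))
    x = c * series.x - s * series.y
    y = s * series.x + c * series.y
    return PointSeries(series.t.copy(), x, y)


def rotate_xy(xy: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate an (n, 2) array counterclockwise by ``angle_deg``."""
    c, s = np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))
    rot = np.array([[c, -s], [s, c]])
    return xy @ rot.T
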