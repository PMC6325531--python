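"""Raw-sample conditioning: gaze calibration, filtering, blink masking, kinematics.

The processing chain mirrors common oculomotor practice: position signals are
low-pass filtered (4th-order Butterworth, 25 Hz cutoff), differentiated to
velocity, re-filtered, reduced to tangential speed, differentiated again to
tangential acceleration and filtered once more.  Zero-phase (forward-backward)
filtering is the default so that temporal-lag estimates downstream are not
biased by filter group delay.  Blinks are excluded by masking, never
interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "FilterConfig",
    "GazeCalibration",
    "fit_gaze_calibration",
    "lowpass",
    "mask_blinks",
    "kinematics",
    "analysis_mask",
]


@dataclass(frozen=True)
class FilterConfig:
    """Butterworth low-pass settings (order 4, 25 Hz cutoff by default)."""

    order: int = 4
    cutoff: float = 25.0
    mode: str = "zero-phase"  # or "causal"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")
        if self.mode not in ("zero-phase", "causal"):
            raise ValueError("mode must be 'zero-phase' or 'causal'")


@dataclass(frozen=True)
class GazeCalibration:
    """Affine map from raw tracker units to screen cm.

    ``coeffs`` is 2x3: ``screen = coeffs[:, :2] @ raw + coeffs[:, 2]``.
    """

    coeffs: np.ndarray
    residual_rms: float

    def __post_init__(self) -> None:
        if np.asarray(self.coeffs).shape != (2, 3):
            raise ValueError("calibration coefficients must be 2x3")
        if abs(np.linalg.det(np.asarray(self.coeffs)[:, :2])) < 1e-12:
            raise ValueError("calibration linear part is singular")

    def apply(self, raw_xy: np.ndarray) -> np.ndarray:
        raw_xy = np.asarray(raw_xy, dtype=float)
        A = np.asarray(self.coeffs)
        return raw_xy @ A[:, :2].T + A[:, 2]


def fit_gaze_calibration(raw_fixations: np.ndarray, known_grid: np.ndarray) -> GazeCalibration:
    """Least-squares affine calibration from nine fixation means.

    Parameters
    ----------
    raw_fixations : (9, 2) mean raw tracker coordinates per grid point.
    known_grid : (9, 2) true screen coordinates (cm) of the calibration grid.
    """
    raw = np.asarray(raw_fixations, dtype=float)
    grid = np.asarray(known_grid, dtype=float)
    if raw.shape != (9, 2) or grid.shape != (9, 2):
        raise ValueError("calibration requires exactly 9 paired 2-D points")
    design = np.column_stack([raw, np.ones(len(raw))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("degenerate (collinear) calibration points")
    sol, *_ = np.linalg.lstsq(design, grid, rcond=None)
    coeffs = sol.T  # (2, 3)
    pred = design @ sol
    residual_rms = float(np.sqrt(np.mean(np.sum((pred - grid) ** 2, axis=1))))
    return GazeCalibration(coeffs, residual_rms)


def _sos(cfg: FilterConfig, fs: float) -> np.ndarray:
    if cfg.cutoff >= fs / 2:
        raise ValueError(f"cutoff {cfg.cutoff} Hz must be below Nyquist {fs / 2} Hz")
    return signal.butter(cfg.order, cfg.cutoff, fs=fs, output="sos")


def lowpass(x: np.ndarray, fs: float, cfg: FilterConfig | None = None) -> np.ndarray:
    """Low-pass filter along the first axis (zero-phase by default)."""
    cfg = cfg or FilterConfig()
    sos = _sos(cfg, fs)
    x = np.asarray(x, dtype=float)
    if cfg.mode == "zero-phase":
        return signal.sosfiltfilt(sos, x, axis=0)
    return signal.sosfilt(sos, x, axis=0)


def mask_blinks(
    pupil: np.ndarray,
    fs: float,
    valid: np.ndarray | None = None,
    pupil_threshold: float = 1e-6,
    dilate_ms: float = 50.0,
) -> np.ndarray:
    """Mark blink-affected samples invalid, dilating each blink by ±dilate_ms.

    A sample is a blink when the recorded pupil signal drops to (or below)
    ``pupil_threshold``; a tracker-provided validity flag can be AND-ed in.
    """
    pupil = np.asarray(pupil, dtype=float)
    bad = pupil <= pupil_threshold
    if valid is not None:
        bad |= ~np.asarray(valid, dtype=bool)
    if bad.any():
        width = int(round(dilate_ms * fs / 1000.0))
        if width > 0:
            kernel = np.ones(2 * width + 1, dtype=int)
            bad = np.convolve(bad.astype(int), kernel, mode="same") > 0
    return ~bad


def analysis_mask(n: int, fs: float, valid: np.ndarray | None = None,
                  discard_s: float = 1.0) -> np.ndarray:
    """Validity mask with the first ``discard_s`` seconds removed."""
    mask = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool).copy()
    mask[: int(round(discard_s * fs))] = False
    return mask


def kinematics(
    xy: np.ndarray,
    fs: float,
    cfg: FilterConfig | None = None,
    prefilter: bool = True,
) -> dict[str, np.ndarray]:
    """Differentiate a planar position signal into speed and acceleration.

    The chain is: position -> low-pass -> central-difference velocity ->
    low-pass -> tangential speed -> central-difference -> low-pass tangential
    acceleration.  Returns a dict with keys ``position``, ``velocity``,
    ``speed`` and ``acceleration`` (tangential, signed).
    """
    cfg = cfg or FilterConfig()
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("kinematics expects an (n, 2) position array")
    pos = lowpass(xy, fs, cfg) if prefilter else xy
    dt = 1.0 / fs
    vel = np.gradient(pos, dt, axis=0)
    vel = lowpass(vel, fs, cfg)
    speed = np.linalg.norm(vel, axis=1)
    acc = np.gradient(speed, dt)
    acc = lowpass(acc, fs, cfg)
    return {"position": pos, "velocity": vel, "speed": speed, "acceleration": acc}
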