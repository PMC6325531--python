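"""Learning-curve modelling and transfer summaries.

Trial-by-trial tracking error during adaptation is modelled as a constrained
exponential decay, ``error = a * exp(b * trial) + c`` with ``a >= 0``,
``b <= 0`` and ``c >= 0``: ``a`` is the initial error amplitude above the
asymptote, ``b`` the per-trial learning rate and ``c`` the asymptotic error.
Goodness of fit is summarized by the Pearson correlation R between fitted
and observed series; R values are normalized with the Fisher z (arctanh)
transform before parametric group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from .simulate import GROUP_EYE_FIRST, GROUP_HAND_FIRST

__all__ = [
    "LearningCurveModel",
    "LearningCurveResult",
    "fit_learning_curve",
    "fisher_z",
    "aftereffect_percent",
    "transfer_index",
    "transfer_report",
]


@dataclass
class LearningCurveResult:
    """Fitted exponential learning curve and goodness of fit."""

    a: float
    b: float
    c: float
    r: float
    r_z: float
    converged: bool
    sse: float
    n_trials: int
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    def predict(self, trials: np.ndarray) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(trials, dtype=float)) + self.c

    def summary(self) -> str:
        lines = [
            "Exponential learning-curve fit: error = a*exp(b*trial) + c",
            f"  n trials : {self.n_trials}",
            f"  a (initial amplitude) : {self.a:10.4f} cm",
            f"  b (per-trial rate)    : {self.b:10.4f} /trial",
            f"  c (asymptote)         : {self.c:10.4f} cm",
            f"  R (fit vs observed)   : {self.r:10.4f}"
            + ("" if np.isfinite(self.r) else "  [undefined: flat fit]"),
            f"  Fisher z(R)           : {self.r_z:10.4f}",
            f"  SSE                   : {self.sse:10.4f}",
            f"  converged             : {self.converged}",
        ]
        return "\n".join(lines)


class LearningCurveModel:
    """Constrained exponential decay model of a per-trial error series.

    Parameters
    ----------
    errors : sequence of per-trial errors (cm), trial 1 first.

    ``fit`` performs bounded nonlinear least squares with a multi-start over
    the rate parameter (b in {-1, -0.3, -0.1, -0.03}) and returns the best
    solution by SSE as a :class:`LearningCurveResult`.
    """

    B_STARTS = (-1.0, -0.3, -0.1, -0.03)

    def __init__(self, errors) -> None:
        self.errors = np.asarray(errors, dtype=float)
        if self.errors.size < 5:
            raise ValueError("learning-curve fit requires at least 5 trials")
        if not np.all(np.isfinite(self.errors)):
            raise ValueError("error series must be finite")
        self.trials = np.arange(1, self.errors.size + 1, dtype=float)

    def _residuals(self, p: np.ndarray) -> np.ndarray:
        a, b, c = p
        return a * np.exp(b * self.trials) + c - self.errors

    def fit(self) -> LearningCurveResult:
        y = self.errors
        a0 = max(float(y[0] - y.min()), 1e-6)
        c0 = max(float(y.min()), 0.0)
        best = None
        for b0 in self.B_STARTS:
            try:
                sol = least_squares(
                    self._residuals,
                    x0=[a0, b0, c0],
                    bounds=([0.0, -np.inf, 0.0], [np.inf, 0.0, np.inf]),
                    method="trf",
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            sse = float(np.sum(sol.fun**2))
            if sol.success and (best is None or sse < best[0]):
                best = (sse, sol)
        if best is None:
            return LearningCurveResult(np.nan, np.nan, np.nan, np.nan, np.nan,
                                       False, np.nan, y.size, None)
        sse, sol = best
        a, b, c = (float(v) for v in sol.x)
        fitted = a * np.exp(b * self.trials) + c
        if np.ptp(fitted) < 1e-12 or np.ptp(y) < 1e-12:
            r = np.nan  # flat fit or flat data: correlation undefined
            r_z = np.nan
        else:
            r = float(pearsonr(fitted, y).statistic)
            r_z = fisher_z(r) if abs(r) < 1.0 else np.inf * np.sign(r)
        return LearningCurveResult(a, b, c, r, r_z, True, sse, y.size, fitted)


def fit_learning_curve(errors) -> LearningCurveResult:
    """Convenience wrapper: ``LearningCurveModel(errors).fit()``."""
    return LearningCurveModel(errors).fit()


def fisher_z(r: float) -> float:
    """Fisher z (arctanh) normalization of a correlation coefficient."""
    r = float(r)
    if not abs(r) < 1.0:
        raise ValueError("Fisher z requires |R| < 1")
    return 0.5 * np.log((1.0 + r) / (1.0 - r))


def aftereffect_percent(late_errors, post_errors) -> float:
    """Percent error increase from late-rotation to post-washout trials."""
    late = np.asarray(late_errors, dtype=float)
    post = np.asarray(post_errors, dtype=float)
    if late.size == 0 or post.size == 0:
        raise ValueError("late and post error series must be non-empty")
    late_mean = late.mean()
    if late_mean == 0:
        raise ValueError("late-trial mean error is zero")
    return float(100.0 * (post.mean() - late_mean) / late_mean)


def transfer_index(naive_early: float, experienced_early: float,
                   naive_baseline: float) -> float:
    """Locate the experienced group's initial error between naive (0) and baseline (1).

    1 means complete transfer (experienced group starts at baseline), 0 means
    none (experienced group starts where naive participants start).
    """
    denom = naive_early - naive_baseline
    if denom == 0:
        raise ValueError("naive early and baseline errors coincide")
    return float((naive_early - experienced_early) / denom)


#: group that is naive (no prior rotation experience in the other task)
#: for each task, given the block orders of the two groups
NAIVE_GROUP = {"hand": GROUP_HAND_FIRST, "eye": GROUP_EYE_FIRST}
EXPERIENCED_GROUP = {"hand": GROUP_EYE_FIRST, "eye": GROUP_HAND_FIRST}


def _task_error_column(task: str) -> str:
    return "cursor_target_cm" if task == "hand" else "eye_target_cm"


def _phase_trial_mean(df: pd.DataFrame, task: str, phase: str,
                      trials) -> float:
    col = _task_error_column(task)
    sel = df[(df.task == task) & (df.phase == phase) & df.trial_index.isin(trials)]
    return float(sel.groupby("participant")[col].mean().mean())


def transfer_report(metrics: pd.DataFrame) -> dict:
    """Group-level adaptation and transfer summary from a tidy metrics table.

    Expects one row per trial with columns ``task``, ``group``, ``phase``,
    ``trial_index``, ``participant`` and the task error columns.  Returns a
    nested dict with, per task: binned group learning curves, per-group
    exponential fit parameters (on the group-mean rotation curve), early/
    intermediate/late contrasts, aftereffect percentages and the transfer
    index.
    """
    required_phases = {"baseline", "rotation", "washout"}
    if not required_phases <= set(metrics.phase.unique()):
        missing = required_phases - set(metrics.phase.unique())
        raise ValueError(f"metrics table is missing phases: {sorted(missing)}")

    report: dict = {}
    for task in ("hand", "eye"):
        col = _task_error_column(task)
        task_df = metrics[metrics.task == task]
        naive = NAIVE_GROUP[task]
        exp = EXPERIENCED_GROUP[task]

        curves = {}
        fits = {}
        for grp in (naive, exp):
            g = task_df[(task_df.group == grp) & (task_df.phase == "rotation")]
            curve = g.groupby("trial_index")[col].mean()
            curves[grp] = curve.to_dict()
            fits[grp] = fit_learning_curve(curve.to_numpy())

        naive_early = _phase_trial_mean(task_df[task_df.group == naive],
                                        task, "rotation", (1, 2))
        exp_early = _phase_trial_mean(task_df[task_df.group == exp],
                                      task, "rotation", (1, 2))
        naive_base = _phase_trial_mean(task_df[task_df.group == naive],
                                       task, "baseline", (9, 10))
        t_index = transfer_index(naive_early, exp_early, naive_base)

        aftereffects = {}
        for grp in (naive, exp):
            g = task_df[task_df.group == grp]
            late = g[(g.phase == "rotation") & g.trial_index.isin((39, 40))]
            post = g[g.phase == "washout"]
            aftereffects[grp] = aftereffect_percent(
                late.groupby("participant")[col].mean().to_numpy(),
                post.groupby("participant")[col].mean().to_numpy(),
            )

        report[task] = {
            "error_column": col,
            "naive_group": naive,
            "experienced_group": exp,
            "learning_curves": curves,
            "fits": {g: {"a": f.a, "b": f.b, "c": f.c, "r": f.r}
                     for g, f in fits.items()},
            "early_error": {naive: naive_early, exp: exp_early},
            "baseline_error_naive": naive_base,
            "intermediate_error": {
                g: _phase_trial_mean(task_df[task_df.group == g], task,
                                     "rotation", (19, 20)) for g in (naive, exp)},
            "late_error": {
                g: _phase_trial_mean(task_df[task_df.group == g], task,
                                     "rotation", (39, 40)) for g in (naive, exp)},
            "aftereffect_percent": aftereffects,
            "transfer_index": t_index,
        }
    return report
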