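"""Two-way mixed-design ANOVA and Newman-Keuls post-hoc tests.

The design is one between-subject factor (GROUP: prior experience in the
other task or not) crossed with one within-subject factor (TIME: trial-pair
bins, e.g. early/intermediate/late).  The balanced decomposition splits
between-subject variation into GROUP and subjects-within-group, and
within-subject variation into TIME, GROUP x TIME, and TIME x subjects-within-
group; F ratios use the matching error terms.

Post-hoc pairwise comparisons use the Newman-Keuls stepwise studentized-range
procedure; critical values come from the studentized range distribution
(computed numerically, no embedded tables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MixedAnova",
    "MixedAnovaResult",
    "newman_keuls",
    "NewmanKeulsResult",
    "trial_pair_bins",
]

#: bins of trial pairs conventionally contrasted across a 40-trial block
TRIAL_BINS = {"early": (1, 2), "intermediate": (19, 20), "late": (39, 40)}


def trial_pair_bins(df: pd.DataFrame, value_col: str,
                    bins: dict[str, tuple[int, int]] | None = None) -> pd.DataFrame:
    """Average the named trial pairs per participant into a long table.

    Input needs columns ``participant``, ``group``, ``trial_index`` and
    ``value_col``; output has one row per participant x bin with columns
    ``subject``, ``group``, ``time``, ``value``.
    """
    bins = bins or TRIAL_BINS
    rows = []
    for name, trials in bins.items():
        sel = df[df.trial_index.isin(trials)]
        agg = sel.groupby(["participant", "group"], observed=True)[value_col].mean()
        for (subj, grp), val in agg.items():
            rows.append({"subject": subj, "group": grp, "time": name, "value": val})
    return pd.DataFrame(rows)


@dataclass
class MixedAnovaResult:
    """ANOVA table plus the pieces needed for post-hoc range tests."""

    table: pd.DataFrame
    cell_means: pd.DataFrame
    ms_within_error: float
    df_within_error: int
    ms_between_error: float
    df_between_error: int
    n_per_cell: int

    def summary(self) -> str:
        lines = ["Two-way mixed ANOVA (between: group, within: time)", ""]
        lines.append(self.table.to_string(
            float_format=lambda v: f"{v:.4f}"))
        lines.append("")
        lines.append("Cell means:")
        lines.append(self.cell_means.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


class MixedAnova:
    """Balanced two-way mixed ANOVA built from a long-format table.

    Parameters
    ----------
    data : DataFrame with columns ``value``, ``group`` (between factor),
        ``time`` (within factor) and ``subject``.
    """

    def __init__(self, data: pd.DataFrame, value: str = "value",
                 group: str = "group", time: str = "time",
                 subject: str = "subject") -> None:
        self.data = data[[value, group, time, subject]].rename(
            columns={value: "value", group: "group", time: "time",
                     subject: "subject"})
        self._check_balanced()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **names) -> "MixedAnova":
        return cls(data, **names)

    def _check_balanced(self) -> None:
        d = self.data
        counts = d.groupby(["group", "subject"], observed=True)["time"].nunique()
        n_times = d["time"].nunique()
        if not (counts == n_times).all():
            raise ValueError("unbalanced design: every subject needs every "
                             "within-factor level exactly once")
        per_cell = d.groupby(["group", "time"], observed=True).size()
        if per_cell.nunique() != 1:
            raise ValueError("unbalanced design: unequal subjects per group")
        dup = d.groupby(["subject", "time"], observed=True).size()
        if (dup > 1).any():
            raise ValueError("duplicate subject x time observations")

    def fit(self) -> MixedAnovaResult:
        d = self.data
        groups = sorted(d["group"].unique())
        times = sorted(d["time"].unique())
        a, b = len(groups), len(times)
        s = d[d["group"] == groups[0]]["subject"].nunique()

        y = d["value"].to_numpy(dtype=float)
        gm = y.mean()
        ss_total = float(np.sum((y - gm) ** 2))

        grp_means = d.groupby("group", observed=True)["value"].mean()
        time_means = d.groupby("time", observed=True)["value"].mean()
        cell_means = d.groupby(["group", "time"], observed=True)["value"].mean()
        subj_means = d.groupby(["group", "subject"], observed=True)["value"].mean()

        ss_group = b * s * float(((grp_means - gm) ** 2).sum())
        ss_subj = b * float(
            ((subj_means - subj_means.index.get_level_values(0).map(grp_means)) ** 2).sum()
        )
        ss_time = a * s * float(((time_means - gm) ** 2).sum())
        inter = cell_means.copy()
        for (g, t), v in cell_means.items():
            inter.loc[(g, t)] = v - grp_means[g] - time_means[t] + gm
        ss_gxt = s * float((inter**2).sum())
        ss_err = ss_total - ss_group - ss_subj - ss_time - ss_gxt
        ss_err = max(ss_err, 0.0)

        df_group, df_subj = a - 1, a * (s - 1)
        df_time, df_gxt = b - 1, (a - 1) * (b - 1)
        df_err = a * (s - 1) * (b - 1)
        if df_subj < 1 or df_err < 1:
            raise ValueError("design too small for a mixed ANOVA")

        ms_subj = ss_subj / df_subj
        ms_err = ss_err / df_err

        rows = []
        tol = 1e-12 * max(ss_total, 1.0)
        for name, ss, df, ms_e, df_e in (
            ("group", ss_group, df_group, ms_subj, df_subj),
            ("subjects(group)", ss_subj, df_subj, np.nan, np.nan),
            ("time", ss_time, df_time, ms_err, df_err),
            ("group:time", ss_gxt, df_gxt, ms_err, df_err),
            ("time:subjects(group)", ss_err, df_err, np.nan, np.nan),
        ):
            ms = ss / df
            if np.isnan(ms_e):
                rows.append({"effect": name, "ss": ss, "df": df, "ms": ms,
                             "F": np.nan, "df_error": np.nan, "p": np.nan})
                continue
            if ms_e <= tol:
                # degenerate variance: a zero effect over zero error is F = 0
                # by convention; a real effect over zero error is undefined
                if ss <= tol:
                    rows.append({"effect": name, "ss": ss, "df": df, "ms": ms,
                                 "F": 0.0, "df_error": df_e, "p": 1.0})
                    continue
                raise ValueError(
                    f"zero error variance for effect '{name}': F undefined")
            f = ms / ms_e
            p = float(stats.f.sf(f, df, df_e))
            rows.append({"effect": name, "ss": ss, "df": df, "ms": ms,
                         "F": f, "df_error": df_e, "p": p})
        table = pd.DataFrame(rows).set_index("effect")
        return MixedAnovaResult(
            table=table,
            cell_means=cell_means.unstack(),
            ms_within_error=ms_err,
            df_within_error=df_err,
            ms_between_error=ms_subj,
            df_between_error=df_subj,
            n_per_cell=s,
        )


@dataclass
class NewmanKeulsResult:
    """Stepwise range-test decisions over a set of cell means."""

    means: np.ndarray
    labels: list
    significant: np.ndarray  # boolean (k, k) in input order
    p_values: np.ndarray     # (k, k), NaN on blocked/diagonal entries
    alpha: float

    def summary(self) -> str:
        k = len(self.means)
        lines = [f"Newman-Keuls post-hoc (alpha = {self.alpha})"]
        for i in range(k):
            for j in range(i + 1, k):
                mark = "*" if self.significant[i, j] else " "
                p = self.p_values[i, j]
                p_str = f"p = {p:.4f}" if np.isfinite(p) else "blocked"
                lines.append(
                    f"  {self.labels[i]} vs {self.labels[j]}: "
                    f"diff = {abs(self.means[i] - self.means[j]):.4f}  {p_str} {mark}"
                )
        return "\n".join(lines)


def newman_keuls(
    means,
    ms_error: float,
    df_error: int,
    n_per_cell: int,
    labels: list | None = None,
    alpha: float = 0.05,
) -> NewmanKeulsResult:
    """Newman-Keuls stepwise comparisons of a set of cell means.

    Ordered means are compared with studentized-range criticals q(r, df)
    where r is the stretch size of the comparison; a non-significant stretch
    blocks all comparisons nested inside it.
    """
    means = np.asarray(means, dtype=float)
    k = means.size
    if df_error < 2:
        raise ValueError("error degrees of freedom must be >= 2")
    if not (ms_error > 0 and n_per_cell > 0):
        raise ValueError("ms_error and n_per_cell must be positive")
    labels = list(labels) if labels is not None else list(range(k))

    order = np.argsort(means)
    sorted_means = means[order]
    se = np.sqrt(ms_error / n_per_cell)

    sig_sorted = np.zeros((k, k), dtype=bool)
    p_sorted = np.full((k, k), np.nan)
    blocked = np.zeros((k, k), dtype=bool)

    for stretch in range(k, 1, -1):
        for i in range(0, k - stretch + 1):
            j = i + stretch - 1
            if blocked[i, j]:
                continue
            q_obs = (sorted_means[j] - sorted_means[i]) / se
            p = float(stats.studentized_range.sf(q_obs, stretch, df_error))
            p_sorted[i, j] = p_sorted[j, i] = p
            if p < alpha:
                sig_sorted[i, j] = sig_sorted[j, i] = True
            else:
                # block every comparison nested within this stretch
                for ii in range(i, j + 1):
                    for jj in range(ii + 1, j + 1):
                        if (ii, jj) != (i, j):
                            blocked[ii, jj] = blocked[jj, ii] = True

    inv = np.empty(k, dtype=int)
    inv[order] = np.arange(k)
    significant = sig_sorted[np.ix_(inv, inv)]
    p_values = p_sorted[np.ix_(inv, inv)]
    return NewmanKeulsResult(means, labels, significant, p_values, alpha)
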