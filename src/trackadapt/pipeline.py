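"""End-to-end orchestration: simulate -> preprocess -> metrics -> stats.

A run writes a deterministic directory tree::

    out/
      raw/trial_0000.csv ...   one CSV per trial (sample streams)
      raw/manifest.json        per-trial metadata + provenance
      kin/trial_0000.kin.csv   appended speed/acceleration columns
      metrics.csv              one row per trial (TrialMetrics + metadata)
      report.json              fits, ANOVA tables, transfer indices
      report.md                human-readable summary
      config.resolved.yaml     fully resolved configuration incl. seed
      run.log                  one line per stage
"""

from __future__ import annotations

import json
import logging
import platform
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import MixedAnova, trial_pair_bins
from .learning import transfer_report
from .metrics import (
    ApEnSettings,
    SaccadeDetectorConfig,
    TrialMetrics,
    compute_trial_metrics,
)
from .preprocess import FilterConfig, kinematics
from .simulate import SimConfig, TrialRecording, run_experiment

__all__ = ["RunConfig", "run_all", "validate_dataset", "metrics_table",
           "write_dataset", "load_dataset"]

log = logging.getLogger("trackadapt")


@dataclass
class RunConfig:
    """Full configuration of a reproducible pipeline run."""

    seed: int = 0
    participants_per_group: int = 12
    out_dir: str = "run"
    force: bool = False
    sim: dict = field(default_factory=dict)        # SimConfig overrides
    filter: dict = field(default_factory=dict)     # FilterConfig overrides
    detector: dict = field(default_factory=dict)   # SaccadeDetectorConfig
    apen: dict = field(default_factory=dict)       # ApEnSettings overrides
    max_lag_ms: float = 500.0

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(**self.filter)

    def detector_config(self) -> SaccadeDetectorConfig:
        return SaccadeDetectorConfig(**self.detector)

    def apen_settings(self) -> ApEnSettings:
        return ApEnSettings(**self.apen)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# dataset IO


def write_dataset(dataset: list[TrialRecording], raw_dir: Path,
                  seed: int | None = None) -> None:
    raw_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "version": __version__, "trials": []}
    for i, rec in enumerate(dataset):
        name = f"trial_{i:04d}.csv"
        rec.to_frame().to_csv(raw_dir / name, index=False,
                              float_format="%.6f")
        manifest["trials"].append({"file": name, **rec.meta()})
    with open(raw_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_dataset(raw_dir: Path) -> list[TrialRecording]:
    with open(raw_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    dataset = []
    for entry in manifest["trials"]:
        df = pd.read_csv(raw_dir / entry["file"])
        meta = {k: entry[k] for k in ("task", "mapping_deg", "group", "phase",
                                      "trial_index", "pattern_id", "participant")}
        dataset.append(TrialRecording.from_frame(df, **meta))
    return dataset


# ---------------------------------------------------------------------------
# stages


def metrics_table(
    dataset: list[TrialRecording],
    filter_cfg: FilterConfig | None = None,
    detector_cfg: SaccadeDetectorConfig | None = None,
    apen_settings: ApEnSettings | None = None,
    max_lag_ms: float = 500.0,
) -> pd.DataFrame:
    """Per-trial metrics for a dataset as one tidy DataFrame."""
    rows = []
    for rec in dataset:
        m = compute_trial_metrics(rec, filter_cfg, detector_cfg,
                                  apen_settings, max_lag_ms)
        rows.append({**rec.meta(), **vars(m)})
    return pd.DataFrame(rows)


def _stats_report(metrics: pd.DataFrame, seed: int) -> dict:
    report = {"provenance": {
        "package": "trackadapt",
        "version": __version__,
        "seed": seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }}
    report["transfer"] = transfer_report(metrics)
    report["anova"] = {}
    for task, col in (("hand", "cursor_target_cm"), ("eye", "eye_target_cm")):
        rot = metrics[(metrics.task == task) & (metrics.phase == "rotation")]
        binned = trial_pair_bins(rot, col)
        res = MixedAnova(binned).fit()
        report["anova"][task] = {
            "table": res.table.reset_index().to_dict(orient="records"),
            "cell_means": {str(k): v for k, v in
                           res.cell_means.stack().to_dict().items()},
        }
    return report


def _render_md(report: dict) -> str:
    lines = ["# Tracking adaptation run report", ""]
    for task in ("hand", "eye"):
        t = report["transfer"][task]
        lines += [
            f"## {task} task",
            "",
            f"- error measure: `{t['error_column']}`",
            f"- naive group: {t['naive_group']}, experienced: {t['experienced_group']}",
            f"- early rotation error (naive / experienced): "
            f"{t['early_error'][t['naive_group']]:.2f} / "
            f"{t['early_error'][t['experienced_group']]:.2f} cm",
            f"- naive baseline error: {t['baseline_error_naive']:.2f} cm",
            f"- transfer index: {t['transfer_index']:.2f}",
            f"- aftereffect (%): " + ", ".join(
                f"{g}: {v:+.0f}%" for g, v in t["aftereffect_percent"].items()),
            "",
        ]
        anova = report["anova"][task]["table"]
        lines.append("| effect | df | F | p |")
        lines.append("|---|---|---|---|")
        for row in anova:
            if np.isnan(row["F"]):
                continue
            lines.append(f"| {row['effect']} | ({row['df']:.0f}, "
                         f"{row['df_error']:.0f}) | {row['F']:.2f} | "
                         f"{row['p']:.4f} |")
        lines.append("")
    return "\n".join(lines)


def run_all(config: RunConfig) -> Path:
    """Execute the full protocol end to end; returns the run directory."""
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()):
        if not config.force:
            raise FileExistsError(
                f"output directory {out} is not empty (use force=True)")
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "config.resolved.yaml")
        log.info("simulating: %d participants/group, seed %d",
                 config.participants_per_group, config.seed)
        dataset = run_experiment(config.sim_config(), seed=config.seed,
                                 participants_per_group=config.participants_per_group)
        log.info("writing %d trials", len(dataset))
        write_dataset(dataset, out / "raw", seed=config.seed)

        log.info("preprocessing kinematics")
        kin_dir = out / "kin"
        kin_dir.mkdir(exist_ok=True)
        fcfg = config.filter_config()
        for i, rec in enumerate(dataset):
            kin = kinematics(rec.eye_xy, rec.fs, fcfg)
            df = rec.to_frame()
            df["eye_speed_cm_s"] = kin["speed"]
            df["eye_acc_cm_s2"] = kin["acceleration"]
            df.to_csv(kin_dir / f"trial_{i:04d}.kin.csv", index=False,
                      float_format="%.6f")

        log.info("computing per-trial metrics")
        metrics = metrics_table(dataset, fcfg, config.detector_config(),
                                config.apen_settings(), config.max_lag_ms)
        metrics.to_csv(out / "metrics.csv", index=False, float_format="%.6f")

        log.info("running group statistics")
        report = _stats_report(metrics, config.seed)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
        (out / "report.md").write_text(_render_md(report))
        log.info("done")
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


# ---------------------------------------------------------------------------
# validation


def validate_dataset(directory: str | Path,
                     expected_samples: int = 10_000) -> list[dict]:
    """Schema and consistency checks over a raw dataset directory.

    Returns a machine-readable list of issues (empty when pristine).
    """
    directory = Path(directory)
    issues: list[dict] = []
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        return [{"issue": "missing_manifest", "path": str(manifest_path)}]
    with open(manifest_path) as fh:
        manifest = json.load(fh)

    required = {"t_ms", "target_x_cm", "target_y_cm", "eye_x_cm", "eye_y_cm",
                "pupil", "valid"}
    for entry in manifest["trials"]:
        path = directory / entry["file"]
        if not path.exists():
            issues.append({"issue": "missing_file", "file": entry["file"]})
            continue
        df = pd.read_csv(path)
        missing = required - set(df.columns)
        if missing:
            issues.append({"issue": "missing_columns", "file": entry["file"],
                           "columns": sorted(missing)})
            continue
        if len(df) != entry.get("n_samples", expected_samples):
            issues.append({"issue": "sample_count", "file": entry["file"],
                           "expected": entry.get("n_samples", expected_samples),
                           "found": len(df)})
        if len(df) != expected_samples:
            issues.append({"issue": "unexpected_length", "file": entry["file"],
                           "expected": expected_samples, "found": len(df)})
        if not np.all(np.diff(df["t_ms"].to_numpy()) > 0):
            issues.append({"issue": "non_monotone_time", "file": entry["file"]})
        blink = df["pupil"].to_numpy() <= 0
        invalid = df["valid"].to_numpy() == 0
        if not np.array_equal(blink, invalid):
            issues.append({"issue": "valid_mask_mismatch", "file": entry["file"]})
        if entry["task"] == "hand" and "cursor_x_cm" not in df.columns:
            issues.append({"issue": "manifest_task_mismatch",
                           "file": entry["file"],
                           "detail": "hand trial without cursor columns"})
    return issues
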