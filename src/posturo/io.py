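"""File formats, session configuration, and the end-to-end pipeline.

CSV dialect everywhere: comma separator, period decimal, UTF-8, mandatory
header. Raw recordings use the header ``t,f_tl,f_tr,f_bl,f_br``; per-trial
metric tables and condition summaries use the column contracts defined in
:mod:`posturo.metrics`; reliability reports use the column layout of
:mod:`posturo.reliability`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .board import (
    BoardGeometry,
    DEFAULT_GEOMETRY,
    DEFAULT_MIN_LOAD_FRACTION,
    RawRecording,
    compute_cop_series,
)
from .errors import DesignError, FormatError, PosturoError
from .metrics import (
    DEFAULT_PROTOCOL,
    TaskProtocol,
    metrics_to_frame,
    summarize_table,
    trial_metrics,
)
from .preprocess import FilterSpec, preprocess
from .reliability import (
    ComparisonSpec,
    DEFAULT_COMPARISONS,
    bland_altman_table,
    reliability_report,
    render_report_text,
)

logger = logging.getLogger(__name__)

RAW_COLUMNS = ("t", "f_tl", "f_tr", "f_bl", "f_br")


# ---------------------------------------------------------------------------
# Raw recording IO
# ---------------------------------------------------------------------------

def read_raw_recording(
    path,
    geometry: BoardGeometry = DEFAULT_GEOMETRY,
    meta: Optional[dict] = None,
) -> RawRecording:
    """Parse and validate a raw-recording CSV.

    Columns are keyed by header name, so column order is free. Malformed
    content raises :class:`FormatError` naming the offending data row
    (1-based, excluding the header).
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in RAW_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    frame = frame[list(RAW_COLUMNS)]
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path.name}: non-numeric value {frame.iat[r, c]!r} in column "
            f"{frame.columns[c]!r} at data row {r + 1}"
        )
    if numeric.isna().to_numpy().any():
        r = int(np.argwhere(numeric.isna().to_numpy())[0, 0])
        raise FormatError(f"{path.name}: empty cell at data row {r + 1}")
    t = numeric["t"].to_numpy(float)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        r = int(np.argmax(np.diff(t) <= 0)) + 2
        raise FormatError(f"{path.name}: non-increasing timestamp at data row {r}")
    forces = numeric[list(RAW_COLUMNS[1:])].to_numpy(float)
    if np.any(forces < 0):
        r = int(np.argwhere(forces < 0)[0, 0]) + 1
        raise FormatError(f"{path.name}: negative force at data row {r}")
    return RawRecording(t=t, forces=forces, geometry=geometry, meta=dict(meta or {}))


def write_raw_recording(rec: RawRecording, path) -> None:
    pd.DataFrame(
        np.column_stack([rec.t, rec.forces]), columns=list(RAW_COLUMNS)
    ).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Session configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SessionConfig:
    """Everything the pipeline needs: geometry, filtering, protocol, design."""

    geometry: BoardGeometry = DEFAULT_GEOMETRY
    preprocessing: FilterSpec = FilterSpec()
    tasks: Tuple[TaskProtocol, ...] = DEFAULT_PROTOCOL
    sessions: Tuple[str, ...] = ("A1", "B", "A2", "A3")
    comparisons: Tuple[ComparisonSpec, ...] = DEFAULT_COMPARISONS
    min_load_fraction: float = DEFAULT_MIN_LOAD_FRACTION
    trim_s: float = 0.0

    def __post_init__(self) -> None:
        declared = set(self.sessions)
        for cmp_ in self.comparisons:
            undeclared = {cmp_.session_a, cmp_.session_b} - declared
            if undeclared:
                raise DesignError(
                    f"comparison {cmp_.name!r} references undeclared "
                    f"session(s) {sorted(undeclared)}"
                )

    def to_dict(self) -> dict:
        return {
            "geometry": {"width_x": self.geometry.width_x, "depth_y": self.geometry.depth_y},
            "preprocessing": dataclasses.asdict(self.preprocessing),
            "tasks": [dataclasses.asdict(t) for t in self.tasks],
            "sessions": list(self.sessions),
            "comparisons": [dataclasses.asdict(c) for c in self.comparisons],
            "min_load_fraction": self.min_load_fraction,
            "trim_s": self.trim_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        kwargs = {}
        if "geometry" in d:
            kwargs["geometry"] = BoardGeometry(**d["geometry"])
        if "preprocessing" in d:
            kwargs["preprocessing"] = FilterSpec(**d["preprocessing"])
        if "tasks" in d:
            kwargs["tasks"] = tuple(TaskProtocol(**t) for t in d["tasks"])
        if "sessions" in d:
            kwargs["sessions"] = tuple(d["sessions"])
        if "comparisons" in d:
            kwargs["comparisons"] = tuple(ComparisonSpec(**c) for c in d["comparisons"])
        for key in ("min_load_fraction", "trim_s"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)


def load_config(path) -> SessionConfig:
    return SessionConfig.from_dict(json.loads(Path(path).read_text()))


def save_config(config: SessionConfig, path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def process_manifest(
    config: SessionConfig,
    manifest: Union[pd.DataFrame, str, Path],
    base_dir: Optional[Path] = None,
) -> pd.DataFrame:
    """Raw recordings -> per-trial metric table.

    ``manifest`` maps recordings to identities with columns
    ``subject,task,session,trial,path`` (paths relative to ``base_dir``, which
    defaults to the manifest's directory). Trials whose file fails parsing or
    preprocessing are dropped with a reason-coded warning rather than
    aborting the run.
    """
    if not isinstance(manifest, pd.DataFrame):
        mpath = Path(manifest)
        base_dir = mpath.parent if base_dir is None else Path(base_dir)
        manifest = pd.read_csv(mpath)
    else:
        base_dir = Path(".") if base_dir is None else Path(base_dir)
    required = {"subject", "task", "session", "trial", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")

    results = []
    for _, row in manifest.iterrows():
        ident = f"{row['subject']}/{row['task']}/{row['session']}/trial{row['trial']}"
        try:
            rec = read_raw_recording(base_dir / row["path"], config.geometry)
            traj = compute_cop_series(rec, config.min_load_fraction)
            traj = preprocess(traj, config.preprocessing, config.trim_s)
            results.append(
                trial_metrics(
                    traj, str(row["subject"]), str(row["task"]),
                    str(row["session"]), int(row["trial"]),
                )
            )
        except (PosturoError, OSError) as exc:
            logger.warning("DROPPED_TRIAL:%s: %s: %s", type(exc).__name__, ident, exc)
    return metrics_to_frame(results)


def run_pipeline(
    config: SessionConfig,
    manifest: Union[pd.DataFrame, str, Path],
    outdir,
    base_dir: Optional[Path] = None,
    metrics: Sequence[str] = ("pl_cm", "va_cm_s"),
) -> dict:
    """Full pipeline: raw -> metrics -> summaries -> reliability reports.

    Writes ``trials.csv``, ``summaries.csv``, and per-comparison report CSV /
    aligned-text / Bland–Altman artifacts under ``outdir``. A comparison
    whose sessions are absent from the data is skipped with a warning.
    Returns a dict mapping artifact names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials = process_manifest(config, manifest, base_dir)
    if trials.empty:
        raise FormatError("no trial could be processed from the manifest")
    summaries = summarize_table(trials)
    artifacts = {}
    trials.to_csv(outdir / "trials.csv", index=False, float_format="%.6f")
    summaries.to_csv(outdir / "summaries.csv", index=False, float_format="%.6f")
    artifacts["trials"] = outdir / "trials.csv"
    artifacts["summaries"] = outdir / "summaries.csv"

    present = set(summaries["session"])
    for cmp_ in config.comparisons:
        if not {cmp_.session_a, cmp_.session_b} <= present:
            logger.warning(
                "SKIPPED_COMPARISON:%s: session(s) %s absent from data",
                cmp_.name,
                sorted({cmp_.session_a, cmp_.session_b} - present),
            )
            continue
        report = reliability_report(summaries, cmp_, metrics=metrics)
        rpath = outdir / f"report_{cmp_.name}.csv"
        report.to_csv(rpath, index=False, float_format="%.6f")
        (outdir / f"report_{cmp_.name}.txt").write_text(
            render_report_text(report, cmp_) + "\n"
        )
        artifacts[f"report_{cmp_.name}"] = rpath

        ba_rows, ba_json = [], {}
        for task in report["task"].unique():
            for metric in metrics:
                points, res = bland_altman_table(summaries, cmp_, task, metric)
                points.insert(0, "metric", metric)
                points.insert(0, "task", task)
                ba_rows.append(points)
                ba_json[f"{task}:{metric}"] = {
                    "bias": res.bias,
                    "sd_diff": res.sd_diff,
                    "loa_low": res.loa_low,
                    "loa_high": res.loa_high,
                }
        bpath = outdir / f"bland_altman_{cmp_.name}.csv"
        pd.concat(ba_rows, ignore_index=True).to_csv(
            bpath, index=False, float_format="%.6f"
        )
        (outdir / f"bland_altman_{cmp_.name}.json").write_text(
            json.dumps(ba_json, indent=2, sort_keys=True) + "\n"
        )
        artifacts[f"bland_altman_{cmp_.name}"] = bpath
    return artifacts
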