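"""Sway outcome measures: COP path length and average velocity.

Path length (PL) is the summed Euclidean distance between consecutive COP
samples, in cm; average velocity (VA) is PL divided by the elapsed recorded
duration T = (N-1)/fs, in cm/s, so VA*T == PL by definition. The standard
protocol runs four stance tasks — STOE/STCE (two legs, 30 s) and SOOE/SOCE
(one leg, 10 s), eyes open/closed — three trials each, and analyses the mean
of the three repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .board import COPTrajectory
from .errors import GroupingError, TooShortError

#: Canonical task order used in reports.
TASKS = ("STOE", "STCE", "SOOE", "SOCE")

#: Columns of the per-trial metric table (the statistics layer's contract).
TRIAL_COLUMNS = ("subject", "task", "session", "trial", "pl_cm", "va_cm_s")
SUMMARY_COLUMNS = ("subject", "task", "session", "pl_cm", "va_cm_s", "n_trials_used")


@dataclass(frozen=True)
class TaskProtocol:
    """One stance task: label, trial duration in s, number of trials."""

    task: str
    duration_s: float
    n_trials: int = 3

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")


#: The standard four-task protocol: 30 s two-leg stances, 10 s one-leg stances.
DEFAULT_PROTOCOL = (
    TaskProtocol("STOE", 30.0),
    TaskProtocol("STCE", 30.0),
    TaskProtocol("SOOE", 10.0),
    TaskProtocol("SOCE", 10.0),
)


@dataclass(frozen=True)
class TrialMetrics:
    """Outcome measures for a single trial."""

    subject: str
    task: str
    session: str
    trial: int
    pl_cm: float
    va_cm_s: float

    def __post_init__(self) -> None:
        if self.pl_cm < 0 or self.va_cm_s < 0:
            raise ValueError("path length and velocity must be non-negative")


@dataclass(frozen=True)
class ConditionSummary:
    """Mean-of-trials outcome for one subject x task x session condition."""

    subject: str
    task: str
    session: str
    pl_cm: float
    va_cm_s: float
    n_trials_used: int


def path_length(traj: COPTrajectory) -> float:
    """Total COP path length in cm: sum of consecutive-sample distances."""
    if traj.n < 2:
        raise TooShortError("path length needs at least 2 samples")
    return float(np.hypot(np.diff(traj.x), np.diff(traj.y)).sum())


def mean_velocity(traj: COPTrajectory) -> float:
    """Average COP speed in cm/s: path length over elapsed duration."""
    return path_length(traj) / traj.duration


def trial_metrics(
    traj: COPTrajectory, subject: str, task: str, session: str, trial: int
) -> TrialMetrics:
    """Compute both outcome measures for one preprocessed trial."""
    pl = path_length(traj)
    return TrialMetrics(
        subject=subject,
        task=task,
        session=session,
        trial=trial,
        pl_cm=pl,
        va_cm_s=pl / traj.duration,
    )


def summarize_condition(trials: Sequence[TrialMetrics]) -> ConditionSummary:
    """Mean of repetitions for one condition.

    All trials must share subject/task/session keys; the protocol uses the
    mean of three repetitions but any count >= 1 is accepted (trials that
    failed preprocessing are dropped upstream).
    """
    if len(trials) == 0:
        raise GroupingError("cannot summarise an empty trial list")
    key = (trials[0].subject, trials[0].task, trials[0].session)
    for tr in trials:
        if (tr.subject, tr.task, tr.session) != key:
            raise GroupingError(
                f"mixed condition keys: {key} vs "
                f"{(tr.subject, tr.task, tr.session)}"
            )
    return ConditionSummary(
        subject=key[0],
        task=key[1],
        session=key[2],
        pl_cm=float(np.mean([tr.pl_cm for tr in trials])),
        va_cm_s=float(np.mean([tr.va_cm_s for tr in trials])),
        n_trials_used=len(trials),
    )


def metrics_to_frame(trials: Iterable[TrialMetrics]) -> pd.DataFrame:
    """Per-trial metric table in the statistics layer's column contract."""
    rows = [
        (tr.subject, tr.task, tr.session, tr.trial, tr.pl_cm, tr.va_cm_s)
        for tr in trials
    ]
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def summarize_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-trial table to condition summaries (mean of trials)."""
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise GroupingError(f"trial table missing columns: {sorted(missing)}")
    grouped = (
        trials.groupby(["subject", "task", "session"], sort=False)
        .agg(
            pl_cm=("pl_cm", "mean"),
            va_cm_s=("va_cm_s", "mean"),
            n_trials_used=("trial", "size"),
        )
        .reset_index()
    )
    return grouped[list(SUMMARY_COLUMNS)]
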