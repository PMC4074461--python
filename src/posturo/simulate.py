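"""Synthetic sway trajectories and full multi-session reliability studies.

Two layers of simulation with known ground truth:

* **Trajectory level** — quiet-stance COP sway as a discrete Ornstein–
  Uhlenbeck (OU) process per axis: mean-reverting, stationary, band-limited,
  visually plausible. An optional calibration rescales the path about its
  mean so the path length hits an exact target (the path length of a scaled
  path scales linearly, so the rescale is exact).

* **Study level** — a variance-components model of the standard reliability
  design: 20 subjects x 4 tasks x 3 trials x 4 sessions (rater1/day1 = A1,
  rater2/day1 = B, rater1/day2 = A2, force platform/day3 = A3). Per task,
  subject true scores are Normal(task mean, sigma_subject^2), each
  board session adds a shared Normal(0, sigma_session^2) offset, the platform
  session instead applies a fixed bias + scale distortion, and every trial
  adds Normal(0, sigma_error^2) noise (floored at 0). The implied
  single-trial intraclass correlation sigma_s^2 / (sigma_s^2 + sigma_sess^2
  + sigma_e^2) is the recoverable ground truth.

Default task means and between-subject SDs are set to the magnitudes healthy
adults show on these tasks (two-leg stances ~36-40 cm over 30 s, one-leg
stances ~44-81 cm over 10 s), with noise fractions giving high reliability on
two-leg tasks and moderate on the one-leg eyes-open task.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .board import BoardGeometry, COPTrajectory, DEFAULT_GEOMETRY, forces_from_cop
from .errors import ParameterError
from .metrics import TRIAL_COLUMNS
from .preprocess import FilterSpec, lowpass_filter, resample_uniform

#: Body load written into simulated recordings (kg-equivalent), typical adult.
DEFAULT_LOAD = 64.5


@dataclass(frozen=True)
class SwayModelParams:
    """Ornstein–Uhlenbeck sway parameters.

    theta : mean-reversion rate toward the stance point, 1/s
    sigma_x, sigma_y : diffusion scale per axis, cm/sqrt(s)
    duration_s, fs_hz : trial length and sampling rate
    target_pl_cm : optional exact path-length calibration target (raw path)
    """

    theta: float = 0.8
    sigma_x: float = 0.15
    sigma_y: float = 0.15
    duration_s: float = 30.0
    fs_hz: float = 50.0
    target_pl_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ParameterError(f"theta must be positive, got {self.theta}")
        if not (self.sigma_x > 0 and self.sigma_y > 0):
            raise ParameterError("diffusion scales must be positive")
        if self.duration_s * self.fs_hz < 2:
            raise ParameterError("duration_s * fs_hz must be >= 2 samples")
        if self.target_pl_cm is not None and not self.target_pl_cm > 0:
            raise ParameterError("target_pl_cm must be positive when given")


def simulate_cop_trajectory(
    p: SwayModelParams,
    seed,
    geometry: BoardGeometry = DEFAULT_GEOMETRY,
    load: float = DEFAULT_LOAD,
) -> COPTrajectory:
    """Simulate one OU sway trajectory, reproducible for a fixed seed.

    Euler–Maruyama updates ``x_{t+1} = x_t - theta*x_t*dt + sigma*sqrt(dt)*eps``
    started from the stationary distribution; points are clipped to the board
    rectangle. With ``target_pl_cm`` set, the path is rescaled about its mean
    so its raw path length equals the target exactly.
    """
    rng = np.random.default_rng(seed)
    n = int(round(p.duration_s * p.fs_hz))
    dt = 1.0 / p.fs_hz
    out = np.empty((n, 2))
    sig = np.array([p.sigma_x, p.sigma_y])
    # stationary start: Var = sigma^2 / (2 theta)
    out[0] = rng.standard_normal(2) * sig / np.sqrt(2 * p.theta)
    steps = rng.standard_normal((n - 1, 2)) * sig * np.sqrt(dt)
    for i in range(1, n):
        out[i] = out[i - 1] * (1 - p.theta * dt) + steps[i - 1]
    np.clip(out[:, 0], -geometry.half_width, geometry.half_width, out=out[:, 0])
    np.clip(out[:, 1], -geometry.half_depth, geometry.half_depth, out=out[:, 1])
    if p.target_pl_cm is not None:
        pl = np.hypot(np.diff(out[:, 0]), np.diff(out[:, 1])).sum()
        if pl <= 0:
            raise ParameterError("degenerate path cannot be calibrated to a target")
        out = out.mean(axis=0) + (out - out.mean(axis=0)) * (p.target_pl_cm / pl)
    return COPTrajectory(
        fs=p.fs_hz,
        x=out[:, 0],
        y=out[:, 1],
        total_load=np.full(n, float(load)),
        t=None,
    )


def calibrated_recording(
    pl_target_cm: float,
    duration_s: float,
    seed,
    sway: SwayModelParams = SwayModelParams(),
    filter_spec: FilterSpec = FilterSpec(),
    geometry: BoardGeometry = DEFAULT_GEOMETRY,
    load: float = DEFAULT_LOAD,
):
    """Materialise a raw recording whose *pipeline* path length equals a target.

    The OU path is simulated, pushed through the preprocessing chain
    (resample + low-pass), and then rescaled about its mean so the filtered
    path length equals ``pl_target_cm``; because resampling and the filter
    are linear with unit DC gain, the rescale is exact. Returns the
    four-force :class:`~posturo.board.RawRecording`.
    """
    p = SwayModelParams(
        theta=sway.theta,
        sigma_x=sway.sigma_x,
        sigma_y=sway.sigma_y,
        duration_s=duration_s,
        fs_hz=filter_spec.fs_hz,
        target_pl_cm=None,
    )
    traj = simulate_cop_trajectory(p, seed, geometry=geometry, load=load)
    filt = lowpass_filter(resample_uniform(traj, filter_spec.fs_hz), filter_spec)
    pl_filt = np.hypot(np.diff(filt.x), np.diff(filt.y)).sum()
    if pl_filt <= 0:
        raise ParameterError("degenerate filtered path cannot be calibrated")
    s = pl_target_cm / pl_filt
    x = traj.x.mean() + (traj.x - traj.x.mean()) * s
    y = traj.y.mean() + (traj.y - traj.y.mean()) * s
    scaled = COPTrajectory(fs=traj.fs, x=x, y=y, total_load=traj.total_load, t=None)
    return forces_from_cop(scaled, geometry=geometry)


# ---------------------------------------------------------------------------
# Study-level simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskEffects:
    """Variance components for one task's path-length metric (cm)."""

    task: str
    duration_s: float
    mean_pl_cm: float
    sigma_subject: float
    sigma_session: float
    sigma_error: float

    def __post_init__(self) -> None:
        if min(self.sigma_subject, self.sigma_session, self.sigma_error) < 0:
            raise ParameterError("variance components must be >= 0")
        if not self.duration_s > 0:
            raise ParameterError("duration_s must be positive")

    @property
    def true_icc(self) -> float:
        """Population single-trial ICC implied by the components."""
        tot = self.sigma_subject**2 + self.sigma_session**2 + self.sigma_error**2
        return self.sigma_subject**2 / tot if tot > 0 else 0.0


#: Default study conditions: two-leg tasks highly reliable, one-leg
#: eyes-open moderate, one-leg eyes-closed in between.
DEFAULT_TASK_EFFECTS = (
    TaskEffects("STOE", 30.0, 36.0, 7.9, 1.58, 1.58),
    TaskEffects("STCE", 30.0, 39.8, 6.4, 1.28, 1.28),
    TaskEffects("SOOE", 10.0, 44.4, 8.5, 3.83, 3.83),
    TaskEffects("SOCE", 10.0, 81.0, 18.0, 5.04, 5.04),
)


@dataclass(frozen=True)
class StudyDesign:
    """Full multi-session reliability study layout with ground truth."""

    n_subjects: int = 20
    tasks: Tuple[TaskEffects, ...] = DEFAULT_TASK_EFFECTS
    n_trials: int = 3
    sessions: Tuple[str, ...] = ("A1", "B", "A2", "A3")
    platform_session: Optional[str] = "A3"
    device_bias: float = 0.0
    device_scale: float = 0.92
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("need at least 2 subjects")
        if self.n_trials < 1:
            raise ParameterError("need at least 1 trial")
        if self.platform_session is not None and (
            self.platform_session not in self.sessions
        ):
            raise ParameterError(
                f"platform session {self.platform_session!r} not in sessions"
            )
        if not self.device_scale > 0:
            raise ParameterError("device_scale must be positive")

    def truth(self) -> dict:
        """Ground-truth summary: per-task components and implied ICCs."""
        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "n_trials": self.n_trials,
            "sessions": list(self.sessions),
            "platform_session": self.platform_session,
            "device_bias": self.device_bias,
            "device_scale": self.device_scale,
            "tasks": {
                t.task: {
                    "duration_s": t.duration_s,
                    "mean_pl_cm": t.mean_pl_cm,
                    "sigma_subject": t.sigma_subject,
                    "sigma_session": t.sigma_session,
                    "sigma_error": t.sigma_error,
                    "true_icc_single_trial": t.true_icc,
                    "true_icc_trial_mean": t.sigma_subject**2
                    / (
                        t.sigma_subject**2
                        + t.sigma_session**2
                        + t.sigma_error**2 / self.n_trials
                    ),
                }
                for t in self.tasks
            },
        }


def simulate_ratings_matrix(
    n: int,
    k: int,
    sigma_subject: float,
    sigma_session: float,
    sigma_error: float,
    rng,
    mean: float = 0.0,
) -> np.ndarray:
    """One n x k ratings matrix from the additive variance-components model.

    ``y_ij = mean + subject_i + session_j + e_ij`` — the generator behind the
    study simulator, exposed for ICC-recovery and CI-coverage experiments.
    """
    subj = rng.normal(0.0, sigma_subject, size=(n, 1))
    sess = rng.normal(0.0, sigma_session, size=(1, k))
    err = rng.normal(0.0, sigma_error, size=(n, k))
    return mean + subj + sess + err


def simulate_study(
    design: StudyDesign = StudyDesign(),
    seed: Optional[int] = None,
    raw_dir: Optional[Path] = None,
    filter_spec: FilterSpec = FilterSpec(),
    geometry: BoardGeometry = DEFAULT_GEOMETRY,
) -> Tuple[pd.DataFrame, dict]:
    """Simulate the full study; returns (per-trial metric table, ground truth).

    The table follows the statistics layer's contract
    (``subject,task,session,trial,pl_cm,va_cm_s``) with velocity defined as
    PL / duration. Trial values are floored at 0 (a negligible truncation at
    the default parameters). With ``raw_dir`` set, each trial is additionally
    materialised as a raw four-force recording (CSV) calibrated so that the
    preprocessing pipeline reproduces the tabulated path length, and a
    manifest CSV is written alongside.
    """
    master = design.seed if seed is None else int(seed)
    ss = np.random.SeedSequence(master)
    rng = np.random.default_rng(ss)
    subjects = [f"S{i + 1:02d}" for i in range(design.n_subjects)]

    rows = []
    for te in design.tasks:
        mu = rng.normal(te.mean_pl_cm, te.sigma_subject, size=design.n_subjects)
        for ses in design.sessions:
            if ses == design.platform_session:
                base = design.device_bias + design.device_scale * mu
            else:
                base = mu + rng.normal(0.0, te.sigma_session)
            for trial in range(1, design.n_trials + 1):
                y = base + rng.normal(0.0, te.sigma_error, size=design.n_subjects)
                y = np.maximum(y, 0.0)
                for subj, pl in zip(subjects, y):
                    rows.append(
                        (subj, te.task, ses, trial, float(pl), float(pl) / te.duration_s)
                    )
    table = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    truth = design.truth()
    truth["seed"] = master

    if raw_dir is not None:
        raw_dir = Path(raw_dir)
        raw_dir.mkdir(parents=True, exist_ok=True)
        durations = {te.task: te.duration_s for te in design.tasks}
        child_seeds = ss.spawn(len(table))
        manifest = []
        for (idx, row), child in zip(table.iterrows(), child_seeds):
            rec = calibrated_recording(
                row["pl_cm"],
                durations[row["task"]],
                child,
                filter_spec=filter_spec,
                geometry=geometry,
            )
            name = f"{row['subject']}_{row['task']}_{row['session']}_t{row['trial']}.csv"
            path = raw_dir / name
            frame = pd.DataFrame(
                np.column_stack([rec.t, rec.forces]),
                columns=["t", "f_tl", "f_tr", "f_bl", "f_br"],
            )
            frame.to_csv(path, index=False, float_format="%.6f")
            manifest.append(
                (row["subject"], row["task"], row["session"], row["trial"], name)
            )
        pd.DataFrame(
            manifest, columns=["subject", "task", "session", "trial", "path"]
        ).to_csv(raw_dir / "manifest.csv", index=False)
        truth["raw_dir"] = str(raw_dir)

    return table, truth


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))
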