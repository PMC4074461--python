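"""Four-load-cell balance board model.

A consumer balance board senses the vertical load at its four corners. The
point of application of the resultant vertical force — the center of pressure
(COP) — follows from a moment balance over the corners. Axis convention
(documented here because board vendors do not state one): ``x`` is
medio-lateral along the long 45 cm edge, positive toward the user's right
(top-right/bottom-right cells); ``y`` is antero-posterior along the 26.5 cm
edge, positive forward (top-left/top-right cells); origin at the board center.

Forces are unit-agnostic (newtons or kg-equivalent): the COP is invariant to
uniform scaling of the four signals, and the summed load is passed through
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np

from .errors import (
    DomainError,
    FormatError,
    ParameterError,
    UnrecoverableSignalError,
)

logger = logging.getLogger(__name__)

#: Default fraction of the median total load below which a sample is invalid.
DEFAULT_MIN_LOAD_FRACTION = 0.05


@dataclass(frozen=True)
class BoardGeometry:
    """Physical sensor layout of a rectangular four-corner board.

    Parameters
    ----------
    width_x : float
        Medio-lateral extent in cm (the 45 cm edge on the standard board).
    depth_y : float
        Antero-posterior extent in cm (the 26.5 cm edge).

    The coordinate origin is fixed at the board center.
    """

    width_x: float = 45.0
    depth_y: float = 26.5

    def __post_init__(self) -> None:
        if not (self.width_x > 0 and self.depth_y > 0):
            raise ParameterError(
                f"board dimensions must be positive, got "
                f"({self.width_x}, {self.depth_y})"
            )

    @property
    def half_width(self) -> float:
        return self.width_x / 2.0

    @property
    def half_depth(self) -> float:
        return self.depth_y / 2.0

    def contains(self, x: np.ndarray, y: np.ndarray, tol: float = 0.0) -> np.ndarray:
        """Boolean mask of points inside the board rectangle (± ``tol`` cm)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (np.abs(x) <= self.half_width + tol) & (np.abs(y) <= self.half_depth + tol)


DEFAULT_GEOMETRY = BoardGeometry()

#: Corner order used throughout for force arrays of shape (n, 4).
CORNERS = ("f_tl", "f_tr", "f_bl", "f_br")


class LoadCellSample(NamedTuple):
    """One raw sample: time plus the four corner loads (tl, tr, bl, br)."""

    t: float
    f_tl: float
    f_tr: float
    f_bl: float
    f_br: float


@dataclass
class RawRecording:
    """Time series of the four corner loads for one trial.

    ``forces`` has shape (n, 4) with columns ordered top-left, top-right,
    bottom-left, bottom-right. Timestamps must be strictly increasing and the
    recording must hold at least two samples.
    """

    t: np.ndarray
    forces: np.ndarray
    geometry: BoardGeometry = DEFAULT_GEOMETRY
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.t.ndim != 1 or self.forces.shape != (self.t.size, 4):
            raise FormatError(
                f"expected t of shape (n,) and forces of shape (n, 4), got "
                f"{self.t.shape} and {self.forces.shape}"
            )
        if self.t.size < 2:
            raise FormatError("a recording needs at least 2 samples")
        if not np.all(np.isfinite(self.t)):
            raise FormatError("non-finite timestamp in recording")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise FormatError(
                f"timestamps must be strictly increasing (violated at sample {bad})"
            )
        if not np.all(np.isfinite(self.forces)):
            raise FormatError("non-finite force reading in recording")
        if np.any(self.forces < 0):
            bad = int(np.argwhere(self.forces < 0)[0, 0])
            raise FormatError(f"negative load-cell reading at sample {bad}")

    @classmethod
    def from_samples(
        cls,
        samples: Iterable[LoadCellSample],
        geometry: BoardGeometry = DEFAULT_GEOMETRY,
        meta: Optional[dict] = None,
    ) -> "RawRecording":
        arr = np.asarray([tuple(s) for s in samples], dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 5:
            raise FormatError("samples must be (t, f_tl, f_tr, f_bl, f_br) tuples")
        return cls(arr[:, 0], arr[:, 1:], geometry, dict(meta or {}))

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def nominal_fs(self) -> float:
        """Average sampling rate implied by the timestamps, in Hz."""
        return (self.n - 1) / (self.t[-1] - self.t[0])


@dataclass
class COPTrajectory:
    """Sampled 2-D COP path in board coordinates (cm).

    ``fs`` is the nominal sampling rate; ``t`` carries the actual timestamps
    when the trajectory came from a (possibly jittered) raw recording and is
    ``None`` once the signal is uniformly resampled. ``total_load`` is the
    per-sample summed corner load, in the input's own units.
    """

    fs: float
    x: np.ndarray
    y: np.ndarray
    total_load: np.ndarray
    t: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.total_load = np.asarray(self.total_load, dtype=float)
        if self.t is not None:
            self.t = np.asarray(self.t, dtype=float)
        if not self.fs > 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        n = self.x.size
        if self.y.size != n or self.total_load.size != n:
            raise FormatError("x, y and total_load must have equal length")
        if self.t is not None and self.t.size != n:
            raise FormatError("t must match the coordinate length")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def duration(self) -> float:
        """Elapsed recorded duration (N-1)/fs in seconds."""
        return (self.n - 1) / self.fs


def compute_cop_series(
    rec: RawRecording,
    min_load_fraction: float = DEFAULT_MIN_LOAD_FRACTION,
) -> COPTrajectory:
    """Reconstruct the COP trajectory from the four corner loads.

    Moment balance over the corners: with total load ``F`` per sample,

    .. math::

        x = \\tfrac{W}{2}\\,\\frac{(f_{tr}+f_{br}) - (f_{tl}+f_{bl})}{F},
        \\qquad
        y = \\tfrac{D}{2}\\,\\frac{(f_{tl}+f_{tr}) - (f_{bl}+f_{br})}{F}.

    Samples whose total load falls below ``min_load_fraction`` of the trial
    median are invalid (stepping on/off, dropouts): leading/trailing invalid
    runs are dropped and interior invalid samples are linearly interpolated
    from their valid neighbours.

    Raises
    ------
    UnrecoverableSignalError
        If no sample (or fewer than two) passes the load threshold.
    """
    if not (0.0 < min_load_fraction < 1.0):
        raise ParameterError(
            f"min_load_fraction must lie in (0, 1), got {min_load_fraction}"
        )
    geom = rec.geometry
    F = rec.forces.sum(axis=1)
    threshold = min_load_fraction * float(np.median(F))
    valid = F > max(threshold, 0.0)
    if valid.sum() < 2:
        raise UnrecoverableSignalError(
            "fewer than 2 samples exceed the minimum-load threshold"
        )

    idx = np.nonzero(valid)[0]
    lo, hi = idx[0], idx[-1] + 1  # drop leading/trailing invalid runs
    t = rec.t[lo:hi]
    f = rec.forces[lo:hi]
    Fw = F[lo:hi]
    ok = valid[lo:hi]

    with np.errstate(divide="ignore", invalid="ignore"):
        x = geom.half_width * ((f[:, 1] + f[:, 3]) - (f[:, 0] + f[:, 2])) / Fw
        y = geom.half_depth * ((f[:, 0] + f[:, 1]) - (f[:, 2] + f[:, 3])) / Fw
    if not ok.all():
        n_bad = int((~ok).sum())
        logger.warning(
            "INTERPOLATED_LOW_LOAD: %d interior sample(s) below %.1f%% of median load",
            n_bad,
            100 * min_load_fraction,
        )
        x[~ok] = np.interp(t[~ok], t[ok], x[ok])
        y[~ok] = np.interp(t[~ok], t[ok], y[ok])

    fs = (t.size - 1) / (t[-1] - t[0])
    return COPTrajectory(fs=fs, x=x, y=y, total_load=Fw, t=t, meta=dict(rec.meta))


def forces_from_cop(
    traj: COPTrajectory,
    load_series: Optional[np.ndarray] = None,
    geometry: BoardGeometry = DEFAULT_GEOMETRY,
) -> RawRecording:
    """Decompose a COP trajectory into a consistent four-corner force set.

    Uses bilinear weighting over the corners, the unique separable
    decomposition: with normalised coordinates ``u = (x + W/2)/W`` and
    ``v = (y + D/2)/D``,

    ``f_tl = F(1-u)v``, ``f_tr = F u v``, ``f_bl = F(1-u)(1-v)``,
    ``f_br = F u (1-v)``,

    so ``compute_cop_series`` recovers the trajectory exactly. Inverse of the
    reconstruction; used by the simulator to materialise raw recordings.
    """
    load = traj.total_load if load_series is None else np.asarray(load_series, float)
    if load.size != traj.n:
        raise ParameterError("load_series length must match the trajectory")
    if np.any(load <= 0):
        raise ParameterError("total load must be strictly positive everywhere")
    inside = geometry.contains(traj.x, traj.y)
    if not inside.all():
        bad = int(np.argmax(~inside))
        raise DomainError(
            f"COP outside the board rectangle at sample {bad}: "
            f"({traj.x[bad]:.2f}, {traj.y[bad]:.2f}) cm"
        )
    u = (traj.x + geometry.half_width) / geometry.width_x
    v = (traj.y + geometry.half_depth) / geometry.depth_y
    f_tl = load * (1 - u) * v
    f_tr = load * u * v
    f_bl = load * (1 - u) * (1 - v)
    f_br = load * u * (1 - v)
    t = traj.t if traj.t is not None else np.arange(traj.n) / traj.fs
    forces = np.column_stack([f_tl, f_tr, f_bl, f_br])
    return RawRecording(t=t, forces=forces, geometry=geometry, meta=dict(traj.meta))
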