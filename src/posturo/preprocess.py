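"""COP signal conditioning: uniform resampling and Butterworth low-pass.

The acquisition chain delivers samples at a nominal 50 Hz with some timestamp
jitter; the analysis pipeline first linearly interpolates onto a uniform grid,
then applies a 4th-order Butterworth low-pass at 12 Hz. Filtering is done on
the COP coordinates (reconstruct -> resample -> filter), and always after
resampling, because the digital filter design assumes uniform sampling.

Two application modes are offered: ``causal`` (a literal single forward pass
of the designed filter) and ``zero_phase`` (forward-backward pass of the same
design, the posturography convention — no phase lag, squared magnitude
response, so the gain at the cutoff is 1/2 instead of 1/sqrt(2)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .board import COPTrajectory
from .errors import FormatError, ParameterError, TooShortError

FILTER_MODES = ("causal", "zero_phase")


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass design parameters.

    order : filter order (default 4)
    cutoff_hz : -3 dB cutoff in Hz (default 12)
    fs_hz : sampling rate the design assumes, Hz (default 50)
    mode : "zero_phase" (default, forward-backward) or "causal"
    """

    order: int = 4
    cutoff_hz: float = 12.0
    fs_hz: float = 50.0
    mode: str = "zero_phase"

    def __post_init__(self) -> None:
        if not (isinstance(self.order, (int, np.integer)) and self.order >= 1):
            raise ParameterError(f"filter order must be an integer >= 1, got {self.order}")
        if not self.fs_hz > 0:
            raise ParameterError(f"fs_hz must be positive, got {self.fs_hz}")
        if not (0 < self.cutoff_hz < self.fs_hz / 2):
            raise ParameterError(
                f"cutoff must lie in (0, Nyquist) = (0, {self.fs_hz / 2} Hz), "
                f"got {self.cutoff_hz} Hz"
            )
        if self.mode not in FILTER_MODES:
            raise ParameterError(f"mode must be one of {FILTER_MODES}, got {self.mode!r}")


def resample_uniform(traj: COPTrajectory, target_fs: float) -> COPTrajectory:
    """Linearly interpolate a trajectory onto a uniform grid at ``target_fs``.

    The grid spans the original time range starting at the first sample. A
    trajectory that is already uniform (no explicit timestamps) at the target
    rate is returned unchanged (a copy).
    """
    if not target_fs > 0:
        raise ParameterError(f"target_fs must be positive, got {target_fs}")
    if traj.n < 2:
        raise TooShortError("resampling needs at least 2 samples")
    if traj.t is None:
        if np.isclose(traj.fs, target_fs, rtol=1e-12):
            return replace(
                traj,
                x=traj.x.copy(),
                y=traj.y.copy(),
                total_load=traj.total_load.copy(),
                meta=dict(traj.meta),
            )
        t = np.arange(traj.n) / traj.fs
    else:
        t = traj.t
        if np.any(np.diff(t) == 0):
            raise FormatError("duplicate timestamps cannot be resampled")

    span = t[-1] - t[0]
    n_out = int(np.floor(span * target_fs + 1e-9)) + 1
    grid = t[0] + np.arange(n_out) / target_fs
    return COPTrajectory(
        fs=target_fs,
        x=np.interp(grid, t, traj.x),
        y=np.interp(grid, t, traj.y),
        total_load=np.interp(grid, t, traj.total_load),
        t=None,
        meta=dict(traj.meta),
    )


def lowpass_filter(traj: COPTrajectory, spec: FilterSpec = FilterSpec()) -> COPTrajectory:
    """Low-pass filter the x and y coordinate series per ``spec``.

    Zero-phase mode runs the designed filter forward and backward with
    odd-reflection padding of length 3x the filter order, suppressing the
    startup transient on short (10 s) trials. DC gain is exactly 1 in both
    modes, so the mean stance position is preserved.
    """
    if not np.isclose(traj.fs, spec.fs_hz, rtol=1e-9):
        raise ParameterError(
            f"trajectory sampling rate {traj.fs} Hz does not match the filter "
            f"design rate {spec.fs_hz} Hz; resample first"
        )
    if traj.t is not None:
        raise ParameterError("trajectory must be uniformly sampled before filtering")
    warmup = 3 * spec.order
    if traj.n <= warmup:
        raise TooShortError(
            f"trajectory of {traj.n} samples is shorter than the filter "
            f"warm-up of {warmup} samples"
        )
    b, a = signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=spec.fs_hz)

    def _apply(sig: np.ndarray) -> np.ndarray:
        if spec.mode == "causal":
            # initialise the filter state at the signal's starting value so a
            # constant input passes through unchanged (no startup transient)
            zi = signal.lfilter_zi(b, a) * sig[0]
            out, _ = signal.lfilter(b, a, sig, zi=zi)
            return out
        return signal.filtfilt(b, a, sig, padtype="odd", padlen=warmup)

    return replace(
        traj,
        x=_apply(traj.x),
        y=_apply(traj.y),
        total_load=traj.total_load.copy(),
        meta=dict(traj.meta),
    )


def preprocess(
    traj: COPTrajectory,
    spec: FilterSpec = FilterSpec(),
    trim_s: float = 0.0,
) -> COPTrajectory:
    """Standard conditioning chain: resample to ``spec.fs_hz``, filter, trim.

    ``trim_s`` seconds are cut from each end *after* filtering (default 0:
    the protocol analyses the full trial).
    """
    if trim_s < 0:
        raise ParameterError(f"trim_s must be >= 0, got {trim_s}")
    out = lowpass_filter(resample_uniform(traj, spec.fs_hz), spec)
    if trim_s > 0:
        k = int(round(trim_s * spec.fs_hz))
        if out.n - 2 * k < 2:
            raise TooShortError("trimming would leave fewer than 2 samples")
        out = replace(
            out,
            x=out.x[k : out.n - k],
            y=out.y[k : out.n - k],
            total_load=out.total_load[k : out.n - k],
        )
    return out
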