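"""Trajectory preprocessing: zero-phase low-pass filtering, linear detrend, resampling.

Tracker trajectories are smoothed with a forward-backward (zero-phase)
Butterworth low-pass filter before event detection; the vertical channel is
additionally detrended so that the stance baseline sits near zero regardless
of how the tracking volume was calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .io_formats import ReferenceEventTable, TrackerSeries


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth design: order 3, cutoff 12 Hz, applied forward-backward."""

    order: int = 3
    cutoff_hz: float = 12.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff frequency must be positive")


def _pad_length(order: int) -> int:
    # odd-reflection padding of 3*(order+1) samples at each end
    return 3 * (order + 1)


def lowpass_zero_phase(signal, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Forward-backward Butterworth low-pass filter (zero phase shift).

    The effective magnitude response is the squared single-pass response, so
    the half-power point of the cascade sits at the design cutoff with
    amplitude ratio 1/2.

    Raises
    ------
    ValueError
        If the cutoff is at or above the Nyquist frequency, or the signal is
        shorter than the edge-padding length requires.
    """
    x = np.asarray(signal, dtype=float)
    nyquist = fs / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    padlen = _pad_length(spec.order)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"signal too short for order-{spec.order} zero-phase filtering: "
            f"need more than {padlen} samples, got {x.shape[-1]}"
        )
    b, a = scipy.signal.butter(spec.order, spec.cutoff_hz / nyquist)
    return scipy.signal.filtfilt(b, a, x, axis=-1, padtype="odd", padlen=padlen)


def detrend_linear(signal) -> np.ndarray:
    """Remove the least-squares straight line from a signal.

    The residual has zero mean and zero best-fit slope; applying the operation
    twice equals applying it once.
    """
    x = np.asarray(signal, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("detrend needs at least 2 samples")
    return scipy.signal.detrend(x, type="linear", axis=-1)


def resample_series(series: TrackerSeries, fs_target: float) -> TrackerSeries:
    """Linearly interpolate a pose stream onto a uniform grid spanning its time range.

    Positions are interpolated componentwise; quaternions are interpolated
    componentwise and renormalized (adequate for the slow orientation changes
    of a foot tracker between neighbouring samples).
    """
    if fs_target <= 0:
        raise ValueError("fs_target must be positive")
    if len(series) == 0:
        return TrackerSeries(series.foot, series.t, series.pos, series.quat, fs_target)
    t0, t1 = series.t[0], series.t[-1]
    n = int(np.floor((t1 - t0) * fs_target + 1e-9)) + 1
    t_new = t0 + np.arange(n) / fs_target
    pos = np.column_stack([np.interp(t_new, series.t, series.pos[:, k]) for k in range(3)])
    quat = np.column_stack([np.interp(t_new, series.t, series.quat[:, k]) for k in range(4)])
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    return TrackerSeries(series.foot, t_new, pos, quat, float(fs_target))


def snap_events_to_grid(
    table: ReferenceEventTable, fs_target: float, t_origin: float = 0.0
) -> ReferenceEventTable:
    """Snap event times to the nearest instant of a uniform ``fs_target`` grid.

    The grid is anchored at ``t_origin``.  Events, not waveforms, are what the
    reference device contributes, so downsampling an event table is a pure
    time quantization.
    """
    if fs_target <= 0:
        raise ValueError("fs_target must be positive")
    df = table.events.copy()
    df["t"] = t_origin + np.round((df["t"].to_numpy(float) - t_origin) * fs_target) / fs_target
    return ReferenceEventTable(events=df, rate_hz=float(fs_target))


def resample_to(obj, fs_target: float):
    """Dispatch: pose streams are interpolated, event tables are grid-snapped."""
    if isinstance(obj, TrackerSeries):
        return resample_series(obj, fs_target)
    if isinstance(obj, ReferenceEventTable):
        return snap_events_to_grid(obj, fs_target)
    raise TypeError(f"cannot resample object of type {type(obj).__name__}")
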