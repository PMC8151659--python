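"""Gait event detection from the vertical tracker trajectory.

During walking the (filtered, detrended) vertical displacement of a foot
tracker traces a double-peaked hump per stride: the trajectory leaves the
stance baseline as the heel lifts, peaks a first time as the foot pushes off
the ground (toe off, TO), dips while the foot swings through, peaks a second
time as the foot reaches the ground again (heel strike, HS), and settles back
to the baseline during the next stance.

The detector therefore:

1. levels the stance baseline robustly: a least-squares detrend is pulled
   toward the swing bumps, leaving the stance floor offset and slightly
   tilted, so the detector fits a line to the lower half of the samples
   (stance is the signal's floor) and refines it once on the samples inside
   the baseline band — after which stance sits at zero;
2. finds "swing excursions" — maximal runs of samples above a band of half
   the peak-prominence floor around the levelled baseline;
3. picks prominent local maxima within each excursion;
4. labels the earlier of exactly two qualifying peaks TO and the later HS.

Excursions with one or more qualifying peaks but not exactly two are
discarded with a warning (a conservative failure mode: a malformed hump
yields no events rather than wrong ones); runs with no qualifying peak at all
are baseline jitter, not excursions, and are ignored silently.  Excursions
touching the ends of the recording (transitional strides before/after the
analyzed bout) are likewise discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .io_formats import EVENT_KINDS, FOOT_SIDES


@dataclass(frozen=True)
class GaitEvent:
    """One detected gait event: kind (HS/TO), foot side, time and sample index."""

    kind: str
    foot: str
    t: float
    idx: int

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.foot not in FOOT_SIDES:
            raise ValueError(f"unknown foot side {self.foot!r}")


@dataclass(frozen=True)
class GaitCycle:
    """One gait cycle of a single foot: HS -> TO -> HS.

    Stance is ``hs_prev``..``to``; swing is ``to``..``hs_cur``.
    """

    foot: str
    hs_prev: GaitEvent
    to: GaitEvent
    hs_cur: GaitEvent

    def __post_init__(self) -> None:
        if not (self.hs_prev.kind == "HS" and self.to.kind == "TO" and self.hs_cur.kind == "HS"):
            raise ValueError("cycle must be (HS, TO, HS)")
        if not (self.hs_prev.foot == self.to.foot == self.hs_cur.foot == self.foot):
            raise ValueError("all cycle events must belong to the same foot")
        if not (self.hs_prev.t < self.to.t < self.hs_cur.t):
            raise ValueError("cycle events must satisfy hs_prev.t < to.t < hs_cur.t")

    @property
    def duration_s(self) -> float:
        return self.hs_cur.t - self.hs_prev.t


@dataclass(frozen=True)
class DetectorParams:
    """Peak-picking thresholds.

    Foot clearance during swing is multi-centimeter, so a 1 cm prominence
    floor rejects sensor jitter while keeping genuine humps; double peaks
    closer than 100 ms are likewise treated as jitter.  Cycle-duration
    bounds of 0.4–2.5 s bracket plausible walking cadences.
    """

    min_prominence: float = 0.01
    min_peak_separation_s: float = 0.10
    min_cycle_s: float = 0.4
    max_cycle_s: float = 2.5

    def __post_init__(self) -> None:
        for name in ("min_prominence", "min_peak_separation_s", "min_cycle_s", "max_cycle_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_cycle_s >= self.max_cycle_s:
            raise ValueError("min_cycle_s must be below max_cycle_s")


def _runs_above(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs (stop exclusive)."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _level_baseline(z: np.ndarray, t: np.ndarray, band: float) -> np.ndarray:
    """Remove the stance-floor line from z: fit on the lower half of samples,
    refine on the samples within ``band`` of the fitted line."""
    mask = z <= np.median(z)
    for _ in range(2):
        coef = np.polyfit(t[mask], z[mask], 1)
        resid = z - np.polyval(coef, t)
        refined = np.abs(resid) <= band
        if refined.sum() < 2:
            break
        mask = refined
    return resid


def detect_events(z, t, foot: str, params: DetectorParams = DetectorParams()) -> list[GaitEvent]:
    """Detect TO and HS events on a detrended, filtered vertical signal.

    Returns time-ordered events alternating TO, HS, TO, HS, ...; the event
    time is the peak sample's time (no sub-sample refinement).
    """
    z = np.asarray(z, dtype=float)
    t = np.asarray(t, dtype=float)
    if z.shape != t.shape:
        raise ValueError("z and t must have the same length")
    if z.size < 3:
        warnings.warn("signal too short to contain gait events", UserWarning, stacklevel=2)
        return []
    fs = 1.0 / float(np.median(np.diff(t)))
    distance = max(1, int(round(params.min_peak_separation_s * fs)))
    band = 0.5 * params.min_prominence
    z = _level_baseline(z, t, band)
    runs = _runs_above(z > band)

    events: list[GaitEvent] = []
    n_discarded = 0
    for a, b in runs:
        if a == 0 or b == z.size:
            continue  # partial excursion at a recording edge
        peaks, _ = scipy.signal.find_peaks(
            z[a:b], prominence=params.min_prominence, distance=distance
        )
        if len(peaks) == 0:
            continue  # baseline jitter, not a swing excursion
        if len(peaks) != 2:
            n_discarded += 1
            continue
        i_to, i_hs = (int(a + p) for p in peaks)
        events.append(GaitEvent("TO", foot, float(t[i_to]), i_to))
        events.append(GaitEvent("HS", foot, float(t[i_hs]), i_hs))

    if n_discarded:
        warnings.warn(
            f"{n_discarded} swing excursion(s) discarded ({foot} foot): "
            "expected exactly two qualifying peaks",
            UserWarning,
            stacklevel=2,
        )
    if not events:
        warnings.warn(f"no gait events detected ({foot} foot)", UserWarning, stacklevel=2)
    return events


def segment_cycles(
    events: list[GaitEvent], params: DetectorParams = DetectorParams()
) -> list[GaitCycle]:
    """Group time-ordered single-foot events into HS -> TO -> HS cycles.

    Every consecutive (HS, TO, HS) triple whose total duration lies within
    ``[min_cycle_s, max_cycle_s]`` becomes one cycle; out-of-bound candidates
    are dropped with a warning.  The first TO of a bout has no preceding HS
    and so opens no cycle.
    """
    cycles: list[GaitCycle] = []
    n_dropped = 0
    for i in range(len(events) - 2):
        a, b, c = events[i], events[i + 1], events[i + 2]
        if (a.kind, b.kind, c.kind) != ("HS", "TO", "HS"):
            continue
        duration = c.t - a.t
        if not (params.min_cycle_s <= duration <= params.max_cycle_s):
            n_dropped += 1
            continue
        cycles.append(GaitCycle(a.foot, a, b, c))
    if n_dropped:
        warnings.warn(
            f"{n_dropped} cycle candidate(s) dropped: duration outside "
            f"[{params.min_cycle_s}, {params.max_cycle_s}] s",
            UserWarning,
            stacklevel=2,
        )
    return cycles


def exclude_out_of_bounds(
    cycles: list[GaitCycle], heel_xy: np.ndarray, bbox: tuple | None
) -> list[GaitCycle]:
    """Keep cycles whose bounding heel strikes both fall inside the walkway.

    ``heel_xy`` is the (n, 2) array of heel XY positions indexed by event
    sample index; ``bbox`` is (x_min, x_max, y_min, y_max) with closed
    boundaries, or None to keep everything (turnarounds happen off the
    walkway, so cycles outside it are excluded from analysis).
    """
    if bbox is None:
        return list(cycles)
    x0, x1, y0, y1 = bbox
    heel_xy = np.asarray(heel_xy, dtype=float)

    def inside(idx: int) -> bool:
        x, y = heel_xy[idx]
        return (x0 <= x <= x1) and (y0 <= y <= y1)

    return [c for c in cycles if inside(c.hs_prev.idx) and inside(c.hs_cur.idx)]
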