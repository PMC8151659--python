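"""Spatiotemporal stride features.

Six per-stride parameters are computed from heel positions at the detected
events, in 2D (the horizontal plane), matching what a pressure walkway can
measure:

* stride length   SL = ||heel(HS_i) - heel(HS_{i-1})||            [m]
* stride time     ST = t(HS_i) - t(HS_{i-1})                      [s]
* stride width    SW = sqrt(d^2 - (SL/2)^2)                       [m]
  where d is the distance from the current same-foot HS heel to the
  contralateral HS heel of the same cycle.  When the contralateral step
  lands near the stride midline this equals the perpendicular distance
  from the contralateral heel to the line through the two same-foot HS
  heels; a negative radicand means the midline assumption is violated and
  the stride is flagged invalid rather than clamped.
* stride velocity SV = SL / ST                                    [m/s]
* stance percent  STC% = 100 * (t_TO - t_HS_prev) / ST            [%]
* swing percent   SWC% = 100 * (t_HS_cur - t_TO) / ST             [%]

STC% + SWC% = 100 by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .event_detection import GaitCycle, GaitEvent

#: tolerance for the stride-width radicand: tiny negative values from
#: floating-point cancellation in the collinear case are treated as zero
_RADICAND_TOL = 1e-12


@dataclass
class StrideFeatures:
    """The six spatiotemporal parameters of one stride (SI units)."""

    foot: str
    t_hs_prev: float
    t_to: float
    t_hs_cur: float
    SL: float
    ST: float
    SW: float
    SV: float
    STC_pct: float
    SWC_pct: float
    valid_SW: bool = True


def stride_length(heel_prev_xy, heel_cur_xy) -> float:
    """Horizontal Euclidean distance between consecutive same-foot HS heels."""
    a = np.asarray(heel_prev_xy, dtype=float)
    b = np.asarray(heel_cur_xy, dtype=float)
    return float(math.hypot(b[0] - a[0], b[1] - a[1]))


def stride_time(t_hs_prev: float, t_hs_cur: float) -> float:
    if t_hs_cur <= t_hs_prev:
        raise ValueError("t_hs_cur must be after t_hs_prev")
    return float(t_hs_cur - t_hs_prev)


def stride_width(same_foot_hs_cur_xy, contra_hs_xy, SL_i: float) -> tuple[float, bool]:
    """Stride width from the current same-foot HS heel and the contralateral HS heel.

    Returns ``(SW, valid)``; ``(nan, False)`` when the radicand
    ``d^2 - (SL/2)^2`` is negative, i.e. the contralateral heel is too close
    to the current heel for the midline geometry to hold.
    """
    if SL_i <= 0:
        raise ValueError("SL_i must be positive")
    a = np.asarray(same_foot_hs_cur_xy, dtype=float)
    b = np.asarray(contra_hs_xy, dtype=float)
    d2 = float((a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2)
    radicand = d2 - (SL_i / 2.0) ** 2
    if radicand < -_RADICAND_TOL:
        return float("nan"), False
    return math.sqrt(max(radicand, 0.0)), True


def stride_velocity(SL: float, ST: float) -> float:
    if ST <= 0:
        raise ValueError("ST must be positive")
    return float(SL) / float(ST)


def phase_percentages(cycle: GaitCycle) -> tuple[float, float]:
    """Stance and swing as percentages of the gait cycle; they sum to 100."""
    stance = cycle.to.t - cycle.hs_prev.t
    swing = cycle.hs_cur.t - cycle.to.t
    total = cycle.hs_cur.t - cycle.hs_prev.t
    return 100.0 * stance / total, 100.0 * swing / total


def _contralateral_hs_in(cycle: GaitCycle, contra_events: list[GaitEvent]) -> GaitEvent | None:
    """Latest contralateral HS strictly inside the cycle's (hs_prev.t, hs_cur.t)."""
    best = None
    for e in contra_events:
        if e.kind == "HS" and cycle.hs_prev.t < e.t < cycle.hs_cur.t:
            best = e
    return best


def compute_stride_features(
    cycles_left: list[GaitCycle],
    cycles_right: list[GaitCycle],
    events_left: list[GaitEvent],
    events_right: list[GaitEvent],
    heel_xy_left: np.ndarray,
    heel_xy_right: np.ndarray,
) -> list[StrideFeatures]:
    """Compute one :class:`StrideFeatures` per cycle, both feet, time-ordered.

    ``heel_xy_left``/``heel_xy_right`` are (n, 2) arrays of heel horizontal
    positions indexed by event sample index (heel position at an event is the
    transformed heel at that event's sample; no interpolation).  Stride width
    uses the contralateral HS whose time falls inside the cycle; if none
    exists (e.g. a single-foot trial) SW is flagged invalid for that stride.
    """
    heel = {"left": np.asarray(heel_xy_left, dtype=float),
            "right": np.asarray(heel_xy_right, dtype=float)}
    contra_events = {"left": events_right, "right": events_left}
    contra_side = {"left": "right", "right": "left"}

    out: list[StrideFeatures] = []
    for cycles in (cycles_left, cycles_right):
        for cyc in cycles:
            foot = cyc.foot
            xy = heel[foot]
            p_prev = xy[cyc.hs_prev.idx]
            p_cur = xy[cyc.hs_cur.idx]
            SL = stride_length(p_prev, p_cur)
            ST = stride_time(cyc.hs_prev.t, cyc.hs_cur.t)
            SV = stride_velocity(SL, ST)
            stc, swc = phase_percentages(cyc)

            contra = _contralateral_hs_in(cyc, contra_events[foot])
            if contra is None or SL <= 0:
                SW, valid = float("nan"), False
            else:
                contra_xy = heel[contra_side[foot]][contra.idx]
                SW, valid = stride_width(p_cur, contra_xy, SL)

            out.append(StrideFeatures(
                foot=foot,
                t_hs_prev=cyc.hs_prev.t, t_to=cyc.to.t, t_hs_cur=cyc.hs_cur.t,
                SL=SL, ST=ST, SW=SW, SV=SV,
                STC_pct=stc, SWC_pct=swc, valid_SW=valid,
            ))
    out.sort(key=lambda f: f.t_hs_cur)
    return out
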