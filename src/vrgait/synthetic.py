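"""Synthetic paired VR-tracker / reference-walkway gait trials with known truth.

The generator emulates the two data streams of a walkway-validation session
so every pipeline stage can be exercised without hardware:

* a "VR" pose stream per foot at ``fs_vr`` (default 90 Hz): the heel follows
  an analytic straight-line walk; the tracker pose is obtained by inverting
  the heel transformation with a known tracker-frame offset, and white
  Gaussian noise is optionally added to the tracker positions;
* a "walkway" event table at ``fs_ref`` (default 120 Hz): the exact event
  times snapped to the reference grid and shifted by a known clock offset.

Vertical kinematics.  Each stride produces one airborne excursion of the
vertical channel with the double-peaked morphology of a foot tracker: zero
at both ends, a sharp first peak at toe off, a dip during mid-swing that
stays well above the stance baseline, a sharp second peak at heel strike.
The curve is built from C^1 pieces whose analytic extrema are exact: a
flat-topped plateau (raised-cosine edges) carrying the mid-swing clearance
floor, plus two symmetric raised-cosine bumps centered on the peaks.  The
plateau is flat and the other bump zero at each peak, so peak positions and
heights are exact, and the signal is locally symmetric around every peak —
zero-phase filtering cannot bias the event times.  The excursion is anchored
so the two peaks fall exactly on the toe-off and heel-strike instants: the
trajectory starts rising shortly before TO (heel-off) and settles shortly
after HS (foot-flat).  With ``peak1_frac``/``peak2_frac`` the peak positions
as fractions of the excursion, the excursion length is
``swing / (peak2_frac - peak1_frac)``.

Ground truth.  True event times, per-stride features and a walkway-style
feature table (recomputed from the grid-snapped reference event times, as the
real device would) are returned alongside the raw streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .features import StrideFeatures
from .io_formats import ReferenceEventTable, TrackerSeries

#: mid-swing clearance floor as a fraction of the lower peak height
_DIP_FRACTION = 0.35


@dataclass
class SyntheticGaitSpec:
    """Study conditions for one synthetic walking trial.

    Defaults describe an unremarkable healthy adult walking at a comfortable
    pace: 1.25 m strides of 1.1 s (stride velocity ~1.14 m/s), 10 cm stride
    width, 62% stance fraction, foot-clearance peaks of 12 cm (push-off) and
    8 cm (terminal swing), sampled at 90 Hz (tracker) and 120 Hz (walkway).
    """

    n_strides: int = 20
    SL_true: float = 1.25
    ST_true: float = 1.1
    SW_true: float = 0.10
    stance_fraction: float = 0.62
    clearance_peak1: float = 0.12
    clearance_peak2: float = 0.08
    peak1_frac: float = 0.2
    peak2_frac: float = 0.8
    noise_sd_pos: float = 0.0
    fs_vr: float = 90.0
    fs_ref: float = 120.0
    clock_offset_s: float = 0.0
    heel_offset: tuple = (-0.15, 0.0, -0.08)
    yaw_deg: float = 0.0
    walkway_length_m: float = 6.10
    seed: int = 0
    #: intervals (foot, t_start, t_end) whose tracker samples are deleted, to
    #: emulate tracking dropout and exercise false-negative paths
    dropout_intervals: tuple = ()

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if not (0.0 < self.stance_fraction < 1.0):
            raise ValueError("stance_fraction must be in (0, 1)")
        if not (0.0 < self.peak1_frac < self.peak2_frac < 1.0):
            raise ValueError("need 0 < peak1_frac < peak2_frac < 1")
        if min(self.fs_vr, self.fs_ref) <= 0:
            raise ValueError("sampling rates must be positive")
        if min(self.clearance_peak1, self.clearance_peak2) <= 0:
            raise ValueError("clearance peaks must be positive")
        if min(self.SL_true, self.ST_true, self.SW_true) <= 0:
            raise ValueError("SL_true, ST_true and SW_true must be positive")
        if self.noise_sd_pos < 0:
            raise ValueError("noise_sd_pos must be non-negative")
        # the excursion extends peak1_frac*L before TO and (1-peak2_frac)*L
        # after HS; consecutive excursions of one foot must not overlap
        L = self.excursion_s
        lead = self.peak1_frac * L
        lag = (1.0 - self.peak2_frac) * L
        if lead + lag >= self.stance_fraction * self.ST_true:
            raise ValueError(
                "excursion shoulders overlap the stance phase; bring peak1_frac/"
                "peak2_frac closer to 0/1 or increase stance_fraction"
            )

    @property
    def swing_s(self) -> float:
        return (1.0 - self.stance_fraction) * self.ST_true

    @property
    def excursion_s(self) -> float:
        return self.swing_s / (self.peak2_frac - self.peak1_frac)


def _raised_cosine(x, center, half_width, height):
    """Symmetric raised-cosine bump: C^1, zero value and slope at its edges."""
    u = (np.asarray(x, dtype=float) - center) / half_width
    return np.where(np.abs(u) < 1.0, 0.5 * height * (1.0 + np.cos(np.pi * u)), 0.0)


def _plateau(x, lo, hi, half_left, half_right, height):
    """Flat-topped plateau with raised-cosine edges: C^1, flat on [lo, hi]."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, float(height))
    left = x < lo
    out[left] = _raised_cosine(x[left], lo, half_left, height)
    right = x > hi
    out[right] = _raised_cosine(x[right], hi, half_right, height)
    return out


def vertical_profile(phase, spec: SyntheticGaitSpec) -> np.ndarray:
    """Vertical clearance (m) at excursion phase(s) in [0, 1].

    Zero at phase 0 and 1, with exactly two strict interior maxima of heights
    ``clearance_peak1`` at ``peak1_frac`` and ``clearance_peak2`` at
    ``peak2_frac``, separated by a dip at a fraction of the lower peak.  The
    plateau carrying the mid-swing clearance floor is flat at each peak and
    each bump vanishes (with zero slope) at the other bump's peak, so peak
    positions and heights are analytically exact.
    """
    x0 = np.asarray(phase, dtype=float)
    if np.any(x0 < 0.0) or np.any(x0 > 1.0):
        raise ValueError("phase must lie in [0, 1]")
    x = np.atleast_1d(x0)
    p1, p2 = spec.peak1_frac, spec.peak2_frac
    h1, h2 = spec.clearance_peak1, spec.clearance_peak2
    h_dip = _DIP_FRACTION * min(h1, h2)
    w = min(p1, 1.0 - p2, p2 - p1)  # bumps vanish at phase 0/1 and at each other
    z = _plateau(x, p1, p2, p1, 1.0 - p2, h_dip)
    z = z + _raised_cosine(x, p1, w, h1 - h_dip)
    z = z + _raised_cosine(x, p2, w, h2 - h_dip)
    return z if x0.shape else float(z[0])


@dataclass
class _FootTimeline:
    hs: np.ndarray        # HS_i, i = 0..n-1
    to: np.ndarray        # TO_i (precedes HS_i within stride i)
    exc_start: np.ndarray
    exc_len: float
    x_at_hs: np.ndarray   # heel X at each HS
    y: float              # constant heel Y of this foot


def _timelines(spec: SyntheticGaitSpec, t_margin: float) -> dict[str, _FootTimeline]:
    L = spec.excursion_s
    swing = spec.swing_s
    lead = spec.peak1_frac * L
    first_hs_left = t_margin + lead + swing
    out = {}
    for foot, shift, x0, y in (
        ("left", 0.0, 0.0, +spec.SW_true / 2.0),
        ("right", spec.ST_true / 2.0, spec.SL_true / 2.0, -spec.SW_true / 2.0),
    ):
        hs = first_hs_left + shift + spec.ST_true * np.arange(spec.n_strides)
        to = hs - swing
        exc_start = to - lead
        x_at_hs = x0 + spec.SL_true * np.arange(spec.n_strides)
        out[foot] = _FootTimeline(hs, to, exc_start, L, x_at_hs, y)
    return out


@dataclass(eq=False)
class SyntheticTrial:
    """One simulated walking trial: raw streams plus ground truth."""

    spec: SyntheticGaitSpec
    left: TrackerSeries
    right: TrackerSeries
    reference: ReferenceEventTable
    truth_events: pd.DataFrame          # columns kind, foot, t (exact times)
    truth_features: list[StrideFeatures]
    ref_features: list[StrideFeatures]  # walkway-style, from snapped times
    heel_true: dict                     # foot -> (n, 3) noiseless heel positions


def _heel_kinematics(t: np.ndarray, tl: _FootTimeline, spec: SyntheticGaitSpec):
    """Noiseless heel trajectory of one foot on the time grid ``t``."""
    x = np.full(t.shape, tl.x_at_hs[0] - spec.SL_true)
    z = np.zeros_like(t)
    for i in range(spec.n_strides):
        s = tl.exc_start[i]
        in_exc = (t >= s) & (t <= s + tl.exc_len)
        z[in_exc] = vertical_profile((t[in_exc] - s) / tl.exc_len, spec)
        # the heel advances one stride length between TO and HS with a
        # cosine ease (zero velocity at both ends, so the position at the
        # detected HS sample is insensitive to +-1 sample timing error)
        x_prev = tl.x_at_hs[i] - spec.SL_true
        u = np.clip((t - tl.to[i]) / (tl.hs[i] - tl.to[i]), 0.0, 1.0)
        seg = (t >= tl.to[i]) & (t < tl.hs[i])
        x[seg] = x_prev + spec.SL_true * 0.5 * (1.0 - np.cos(np.pi * u[seg]))
        x[t >= tl.hs[i]] = tl.x_at_hs[i]
    y = np.full(t.shape, tl.y)
    return np.column_stack([x, y, z])


def simulate_trial(spec: SyntheticGaitSpec) -> SyntheticTrial:
    """Generate one paired VR/walkway trial with exact ground truth.

    Feet alternate with a 50% cycle phase shift (symmetric gait); the right
    foot's heel strikes land midway between consecutive left strikes, both in
    time and along the walking direction, so the true stride width equals
    ``SW_true`` for every stride.
    """
    rng = np.random.default_rng(spec.seed)
    t_margin = 0.3
    tls = _timelines(spec, t_margin)
    t_end = max(tl.exc_start[-1] + tl.exc_len for tl in tls.values()) + t_margin
    n = int(np.floor(t_end * spec.fs_vr)) + 1
    t = np.arange(n) / spec.fs_vr

    yaw = np.deg2rad(spec.yaw_deg)
    quat1 = np.array([np.cos(yaw / 2.0), 0.0, 0.0, np.sin(yaw / 2.0)])
    rot = Rotation.from_quat(quat1, scalar_first=True)
    offset_world = rot.apply(np.asarray(spec.heel_offset, dtype=float))

    series = {}
    heel_true = {}
    for foot, tl in tls.items():
        heel = _heel_kinematics(t, tl, spec)
        heel_true[foot] = heel
        tracker = heel - offset_world  # invert heel = tracker + R @ offset
        if spec.noise_sd_pos > 0:
            tracker = tracker + rng.normal(0.0, spec.noise_sd_pos, tracker.shape)
        keep = np.ones(n, dtype=bool)
        for d_foot, d0, d1 in spec.dropout_intervals:
            if d_foot == foot:
                keep &= ~((t >= d0) & (t <= d1))
        series[foot] = TrackerSeries(
            foot=foot,
            t=t[keep],
            pos=tracker[keep],
            quat=np.tile(quat1, (int(keep.sum()), 1)),
            rate_hz=spec.fs_vr,
        )

    # exact truth events
    rows = []
    for foot, tl in tls.items():
        for i in range(spec.n_strides):
            rows.append({"kind": "TO", "foot": foot, "t": float(tl.to[i])})
            rows.append({"kind": "HS", "foot": foot, "t": float(tl.hs[i])})
    truth_events = (
        pd.DataFrame(rows, columns=["kind", "foot", "t"])
        .sort_values(["foot", "t"], kind="stable")
        .reset_index(drop=True)
    )

    # reference stream: truth snapped to the walkway grid, then clock-shifted
    ref = truth_events.copy()
    ref["t"] = np.round(ref["t"].to_numpy() * spec.fs_ref) / spec.fs_ref + spec.clock_offset_s
    reference = ReferenceEventTable(events=ref, rate_hz=spec.fs_ref)

    truth_features = _truth_features(spec, tls)
    ref_features = _walkway_features(spec, tls)

    return SyntheticTrial(
        spec=spec, left=series["left"], right=series["right"], reference=reference,
        truth_events=truth_events, truth_features=truth_features,
        ref_features=ref_features, heel_true=heel_true,
    )


def _truth_features(spec: SyntheticGaitSpec, tls) -> list[StrideFeatures]:
    out = []
    for foot, tl in tls.items():
        for i in range(1, spec.n_strides):
            out.append(StrideFeatures(
                foot=foot,
                t_hs_prev=float(tl.hs[i - 1]), t_to=float(tl.to[i]),
                t_hs_cur=float(tl.hs[i]),
                SL=spec.SL_true, ST=spec.ST_true, SW=spec.SW_true,
                SV=spec.SL_true / spec.ST_true,
                STC_pct=100.0 * spec.stance_fraction,
                SWC_pct=100.0 * (1.0 - spec.stance_fraction),
                valid_SW=True,
            ))
    out.sort(key=lambda f: f.t_hs_cur)
    return out


def _walkway_features(spec: SyntheticGaitSpec, tls) -> list[StrideFeatures]:
    """Features as the reference device would report them: temporal values from
    its own grid-snapped event times (on the reference clock), spatial values
    from the exact footfall geometry."""

    def snap(x):
        return np.round(np.asarray(x) * spec.fs_ref) / spec.fs_ref + spec.clock_offset_s

    out = []
    for foot, tl in tls.items():
        hs = snap(tl.hs)
        to = snap(tl.to)
        for i in range(1, spec.n_strides):
            st = float(hs[i] - hs[i - 1])
            stance = float(to[i] - hs[i - 1])
            out.append(StrideFeatures(
                foot=foot,
                t_hs_prev=float(hs[i - 1]), t_to=float(to[i]), t_hs_cur=float(hs[i]),
                SL=spec.SL_true, ST=st, SW=spec.SW_true,
                SV=spec.SL_true / st,
                STC_pct=100.0 * stance / st,
                SWC_pct=100.0 * (st - stance) / st,
                valid_SW=True,
            ))
    out.sort(key=lambda f: f.t_hs_cur)
    return out
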