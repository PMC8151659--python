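"""File formats and run configuration.

All on-disk interchange is plain CSV/YAML/JSON:

* tracker logs  -- one row per pose sample: ``t, x, y, z, qw, qx, qy, qz``
* event tables  -- one row per gait event: ``kind, foot, t`` (reference) or
  ``kind, foot, t, idx`` (detected)
* feature tables -- one row per stride (see :data:`FEATURE_COLUMNS`)
* validation reports -- JSON

Internal units are SI (meters, seconds).  Axes follow the lab convention:
X anteroposterior (forward-positive), Y mediolateral (left-positive),
Z vertical (up-positive).  Quaternions are scalar-first and rotate vectors
from the tracker frame into the world frame.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

FOOT_SIDES = ("left", "right")
EVENT_KINDS = ("HS", "TO")

TRACKER_COLUMNS = ("t", "x", "y", "z", "qw", "qx", "qy", "qz")
REFERENCE_COLUMNS = ("kind", "foot", "t")
EVENT_CSV_COLUMNS = ("kind", "foot", "t", "idx")
FEATURE_COLUMNS = (
    "foot", "t_hs_prev", "t_to", "t_hs_cur",
    "SL_m", "ST_s", "SW_m", "SV_mps", "STC_pct", "SWC_pct",
)

#: maximum allowed deviation of a stored quaternion norm from 1
QUAT_NORM_TOL = 1e-6


class FormatError(ValueError):
    """The file does not conform to the expected layout (missing column, bad token)."""


class DataError(ValueError):
    """The file parses but its contents violate a data invariant."""


# ---------------------------------------------------------------------------
# tracker pose streams
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class TrackerSeries:
    """Timestamped world-frame pose stream of one foot tracker.

    Parameters
    ----------
    foot : {"left", "right"}
    t : (n,) array
        Sample times in seconds, strictly increasing.
    pos : (n, 3) array
        World positions in meters (X forward, Y left, Z up).
    quat : (n, 4) array
        Unit quaternions, scalar-first, world-from-tracker.
    rate_hz : float
        Nominal sampling frequency.
    """

    foot: str
    t: np.ndarray
    pos: np.ndarray
    quat: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        if self.foot not in FOOT_SIDES:
            raise DataError(f"unknown foot side {self.foot!r}; expected one of {FOOT_SIDES}")
        self.t = np.asarray(self.t, dtype=float).reshape(-1)
        self.pos = np.asarray(self.pos, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        n = self.t.size
        if self.pos.shape != (n, 3):
            raise DataError(f"pos shape {self.pos.shape} does not match {n} timestamps")
        if self.quat.shape != (n, 4):
            raise DataError(f"quat shape {self.quat.shape} does not match {n} timestamps")
        if n > 1:
            dt = np.diff(self.t)
            bad = np.flatnonzero(dt <= 0)
            if bad.size:
                raise DataError(f"non-increasing timestamp at index {bad[0] + 1}")
        if n:
            norms = np.linalg.norm(self.quat, axis=1)
            off = np.flatnonzero(np.abs(norms - 1.0) > QUAT_NORM_TOL)
            if off.size:
                raise DataError(
                    f"non-unit quaternion at index {off[0]} (norm {norms[off[0]]:.9f})"
                )

    def __len__(self) -> int:
        return self.t.size


def read_tracker_log(path, foot: str) -> TrackerSeries:
    """Read a tracker pose CSV into a validated :class:`TrackerSeries`.

    ``rate_hz`` is estimated as ``1 / median(diff(t))``.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) < 2:
        raise DataError(f"{path}: a tracker log needs at least 2 samples, got {len(df)}")
    t = df["t"].to_numpy(float)
    pos = df[["x", "y", "z"]].to_numpy(float)
    quat = df[["qw", "qx", "qy", "qz"]].to_numpy(float)
    rate_hz = 1.0 / float(np.median(np.diff(t)))
    return TrackerSeries(foot=foot, t=t, pos=pos, quat=quat, rate_hz=rate_hz)


def write_tracker_log(series: TrackerSeries, path) -> None:
    df = pd.DataFrame(
        np.column_stack([series.t, series.pos, series.quat]),
        columns=list(TRACKER_COLUMNS),
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class ReferenceEventTable:
    """Reference (walkway) gait events: rows of (kind, foot, t), sorted by (foot, t).

    Per-foot event times must be strictly increasing.  Per-foot kinds are
    expected to alternate HS/TO; a violation is reported as a warning and the
    rows are kept, because real walkway exports can drop events.
    """

    events: pd.DataFrame
    rate_hz: float | None = None

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.events)
        missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"event table missing column(s) {', '.join(missing)}")
        df = df[list(REFERENCE_COLUMNS)].copy()
        bad_kind = ~df["kind"].isin(EVENT_KINDS)
        if bad_kind.any():
            i = int(np.flatnonzero(bad_kind.to_numpy())[0])
            raise FormatError(f"unknown event kind {df['kind'].iloc[i]!r} in row {i}")
        bad_foot = ~df["foot"].isin(FOOT_SIDES)
        if bad_foot.any():
            i = int(np.flatnonzero(bad_foot.to_numpy())[0])
            raise FormatError(f"unknown foot side {df['foot'].iloc[i]!r} in row {i}")
        df["t"] = df["t"].astype(float)
        df = df.sort_values(["foot", "t"], kind="stable").reset_index(drop=True)
        for foot in FOOT_SIDES:
            sub = df[df["foot"] == foot]
            tt = sub["t"].to_numpy()
            if tt.size > 1 and np.any(np.diff(tt) <= 0):
                i = int(np.flatnonzero(np.diff(tt) <= 0)[0])
                raise DataError(
                    f"{foot} event times not strictly increasing at t={tt[i + 1]!r}"
                )
            kinds = sub["kind"].to_numpy()
            rep = np.flatnonzero(kinds[1:] == kinds[:-1])
            if rep.size:
                warnings.warn(
                    f"HS/TO alternation violated for {foot} foot near t={tt[rep[0] + 1]:.3f}s "
                    f"({rep.size} violation(s)); rows kept",
                    UserWarning,
                    stacklevel=2,
                )
        self.events = df

    def __len__(self) -> int:
        return len(self.events)

    def times(self, foot: str, kind: str) -> np.ndarray:
        sel = (self.events["foot"] == foot) & (self.events["kind"] == kind)
        return self.events.loc[sel, "t"].to_numpy(float)


def read_reference_events(path, rate_hz: float | None = None) -> ReferenceEventTable:
    df = pd.read_csv(path)
    return ReferenceEventTable(events=df, rate_hz=rate_hz)


def write_reference_events(table: ReferenceEventTable, path) -> None:
    table.events.to_csv(path, index=False)


def write_events(events, path) -> None:
    """Write detected events (objects with kind/foot/t/idx) as CSV."""
    rows = [
        {"kind": e.kind, "foot": e.foot, "t": e.t, "idx": e.idx} for e in events
    ]
    pd.DataFrame(rows, columns=list(EVENT_CSV_COLUMNS)).to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


# ---------------------------------------------------------------------------
# stride feature tables
# ---------------------------------------------------------------------------

_FEATURE_ATTRS = ("foot", "t_hs_prev", "t_to", "t_hs_cur",
                  "SL", "ST", "SW", "SV", "STC_pct", "SWC_pct")


def write_features(features, path) -> None:
    """Write per-stride features as CSV (one row per stride, SI units).

    ``features`` is an iterable of objects exposing the attributes in
    ``_FEATURE_ATTRS`` (e.g. :class:`vrgait.features.StrideFeatures`), or an
    already-shaped DataFrame with :data:`FEATURE_COLUMNS`.
    """
    if isinstance(features, pd.DataFrame):
        df = features[list(FEATURE_COLUMNS)]
    else:
        rows = []
        for f in features:
            vals = [getattr(f, a) for a in _FEATURE_ATTRS]
            rows.append(dict(zip(FEATURE_COLUMNS, vals)))
        df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    df.to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(report, path) -> None:
    """Serialize a validation report (or any dict-convertible object) to JSON."""
    obj = report.to_dict() if hasattr(report, "to_dict") else report
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline configuration.

    Attributes
    ----------
    filter_order, filter_cutoff_hz :
        Low-pass Butterworth design applied forward-backward to tracker
        trajectories (defaults: order 3, 12 Hz).
    match_tolerance_s :
        Event-matching window for validation; default 3 samples at 90 Hz
        (33.3 ms).
    outlier_k :
        Offsets further than ``outlier_k`` scaled-MADs from the median are
        rejected before offset statistics (default 3.5).
    heel_offsets :
        Shoe-size label -> tracker-frame [ox, oy, oz] heel offset in meters.
    walkway_bbox :
        (x_min, x_max, y_min, y_max) in meters, or None to keep all cycles.
    sync_offset_s :
        Known clock offset such that ``t_vr = t_reference - sync_offset_s``.
    """

    filter_order: int = 3
    filter_cutoff_hz: float = 12.0
    match_tolerance_s: float = 3.0 / 90.0
    outlier_k: float = 3.5
    heel_offsets: dict = field(default_factory=dict)
    walkway_bbox: tuple | None = None
    sync_offset_s: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.filter_cutoff_hz <= 0:
            raise ValueError("filter_cutoff_hz must be positive")
        if self.match_tolerance_s <= 0:
            raise ValueError("match_tolerance_s must be positive")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be positive")
        if self.walkway_bbox is not None:
            x0, x1, y0, y1 = self.walkway_bbox
            if not (x0 < x1 and y0 < y1):
                raise ValueError("walkway_bbox must satisfy x_min < x_max and y_min < y_max")
            self.walkway_bbox = (float(x0), float(x1), float(y0), float(y1))
        self.heel_offsets = {
            str(k): tuple(float(v) for v in vec) for k, vec in self.heel_offsets.items()
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
        if "walkway_bbox" in raw and raw["walkway_bbox"] is not None:
            raw["walkway_bbox"] = tuple(raw["walkway_bbox"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        obj = dataclasses.asdict(self)
        if obj["walkway_bbox"] is not None:
            obj["walkway_bbox"] = list(obj["walkway_bbox"])
        obj["heel_offsets"] = {k: list(v) for k, v in obj["heel_offsets"].items()}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(obj, fh, sort_keys=False)
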