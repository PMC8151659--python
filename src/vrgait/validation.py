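"""Agreement between detected gait events/features and a reference stream.

The detector is scored against a reference system (an instrumented walkway)
by one-to-one temporal matching within a tolerance window (default 3 samples
at 90 Hz = 33.3 ms), from which follow:

* sensitivity = 100 * TP / (TP + FN), where TP are reference events recovered
  by the detector and FN reference events it missed;
* signed time-offset statistics (mean, SD, absolute mean, RMSE, in ms) after
  robust outlier rejection: offsets further than k (default 3.5) scaled MADs
  from the median are removed (scaled MAD = 1.4826 * MAD, the
  normal-consistent convention);
* Bland-Altman limits of agreement, mean +/- 1.96 SD;
* per-feature agreement over strides paired through their matched heel
  strikes: mean offset, absolute error, RMSE, Pearson r, limits of agreement.

False positives (detected events with no reference within tolerance) are
counted and reported but do not enter sensitivity.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .io_formats import EVENT_KINDS, FOOT_SIDES, ReferenceEventTable, RunConfig

#: scale factor making the MAD a consistent estimator of the SD under normality
MAD_SCALE = 1.4826

#: per-feature report units: attribute -> (unit label, SI-to-report factor)
FEATURE_UNITS = {
    "SL": ("cm", 100.0),
    "ST": ("ms", 1000.0),
    "SW": ("cm", 100.0),
    "SV": ("cm/s", 100.0),
    "STC_pct": ("%", 1.0),
}


def matching_window_s(n_samples: int = 3, fs_hz: float = 90.0) -> float:
    """Default event-matching tolerance: ``n_samples`` periods at ``fs_hz``."""
    if n_samples <= 0 or fs_hz <= 0:
        raise ValueError("n_samples and fs_hz must be positive")
    return n_samples / fs_hz


# ---------------------------------------------------------------------------
# event matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventMatch:
    """A detected/reference event pair with their signed time offset (s)."""

    detected: object
    reference: object
    offset_s: float


@dataclass
class MatchResult:
    matches: list[EventMatch]
    TP: int
    FN: int
    FP: int

    @property
    def offsets_s(self) -> np.ndarray:
        return np.array([m.offset_s for m in self.matches], dtype=float)


def _times(seq) -> np.ndarray:
    return np.array([getattr(e, "t", e) for e in seq], dtype=float)


def match_events(detected, reference, tol_s: float) -> MatchResult:
    """Greedy one-to-one matching of two time-ordered event streams.

    Candidate (detected, reference) pairs with ``|dt| <= tol_s`` are taken in
    order of ascending ``|dt|`` (ties broken deterministically by earlier
    reference, then earlier detected event); each event participates in at
    most one match.  Unmatched reference events are FN, unmatched detected
    events FP.  Both inputs must belong to one (foot, kind) stream.
    """
    if tol_s <= 0:
        raise ValueError("tol_s must be positive")
    dt = _times(detected)
    rt = _times(reference)
    pairs = []
    for i, td in enumerate(dt):
        for j, tr in enumerate(rt):
            delta = td - tr
            if abs(delta) <= tol_s:
                pairs.append((abs(delta), j, i, delta))
    pairs.sort()
    used_d: set[int] = set()
    used_r: set[int] = set()
    matches: list[EventMatch] = []
    for _, j, i, delta in pairs:
        if i in used_d or j in used_r:
            continue
        used_d.add(i)
        used_r.add(j)
        matches.append(EventMatch(detected[i], reference[j], float(delta)))
    matches.sort(key=lambda m: getattr(m.detected, "t", m.detected))
    return MatchResult(
        matches=matches,
        TP=len(matches),
        FN=len(rt) - len(matches),
        FP=len(dt) - len(matches),
    )


def sensitivity(result: MatchResult) -> float:
    """Percentage of reference events recovered: 100 * TP / (TP + FN)."""
    denom = result.TP + result.FN
    if denom == 0:
        raise ValueError("sensitivity undefined: no reference events")
    return 100.0 * result.TP / denom


# ---------------------------------------------------------------------------
# robust outlier rejection and offset statistics
# ---------------------------------------------------------------------------

def mad_outlier_mask(values, k: float = 3.5) -> np.ndarray:
    """True where a value lies further than ``k`` scaled MADs from the median.

    With a zero MAD (at least half the values identical) any value different
    from the median is flagged.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for MAD outlier detection")
    med = np.median(x)
    absdev = np.abs(x - med)
    scaled_mad = MAD_SCALE * np.median(absdev)
    if scaled_mad == 0.0:
        return x != med
    return absdev > k * scaled_mad


@dataclass
class OffsetStats:
    """Summary of signed time offsets, reported in milliseconds."""

    mean_ms: float
    sd_ms: float
    abs_mean_ms: float
    abs_sd_ms: float
    rmse_ms: float
    n: int


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def offset_statistics(offsets_s, mask=None) -> OffsetStats:
    """Mean/SD, absolute mean/SD and RMSE of offsets (ms), over unmasked values.

    SD uses the n-1 denominator; RMSE is the root of the mean squared offset.
    """
    x = np.asarray(offsets_s, dtype=float)
    if mask is not None:
        x = x[~np.asarray(mask, dtype=bool)]
    if x.size == 0:
        raise ValueError("no unmasked offsets to summarize")
    ax = np.abs(x)
    return OffsetStats(
        mean_ms=float(np.mean(x)) * 1e3,
        sd_ms=_sd(x) * 1e3,
        abs_mean_ms=float(np.mean(ax)) * 1e3,
        abs_sd_ms=_sd(ax) * 1e3,
        rmse_ms=float(np.sqrt(np.mean(x ** 2))) * 1e3,
        n=int(x.size),
    )


def limits_of_agreement(errors) -> tuple[float, float]:
    """Bland-Altman 95% band: (mean - 1.96 SD, mean + 1.96 SD), SD with n-1."""
    x = np.asarray(errors, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 errors for limits of agreement")
    m, s = float(np.mean(x)), _sd(x)
    return m - 1.96 * s, m + 1.96 * s


# ---------------------------------------------------------------------------
# event-stream validation
# ---------------------------------------------------------------------------

@dataclass
class EventValidation:
    """Agreement summary for one event kind (offsets in ms, pooled over feet)."""

    kind: str
    tp: int
    fn: int
    fp: int
    sensitivity_pct: float
    n_outliers: int
    outlier_pct: float
    stats: OffsetStats | None
    loa_ms: tuple[float, float] | None


def validate_events(
    detected_events, reference: ReferenceEventTable, config: RunConfig
) -> dict[str, EventValidation]:
    """Match detected events to the reference table, per (foot, kind) stream.

    Reference times are first brought onto the detector clock by subtracting
    ``config.sync_offset_s``.  Offsets are pooled per kind across feet;
    MAD outlier rejection (k = ``config.outlier_k``) is applied to the pooled
    offsets before statistics (and needs at least 3 matches to engage).
    """
    out: dict[str, EventValidation] = {}
    for kind in EVENT_KINDS:
        tp = fn = fp = 0
        offsets: list[float] = []
        for foot in FOOT_SIDES:
            det = [e for e in detected_events if e.foot == foot and e.kind == kind]
            ref_t = reference.times(foot, kind) - config.sync_offset_s
            if len(det) == 0 and ref_t.size == 0:
                continue
            res = match_events(det, list(ref_t), config.match_tolerance_s)
            tp += res.TP
            fn += res.FN
            fp += res.FP
            offsets.extend(res.offsets_s)

        x = np.asarray(offsets, dtype=float)
        if x.size >= 3:
            mask = mad_outlier_mask(x, k=config.outlier_k)
        else:
            mask = np.zeros(x.size, dtype=bool)
        n_out = int(mask.sum())
        stats = offset_statistics(x, mask) if x.size and n_out < x.size else None
        kept = x[~mask]
        loa = None
        if kept.size >= 2:
            lo, hi = limits_of_agreement(kept * 1e3)
            loa = (lo, hi)
        sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
        out[kind] = EventValidation(
            kind=kind, tp=tp, fn=fn, fp=fp, sensitivity_pct=sens,
            n_outliers=n_out,
            outlier_pct=100.0 * n_out / x.size if x.size else 0.0,
            stats=stats, loa_ms=loa,
        )
    return out


# ---------------------------------------------------------------------------
# feature agreement
# ---------------------------------------------------------------------------

@dataclass
class FeatureAgreement:
    """Agreement summary for one stride feature, in its report unit."""

    name: str
    unit: str
    n: int
    mean_offset: float
    sd_offset: float
    abs_mean: float
    abs_sd: float
    rmse: float
    pearson_r: float | None
    loa: tuple[float, float]


def pair_strides(vr_features, ref_features, tol_s: float):
    """Pair strides across systems through their defining heel strikes.

    Per foot, the defining (current) HS times are matched greedily within
    ``tol_s``; a pair is kept only if the opening HS times also agree within
    ``tol_s``, so both systems describe the same stride.  Returns two
    equal-length lists of paired features.
    """
    vr_out, ref_out = [], []
    for foot in FOOT_SIDES:
        vr = [f for f in vr_features if f.foot == foot]
        ref = [f for f in ref_features if f.foot == foot]
        res = match_events(
            [f.t_hs_cur for f in vr], [f.t_hs_cur for f in ref], tol_s
        )
        vr_by_t = {f.t_hs_cur: f for f in vr}
        ref_by_t = {f.t_hs_cur: f for f in ref}
        for m in res.matches:
            fv, fr = vr_by_t[m.detected], ref_by_t[m.reference]
            if abs(fv.t_hs_prev - fr.t_hs_prev) <= tol_s:
                vr_out.append(fv)
                ref_out.append(fr)
    return vr_out, ref_out


def feature_agreement(vr_features, ref_features) -> dict[str, FeatureAgreement]:
    """Per-feature agreement over paired strides (detector minus reference).

    Inputs are equal-length lists of paired :class:`StrideFeatures` (see
    :func:`pair_strides`).  Strides with an invalid or non-finite value on
    either side are skipped for that feature.  Pearson r is reported as None
    when either side has zero variance (correlation undefined on constants).
    """
    if len(vr_features) != len(ref_features):
        raise ValueError("vr_features and ref_features must be paired (equal length)")
    if len(vr_features) < 2:
        raise ValueError("need at least 2 paired strides for feature agreement")

    out: dict[str, FeatureAgreement] = {}
    for name, (unit, factor) in FEATURE_UNITS.items():
        a, b = [], []
        for fv, fr in zip(vr_features, ref_features):
            va, vb = getattr(fv, name), getattr(fr, name)
            if name == "SW" and not (fv.valid_SW and fr.valid_SW):
                continue
            if not (math.isfinite(va) and math.isfinite(vb)):
                continue
            a.append(va * factor)
            b.append(vb * factor)
        if len(a) < 2:
            warnings.warn(
                f"fewer than 2 valid paired strides for {name}; skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        a = np.asarray(a)
        b = np.asarray(b)
        diff = a - b
        adiff = np.abs(diff)
        if np.std(a) > 0 and np.std(b) > 0:
            r = float(np.corrcoef(a, b)[0, 1])
        else:
            r = None
        out[name] = FeatureAgreement(
            name=name, unit=unit, n=int(diff.size),
            mean_offset=float(np.mean(diff)), sd_offset=_sd(diff),
            abs_mean=float(np.mean(adiff)), abs_sd=_sd(adiff),
            rmse=float(np.sqrt(np.mean(diff ** 2))),
            pearson_r=r, loa=limits_of_agreement(diff),
        )
    return out


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Full detector-vs-reference agreement report."""

    tolerance_s: float
    events: dict[str, EventValidation] = field(default_factory=dict)
    features: dict[str, FeatureAgreement] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def ev(e: EventValidation) -> dict:
            d = asdict(e)
            if e.loa_ms is not None:
                d["loa_ms"] = list(e.loa_ms)
            return d

        def fa(f: FeatureAgreement) -> dict:
            d = asdict(f)
            d["loa"] = list(f.loa)
            return d

        return {
            "tolerance_s": self.tolerance_s,
            "events": {k: ev(v) for k, v in self.events.items()},
            "features": {k: fa(v) for k, v in self.features.items()},
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "ValidationReport":
        events = {}
        for k, d in obj.get("events", {}).items():
            stats = OffsetStats(**d["stats"]) if d.get("stats") else None
            loa = tuple(d["loa_ms"]) if d.get("loa_ms") else None
            events[k] = EventValidation(
                kind=d["kind"], tp=d["tp"], fn=d["fn"], fp=d["fp"],
                sensitivity_pct=d["sensitivity_pct"], n_outliers=d["n_outliers"],
                outlier_pct=d["outlier_pct"], stats=stats, loa_ms=loa,
            )
        feats = {}
        for k, d in obj.get("features", {}).items():
            d = dict(d)
            d["loa"] = tuple(d["loa"])
            feats[k] = FeatureAgreement(**d)
        return cls(tolerance_s=obj["tolerance_s"], events=events, features=feats)

    def to_text(self) -> str:
        lines = [f"Validation report (matching window {self.tolerance_s * 1e3:.1f} ms)", ""]
        lines.append("Gait events:")
        for kind, e in self.events.items():
            lines.append(
                f"  {kind}: sensitivity {e.sensitivity_pct:.1f}% "
                f"(TP {e.tp}, FN {e.fn}, FP {e.fp}); "
                f"outliers removed {e.n_outliers} ({e.outlier_pct:.2f}%)"
            )
            if e.stats is not None:
                s = e.stats
                lines.append(
                    f"      offset {s.mean_ms:+.1f} ± {s.sd_ms:.1f} ms, "
                    f"|offset| {s.abs_mean_ms:.1f} ± {s.abs_sd_ms:.1f} ms, "
                    f"RMSE {s.rmse_ms:.1f} ms (n={s.n})"
                )
        if self.features:
            lines.append("")
            lines.append("Stride features (detector - reference):")
            for name, f in self.features.items():
                r_txt = f"{f.pearson_r:.3f}" if f.pearson_r is not None else "n/a"
                lines.append(
                    f"  {name:8s} offset {f.mean_offset:+.2f} ± {f.sd_offset:.2f} {f.unit}, "
                    f"|err| {f.abs_mean:.2f} ± {f.abs_sd:.2f} {f.unit}, "
                    f"RMSE {f.rmse:.2f} {f.unit}, r {r_txt}, "
                    f"LoA [{f.loa[0]:.2f}, {f.loa[1]:.2f}] {f.unit} (n={f.n})"
                )
        return "\n".join(lines) + "\n"


def validate_trial(
    detected_events,
    reference: ReferenceEventTable,
    vr_features=None,
    ref_features=None,
    config: RunConfig | None = None,
) -> ValidationReport:
    """Event matching plus (optionally) feature agreement, as one report.

    Reference feature stride times are assumed to be on the reference clock
    and are shifted by ``-sync_offset_s`` before pairing, like reference
    event times.
    """
    config = config or RunConfig()
    report = ValidationReport(tolerance_s=config.match_tolerance_s)
    report.events = validate_events(detected_events, reference, config)
    if vr_features is not None and ref_features is not None:
        if config.sync_offset_s:
            shifted = []
            for f in ref_features:
                g = copy.copy(f)
                g.t_hs_prev = f.t_hs_prev - config.sync_offset_s
                g.t_to = f.t_to - config.sync_offset_s
                g.t_hs_cur = f.t_hs_cur - config.sync_offset_s
                shifted.append(g)
            ref_features = shifted
        vr_p, ref_p = pair_strides(vr_features, ref_features, config.match_tolerance_s)
        if len(vr_p) >= 2:
            report.features = feature_agreement(vr_p, ref_p)
        else:
            warnings.warn(
                "fewer than 2 paired strides; feature agreement skipped",
                UserWarning,
                stacklevel=2,
            )
    return report
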