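"""Tracker-to-heel rigid transformation.

The tracker sits on the instep of the shoe while spatial gait features are
conventionally measured at the heel.  Given the tracker's world pose and a
fixed tracker-frame offset vector (measured once per subject and shoe), the
heel position is ``pos + R(quat) @ offset``.

Offsets are looked up by shoe-size label from a user-supplied table; no
interpolation between sizes is performed.  The shipped template config holds
placeholder vectors only — offsets are anthropometric measurements that must
come from the user (or, in tests, from the synthetic generator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

#: quaternion norms within this tolerance of 1 are silently renormalized
_QUAT_FIX_TOL = 1e-3
#: sanity bound on a heel offset magnitude (no shoe is half a meter long)
_MAX_OFFSET_M = 0.5


@dataclass
class HeelOffsetTable:
    """Map of shoe-size label -> tracker-frame heel offset [ox, oy, oz] in meters."""

    entries: dict

    def __post_init__(self) -> None:
        clean = {}
        for label, vec in self.entries.items():
            v = np.asarray(vec, dtype=float).reshape(3)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite heel offset for size {label!r}")
            if np.linalg.norm(v) >= _MAX_OFFSET_M:
                raise ValueError(
                    f"heel offset for size {label!r} has magnitude "
                    f"{np.linalg.norm(v):.3f} m >= {_MAX_OFFSET_M} m"
                )
            clean[str(label)] = v
        self.entries = clean


def offset_for_shoe_size(size_label: str, table: HeelOffsetTable) -> np.ndarray:
    """Exact-match lookup of the heel offset for a shoe size."""
    if not table.entries:
        raise ValueError("heel offset table is empty")
    key = str(size_label)
    if key not in table.entries:
        raise KeyError(
            f"unknown shoe size {key!r}; available sizes: {sorted(table.entries)}"
        )
    return table.entries[key].copy()


def heel_position(pos, quat, offset) -> np.ndarray:
    """Map tracker pose(s) to world heel position(s).

    Parameters
    ----------
    pos : (3,) or (n, 3) array
        Tracker world position(s) in meters.
    quat : (4,) or (n, 4) array
        Scalar-first unit quaternion(s), world-from-tracker.
    offset : (3,) array
        Heel offset in the tracker's local frame, meters.

    Returns
    -------
    (3,) or (n, 3) array of world heel positions: ``pos + R(quat) @ offset``.
    """
    pos = np.asarray(pos, dtype=float)
    quat = np.asarray(quat, dtype=float)
    offset = np.asarray(offset, dtype=float).reshape(3)
    single = pos.ndim == 1
    pos2 = np.atleast_2d(pos)
    quat2 = np.atleast_2d(quat)
    if pos2.shape[0] != quat2.shape[0]:
        raise ValueError("pos and quat must have the same number of samples")
    norms = np.linalg.norm(quat2, axis=1)
    err = np.abs(norms - 1.0)
    if np.any(err > _QUAT_FIX_TOL):
        i = int(np.argmax(err))
        raise ValueError(
            f"quaternion at index {i} is too far from unit norm ({norms[i]:.6f})"
        )
    quat2 = quat2 / norms[:, None]
    rot = Rotation.from_quat(quat2, scalar_first=True)
    out = pos2 + rot.apply(offset)
    return out[0] if single else out
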