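"""Contour and point primitives in the canonical frame.

Every esthetic parameter reduces to a handful of operations on ordered
3D point chains: axis-aligned extrema of a contour, intersection of a
contour with an axis-aligned plane, the angle at a vertex, and the Y
value of a 3D line at a given height.  Extrema are vertex-attained (no
interpolation) — manual contour traces are dense, so vertex resolution
bounds the error; ties are broken by the lowest point index for
determinism.  Plane intersections use exact segment-plane linear
interpolation with a 1e-9 mm coincidence tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError
from .mesh_io import Polyline3D

__all__ = [
    "AXES",
    "AxisExtremum",
    "contour_extremum",
    "contour_plane_intersection",
    "angle_at_vertex",
    "line_y_at_z",
]

AXES = {"X": 0, "Y": 1, "Z": 2}

_COINCIDENCE_TOL = 1e-9


@dataclass
class AxisExtremum:
    """A vertex of a polyline attaining an extreme axis coordinate."""

    axis: str
    kind: str  # "min" or "max"
    point: np.ndarray
    value: float
    index: int


def _axis_index(axis: str) -> int:
    try:
        return AXES[axis.upper()]
    except KeyError:
        raise ValueError(f"axis must be one of {sorted(AXES)}, got {axis!r}") from None


def contour_extremum(c: Polyline3D, axis: str, kind: str) -> AxisExtremum:
    """Vertex of ``c`` with the minimum/maximum coordinate along ``axis``.

    Ties are broken by the lowest vertex index (argmin/argmax semantics),
    so the result is deterministic and invariant to densification that
    appends points.
    """
    ai = _axis_index(axis)
    coords = c.points[:, ai]
    if kind == "min":
        idx = int(np.argmin(coords))
    elif kind == "max":
        idx = int(np.argmax(coords))
    else:
        raise ValueError(f"kind must be 'min' or 'max', got {kind!r}")
    return AxisExtremum(
        axis=axis.upper(),
        kind=kind,
        point=c.points[idx].copy(),
        value=float(coords[idx]),
        index=idx,
    )


def contour_plane_intersection(c: Polyline3D, axis: str, level: float) -> np.ndarray:
    """All crossings of ``c`` with the plane ``{axis coordinate == level}``.

    Crossing points interior to a segment are found by linear
    interpolation; a vertex lying on the plane (within 1e-9 mm) is
    reported once; a segment lying wholly in the plane contributes its
    endpoints.  Returns an (M, 3) array, empty when there is no crossing.
    """
    ai = _axis_index(axis)
    hits: list = []
    for p, q in c.segments():
        d1 = p[ai] - level
        d2 = q[ai] - level
        on1 = abs(d1) <= _COINCIDENCE_TOL
        on2 = abs(d2) <= _COINCIDENCE_TOL
        if on1 and on2:
            hits.append(p)
            hits.append(q)
        elif on1:
            hits.append(p)
        elif on2:
            hits.append(q)
        elif d1 * d2 < 0:
            t = d1 / (d1 - d2)
            hits.append(p + t * (q - p))
    if not hits:
        return np.empty((0, 3))
    # deduplicate coincident reports (shared segment endpoints), keep order
    unique: list = []
    for h in hits:
        if not any(np.linalg.norm(h - u) <= _COINCIDENCE_TOL for u in unique):
            unique.append(h)
    return np.asarray(unique)


def angle_at_vertex(a, apex, b) -> float:
    """Angle (degrees, in [0, 180]) at ``apex`` between rays to ``a`` and ``b``."""
    a = np.asarray(a, dtype=float)
    apex = np.asarray(apex, dtype=float)
    b = np.asarray(b, dtype=float)
    u = a - apex
    v = b - apex
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu <= 0 or nv <= 0:
        raise DegenerateGeometryError("zero-length arm in angle computation")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def line_y_at_z(p1, p2, z: float) -> float:
    """Y coordinate of the 3D line through ``p1`` and ``p2`` at height ``z``
    (the line's sagittal YZ projection evaluated at ``z``).

    Extrapolation beyond the two endpoints is allowed but warned about.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    dz = p2[2] - p1[2]
    if dz == 0:
        raise DegenerateGeometryError(
            "reference line is horizontal (equal Z at both points)"
        )
    t = (z - p1[2]) / dz
    if t < 0 or t > 1:
        warnings.warn(
            f"height z={z:g} lies outside the segment Z range "
            f"[{min(p1[2], p2[2]):g}, {max(p1[2], p2[2]):g}]; extrapolating",
            stacklevel=2,
        )
    return float(p1[1] + t * (p2[1] - p1[1]))
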