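"""Domain types and file I/O for the 3D esthetic-analysis workflow.

The workflow consumes four kinds of geometry, all in millimetres:

* triangulated surface scans (facial OBJ with optional per-vertex color,
  dental-arch PLY),
* named anatomical landmarks (pupils, Frankfort points, nasal points,
  pogonion, upper-lip midpoint),
* open lip-border polylines per facial expression, and
* closed per-tooth gingival-margin contours in FDI numbering.

Landmarks and contours are stored as plain JSON coordinate files rather
than mesh-vertex indices, so they survive rigid registration and are
independent of mesh resolution.  Mesh reading/writing is delegated to
:mod:`trimesh` (PLY ascii + binary little-endian; OBJ with the common
trailing ``r g b`` vertex-color extension).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import trimesh as _trimesh

from .errors import ContourError, LandmarkError, MeshParseError

__all__ = [
    "LANDMARK_VOCABULARY",
    "FRAME_LANDMARKS",
    "SUPPORTED_FDI",
    "LIP_LABELS",
    "EXPRESSIONS",
    "TriMesh",
    "LandmarkSet",
    "Polyline3D",
    "ToothContour",
    "ParameterValue",
    "EstheticReport",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_contours",
    "write_contours",
]

#: Controlled vocabulary of anatomical landmark names.
LANDMARK_VOCABULARY = frozenset(
    {
        "pupil_left",
        "pupil_right",
        "infraorbital_left",
        "ear_superior_left",
        "ear_superior_right",
        "nasal_tip",
        "nasal_columella",
        "nasal_base",
        "pogonion",
        "upper_lip_midpoint",
    }
)

#: Landmarks required to construct the canonical head-pose frame: the three
#: Frankfort-plane points plus both pupils (for the vertical axis).
FRAME_LANDMARKS = (
    "infraorbital_left",
    "ear_superior_left",
    "ear_superior_right",
    "pupil_left",
    "pupil_right",
)

#: FDI tooth codes the analysis supports: the six upper anterior teeth and
#: the two lower central incisors.
SUPPORTED_FDI = frozenset({13, 12, 11, 21, 22, 23, 31, 41})

#: Labels for the inferior border of the upper lip, one per expression.
LIP_LABELS = frozenset(
    {
        "upper_lip_inferior_rest",
        "upper_lip_inferior_smile",
        "upper_lip_inferior_closed",
    }
)

LIP_LABEL_TO_EXPRESSION = {
    "upper_lip_inferior_rest": "rest",
    "upper_lip_inferior_smile": "smile",
    "upper_lip_inferior_closed": "closed_lip",
}

EXPRESSIONS = ("closed_lip", "rest", "smile", "dental")


def _as_points(points, name: str) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{name} must be an (N, 3) array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return arr


@dataclass
class TriMesh:
    """A triangulated surface in millimetres.

    Parameters
    ----------
    vertices : (N, 3) float array
    faces : (M, 3) int array of vertex indices
    colors : optional (N, 3) uint8 per-vertex RGB
    """

    vertices: np.ndarray
    faces: np.ndarray
    colors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vertices = _as_points(self.vertices, "vertices")
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertices.shape[0] == 0:
            raise MeshParseError("mesh has no vertices")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise MeshParseError(
                    f"face index out of range: max index {self.faces.max()} "
                    f"for {len(self.vertices)} vertices"
                )
        if self.colors is not None:
            self.colors = np.asarray(self.colors)
            if self.colors.shape != (len(self.vertices), 3):
                raise MeshParseError(
                    f"colors must be (N, 3), got {self.colors.shape}"
                )
            self.colors = self.colors.astype(np.uint8)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass
class LandmarkSet:
    """Named anatomical 3D points on one scan/expression."""

    points: dict
    expression: str = "closed_lip"

    def __post_init__(self) -> None:
        if self.expression not in EXPRESSIONS:
            raise LandmarkError(
                f"unknown expression {self.expression!r}; expected one of {EXPRESSIONS}"
            )
        unknown = sorted(set(self.points) - LANDMARK_VOCABULARY)
        if unknown:
            raise LandmarkError(
                f"unknown landmark name(s): {', '.join(unknown)}; "
                f"allowed names are {sorted(LANDMARK_VOCABULARY)}"
            )
        self.points = {
            name: np.asarray(p, dtype=float).reshape(3) for name, p in self.points.items()
        }
        for name, p in self.points.items():
            if not np.all(np.isfinite(p)):
                raise LandmarkError(f"landmark {name!r} has non-finite coordinates")

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise LandmarkError(f"landmark {name!r} not present") from None

    def __len__(self) -> int:
        return len(self.points)

    def require(self, names: Iterable[str]) -> None:
        missing = sorted(set(names) - set(self.points))
        if missing:
            raise LandmarkError(f"missing required landmark(s): {', '.join(missing)}")


@dataclass
class Polyline3D:
    """An ordered chain of 3D points; ``closed`` adds an implicit segment
    from the last point back to the first (the first point is not repeated).
    Point order is semantic — interpolation happens along it."""

    points: np.ndarray
    closed: bool = False

    def __post_init__(self) -> None:
        self.points = _as_points(self.points, "polyline points")
        minimum = 3 if self.closed else 2
        if len(self.points) < minimum:
            raise ContourError(
                f"polyline needs at least {minimum} points "
                f"({'closed' if self.closed else 'open'}), got {len(self.points)}"
            )
        deltas = np.diff(self.points, axis=0)
        if np.any(np.all(deltas == 0.0, axis=1)):
            raise ContourError("polyline has consecutive duplicate points")
        if self.closed and np.all(self.points[0] == self.points[-1]):
            raise ContourError(
                "closed polyline must not repeat its first point as the last"
            )

    def __len__(self) -> int:
        return len(self.points)

    def segments(self) -> np.ndarray:
        """(S, 2, 3) array of segment endpoints, including the closing one."""
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return np.stack([pts[:-1], pts[1:]], axis=1)


@dataclass
class ToothContour:
    """Closed gingival-margin outline of a single tooth (FDI numbering)."""

    tooth_fdi: int
    outline: Polyline3D

    def __post_init__(self) -> None:
        if self.tooth_fdi not in SUPPORTED_FDI:
            raise ContourError(
                f"unsupported FDI code {self.tooth_fdi}; "
                f"supported: {sorted(SUPPORTED_FDI)}"
            )
        if not self.outline.closed:
            raise ContourError(f"tooth {self.tooth_fdi} contour must be closed")


@dataclass
class ParameterValue:
    """One measured esthetic quantity."""

    parameter: str
    value: float
    unit: str  # "mm" or "deg"
    tooth_fdi: Optional[int] = None

    def key(self) -> str:
        if self.tooth_fdi is None:
            return self.parameter
        return f"{self.parameter}[{self.tooth_fdi}]"


@dataclass
class EstheticReport:
    """The nine esthetic parameter families measured on one subject.

    ``values`` maps ``"parameter"`` or ``"parameter[fdi]"`` to a
    :class:`ParameterValue`; ``missing`` records parameters that could not
    be computed together with the reason, so nothing is silently omitted.
    """

    values: dict = field(default_factory=dict)
    missing: dict = field(default_factory=dict)
    frame_provenance: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def add(self, pv: ParameterValue) -> None:
        self.values[pv.key()] = pv

    def to_dict(self) -> dict:
        return {
            "values": {
                k: {
                    "parameter": v.parameter,
                    "value": float(v.value),
                    "unit": v.unit,
                    "tooth_fdi": v.tooth_fdi,
                }
                for k, v in self.values.items()
            },
            "missing": dict(self.missing),
            "frame_provenance": dict(self.frame_provenance),
            "metadata": dict(self.metadata),
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {
                "parameter": v.parameter,
                "tooth_fdi": v.tooth_fdi,
                "value": float(v.value),
                "unit": v.unit,
            }
            for v in self.values.values()
        ]
        return pd.DataFrame(rows, columns=["parameter", "tooth_fdi", "value", "unit"])


# ---------------------------------------------------------------------------
# Mesh I/O


def read_mesh(path: Union[str, Path], format: Optional[str] = None) -> TriMesh:
    """Read a PLY (ascii or binary little-endian) or OBJ surface.

    Per-vertex colors are populated when the file carries them.  An empty
    vertex list or out-of-range face index is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise MeshParseError(f"mesh file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("ply", "obj"):
        raise MeshParseError(f"unsupported mesh format {fmt!r} (expected ply or obj)")
    try:
        loaded = _trimesh.load(str(path), file_type=fmt, process=False)
    except Exception as exc:  # trimesh raises assorted exception types
        raise MeshParseError(f"cannot parse {fmt} file {path}: {exc}") from exc
    if isinstance(loaded, _trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise MeshParseError(f"{path} contains no geometry")
        loaded = geoms[0]
    vertices = np.asarray(loaded.vertices, dtype=float)
    if vertices.size == 0:
        raise MeshParseError(f"{path} contains no vertices")
    faces = getattr(loaded, "faces", None)
    faces = np.zeros((0, 3), dtype=np.int64) if faces is None else np.asarray(faces)
    colors = None
    visual = getattr(loaded, "visual", None)
    if visual is not None and getattr(visual, "kind", None) == "vertex":
        rgba = np.asarray(visual.vertex_colors)
        if rgba.shape[0] == len(vertices):
            colors = rgba[:, :3].astype(np.uint8)
    return TriMesh(vertices=vertices, faces=faces, colors=colors)


def _export_ply(mesh: TriMesh, ascii_encoding: bool) -> bytes:
    """PLY serialization with double-precision coordinates.

    Written here because available exporters truncate vertices to float32,
    which breaks the 1e-6 mm round-trip contract at head-scale coordinates.
    """
    n, m = mesh.n_vertices, mesh.n_faces
    fmt_line = "ascii" if ascii_encoding else "binary_little_endian"
    header = ["ply", f"format {fmt_line} 1.0", f"element vertex {n}"]
    header += [f"property double {axis}" for axis in "xyz"]
    if mesh.colors is not None:
        header += [f"property uchar {c}" for c in ("red", "green", "blue")]
    header += [
        f"element face {m}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    head = ("\n".join(header) + "\n").encode()
    if ascii_encoding:
        lines = []
        for i in range(n):
            row = " ".join(f"{v:.17g}" for v in mesh.vertices[i])
            if mesh.colors is not None:
                row += " " + " ".join(str(int(c)) for c in mesh.colors[i])
            lines.append(row)
        for face in mesh.faces:
            lines.append("3 " + " ".join(str(int(i)) for i in face))
        return head + ("\n".join(lines) + "\n").encode()
    import struct

    body = bytearray()
    for i in range(n):
        body += struct.pack("<3d", *mesh.vertices[i])
        if mesh.colors is not None:
            body += struct.pack("<3B", *(int(c) for c in mesh.colors[i]))
    for face in mesh.faces:
        body += struct.pack("<B3i", 3, *(int(i) for i in face))
    return head + bytes(body)


def write_mesh(
    mesh: TriMesh,
    path: Union[str, Path],
    format: Optional[str] = None,
    encoding: str = "binary",
) -> None:
    """Write a mesh as PLY (``encoding`` "ascii" or "binary") or OBJ.

    Round-trips geometry within 1e-6 mm and colors within 1/255.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        data: Union[str, bytes] = _export_ply(mesh, encoding == "ascii")
    elif fmt == "obj":
        tm = _trimesh.Trimesh(
            vertices=mesh.vertices,
            faces=mesh.faces,
            vertex_colors=mesh.colors,
            process=False,
        )
        kwargs = {"include_color": True} if mesh.colors is not None else {}
        data = tm.export(file_type="obj", **kwargs)
    else:
        raise MeshParseError(f"unsupported mesh format {fmt!r} (expected ply or obj)")
    try:
        if isinstance(data, str):
            path.write_text(data)
        else:
            path.write_bytes(data)
    except OSError as exc:
        raise MeshParseError(f"cannot write mesh to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Landmark I/O — JSON schema {"expression": ..., "points": {name: [x, y, z]}}


def read_landmarks(path: Union[str, Path]) -> LandmarkSet:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise LandmarkError(f"cannot read landmark file {path}: {exc}") from exc
    if not isinstance(data, dict) or "points" not in data:
        raise LandmarkError(f"{path}: expected an object with a 'points' mapping")
    return LandmarkSet(
        points=data["points"], expression=data.get("expression", "closed_lip")
    )


def write_landmarks(landmarks: LandmarkSet, path: Union[str, Path]) -> None:
    payload = {
        "expression": landmarks.expression,
        "points": {name: list(map(float, p)) for name, p in landmarks.points.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Contour I/O — JSON schema
# {"contours": [{"label": "11" | "upper_lip_inferior_rest",
#                "closed": bool, "points": [[x, y, z], ...]}]}


def _parse_contour(entry: Mapping) -> tuple:
    label = entry.get("label")
    if label is None:
        raise ContourError("contour entry missing 'label'")
    points = entry.get("points")
    if points is None or len(points) < 2:
        raise ContourError(f"contour {label!r} needs at least 2 points")
    label_str = str(label)
    if label_str.lstrip("-").isdigit():
        fdi = int(label_str)
        if fdi not in SUPPORTED_FDI:
            raise ContourError(
                f"unsupported FDI code {fdi}; supported: {sorted(SUPPORTED_FDI)}"
            )
        # tooth outlines are forced closed
        contour = ToothContour(tooth_fdi=fdi, outline=Polyline3D(points, closed=True))
        return label_str, contour
    if label_str not in LIP_LABELS:
        raise ContourError(
            f"unknown contour label {label_str!r}; expected an FDI code "
            f"or one of {sorted(LIP_LABELS)}"
        )
    return label_str, Polyline3D(points, closed=bool(entry.get("closed", False)))


def read_contours(path: Union[str, Path]) -> list:
    """Read labeled contours; FDI labels become :class:`ToothContour`
    (forced closed), lip labels become open :class:`Polyline3D`.

    Returns a list of ``(label, contour)`` pairs in file order.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ContourError(f"cannot read contour file {path}: {exc}") from exc
    entries = data.get("contours") if isinstance(data, dict) else None
    if entries is None:
        raise ContourError(f"{path}: expected an object with a 'contours' list")
    return [_parse_contour(e) for e in entries]


def write_contours(
    contours: Sequence[tuple], path: Union[str, Path]
) -> None:
    """Write ``(label, Polyline3D | ToothContour)`` pairs to JSON."""
    entries = []
    for label, c in contours:
        poly = c.outline if isinstance(c, ToothContour) else c
        entries.append(
            {
                "label": str(label),
                "closed": bool(poly.closed),
                "points": [list(map(float, p)) for p in poly.points],
            }
        )
    Path(path).write_text(json.dumps({"contours": entries}, indent=2))
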