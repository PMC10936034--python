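"""Head-pose canonical frame and rigid registration.

The canonical coordinate system is rebuilt from anatomy so that every
esthetic measurement is taken at a reproducible head posture:

* the **XY plane** is the Frankfort horizontal plane, through the left
  infraorbital point and the superior points of both external auditory
  meatus;
* the **Z axis** is perpendicular to that plane and passes through the
  midpoint of the interpupillary line.

Axis orientation is fixed as +Z superior, +Y posterior, +X the subject's
anatomical left (right-handed).  With these signs every parameter formula
downstream (overbite, overjet, exposures) yields conventional positive
values for normal anatomy.  The Z sign is disambiguated by requiring the
pupils to sit above (superior to) the Frankfort plane; the origin is the
orthogonal projection of the interpupillary midpoint onto the plane — the
unique point lying on both the plane and the Z axis.

Registration of auxiliary scans into the closed-lip scan's space is
expressed as corresponding-landmark Kabsch alignment with optional
point-to-point ICP refinement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, RegistrationError
from .mesh_io import FRAME_LANDMARKS, LandmarkSet, Polyline3D, ToothContour, TriMesh

__all__ = [
    "RigidTransform",
    "CanonicalFrame",
    "ICPResult",
    "build_frame",
    "apply_transform",
    "kabsch_align",
    "icp_refine",
]

_ORTHO_TOL = 1e-8


@dataclass
class RigidTransform:
    """A proper rigid motion ``x -> R @ x + t`` (rotation then translation).

    Reflections (det R = -1) are rejected at construction.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > _ORTHO_TOL:
            raise DegenerateGeometryError(
                f"rotation matrix is not orthonormal (max deviation {err:.2e})"
            )
        if np.linalg.det(self.rotation) < 0:
            raise DegenerateGeometryError(
                "improper rotation (reflection, det = -1) rejected"
            )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first,
        then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps({"matrix": self.to_matrix().tolist()}, indent=2)
        )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RigidTransform":
        data = json.loads(Path(path).read_text())
        return cls.from_matrix(np.asarray(data["matrix"]))


@dataclass
class CanonicalFrame:
    """The world-to-canonical rigid transform plus its provenance."""

    world_to_canonical: RigidTransform
    source_landmarks: LandmarkSet
    plane_residual: float = 0.0

    def provenance(self) -> dict:
        return {
            "landmarks_used": list(FRAME_LANDMARKS),
            "plane_residual_mm": float(self.plane_residual),
        }


def build_frame(landmarks: LandmarkSet) -> CanonicalFrame:
    """Construct the canonical head-pose frame from five landmarks.

    Requires the three Frankfort-plane points (left infraorbital, both
    superior auditory-meatus points) and both pupils.  Raises
    :class:`DegenerateGeometryError` if the plane points are collinear
    (triangle area <= 1e-6 mm^2).
    """
    landmarks.require(FRAME_LANDMARKS)
    io_l = landmarks["infraorbital_left"]
    ear_l = landmarks["ear_superior_left"]
    ear_r = landmarks["ear_superior_right"]
    pup_l = landmarks["pupil_left"]
    pup_r = landmarks["pupil_right"]

    normal = np.cross(ear_l - io_l, ear_r - io_l)
    area = 0.5 * np.linalg.norm(normal)
    if area <= 1e-6:
        raise DegenerateGeometryError(
            f"Frankfort plane points are (near-)collinear: triangle area "
            f"{area:.3e} mm^2"
        )
    z_hat = normal / np.linalg.norm(normal)
    # pupils sit superior to the Frankfort plane; the interpupillary
    # midpoint cannot break this tie because it lies on the Z axis itself
    pupil_side = 0.5 * (np.dot(pup_l - io_l, z_hat) + np.dot(pup_r - io_l, z_hat))
    if pupil_side < 0:
        z_hat = -z_hat

    x_raw = ear_l - ear_r
    x_proj = x_raw - np.dot(x_raw, z_hat) * z_hat
    nx = np.linalg.norm(x_proj)
    if nx <= 1e-9:
        raise DegenerateGeometryError(
            "inter-ear direction is perpendicular to the Frankfort plane"
        )
    x_hat = x_proj / nx
    y_hat = np.cross(z_hat, x_hat)  # +Y posterior; (x, y, z) right-handed

    midpoint = 0.5 * (pup_l + pup_r)
    origin = midpoint - np.dot(midpoint - io_l, z_hat) * z_hat

    rotation = np.vstack([x_hat, y_hat, z_hat])
    transform = RigidTransform(rotation, -rotation @ origin)

    canon_plane = transform.apply(np.vstack([io_l, ear_l, ear_r]))
    residual = float(np.abs(canon_plane[:, 2]).max())
    return CanonicalFrame(
        world_to_canonical=transform,
        source_landmarks=landmarks,
        plane_residual=residual,
    )


def apply_transform(x, t: RigidTransform):
    """Apply a rigid transform to a mesh, polyline, tooth contour,
    landmark set, or bare (N, 3) array; structure is preserved."""
    if isinstance(x, TriMesh):
        return TriMesh(
            vertices=t.apply(x.vertices),
            faces=x.faces.copy(),
            colors=None if x.colors is None else x.colors.copy(),
        )
    if isinstance(x, ToothContour):
        return ToothContour(
            tooth_fdi=x.tooth_fdi,
            outline=Polyline3D(t.apply(x.outline.points), closed=True),
        )
    if isinstance(x, Polyline3D):
        return Polyline3D(t.apply(x.points), closed=x.closed)
    if isinstance(x, LandmarkSet):
        return LandmarkSet(
            points={name: t.apply(p) for name, p in x.points.items()},
            expression=x.expression,
        )
    return t.apply(np.asarray(x, dtype=float))


def kabsch_align(source_points, target_points) -> RigidTransform:
    """Least-squares rigid alignment of corresponding point sets.

    Returns the proper rigid transform minimizing the RMSD between the
    transformed source and the target (Kabsch/Umeyama, no scaling, no
    reflection).  Requires >= 3 non-collinear correspondences.
    """
    src = np.asarray(source_points, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target_points, dtype=float).reshape(-1, 3)
    if src.shape != tgt.shape:
        raise RegistrationError(
            f"point counts differ: {src.shape[0]} source vs {tgt.shape[0]} target"
        )
    if len(src) < 3:
        raise RegistrationError(f"need at least 3 point pairs, got {len(src)}")
    c_src = src.mean(axis=0)
    c_tgt = tgt.mean(axis=0)
    src_c = src - c_src
    tgt_c = tgt - c_tgt
    # collinearity check: second singular value of either centered cloud
    if min(np.linalg.svd(src_c, compute_uv=False)[1],
           np.linalg.svd(tgt_c, compute_uv=False)[1]) <= 1e-9:
        raise RegistrationError("degenerate (collinear) point configuration")
    rot, _ = Rotation.align_vectors(tgt_c, src_c)  # proper rotation guaranteed
    r = rot.as_matrix()
    return RigidTransform(r, c_tgt - r @ c_src)


@dataclass
class ICPResult:
    """Outcome of an ICP refinement run."""

    transform: RigidTransform
    rmsd_history: List[float] = field(default_factory=list)
    n_iterations: int = 0

    @property
    def rmsd(self) -> float:
        return self.rmsd_history[-1] if self.rmsd_history else float("nan")


def icp_refine(
    source: TriMesh,
    target: TriMesh,
    init: Optional[RigidTransform] = None,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> ICPResult:
    """Point-to-point ICP: nearest-neighbor correspondences on the target
    vertex set, Kabsch update per iteration.

    The RMSD sequence is non-increasing; iteration stops at ``max_iter``
    or when the improvement drops below ``tol`` (mm).
    """
    if source.n_vertices == 0 or target.n_vertices == 0:
        raise RegistrationError("ICP requires non-empty meshes")
    transform = init if init is not None else RigidTransform.identity()
    tree = cKDTree(target.vertices)
    history: List[float] = []
    moved = transform.apply(source.vertices)
    for it in range(max_iter):
        dists, idx = tree.query(moved)
        rmsd = float(np.sqrt(np.mean(dists**2)))
        if history and history[-1] - rmsd < tol:
            history.append(min(rmsd, history[-1]))
            break
        history.append(rmsd)
        try:
            step = kabsch_align(moved, target.vertices[idx])
        except RegistrationError:
            # correspondences collapsed to a degenerate set; no rigid
            # update can be estimated, so stop at the current pose
            break
        transform = step.compose(transform)
        moved = transform.apply(source.vertices)
    return ICPResult(transform=transform, rmsd_history=history, n_iterations=len(history))
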