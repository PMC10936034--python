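"""Synthetic dentofacial cases with exact, known ground truth.

The generator lays out a stylized virtual patient directly in the
canonical head-pose frame — Frankfort plane at Z = 0, interpupillary
midpoint on the Z axis — then maps everything through an arbitrary rigid
pose.  Because landmark and contour coordinates are placed analytically,
every esthetic parameter of the generated case is known exactly, which
makes the generator/analyzer round trip the package's master oracle:
for a noiseless phantom the measured parameters must match the requested
truth to numerical precision, in any pose.

What is emulated: the landmark set, per-expression inferior lip-border
polylines, six upper anterior and two lower incisor gingival-margin
contours (rounded-rectangle crowns), a coarse ellipsoidal face shell and
thin extruded crown meshes for file-format realism.  What is not: real
crown morphology, lip-curve asymmetry, soft-tissue deformation between
expressions, or scanner noise — so passing round-trip tests demonstrates
the correctness of the measurement formulas and frame construction, not
robustness to anatomical variation.

``simulate_raters`` re-enacts a multi-rater reproducibility study by
perturbing landmark picks and contour vertices with isotropic Gaussian
noise per rater and rerunning the full pipeline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DentofaceError, PhantomConstructionError
from .esthetics import AnalysisConfig, PARAMETER_FAMILIES, full_report, make_case
from .frame import RigidTransform, apply_transform
from .mesh_io import LandmarkSet, Polyline3D, ToothContour, TriMesh

__all__ = [
    "PhantomTruth",
    "PhantomCase",
    "RaterStudy",
    "default_truth",
    "random_truth",
    "random_rigid_transform",
    "generate_phantom",
    "analyze_case",
    "simulate_raters",
]

# Canonical-frame layout constants (mm).  The origin is the projection of
# the interpupillary midpoint onto the Frankfort plane; +Z superior,
# +Y posterior, +X subject's left.
_PUPIL_HALF_SPAN = 32.0
_PUPIL_HEIGHT = 8.0
_INFRAORBITAL_LEFT = np.array([33.0, 2.0, 0.0])
_EAR_LEFT = np.array([70.0, 78.0, 0.0])
_EAR_RIGHT = np.array([-70.0, 78.0, 0.0])
_NASAL_TIP = np.array([0.0, -25.0, -20.0])
_NASAL_BASE = np.array([0.0, -18.0, -28.0])
_POGONION = np.array([0.0, -14.0, -95.0])
_LIP_MIDPOINT_Z = -48.0
_COLUMELLA_ARM = 8.0

_UPPER_INCISAL_Z = -55.0       # incisal edge height of the upper incisors
_UPPER_TEETH_Y = -12.0         # labial contour plane of the upper teeth
_LOWER_INCISOR_LENGTH = 9.0
_LOWER_INCISOR_WIDTH = 5.5
_LIP_X_SPAN = 38.0
_LIP_FRONT_Y = -16.0

#: default crown lengths for teeth whose length is not a truth parameter
_OTHER_TOOTH_LENGTH = {13: 9.8, 12: 8.8, 22: 8.8, 23: 9.8}


@dataclass
class PhantomTruth:
    """Ground-truth parameter vector for one synthetic subject.

    Widths/lengths are crown dimensions in mm; ``midline_shift`` is the
    signed X of the dental midline (positive = subject's left);
    ``rest_exposure`` may be negative (lip covering the incisal edge);
    ``gingival_display`` must be >= 0 because a covered gingiva is
    recorded as zero and cannot be recovered; ``nasolabial_deg`` is the
    nasolabial angle.  ``pose`` is the rigid motion from the canonical
    layout to world coordinates.
    """

    tooth_widths: Dict[int, float] = field(
        default_factory=lambda: {13: 7.8, 12: 6.6, 11: 8.5, 21: 8.5, 22: 6.6, 23: 7.8}
    )
    incisor_lengths: Dict[int, float] = field(
        default_factory=lambda: {11: 10.5, 21: 10.5}
    )
    overbite: float = 2.5
    overjet: float = 3.0
    midline_shift: float = 0.0
    rest_exposure: float = 3.0
    gingival_display: float = 1.5
    eline_offset: float = 1.2
    nasolabial_deg: float = 96.0
    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    seed: int = 0

    def __post_init__(self) -> None:
        for fdi, w in self.tooth_widths.items():
            if not (w > 0 and np.isfinite(w)):
                raise PhantomConstructionError(f"width of tooth {fdi} must be > 0")
        for fdi, length in self.incisor_lengths.items():
            if not (length > 0 and np.isfinite(length)):
                raise PhantomConstructionError(f"length of tooth {fdi} must be > 0")
        if not 60.0 < self.nasolabial_deg < 140.0:
            raise PhantomConstructionError(
                f"nasolabial angle {self.nasolabial_deg} deg outside the "
                "plausible (60, 140) range"
            )
        if self.gingival_display < 0:
            raise PhantomConstructionError(
                "gingival_display < 0 is unrecoverable (recorded as zero); "
                "use 0 for a lip that covers the gingiva"
            )
        scalars = [
            self.overbite,
            self.overjet,
            self.midline_shift,
            self.rest_exposure,
            self.gingival_display,
            self.eline_offset,
        ]
        if not np.all(np.isfinite(scalars)):
            raise PhantomConstructionError("truth parameters must be finite")

    def to_dict(self) -> dict:
        return {
            "tooth_widths": {str(k): float(v) for k, v in self.tooth_widths.items()},
            "incisor_lengths": {
                str(k): float(v) for k, v in self.incisor_lengths.items()
            },
            "overbite": float(self.overbite),
            "overjet": float(self.overjet),
            "midline_shift": float(self.midline_shift),
            "rest_exposure": float(self.rest_exposure),
            "gingival_display": float(self.gingival_display),
            "eline_offset": float(self.eline_offset),
            "nasolabial_deg": float(self.nasolabial_deg),
            "pose_matrix": self.pose.to_matrix().tolist(),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomTruth":
        return cls(
            tooth_widths={int(k): float(v) for k, v in d["tooth_widths"].items()},
            incisor_lengths={
                int(k): float(v) for k, v in d["incisor_lengths"].items()
            },
            overbite=d["overbite"],
            overjet=d["overjet"],
            midline_shift=d["midline_shift"],
            rest_exposure=d["rest_exposure"],
            gingival_display=d["gingival_display"],
            eline_offset=d["eline_offset"],
            nasolabial_deg=d["nasolabial_deg"],
            pose=RigidTransform.from_matrix(np.asarray(d["pose_matrix"])),
            seed=int(d.get("seed", 0)),
        )

    def expected(self, config: Optional[AnalysisConfig] = None) -> Dict[str, float]:
        """Parameter values the analyzer should report for this truth,
        keyed like :class:`EstheticReport` values."""
        cfg = config or AnalysisConfig()
        out: Dict[str, float] = {}
        for fdi in cfg.length_teeth:
            out[f"tooth_length[{fdi}]"] = self.incisor_lengths[fdi]
        for fdi in cfg.width_teeth:
            out[f"tooth_width[{fdi}]"] = self.tooth_widths[fdi]
        out["overbite"] = self.overbite
        out["overjet"] = self.overjet
        for fdi in cfg.rest_exposure_teeth:
            out[f"incisor_exposure_rest[{fdi}]"] = self.rest_exposure
        for fdi in cfg.gingival_teeth:
            # the smile lip is placed against tooth 11's zenith; a tooth
            # with a different crown length shows a different display
            delta = self.incisor_lengths[11] - self.incisor_lengths[fdi]
            out[f"gingival_exposure_smile[{fdi}]"] = max(
                self.gingival_display + delta, 0.0
            )
        out["midline_deviation"] = self.midline_shift
        out["eline_distance"] = self.eline_offset
        out["nasolabial_angle"] = self.nasolabial_deg
        return out


@dataclass
class PhantomCase:
    """Generated inputs of one synthetic subject, in posed world
    coordinates (what a registered scan set would provide)."""

    landmarks: LandmarkSet
    tooth_contours: Dict[int, ToothContour]
    lip_contours: Dict[str, Polyline3D]
    face_mesh: TriMesh
    upper_arch_mesh: TriMesh
    lower_arch_mesh: TriMesh
    truth: PhantomTruth


def default_truth(**overrides) -> PhantomTruth:
    """The normal-anatomy reference phantom (population-typical values)."""
    return PhantomTruth(**overrides)


def random_rigid_transform(rng: np.random.Generator, max_translation: float = 50.0) -> RigidTransform:
    """Uniformly random proper rotation plus bounded random translation."""
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    rotation = Rotation.from_quat(quat).as_matrix()
    translation = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(rotation, translation)


def random_truth(
    rng: np.random.Generator, posed: bool = True, seed: int = 0
) -> PhantomTruth:
    """Sample a plausible subject around population-typical anatomy.

    Dispersions approximate between-subject variability in healthy
    dentitions (crown dimensions ~0.5 mm SD, occlusal relations ~0.7 mm,
    nasolabial angle ~8 deg)."""
    widths = {
        13: rng.normal(7.8, 0.4),
        12: rng.normal(6.6, 0.4),
        11: rng.normal(8.5, 0.5),
        21: rng.normal(8.5, 0.5),
        22: rng.normal(6.6, 0.4),
        23: rng.normal(7.8, 0.4),
    }
    length = rng.normal(10.5, 0.8)
    return PhantomTruth(
        tooth_widths={k: float(max(v, 4.0)) for k, v in widths.items()},
        incisor_lengths={11: float(max(length, 7.0)), 21: float(max(length, 7.0))},
        overbite=float(rng.normal(2.5, 0.7)),
        overjet=float(rng.normal(3.0, 0.7)),
        midline_shift=float(rng.normal(0.0, 1.0)),
        rest_exposure=float(rng.normal(3.0, 1.2)),
        gingival_display=float(rng.uniform(0.5, 2.5)),
        eline_offset=float(rng.normal(1.2, 1.0)),
        nasolabial_deg=float(np.clip(rng.normal(96.0, 8.0), 65.0, 135.0)),
        pose=random_rigid_transform(rng) if posed else RigidTransform.identity(),
        seed=seed,
    )


def _rounded_rectangle(
    x_min: float,
    x_max: float,
    z_min: float,
    z_max: float,
    y: float,
    n_side: int = 8,
    n_arc: int = 4,
) -> np.ndarray:
    """Closed rounded-rectangle outline in the XZ plane at depth ``y``.

    Sides are exactly straight at the four extreme coordinates, so the
    outline attains the requested width/length at polyline vertices; the
    first vertex is the bottom-center so the Zmin tie-break lands there.
    Traversal is bottom -> right-side (-X) -> top -> left-side (+X).
    """
    w = x_max - x_min
    h = z_max - z_min
    if w <= 0 or h <= 0:
        raise PhantomConstructionError("rounded rectangle needs positive extent")
    r = min(1.0, 0.3 * min(w, h))
    cx = 0.5 * (x_min + x_max)

    def seg(p0, p1, n, include_start):
        ts = np.linspace(0.0, 1.0, n + 1)
        if not include_start:
            ts = ts[1:]
        return [(p0[0] + t * (p1[0] - p0[0]), p0[1] + t * (p1[1] - p0[1])) for t in ts]

    def arc(center, a0, a1, n):
        angles = np.linspace(a0, a1, n + 1)[1:-1]  # corners' tangent points
        return [
            (center[0] + r * np.cos(a), center[1] + r * np.sin(a)) for a in angles
        ]

    pts2: List = []
    half = max(n_side // 2, 1)
    # bottom edge, starting at center and heading toward -X
    pts2 += seg((cx, z_min), (x_min + r, z_min), half, include_start=True)
    pts2 += arc((x_min + r, z_min + r), -0.5 * np.pi, -np.pi, n_arc)
    pts2 += seg((x_min, z_min + r), (x_min, z_max - r), n_side, include_start=True)
    pts2 += arc((x_min + r, z_max - r), np.pi, 0.5 * np.pi, n_arc)
    pts2 += seg((x_min + r, z_max), (x_max - r, z_max), n_side, include_start=True)
    pts2 += arc((x_max - r, z_max - r), 0.5 * np.pi, 0.0, n_arc)
    pts2 += seg((x_max, z_max - r), (x_max, z_min + r), n_side, include_start=True)
    pts2 += arc((x_max - r, z_min + r), 0.0, -0.5 * np.pi, n_arc)
    pts2 += seg((x_max - r, z_min), (cx, z_min), half, include_start=True)[:-1]
    arr = np.array([[x, y, z] for x, z in pts2])
    # drop any duplicate introduced by tiny radii
    keep = np.ones(len(arr), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(arr, axis=0), axis=1) > 1e-12
    return arr[keep]


def _lip_polyline(z: float, n: int = 41) -> Polyline3D:
    """Inferior lip border: constant height, gentle posterior curve at
    the corners of the mouth."""
    xs = np.linspace(-_LIP_X_SPAN, _LIP_X_SPAN, n)
    ys = _LIP_FRONT_Y + 0.004 * xs**2
    zs = np.full(n, z)
    return Polyline3D(np.column_stack([xs, ys, zs]), closed=False)


def _ellipsoid_face(landmarks: Dict[str, np.ndarray]) -> TriMesh:
    """Coarse head shell (icosphere scaled to head proportions) with the
    landmark coordinates appended as exact vertices."""
    import trimesh as _trimesh

    sphere = _trimesh.creation.icosphere(subdivisions=2, radius=1.0)
    verts = sphere.vertices * np.array([75.0, 95.0, 110.0]) + np.array([0.0, 30.0, -30.0])
    verts = np.vstack([verts, np.array(list(landmarks.values()))])
    return TriMesh(vertices=verts, faces=np.asarray(sphere.faces))


def _extrude_contour(outline: Polyline3D, depth: float = 1.5) -> TriMesh:
    """Thin prism from a closed convex contour, extruded along +Y."""
    front = outline.points
    back = front + np.array([0.0, depth, 0.0])
    n = len(front)
    verts = np.vstack([front, back, front.mean(axis=0), back.mean(axis=0)])
    ci_f, ci_b = 2 * n, 2 * n + 1
    faces = []
    for i in range(n):
        j = (i + 1) % n
        faces.append([i, j, n + i])
        faces.append([j, n + j, n + i])
        faces.append([ci_f, j, i])        # front cap fan
        faces.append([ci_b, n + i, n + j])  # back cap fan
    return TriMesh(vertices=verts, faces=np.asarray(faces))


def _canonical_layout(truth: PhantomTruth):
    """Place all landmarks and contours in the canonical frame so that
    every parameter equals its truth value analytically."""
    lm: Dict[str, np.ndarray] = {
        "pupil_left": np.array([_PUPIL_HALF_SPAN, 0.0, _PUPIL_HEIGHT]),
        "pupil_right": np.array([-_PUPIL_HALF_SPAN, 0.0, _PUPIL_HEIGHT]),
        "infraorbital_left": _INFRAORBITAL_LEFT.copy(),
        "ear_superior_left": _EAR_LEFT.copy(),
        "ear_superior_right": _EAR_RIGHT.copy(),
        "nasal_tip": _NASAL_TIP.copy(),
        "nasal_base": _NASAL_BASE.copy(),
        "pogonion": _POGONION.copy(),
    }

    # upper lip midpoint: height fixed, Y set by the E-line offset
    t = (_LIP_MIDPOINT_Z - _NASAL_TIP[2]) / (_POGONION[2] - _NASAL_TIP[2])
    y_line = _NASAL_TIP[1] + t * (_POGONION[1] - _NASAL_TIP[1])
    lip_mid = np.array([0.0, y_line + truth.eline_offset, _LIP_MIDPOINT_Z])
    lm["upper_lip_midpoint"] = lip_mid

    # nasal columella: rotate the base->lip direction by the nasolabial
    # angle about +X (sagittal plane), so the angle at the base is exact
    u = lip_mid - _NASAL_BASE
    u /= np.linalg.norm(u)
    theta = np.radians(truth.nasolabial_deg)
    rot_x = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, np.cos(-theta), -np.sin(-theta)],
            [0.0, np.sin(-theta), np.cos(-theta)],
        ]
    )
    lm["nasal_columella"] = _NASAL_BASE + _COLUMELLA_ARM * (rot_x @ u)

    # upper anterior teeth, mesial-to-distal from the shifted midline
    s = truth.midline_shift
    teeth: Dict[int, ToothContour] = {}

    def z_range(fdi: int) -> tuple:
        length = truth.incisor_lengths.get(fdi, _OTHER_TOOTH_LENGTH.get(fdi, 9.5))
        return _UPPER_INCISAL_Z, _UPPER_INCISAL_Z + length

    x_hi = s  # running distal edge for the subject's right side (-X)
    for fdi in (11, 12, 13):
        w = truth.tooth_widths[fdi]
        z0, z1 = z_range(fdi)
        teeth[fdi] = ToothContour(
            fdi, Polyline3D(_rounded_rectangle(x_hi - w, x_hi, z0, z1, _UPPER_TEETH_Y), closed=True)
        )
        x_hi -= w
    x_lo = s
    for fdi in (21, 22, 23):
        w = truth.tooth_widths[fdi]
        z0, z1 = z_range(fdi)
        teeth[fdi] = ToothContour(
            fdi, Polyline3D(_rounded_rectangle(x_lo, x_lo + w, z0, z1, _UPPER_TEETH_Y), closed=True)
        )
        x_lo += w

    # lower central incisors: top edge realizes the overbite, contour
    # plane depth realizes the overjet
    z_top = _UPPER_INCISAL_Z + truth.overbite
    y_lower = _UPPER_TEETH_Y + truth.overjet
    for fdi, (lo, hi) in {
        41: (s - _LOWER_INCISOR_WIDTH, s),
        31: (s, s + _LOWER_INCISOR_WIDTH),
    }.items():
        teeth[fdi] = ToothContour(
            fdi,
            Polyline3D(
                _rounded_rectangle(lo, hi, z_top - _LOWER_INCISOR_LENGTH, z_top, y_lower),
                closed=True,
            ),
        )

    # lip borders: constant height across the anterior region, so the
    # exposure formulas hold exactly at any X within the incisor span
    zenith_11 = _UPPER_INCISAL_Z + truth.incisor_lengths[11]
    lips = {
        "rest": _lip_polyline(_UPPER_INCISAL_Z + truth.rest_exposure),
        "smile": _lip_polyline(zenith_11 + truth.gingival_display),
        "closed_lip": _lip_polyline(_UPPER_INCISAL_Z - 2.5),
    }
    if abs(truth.midline_shift) + truth.tooth_widths[11] > _LIP_X_SPAN:
        raise PhantomConstructionError(
            "midline shift pushes the central incisors outside the lip span"
        )
    return lm, teeth, lips


def generate_phantom(truth: Optional[PhantomTruth] = None) -> PhantomCase:
    """Generate one synthetic subject in world (posed) coordinates.

    Deterministic: the same truth (including pose and seed) always
    produces byte-identical geometry.
    """
    truth = truth if truth is not None else default_truth()
    lm, teeth, lips = _canonical_layout(truth)

    face = _ellipsoid_face(lm)
    upper_ids = [13, 12, 11, 21, 22, 23]
    upper_meshes = [_extrude_contour(teeth[f].outline) for f in upper_ids]
    lower_meshes = [_extrude_contour(teeth[f].outline) for f in (41, 31)]

    def merge(meshes: Sequence[TriMesh]) -> TriMesh:
        verts, faces, offset = [], [], 0
        for m in meshes:
            verts.append(m.vertices)
            faces.append(m.faces + offset)
            offset += m.n_vertices
        return TriMesh(np.vstack(verts), np.vstack(faces))

    pose = truth.pose
    landmarks = apply_transform(
        LandmarkSet(points=lm, expression="closed_lip"), pose
    )
    return PhantomCase(
        landmarks=landmarks,
        tooth_contours={f: apply_transform(c, pose) for f, c in teeth.items()},
        lip_contours={k: apply_transform(p, pose) for k, p in lips.items()},
        face_mesh=apply_transform(face, pose),
        upper_arch_mesh=apply_transform(merge(upper_meshes), pose),
        lower_arch_mesh=apply_transform(merge(lower_meshes), pose),
        truth=truth,
    )


def analyze_case(case: PhantomCase, config: Optional[AnalysisConfig] = None):
    """Run the full measurement pipeline on a (possibly posed) case."""
    subject = make_case(case.landmarks, case.tooth_contours, case.lip_contours)
    return full_report(subject, config)


def export_phantom(case: PhantomCase, out_dir: Union[str, Path]) -> dict:
    """Write the full file set of one phantom subject; returns the paths."""
    from . import mesh_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "face_mesh": out / "face_closed_lip.obj",
        "upper_arch": out / "upper_arch.ply",
        "lower_arch": out / "lower_arch.ply",
        "landmarks": out / "landmarks_closed_lip.json",
        "tooth_contours": out / "tooth_contours.json",
        "lip_contours": out / "lip_contours.json",
        "truth": out / "truth.json",
    }
    mesh_io.write_mesh(case.face_mesh, paths["face_mesh"], "obj")
    mesh_io.write_mesh(case.upper_arch_mesh, paths["upper_arch"], "ply")
    mesh_io.write_mesh(case.lower_arch_mesh, paths["lower_arch"], "ply")
    mesh_io.write_landmarks(case.landmarks, paths["landmarks"])
    mesh_io.write_contours(
        [(str(f), c) for f, c in sorted(case.tooth_contours.items())],
        paths["tooth_contours"],
    )
    label = {v: k for k, v in mesh_io.LIP_LABEL_TO_EXPRESSION.items()}
    mesh_io.write_contours(
        [(label[k], p) for k, p in case.lip_contours.items()], paths["lip_contours"]
    )
    paths["truth"].write_text(json.dumps(case.truth.to_dict(), indent=2))
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Simulated multi-rater reproducibility study


@dataclass
class RaterStudy:
    """Measurements indexed (subject, rater, parameter), no missing cells."""

    measurements: np.ndarray
    parameters: List[str]
    n_subjects: int
    n_raters: int

    def __post_init__(self) -> None:
        self.measurements = np.asarray(self.measurements, dtype=float)
        expected = (self.n_subjects, self.n_raters, len(self.parameters))
        if self.measurements.shape != expected:
            raise ValueError(
                f"measurements shape {self.measurements.shape} != {expected}"
            )
        if self.n_raters < 2:
            raise ValueError("a rater study needs at least 2 raters")
        if not np.all(np.isfinite(self.measurements)):
            raise ValueError("rater study contains missing/non-finite cells")

    def matrix(self, parameter: str) -> np.ndarray:
        """(n_subjects, n_raters) matrix for one parameter."""
        try:
            j = self.parameters.index(parameter)
        except ValueError:
            raise KeyError(f"unknown parameter {parameter!r}") from None
        return self.measurements[:, :, j]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for s in range(self.n_subjects):
            for r in range(self.n_raters):
                for j, p in enumerate(self.parameters):
                    rows.append(
                        {
                            "subject": s,
                            "rater": r,
                            "parameter": p,
                            "value": self.measurements[s, r, j],
                        }
                    )
        return pd.DataFrame(rows)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "RaterStudy":
        import pandas as pd

        df = pd.read_csv(path)
        params = list(dict.fromkeys(df["parameter"]))
        n_s = df["subject"].nunique()
        n_r = df["rater"].nunique()
        arr = np.full((n_s, n_r, len(params)), np.nan)
        pidx = {p: j for j, p in enumerate(params)}
        sidx = {s: i for i, s in enumerate(sorted(df["subject"].unique()))}
        ridx = {r: i for i, r in enumerate(sorted(df["rater"].unique()))}
        for _, row in df.iterrows():
            arr[sidx[row["subject"]], ridx[row["rater"]], pidx[row["parameter"]]] = row[
                "value"
            ]
        return cls(arr, params, n_s, n_r)


def _study_values(report) -> Dict[str, float]:
    """One representative scalar per parameter family (central incisor 11
    for per-tooth parameters), mirroring a per-subject study row."""
    keyed = {
        "tooth_length": "tooth_length[11]",
        "tooth_width": "tooth_width[11]",
        "overbite": "overbite",
        "overjet": "overjet",
        "incisor_exposure_rest": "incisor_exposure_rest[11]",
        "gingival_exposure_smile": "gingival_exposure_smile[11]",
        "midline_deviation": "midline_deviation",
        "eline_distance": "eline_distance",
        "nasolabial_angle": "nasolabial_angle",
    }
    out = {}
    for family, key in keyed.items():
        if key not in report.values:
            raise DentofaceError(f"report lacks {key}: {report.missing.get(key)}")
        out[family] = report.values[key].value
    return out


def _perturb_case(case: PhantomCase, rng: np.random.Generator,
                  landmark_sigma: float, contour_sigma: float) -> PhantomCase:
    lm = {
        name: p + rng.normal(0.0, landmark_sigma, size=3)
        for name, p in case.landmarks.points.items()
    }
    teeth = {
        f: ToothContour(
            f,
            Polyline3D(
                c.outline.points + rng.normal(0.0, contour_sigma, c.outline.points.shape),
                closed=True,
            ),
        )
        for f, c in case.tooth_contours.items()
    }
    lips = {
        k: Polyline3D(
            p.points + rng.normal(0.0, contour_sigma, p.points.shape), closed=p.closed
        )
        for k, p in case.lip_contours.items()
    }
    return dataclasses.replace(
        case,
        landmarks=LandmarkSet(points=lm, expression=case.landmarks.expression),
        tooth_contours=teeth,
        lip_contours=lips,
    )


def simulate_raters(
    truths: Sequence[PhantomTruth],
    n_raters: int = 3,
    landmark_sigma: float = 0.1,
    contour_sigma: float = 0.05,
    seed: int = 0,
    config: Optional[AnalysisConfig] = None,
) -> RaterStudy:
    """Re-enact a multi-rater reproducibility study on phantom subjects.

    Each subject x rater cell independently perturbs the landmark picks
    (isotropic Gaussian, ``landmark_sigma`` mm) and every contour vertex
    (``contour_sigma`` mm), reruns the whole pipeline and records one
    value per parameter family.  A pipeline failure on a perturbed case
    is retried with a fresh perturbation (up to 5 times).
    """
    if landmark_sigma < 0 or contour_sigma < 0:
        raise ValueError("noise sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    params = list(PARAMETER_FAMILIES)
    data = np.empty((len(truths), n_raters, len(params)))
    for i, truth in enumerate(truths):
        base = generate_phantom(truth)
        for r in range(n_raters):
            for attempt in range(5):
                perturbed = _perturb_case(base, rng, landmark_sigma, contour_sigma)
                try:
                    values = _study_values(analyze_case(perturbed, config))
                    break
                except DentofaceError:
                    if attempt == 4:
                        raise
            data[i, r] = [values[p] for p in params]
    return RaterStudy(data, params, len(truths), n_raters)
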