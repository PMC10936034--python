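"""The nine esthetic parameter formulas, computed in the canonical frame.

Grouped as in clinical use:

* tooth-related — upper-incisor length, upper-anterior-tooth width,
  overbite, overjet;
* dental-facial — incisor exposure at rest, gingival exposure when
  smiling, dental-midline deviation from the facial midline;
* facial — upper lip to E-line distance, nasolabial angle.

All formulas assume the canonical axes (+Z superior, +Y posterior,
+X subject's left):

======================  =====================================================
parameter               formula (canonical coordinates)
======================  =====================================================
tooth length            L = Zmax - Zmin of the tooth contour
tooth width             W = Xmax - Xmin of the tooth contour
overbite                Zmax(lower incisor) - Zmin(upper incisor);
                        negative = open bite
overjet                 Y at Zmax(lower) - Y at Zmin(upper); positive for
                        normal anterior overjet (+Y posterior)
incisor exposure, rest  Zmin of the rest lip border at the X of the tooth's
                        Zmin vertex, minus the tooth's Zmin; negative when
                        the incisor is not exposed (no clamping)
gingival exposure       Zmin of the smile lip border at the X of the tooth's
                        Zmax vertex, minus the tooth's Zmax; clamped to 0
                        when the lip covers the gingiva
midline deviation       X of the dental midline (facial midline is X = 0)
E-line distance         Y(lip midpoint) - Y(nasal-tip-to-pogonion line at
                        the lip midpoint's height); positive = lip posterior
                        to the E-line
nasolabial angle        angle at the nasal base between the columella and
                        the upper-lip midpoint directions
======================  =====================================================

Midline deviation supports two modes.  ``"mesial"`` (default) averages the
mesial-most X of the two upper central incisors, which is the dental-midline
position.  ``"literal"`` averages the minimum X of both incisors, which is
offset from the midline by half a tooth width under any single X-direction
convention; it is retained for comparison with conventions that measure
both teeth from the same side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from .errors import CoverageError, DentofaceError, MissingInputError
from .frame import CanonicalFrame, apply_transform, build_frame
from .geometry import angle_at_vertex, contour_extremum, contour_plane_intersection, line_y_at_z
from .mesh_io import (
    EstheticReport,
    LandmarkSet,
    ParameterValue,
    Polyline3D,
    ToothContour,
)

__all__ = [
    "AnalysisConfig",
    "SubjectCase",
    "make_case",
    "tooth_length",
    "tooth_width",
    "overbite",
    "overjet",
    "incisor_exposure_rest",
    "gingival_exposure_smile",
    "midline_deviation",
    "eline_distance",
    "nasolabial_angle",
    "full_report",
]

PARAMETER_FAMILIES = (
    "tooth_length",
    "tooth_width",
    "overbite",
    "overjet",
    "incisor_exposure_rest",
    "gingival_exposure_smile",
    "midline_deviation",
    "eline_distance",
    "nasolabial_angle",
)


@dataclass
class AnalysisConfig:
    """Which teeth feed each parameter, plus formula modes.

    Defaults measure lengths on the central incisors, widths on all six
    upper anterior teeth, occlusion on 11 vs 41, and exposures on the
    central incisors.
    """

    length_teeth: Tuple[int, ...] = (11, 21)
    width_teeth: Tuple[int, ...] = (13, 12, 11, 21, 22, 23)
    overbite_pair: Tuple[int, int] = (11, 41)
    overjet_pair: Tuple[int, int] = (11, 41)
    rest_exposure_teeth: Tuple[int, ...] = (11, 21)
    gingival_teeth: Tuple[int, ...] = (11, 21)
    midline_mode: str = "mesial"  # or "literal"
    use_icp: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "length_teeth": list(self.length_teeth),
            "width_teeth": list(self.width_teeth),
            "overbite_pair": list(self.overbite_pair),
            "overjet_pair": list(self.overjet_pair),
            "rest_exposure_teeth": list(self.rest_exposure_teeth),
            "gingival_teeth": list(self.gingival_teeth),
            "midline_mode": self.midline_mode,
            "use_icp": self.use_icp,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = dict(d)
        for k in (
            "length_teeth",
            "width_teeth",
            "overbite_pair",
            "overjet_pair",
            "rest_exposure_teeth",
            "gingival_teeth",
        ):
            if k in kwargs:
                kwargs[k] = tuple(int(t) for t in kwargs[k])
        return cls(**kwargs)


@dataclass
class SubjectCase:
    """One virtual patient, fully expressed in its canonical frame."""

    frame: CanonicalFrame
    tooth_contours: Dict[int, ToothContour] = field(default_factory=dict)
    lip_contours: Dict[str, Polyline3D] = field(default_factory=dict)
    landmarks: Optional[LandmarkSet] = None


def make_case(
    landmarks: LandmarkSet,
    tooth_contours: Dict[int, ToothContour],
    lip_contours: Dict[str, Polyline3D],
) -> SubjectCase:
    """Build the canonical frame from ``landmarks`` and express every
    input in it.  ``lip_contours`` is keyed by expression
    ("rest", "smile", "closed_lip")."""
    frame = build_frame(landmarks)
    t = frame.world_to_canonical
    return SubjectCase(
        frame=frame,
        tooth_contours={fdi: apply_transform(c, t) for fdi, c in tooth_contours.items()},
        lip_contours={k: apply_transform(p, t) for k, p in lip_contours.items()},
        landmarks=apply_transform(landmarks, t),
    )


def _tooth(case: SubjectCase, fdi: int) -> ToothContour:
    try:
        return case.tooth_contours[fdi]
    except KeyError:
        raise MissingInputError(f"no contour for tooth {fdi}") from None


def _lip(case: SubjectCase, expression: str) -> Polyline3D:
    try:
        return case.lip_contours[expression]
    except KeyError:
        raise MissingInputError(
            f"no upper-lip border contour for expression {expression!r}"
        ) from None


def _landmark(case: SubjectCase, name: str):
    if case.landmarks is None:
        raise MissingInputError("case has no landmarks")
    return case.landmarks[name]


def tooth_length(case: SubjectCase, fdi: int) -> float:
    """Crown length: Zmax - Zmin of the gingival-margin contour (mm)."""
    outline = _tooth(case, fdi).outline
    zmax = contour_extremum(outline, "Z", "max").value
    zmin = contour_extremum(outline, "Z", "min").value
    return zmax - zmin


def tooth_width(case: SubjectCase, fdi: int) -> float:
    """Crown width: Xmax - Xmin of the gingival-margin contour (mm)."""
    outline = _tooth(case, fdi).outline
    xmax = contour_extremum(outline, "X", "max").value
    xmin = contour_extremum(outline, "X", "min").value
    return xmax - xmin


def overbite(case: SubjectCase, upper_fdi: int = 11, lower_fdi: int = 41) -> float:
    """Vertical incisor overlap: Zmax(lower) - Zmin(upper) (mm).

    Positive when the upper incisal edge reaches below the lower incisal
    edge level; negative in open bite."""
    upper = _tooth(case, upper_fdi).outline
    lower = _tooth(case, lower_fdi).outline
    return (
        contour_extremum(lower, "Z", "max").value
        - contour_extremum(upper, "Z", "min").value
    )


def overjet(case: SubjectCase, upper_fdi: int = 11, lower_fdi: int = 41) -> float:
    """Sagittal incisor distance: Y at the lower incisor's Zmax vertex
    minus Y at the upper incisor's Zmin vertex (mm).  Positive for normal
    anterior overjet under the +Y-posterior convention."""
    upper = _tooth(case, upper_fdi).outline
    lower = _tooth(case, lower_fdi).outline
    y_lower = contour_extremum(lower, "Z", "max").point[1]
    y_upper = contour_extremum(upper, "Z", "min").point[1]
    return float(y_lower - y_upper)


def _lip_z_at(case: SubjectCase, expression: str, x0: float) -> float:
    lip = _lip(case, expression)
    crossings = contour_plane_intersection(lip, "X", x0)
    if len(crossings) == 0:
        xs = lip.points[:, 0]
        raise CoverageError(
            f"{expression} lip contour (X range [{xs.min():.2f}, {xs.max():.2f}] mm) "
            f"does not cross X = {x0:.2f} mm"
        )
    return float(crossings[:, 2].min())


def incisor_exposure_rest(case: SubjectCase, fdi: int = 11) -> float:
    """Incisor exposure at rest (mm): lip border height above the incisal
    edge at the edge's X position; negative when the lip covers the edge."""
    edge = contour_extremum(_tooth(case, fdi).outline, "Z", "min")
    lip_z = _lip_z_at(case, "rest", float(edge.point[0]))
    return lip_z - edge.value


def gingival_exposure_smile(case: SubjectCase, fdi: int = 11) -> float:
    """Gingival exposure when smiling (mm): smile lip border height above
    the gingival zenith at the zenith's X position; clamped to 0 when the
    lip covers the gingiva."""
    zenith = contour_extremum(_tooth(case, fdi).outline, "Z", "max")
    lip_z = _lip_z_at(case, "smile", float(zenith.point[0]))
    return max(lip_z - zenith.value, 0.0)


def midline_deviation(case: SubjectCase, mode: str = "mesial") -> float:
    """Signed X offset of the dental midline from the facial midline (mm).

    The facial midline is X = 0 by frame construction.  ``mode="mesial"``
    averages the mesial-most X of the two central incisors (whichever
    incisor sits on the -X side contributes its Xmax, the other its
    Xmin).  ``mode="literal"`` averages Xmin of both.
    """
    c11 = _tooth(case, 11).outline
    c21 = _tooth(case, 21).outline
    if mode == "literal":
        return 0.5 * (
            contour_extremum(c11, "X", "min").value
            + contour_extremum(c21, "X", "min").value
        )
    if mode != "mesial":
        raise ValueError(f"midline mode must be 'mesial' or 'literal', got {mode!r}")
    # identify sides by centroid so the result is robust to large shifts
    if c11.points[:, 0].mean() <= c21.points[:, 0].mean():
        right, left = c11, c21
    else:
        right, left = c21, c11
    return 0.5 * (
        contour_extremum(right, "X", "max").value
        + contour_extremum(left, "X", "min").value
    )


def eline_distance(case: SubjectCase) -> float:
    """Upper lip to E-line distance along Y (mm).

    The E-line joins the nasal tip and the soft-tissue pogonion; the value
    is Y(lip midpoint) minus the line's Y at the lip midpoint's height.
    Positive = lip posterior to (behind) the E-line."""
    tip = _landmark(case, "nasal_tip")
    pog = _landmark(case, "pogonion")
    lip = _landmark(case, "upper_lip_midpoint")
    return float(lip[1]) - line_y_at_z(tip, pog, float(lip[2]))


def nasolabial_angle(case: SubjectCase) -> float:
    """Nasolabial angle (degrees): at the nasal base, between the columella
    and the upper-lip-midpoint directions."""
    return angle_at_vertex(
        _landmark(case, "nasal_columella"),
        _landmark(case, "nasal_base"),
        _landmark(case, "upper_lip_midpoint"),
    )


def full_report(case: SubjectCase, config: Optional[AnalysisConfig] = None) -> EstheticReport:
    """Measure every configured parameter; parameters that cannot be
    computed are listed under ``missing`` with the reason, never silently
    dropped."""
    cfg = config or AnalysisConfig()
    report = EstheticReport(frame_provenance=case.frame.provenance())
    report.metadata["config"] = cfg.to_dict()

    def attempt(parameter: str, unit: str, fn, tooth: Optional[int] = None) -> None:
        key = parameter if tooth is None else f"{parameter}[{tooth}]"
        try:
            value = fn()
        except DentofaceError as exc:
            report.missing[key] = str(exc)
            return
        report.add(ParameterValue(parameter, float(value), unit, tooth))

    for fdi in cfg.length_teeth:
        attempt("tooth_length", "mm", lambda f=fdi: tooth_length(case, f), fdi)
    for fdi in cfg.width_teeth:
        attempt("tooth_width", "mm", lambda f=fdi: tooth_width(case, f), fdi)
    attempt("overbite", "mm", lambda: overbite(case, *cfg.overbite_pair))
    attempt("overjet", "mm", lambda: overjet(case, *cfg.overjet_pair))
    for fdi in cfg.rest_exposure_teeth:
        attempt(
            "incisor_exposure_rest",
            "mm",
            lambda f=fdi: incisor_exposure_rest(case, f),
            fdi,
        )
    for fdi in cfg.gingival_teeth:
        attempt(
            "gingival_exposure_smile",
            "mm",
            lambda f=fdi: gingival_exposure_smile(case, f),
            fdi,
        )
    attempt(
        "midline_deviation", "mm", lambda: midline_deviation(case, cfg.midline_mode)
    )
    attempt("eline_distance", "mm", lambda: eline_distance(case))
    attempt("nasolabial_angle", "deg", lambda: nasolabial_angle(case))
    return report
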