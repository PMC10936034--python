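"""The nine parameter formulas on constructed and phantom geometry."""

import numpy as np
import pytest

from dentoface.errors import CoverageError, MissingInputError
from dentoface.esthetics import (
    AnalysisConfig,
    SubjectCase,
    eline_distance,
    full_report,
    gingival_exposure_smile,
    incisor_exposure_rest,
    midline_deviation,
    nasolabial_angle,
    overbite,
    overjet,
    tooth_length,
    tooth_width,
)
from dentoface.frame import CanonicalFrame, RigidTransform
from dentoface.mesh_io import LandmarkSet, Polyline3D, ToothContour
from dentoface.phantom import (
    analyze_case,
    default_truth,
    generate_phantom,
    random_rigid_transform,
    random_truth,
)


def rectangle(x0, x1, z0, z1, y=0.0):
    return Polyline3D(
        [[x0, y, z0], [x1, y, z0], [x1, y, z1], [x0, y, z1]], closed=True
    )


def simple_case(**teeth_and_lips):
    """A bare canonical case from rectangle contours and flat lip lines."""
    frame = CanonicalFrame(
        world_to_canonical=RigidTransform.identity(),
        source_landmarks=LandmarkSet(points={}),
    )
    teeth = {
        fdi: ToothContour(fdi, outline)
        for fdi, outline in teeth_and_lips.get("teeth", {}).items()
    }
    return SubjectCase(
        frame=frame,
        tooth_contours=teeth,
        lip_contours=teeth_and_lips.get("lips", {}),
        landmarks=teeth_and_lips.get("landmarks"),
    )


def flat_lip(z, x_span=20.0):
    xs = np.linspace(-x_span, x_span, 21)
    return Polyline3D(np.column_stack([xs, np.full(21, -5.0), np.full(21, z)]))


# --- tooth dimensions --------------------------------------------------------


def test_length_and_width_of_rectangular_contour():
    case = simple_case(teeth={11: rectangle(2.0, 10.5, 0.0, 11.0)})
    assert tooth_length(case, 11) == 11.0
    assert tooth_width(case, 11) == 8.5


def test_degenerate_flat_contour_has_zero_length():
    flat = Polyline3D([[0, 0, 5.0], [4, 0, 5.0], [4, 1, 5.0]], closed=True)
    case = simple_case(teeth={11: flat})
    assert tooth_length(case, 11) == 0.0


def test_missing_contour_is_named_error():
    case = simple_case()
    with pytest.raises(MissingInputError, match="11"):
        tooth_length(case, 11)


# --- occlusion ---------------------------------------------------------------


def test_overbite_signs():
    # normal overlap: upper incisal edge below lower incisal edge level
    case = simple_case(
        teeth={11: rectangle(-8, 0, 0.0, 11.0), 41: rectangle(-5, 0, -7.0, 2.0)}
    )
    assert overbite(case, 11, 41) == 2.0
    # open bite: upper edge above the lower edge -> negative
    case = simple_case(
        teeth={11: rectangle(-8, 0, 3.0, 13.0), 41: rectangle(-5, 0, -9.0, 0.0)}
    )
    assert overbite(case, 11, 41) == -3.0


def test_overjet_from_z_extreme_vertices():
    upper = Polyline3D(
        [[-8, 2.0, 0.0], [0, 2.0, 0.0], [0, 2.0, 11.0], [-8, 2.0, 11.0]], closed=True
    )
    lower = Polyline3D(
        [[-5, 5.0, -7.0], [0, 5.0, -7.0], [0, 5.0, 2.0], [-5, 5.0, 2.0]], closed=True
    )
    case = simple_case(teeth={11: upper, 41: lower})
    assert overjet(case, 11, 41) == 3.0


def test_edge_to_edge_overjet_is_zero():
    case = simple_case(
        teeth={11: rectangle(-8, 0, 0.0, 11.0), 41: rectangle(-5, 0, -9.0, 0.0)}
    )
    assert overjet(case, 11, 41) == 0.0


# --- exposures ---------------------------------------------------------------


def test_incisor_exposure_positive_and_negative_unclamped():
    tooth = rectangle(-2.0, 4.0, 0.0, 11.0)  # Zmin vertex at x=-2 (first vertex)
    case = simple_case(teeth={11: tooth}, lips={"rest": flat_lip(3.0)})
    assert incisor_exposure_rest(case, 11) == 3.0
    case = simple_case(teeth={11: tooth}, lips={"rest": flat_lip(-2.0)})
    assert incisor_exposure_rest(case, 11) == -2.0  # unexposed stays negative


def test_gingival_exposure_clamped_at_zero():
    tooth = rectangle(-2.0, 4.0, 0.0, 10.0)  # zenith Zmax = 10
    case = simple_case(teeth={11: tooth}, lips={"smile": flat_lip(12.0)})
    assert gingival_exposure_smile(case, 11) == 2.0
    case = simple_case(teeth={11: tooth}, lips={"smile": flat_lip(8.0)})
    assert gingival_exposure_smile(case, 11) == 0.0  # covered gingiva -> zero


def test_exposure_out_of_lip_coverage_is_error():
    tooth = rectangle(30.0, 38.0, 0.0, 11.0)
    case = simple_case(teeth={11: tooth}, lips={"rest": flat_lip(3.0, x_span=20.0)})
    with pytest.raises(CoverageError, match="does not cross"):
        incisor_exposure_rest(case, 11)


# --- midline -----------------------------------------------------------------


def test_symmetric_midline_mesial_zero_literal_offset():
    case = simple_case(
        teeth={11: rectangle(-8.5, 0.0, 0, 11), 21: rectangle(0.0, 8.5, 0, 11)}
    )
    assert midline_deviation(case, "mesial") == 0.0
    # literal formula averages both Xmin values: (-8.5 + 0)/2
    assert midline_deviation(case, "literal") == -4.25


def test_shifted_midline_recovered_in_mesial_mode():
    s = 1.2
    case = simple_case(
        teeth={
            11: rectangle(s - 8.5, s, 0, 11),
            21: rectangle(s, s + 8.5, 0, 11),
        }
    )
    assert abs(midline_deviation(case, "mesial") - s) < 1e-12


# --- facial parameters -------------------------------------------------------


def facial_landmarks(lip_y=24.0):
    return LandmarkSet(
        points={
            "nasal_tip": [0.0, 20.0, 40.0],
            "pogonion": [0.0, 20.0, -40.0],
            "upper_lip_midpoint": [0.0, lip_y, 10.0],
            "nasal_base": [0.0, 0.0, 30.0],
            "nasal_columella": [0.0, -1.0, 31.0],
        }
    )


def test_eline_distance_sign_and_zero():
    case = simple_case(landmarks=facial_landmarks(lip_y=24.0))
    assert eline_distance(case) == 4.0  # lip posterior to the E-line
    case = simple_case(landmarks=facial_landmarks(lip_y=20.0))
    assert eline_distance(case) == 0.0


def test_nasolabial_angle_constructed():
    lm = LandmarkSet(
        points={
            "nasal_columella": [0.0, -1.0, 1.0],
            "nasal_base": [0.0, 0.0, 0.0],
            "upper_lip_midpoint": [0.0, -1.0, -1.0],
        }
    )
    case = simple_case(landmarks=lm)
    assert abs(nasolabial_angle(case) - 90.0) < 1e-12


# --- full report -------------------------------------------------------------


def test_full_phantom_report_covers_all_nine_families():
    report = analyze_case(generate_phantom(default_truth()))
    families = {v.parameter for v in report.values.values()}
    assert families == {
        "tooth_length",
        "tooth_width",
        "overbite",
        "overjet",
        "incisor_exposure_rest",
        "gingival_exposure_smile",
        "midline_deviation",
        "eline_distance",
        "nasolabial_angle",
    }
    assert report.missing == {}


def test_report_marks_missing_inputs_with_reason():
    case = generate_phantom(default_truth())
    del case.tooth_contours[41]
    report = analyze_case(case)
    assert "overbite" in report.missing
    assert "overjet" in report.missing
    assert "41" in report.missing["overbite"]
    # everything else still measured
    assert "tooth_length[11]" in report.values


def test_report_pose_invariance(rng):
    truth = default_truth()
    base = analyze_case(generate_phantom(truth))
    truth_posed = default_truth(pose=random_rigid_transform(rng))
    posed = analyze_case(generate_phantom(truth_posed))
    for key, pv in base.values.items():
        assert abs(posed.values[key].value - pv.value) < 1e-6


def test_parameter_recovery_on_random_truth(rng):
    truth = random_truth(rng)
    report = analyze_case(generate_phantom(truth))
    for key, expected in truth.expected().items():
        assert abs(report.values[key].value - expected) < 1e-6, key
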