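"""Canonical frame construction, rigid transforms and registration."""

import numpy as np
import pytest

from dentoface.errors import DegenerateGeometryError, LandmarkError, RegistrationError
from dentoface.frame import (
    RigidTransform,
    apply_transform,
    build_frame,
    icp_refine,
    kabsch_align,
)
from dentoface.mesh_io import FRAME_LANDMARKS, LandmarkSet, TriMesh
from dentoface.phantom import default_truth, generate_phantom, random_rigid_transform


def canonical_landmarks():
    """A landmark set already satisfying every canonical-frame condition."""
    return LandmarkSet(
        points={
            "pupil_left": [32.0, 0.0, 8.0],
            "pupil_right": [-32.0, 0.0, 8.0],
            "infraorbital_left": [33.0, 2.0, 0.0],
            "ear_superior_left": [70.0, 78.0, 0.0],
            "ear_superior_right": [-70.0, 78.0, 0.0],
        }
    )


# --- RigidTransform ----------------------------------------------------------


def test_identity_transform_is_bitwise_noop(rng):
    pts = rng.uniform(-10, 10, size=(7, 3))
    out = RigidTransform.identity().apply(pts)
    assert np.array_equal(out, pts)


def test_inverse_undoes_transform(rng):
    t = random_rigid_transform(rng)
    pts = rng.uniform(-100, 100, size=(50, 3))
    back = t.inverse().apply(t.apply(pts))
    assert np.abs(back - pts).max() < 1e-9


def test_transform_is_isometry(rng):
    t = random_rigid_transform(rng)
    a, b = rng.uniform(-50, 50, size=(2, 3))
    d_before = np.linalg.norm(a - b)
    d_after = np.linalg.norm(t.apply(a) - t.apply(b))
    assert abs(d_before - d_after) < 1e-9


def test_compose_matches_sequential_application(rng):
    t1, t2 = random_rigid_transform(rng), random_rigid_transform(rng)
    pts = rng.uniform(-20, 20, size=(10, 3))
    assert np.abs(t2.compose(t1).apply(pts) - t2.apply(t1.apply(pts))).max() < 1e-9


def test_reflection_rejected():
    reflect = np.diag([1.0, 1.0, -1.0])
    with pytest.raises(DegenerateGeometryError, match="reflection"):
        RigidTransform(reflect, np.zeros(3))


def test_matrix_and_json_round_trip(tmp_path, rng):
    t = random_rigid_transform(rng)
    assert np.abs(RigidTransform.from_matrix(t.to_matrix()).to_matrix() - t.to_matrix()).max() == 0
    path = tmp_path / "t.json"
    t.to_json(path)
    back = RigidTransform.from_json(path)
    assert np.abs(back.to_matrix() - t.to_matrix()).max() < 1e-12


# --- build_frame -------------------------------------------------------------


def test_frame_on_canonical_landmarks_is_identity():
    frame = build_frame(canonical_landmarks())
    t = frame.world_to_canonical
    assert np.abs(t.rotation - np.eye(3)).max() < 1e-9
    assert np.abs(t.translation).max() < 1e-9


def test_frame_postconditions_under_random_pose(rng):
    lm = canonical_landmarks()
    for _ in range(5):
        posed = apply_transform(lm, random_rigid_transform(rng))
        frame = build_frame(posed)
        t = frame.world_to_canonical
        for name in ("infraorbital_left", "ear_superior_left", "ear_superior_right"):
            assert abs(t.apply(posed[name])[2]) <= 1e-9
        midpoint = 0.5 * (posed["pupil_left"] + posed["pupil_right"])
        canon_mid = t.apply(midpoint)
        assert abs(canon_mid[0]) <= 1e-9
        assert abs(canon_mid[1]) <= 1e-9
        # pupils end up superior to the Frankfort plane
        assert t.apply(posed["pupil_left"])[2] > 0
        assert t.apply(posed["pupil_right"])[2] > 0


def test_frame_invariance_canonical_coordinates_unchanged(rng):
    lm = canonical_landmarks()
    base = build_frame(lm).world_to_canonical
    base_coords = {n: base.apply(p) for n, p in lm.points.items()}
    for _ in range(5):
        pose = random_rigid_transform(rng)
        posed = apply_transform(lm, pose)
        t = build_frame(posed).world_to_canonical
        for name, p in posed.points.items():
            assert np.abs(t.apply(p) - base_coords[name]).max() < 1e-9


def test_collinear_plane_points_rejected():
    lm = LandmarkSet(
        points={
            "pupil_left": [1.0, 0.0, 5.0],
            "pupil_right": [-1.0, 0.0, 5.0],
            "infraorbital_left": [0.0, 0.0, 0.0],
            "ear_superior_left": [1.0, 0.0, 0.0],
            "ear_superior_right": [2.0, 0.0, 0.0],
        }
    )
    with pytest.raises(DegenerateGeometryError, match="collinear"):
        build_frame(lm)


def test_missing_landmark_named_in_error():
    points = {n: p for n, p in canonical_landmarks().points.items() if n != "pupil_left"}
    with pytest.raises(LandmarkError, match="pupil_left"):
        build_frame(LandmarkSet(points=points))


# --- kabsch ------------------------------------------------------------------


def test_kabsch_identity_on_equal_sets(rng):
    pts = rng.uniform(-10, 10, size=(8, 3))
    t = kabsch_align(pts, pts)
    assert np.abs(t.rotation - np.eye(3)).max() < 1e-12
    assert np.abs(t.translation).max() < 1e-12


def test_kabsch_recovers_known_transform(rng):
    for _ in range(10):
        truth = random_rigid_transform(rng)
        src = rng.uniform(-30, 30, size=(12, 3))
        tgt = truth.apply(src)
        est = kabsch_align(src, tgt)
        assert np.abs(est.rotation - truth.rotation).max() < 1e-9
        assert np.abs(est.translation - truth.translation).max() < 1e-9


def test_kabsch_noisy_alignment_reduces_rmsd(rng):
    truth = random_rigid_transform(rng)
    src = rng.uniform(-30, 30, size=(40, 3))
    tgt = truth.apply(src) + rng.normal(0, 0.5, size=src.shape)
    est = kabsch_align(src, tgt)
    rmsd_before = np.sqrt(np.mean(np.sum((src - tgt) ** 2, axis=1)))
    rmsd_after = np.sqrt(np.mean(np.sum((est.apply(src) - tgt) ** 2, axis=1)))
    assert rmsd_after <= rmsd_before


def test_kabsch_rejects_degenerate_input(rng):
    with pytest.raises(RegistrationError):
        kabsch_align([[0, 0, 0], [1, 1, 1]], [[0, 0, 0], [1, 1, 1]])
    line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
    with pytest.raises(RegistrationError, match="collinear"):
        kabsch_align(line, line)


def test_kabsch_never_returns_reflection(rng):
    # a near-planar cloud plus its mirror image tempts SVD into det=-1
    src = rng.uniform(-10, 10, size=(20, 3))
    src[:, 2] *= 1e-6
    tgt = src.copy()
    tgt[:, 0] *= -1
    t = kabsch_align(src, tgt)
    assert np.linalg.det(t.rotation) > 0


# --- ICP ---------------------------------------------------------------------


def crown_mesh():
    case = generate_phantom(default_truth())
    return case.upper_arch_mesh


def small_perturbation(rng, max_deg=5.0, max_mm=2.0):
    """A small rigid motion, as between two nearly-aligned scans."""
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0, max_deg))
    rot = Rotation.from_rotvec(angle * axis).as_matrix()
    return RigidTransform(rot, rng.uniform(-max_mm, max_mm, size=3))


def test_icp_identity_on_equal_meshes():
    mesh = crown_mesh()
    result = icp_refine(mesh, mesh)
    assert result.rmsd < 1e-12
    assert np.abs(result.transform.to_matrix() - np.eye(4)).max() < 1e-9


def test_icp_recovers_small_perturbation():
    mesh = crown_mesh()
    angle = np.radians(2.0)
    rot = np.array(
        [
            [np.cos(angle), -np.sin(angle), 0.0],
            [np.sin(angle), np.cos(angle), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    truth = RigidTransform(rot, np.array([0.3, -0.2, 0.3]))
    moved = apply_transform(mesh, truth.inverse())
    result = icp_refine(moved, mesh, max_iter=100, tol=1e-10)
    assert np.abs(result.transform.to_matrix() - truth.to_matrix()).max() < 1e-3


def test_icp_rmsd_monotone_non_increasing(rng):
    mesh = crown_mesh()
    init = small_perturbation(rng)
    result = icp_refine(apply_transform(mesh, init), mesh, max_iter=30, tol=0.0)
    history = np.asarray(result.rmsd_history)
    assert len(history) > 2
    assert np.all(np.diff(history) <= 1e-12)


def test_icp_degenerate_correspondences_stop_cleanly():
    mesh = crown_mesh()
    cloud = TriMesh(vertices=mesh.vertices[:1], faces=np.zeros((0, 3)))
    result = icp_refine(cloud, mesh)  # one point: no rigid update possible
    assert result.n_iterations >= 1


# --- end-to-end pose invariance ---------------------------------------------


def test_apply_transform_preserves_structure(rng):
    case = generate_phantom(default_truth())
    t = random_rigid_transform(rng)
    mesh = apply_transform(case.face_mesh, t)
    assert np.array_equal(mesh.faces, case.face_mesh.faces)
    contour = apply_transform(case.tooth_contours[11], t)
    assert contour.tooth_fdi == 11
    assert contour.outline.closed
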