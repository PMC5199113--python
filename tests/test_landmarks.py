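"""Landmark tracking, Mahalanobis gating and Procrustes couch correction."""

import numpy as np
import pytest

from conftest import make_landmark_set, random_rotation
from hnmargin.grids import IntensityVolume
from hnmargin import landmarks as lm
from hnmargin.landmarks import (
    AlignmentError,
    LandmarkSet,
    RigidTransform,
    TrackingFailureError,
    extract_template,
    fit_geometric_model,
    flag_outliers,
    ncc_track,
    procrustes_align,
    residual_displacements,
)


# ---------------------------------------------------------------------------
# NCC tracking


def _blob_volume(center_idx, shape=(40, 40, 40), sigma=2.5):
    ax = [np.arange(s) for s in shape]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    d2 = (X - center_idx[0]) ** 2 + (Y - center_idx[1]) ** 2 + (Z - center_idx[2]) ** 2
    return IntensityVolume(np.exp(-d2 / (2 * sigma**2)), np.zeros(3), np.ones(3))


def test_ncc_identity_recovers_template_origin():
    vol = _blob_volume((20, 18, 22))
    template = vol.values[15:26, 13:24, 17:28]  # centered on the blob
    pos, score = ncc_track(template, vol, (np.zeros(3, int), np.array(vol.shape)))
    assert score == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(pos, [20.5, 18.5, 22.5])  # voxel-center mm


def test_ncc_recovers_integer_shift_against_exhaustive_oracle():
    rng = np.random.default_rng(0)
    base = rng.random((30, 30, 30))
    shift = np.array([2, -1, 3])
    shifted = np.roll(base, shift, axis=(0, 1, 2))
    vol = IntensityVolume(shifted, np.zeros(3), np.ones(3))
    template = base[10:17, 10:17, 10:17]

    pos, score = ncc_track(template, vol, (np.zeros(3, int), np.array([30, 30, 30])))
    # exhaustive NCC over all placements as the oracle
    best, argbest = -2.0, None
    t = (template - template.mean()) / template.std()
    for i in range(24):
        for j in range(24):
            for k in range(24):
                w = shifted[i:i + 7, j:j + 7, k:k + 7]
                if w.std() == 0:
                    continue
                c = np.mean((w - w.mean()) / w.std() * t)
                if c > best:
                    best, argbest = c, (i, j, k)
    expected_center = np.array(argbest) + 3 + 0.5
    np.testing.assert_allclose(pos, expected_center)
    assert argbest == (12, 9, 13)  # original corner (10,10,10) plus the shift
    assert score == pytest.approx(best, abs=1e-9)


def test_ncc_score_invariant_to_affine_intensity_rescaling():
    vol = _blob_volume((20, 20, 20))
    template = vol.values[16:25, 16:25, 16:25]
    window = (np.zeros(3, int), np.array(vol.shape))
    _, s0 = ncc_track(template, vol, window)
    _, s1 = ncc_track(3.7 * template + 42.0, vol, window)
    assert s1 == pytest.approx(s0, abs=1e-10)


def test_ncc_threshold_flags_landmark_invalid():
    # caller-side gating at the 0.7 acceptance threshold
    rng = np.random.default_rng(1)
    vol = IntensityVolume(rng.random((30, 30, 30)), np.zeros(3), np.ones(3))
    template = rng.random((7, 7, 7))  # unrelated pattern -> poor score
    _, score = ncc_track(template, vol, (np.zeros(3, int), np.array(vol.shape)))
    assert score < 0.7
    valid = score >= 0.7
    assert not valid


def test_ncc_failure_modes():
    vol = _blob_volume((20, 20, 20))
    with pytest.raises(TrackingFailureError):
        ncc_track(np.ones((5, 5, 5)), vol, (np.zeros(3, int), np.array(vol.shape)))
    template = vol.values[16:25, 16:25, 16:25]
    with pytest.raises(TrackingFailureError):
        ncc_track(template, vol, (np.array([38, 38, 38]), np.array([60, 60, 60])))
    with pytest.raises(TrackingFailureError):
        extract_template(vol, np.array([0.5, 0.5, 0.5]), half_size=5)


# ---------------------------------------------------------------------------
# Geometric model / outlier gating


def _training_sets(rng, n, base, cov=None):
    sets = []
    for f in range(n):
        pos = base.copy()
        if cov is not None:
            pos = pos + rng.multivariate_normal(np.zeros(3), cov, size=len(base))
        sets.append(make_landmark_set(pos, region="spine", fraction_id=f))
    return sets


def test_identical_training_sets_give_floor_covariances():
    base = np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0]], float)
    sets = _training_sets(np.random.default_rng(0), 5, base)
    model = fit_geometric_model(sets, {f"lm{i}": "bone" for i in range(3)})
    for e in model.edges:
        np.testing.assert_allclose(model.covariances[e], 1e-6 * np.eye(3), atol=1e-12)


def test_two_observation_edge_mean_is_closed_form():
    # single edge, difference vectors (0,0,0) and (2,0,0) -> mean (1,0,0)
    a = make_landmark_set([[0, 0, 0], [0, 0, 0]], fraction_id=0)
    b = make_landmark_set([[2, 0, 0], [0, 0, 0]], fraction_id=1)
    c = make_landmark_set([[1, 0, 0], [0, 0, 0]], fraction_id=2)
    model = fit_geometric_model([a, b, c], {"lm0": "bone", "lm1": "bone"})
    np.testing.assert_allclose(model.means[("lm0", "lm1")], [1, 0, 0])


def test_gaussian_edge_statistics_recovered_within_3se():
    rng = np.random.default_rng(42)
    n = 1000
    true_cov = np.diag([4.0, 1.0, 0.25])
    base = np.array([[0, 0, 0], [20, 0, 0]], float)
    sets = []
    for f in range(n):
        noise = rng.multivariate_normal(np.zeros(3), true_cov)
        sets.append(make_landmark_set(base + np.array([noise, np.zeros(3)]),
                                      fraction_id=f))
    model = fit_geometric_model(sets, {"lm0": "b", "lm1": "b"})
    e = ("lm0", "lm1")
    se_mean = np.sqrt(np.diag(true_cov) / n)
    np.testing.assert_array_less(np.abs(model.means[e] - [-20, 0, 0]), 3 * se_mean)
    se_var = np.diag(true_cov) * np.sqrt(2.0 / (n - 1))
    np.testing.assert_array_less(
        np.abs(np.diag(model.covariances[e]) - np.diag(true_cov)), 3 * se_var)


def test_unobserved_edge_dropped():
    base = np.array([[0, 0, 0], [10, 0, 0]], float)
    sets = _training_sets(np.random.default_rng(0), 4, base)
    for s in sets:
        s.valid[1] = False
    model = fit_geometric_model(sets, {"lm0": "b", "lm1": "b"})
    assert model.edges == []


class TestOutlierFlagging:
    def _model_and_set(self, displacement=None):
        # edge with unit covariance per axis; landmark 0 displaced
        base = np.array([[0, 0, 0], [10, 0, 0]], float)
        rng = np.random.default_rng(3)
        sets = []
        for f in range(400):
            noise = rng.standard_normal(3)
            sets.append(make_landmark_set(base + np.array([noise, np.zeros(3)]),
                                          region="spine", fraction_id=f))
        model = fit_geometric_model(sets, {"lm0": "b", "lm1": "b"})
        pos = base.copy()
        if displacement is not None:
            pos[0] += displacement
        test_set = make_landmark_set(pos, region="spine", fraction_id=99)
        # use the exact sample mean so the injected displacement maps to a
        # known Mahalanobis distance (edge differences are lm0 - lm1)
        test_set.positions[0] += model.means[("lm0", "lm1")] - (pos[0] - pos[1])
        return model, test_set

    def test_at_model_mean_distance_zero_and_kept(self):
        model, s = self._model_and_set()
        d = model.edge_distance(("lm0", "lm1"),
                                s.positions[0] - s.positions[1])
        assert d == pytest.approx(0.0, abs=1e-9)
        out = flag_outliers(s, model)
        assert out.valid.all()

    def test_injected_displacement_equals_mahalanobis_distance(self):
        model, s = self._model_and_set()
        # displace along x by m standard deviations of the fitted covariance
        sd = np.sqrt(model.covariances[("lm0", "lm1")][0, 0])
        m = 7.0
        s.positions[0, 0] += m * sd
        d = model.edge_distance(("lm0", "lm1"), s.positions[0] - s.positions[1])
        # pure-axis displacement is damped by off-diagonal sample correlation
        assert d == pytest.approx(m, rel=0.05)

    def test_head_landmark_above_threshold_removed(self):
        # triangle of landmarks on one bone: displacing one corrupts only its
        # own edges, the other two keep a consistent mutual edge
        rng = np.random.default_rng(4)
        base = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], float)
        sets = [make_landmark_set(
            base + np.array([rng.standard_normal(3), np.zeros(3), np.zeros(3)]) * 0,
            region="spine", fraction_id=f) for f in range(3)]
        # add small isotropic noise to all landmarks for a non-degenerate fit
        sets = []
        for f in range(300):
            pos = base + rng.standard_normal((3, 3)) * 0.5
            sets.append(make_landmark_set(pos, region="spine", fraction_id=f))
        model = fit_geometric_model(sets, {f"lm{i}": "b" for i in range(3)})
        s = make_landmark_set(base, region="spine", fraction_id=99)
        s.positions[0] += 40.0  # far beyond the gate on every incident edge
        out = flag_outliers(s, model)
        assert not out.valid[0]
        assert out.valid[1] and out.valid[2]

    def test_threshold_is_exclusive(self):
        model, s = self._model_and_set()
        model.head_threshold = model.edge_distance(
            ("lm0", "lm1"), s.positions[0] - s.positions[1])
        out = flag_outliers(s, model)
        assert out.valid.all()  # equal-to-threshold stays


def test_mahalanobis_invariant_under_linear_reparameterization():
    rng = np.random.default_rng(5)
    cov = np.array([[2.0, 0.3, 0], [0.3, 1.0, 0.1], [0, 0.1, 0.5]])
    mean = np.array([1.0, -2.0, 0.5])
    diff = rng.standard_normal(3) * 3
    from hnmargin.landmarks import GeometricLandmarkModel

    m1 = GeometricLandmarkModel([("a", "b")], {("a", "b"): mean}, {("a", "b"): cov})
    A = rng.standard_normal((3, 3)) + 2 * np.eye(3)
    m2 = GeometricLandmarkModel(
        [("a", "b")], {("a", "b"): A @ mean}, {("a", "b"): A @ cov @ A.T})
    d1 = m1.edge_distance(("a", "b"), diff)
    d2 = m2.edge_distance(("a", "b"), A @ diff)
    assert d2 == pytest.approx(d1, rel=1e-9)


# ---------------------------------------------------------------------------
# Procrustes


def test_procrustes_identity(skull_landmarks):
    t = procrustes_align(skull_landmarks, skull_landmarks)
    np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(t.translation, 0, atol=1e-12)


def test_procrustes_recovers_known_rigid_transform(skull_landmarks):
    rng = np.random.default_rng(7)
    R = random_rotation(rng, np.deg2rad(10))
    t = rng.uniform(-10, 10, 3)
    moved = skull_landmarks.copy()
    moved.positions = skull_landmarks.positions @ R.T + t
    rec = procrustes_align(skull_landmarks, moved)
    # recovered transform maps the fraction back onto planning
    back = rec.apply(moved.positions)
    np.testing.assert_allclose(back, skull_landmarks.positions, atol=1e-8)
    np.testing.assert_allclose(rec.rotation, R.T, atol=1e-8)


def test_procrustes_alignment_idempotent(skull_landmarks):
    rng = np.random.default_rng(8)
    moved = skull_landmarks.copy()
    moved.positions = skull_landmarks.positions @ random_rotation(
        rng, 0.2).T + rng.uniform(-5, 5, 3)
    t1 = procrustes_align(skull_landmarks, moved)
    aligned = t1.apply_to_set(moved)
    t2 = procrustes_align(skull_landmarks, aligned)
    np.testing.assert_allclose(t2.rotation, np.eye(3), atol=1e-8)
    np.testing.assert_allclose(t2.translation, 0, atol=1e-8)


def test_procrustes_excludes_reflections(skull_landmarks):
    mirrored = skull_landmarks.copy()
    mirrored.positions = mirrored.positions * np.array([-1, 1, 1])
    t = procrustes_align(skull_landmarks, mirrored)
    assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-10)


def test_procrustes_matches_scipy_rotation_cross_check(skull_landmarks):
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(9)
    moved = skull_landmarks.copy()
    moved.positions = (skull_landmarks.positions
                       + rng.standard_normal(skull_landmarks.positions.shape))
    t = procrustes_align(skull_landmarks, moved)
    P, F = skull_landmarks.positions, moved.positions
    rot, _ = Rotation.align_vectors(P - P.mean(0), F - F.mean(0))
    np.testing.assert_allclose(t.rotation, rot.as_matrix(), atol=1e-8)


def test_procrustes_errors_on_degenerate_references():
    collinear = make_landmark_set([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(AlignmentError):
        procrustes_align(collinear, collinear.copy())
    few = make_landmark_set([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
    few.valid[0] = False
    with pytest.raises(AlignmentError):
        procrustes_align(few, few.copy())


def test_rigid_transform_rejects_reflection_and_nonorthogonal():
    with pytest.raises(ValueError):
        RigidTransform(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))
    with pytest.raises(ValueError):
        RigidTransform(np.eye(3) * 1.1, np.zeros(3))


# ---------------------------------------------------------------------------
# Residual displacements


def test_residuals_zero_when_aligned_equals_planning(skull_landmarks):
    res = residual_displacements(skull_landmarks, skull_landmarks.copy())
    for v in res.values():
        np.testing.assert_allclose(v, 0)


def test_residual_single_cranial_shift(skull_landmarks):
    frac = skull_landmarks.copy()
    frac.positions[2, 2] += 5.0
    res = residual_displacements(skull_landmarks, frac)
    np.testing.assert_allclose(res["lm2"], [0, 0, 5])
    np.testing.assert_allclose(res["lm0"], [0, 0, 0])


def test_invalid_landmarks_absent_from_residuals(skull_landmarks):
    frac = skull_landmarks.copy()
    frac.valid[1] = False
    res = residual_displacements(skull_landmarks, frac)
    assert "lm1" not in res and "lm0" in res


def test_landmark_set_validation():
    with pytest.raises(ValueError):
        LandmarkSet(["a", "a"], np.zeros((2, 3)), ["skull", "skull"])
    with pytest.raises(ValueError):
        LandmarkSet(["a"], np.array([[np.nan, 0, 0]]), ["skull"])
    with pytest.raises(ValueError):
        LandmarkSet(["a"], np.zeros((1, 3)), ["elbow"])
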