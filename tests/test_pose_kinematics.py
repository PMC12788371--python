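"""Stereo projection/triangulation, zero-phase filtering and joint angles."""

import numpy as np
import pytest

import copmat.pose_kinematics as pk


def make_camera(eye, principal=(0.0, 0.0), f=800.0):
    K = np.array([[f, 0, principal[0]], [0, f, principal[1]], [0, 0, 1.0]])
    R = np.eye(3)
    t = -np.asarray(eye, float)
    return pk.CameraModel(K, R, t)


@pytest.fixture
def camera_pair():
    return make_camera((-0.3, 0.0, 0.0)), make_camera((0.3, 0.1, 0.0))


# ---------------------------------------------------------------------------
# projection

def test_canonical_camera_projects_to_principal_point():
    cam = pk.CameraModel(np.eye(3), np.eye(3), np.zeros(3))
    assert np.allclose(cam.project(np.array([0.0, 0.0, 1.0])), [0.0, 0.0])


def test_projection_matches_manual_KRt():
    rng = np.random.default_rng(0)
    th = 0.3
    R = np.array([[np.cos(th), -np.sin(th), 0],
                  [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    K = np.array([[750.0, 2.0, 320.0], [0, 740.0, 240.0], [0, 0, 1.0]])
    t = np.array([0.1, -0.2, 0.5])
    cam = pk.CameraModel(K, R, t)
    X = rng.normal(0, 1, 3) + [0, 0, 5.0]
    uvw = K @ (R @ X + t)
    assert np.allclose(cam.project(X), uvw[:2] / uvw[2], atol=1e-12)


def test_projective_scale_invariance():
    cam = make_camera((0.1, 0.2, -1.0))
    P = cam.projection
    X = np.array([0.3, -0.2, 2.5, 1.0])
    for c in (2.0, -0.7):
        u1 = (P @ X)[:2] / (P @ X)[2]
        u2 = ((c * P) @ X)[:2] / ((c * P) @ X)[2]
        assert np.allclose(u1, u2)


def test_non_orthonormal_rotation_rejected():
    with pytest.raises(ValueError):
        pk.CameraModel(np.eye(3), np.eye(3) * 1.01, np.zeros(3))


# ---------------------------------------------------------------------------
# triangulation

def test_triangulation_exact_round_trip(camera_pair):
    cam_a, cam_b = camera_pair
    X = np.array([0.3, -0.2, 2.5])
    pt, res, ok = pk.triangulate_dlt(cam_a.project(X), cam_b.project(X),
                                     cam_a.projection, cam_b.projection)
    assert ok
    assert np.linalg.norm(pt - X) <= 1e-6
    assert res <= 1e-6


def test_triangulation_under_pixel_noise(camera_pair):
    cam_a, cam_b = camera_pair
    rng = np.random.default_rng(1)
    errs, ress = [], []
    for _ in range(50):
        X = rng.normal(0, 0.5, 3) + [0, 0, 2.0]
        pa = cam_a.project(X) + rng.normal(0, 0.5, 2)
        pb = cam_b.project(X) + rng.normal(0, 0.5, 2)
        pt, res, ok = pk.triangulate_dlt(pa, pb, cam_a.projection, cam_b.projection)
        assert ok
        errs.append(np.linalg.norm(pt - X))
        ress.append(res)
    # 0.5 px at f=800 and 2 m standoff: ~1.3 mm/px leverage -> a few mm
    assert np.median(errs) < 0.01
    assert np.mean(ress) > 0


def test_invalid_in_one_view_not_triangulated(camera_pair):
    cam_a, cam_b = camera_pair
    kp = np.zeros((1, 33, 2))
    va = np.ones((1, 33), bool)
    vb = np.ones((1, 33), bool)
    vb[0, 5] = False
    pos, ok = pk.triangulate_tracks(kp, kp, va, vb, cam_a, cam_b)
    assert not ok[0, 5]
    assert np.isnan(pos[0, 5]).all()


def test_batched_triangulation_matches_single(camera_pair):
    cam_a, cam_b = camera_pair
    rng = np.random.default_rng(2)
    X = rng.normal(0, 0.4, (3, 33, 3)) + [0, 0, 2.5]
    ka = cam_a.project(X)
    kb = cam_b.project(X)
    valid = np.ones((3, 33), bool)
    pos, ok = pk.triangulate_tracks(ka, kb, valid, valid, cam_a, cam_b)
    assert ok.all()
    assert np.abs(pos - X).max() < 1e-6


# ---------------------------------------------------------------------------
# low-pass filtering

def _track(values, fs=30.0):
    T = len(values)
    pos = np.zeros((T, 33, 3))
    pos[:, 0, 0] = values
    return pk.KeypointTrack3D(pos, np.ones((T, 33), bool), fs=fs)


def test_lowpass_dc_gain_unity():
    tr = _track(np.full(200, 3.25))
    out = pk.lowpass_track(tr)
    assert np.allclose(out.positions[:, 0, 0], 3.25, atol=1e-9)


def test_lowpass_zero_phase_peak_preserved():
    x = np.zeros(301)
    x[100:201] = np.concatenate([np.linspace(0, 1, 51), np.linspace(1, 0, 51)[1:]])
    out = pk.lowpass_track(_track(x))
    assert np.argmax(out.positions[:, 0, 0]) == np.argmax(x)


def test_lowpass_attenuation_matches_butterworth_magnitude():
    fs, f0, fc = 30.0, 4.0, 2.0
    t = np.arange(1200) / fs
    x = np.sin(2 * np.pi * f0 * t)
    out = pk.lowpass_track(_track(x, fs), cutoff=fc, order=4).positions[:, 0, 0]
    measured = np.sqrt(2) * np.std(out[300:900])
    # digital (bilinear, prewarped) 4th-order Butterworth magnitude,
    # squared by the forward-backward pass
    ratio = np.tan(np.pi * f0 / fs) / np.tan(np.pi * fc / fs)
    expected = 1.0 / (1.0 + ratio**8)
    assert measured == pytest.approx(expected, rel=0.05)


def test_lowpass_linearity():
    rng = np.random.default_rng(3)
    x, y = rng.normal(0, 1, 200), rng.normal(0, 1, 200)
    a, b = 2.5, -1.2
    fx = pk.lowpass_track(_track(x)).positions[:, 0, 0]
    fy = pk.lowpass_track(_track(y)).positions[:, 0, 0]
    fxy = pk.lowpass_track(_track(a * x + b * y)).positions[:, 0, 0]
    assert np.allclose(fxy, a * fx + b * fy, atol=1e-9)


def test_lowpass_rejects_short_tracks():
    with pytest.raises(ValueError):
        pk.lowpass_track(_track(np.zeros(10)))


# ---------------------------------------------------------------------------
# joint angles

def test_collinear_points_give_straight_angle():
    assert pk.joint_angle([0, 0, 1], [0, 0, 0], [0, 0, -1]) == pytest.approx(180.0)


def test_right_angle():
    assert pk.joint_angle([1, 0, 0], [0, 0, 0], [0, 1, 0]) == pytest.approx(90.0)


def test_joint_angle_matches_formula_oracle():
    rng = np.random.default_rng(4)
    for _ in range(100):
        a, b, c = rng.normal(0, 1, (3, 3))
        u, v = a - b, c - b
        expected = np.degrees(np.arccos(
            np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))
        assert pk.joint_angle(a, b, c) == pytest.approx(expected, abs=1e-9)


def test_joint_angle_rigid_motion_invariant():
    rng = np.random.default_rng(5)
    a, b, c = rng.normal(0, 1, (3, 3))
    th = 0.7
    R = np.array([[np.cos(th), -np.sin(th), 0],
                  [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    shift = np.array([1.0, -2.0, 0.5])
    before = pk.joint_angle(a, b, c)
    after = pk.joint_angle(R @ a + shift, R @ b + shift, R @ c + shift)
    assert after == pytest.approx(before, abs=1e-9)


def test_zero_length_limb_marked_invalid():
    assert np.isnan(pk.joint_angle([0, 0, 0], [0, 0, 0], [1, 0, 0]))


# ---------------------------------------------------------------------------
# angular features

def _angles_dict(track):
    return {key: track.copy() for key in pk.JOINT_TRIPLETS}


def test_derivatives_exact_on_linear_ramp():
    fs, k = 14.0, 3.0
    t = np.arange(50) / fs
    feats = pk.angular_features(_angles_dict(k * t), fs)
    assert feats.shape == (50, 18)
    vel = feats[:, 1]
    acc = feats[:, 2]
    assert np.allclose(vel, k, atol=1e-9)
    assert np.allclose(acc[1:-1], 0.0, atol=1e-9)


def test_derivatives_exact_on_quadratic():
    fs, alpha = 14.0, 4.0
    t = np.arange(50) / fs
    feats = pk.angular_features(_angles_dict(0.5 * alpha * t**2), fs)
    # one-sided velocity at the edges contaminates the outermost
    # acceleration samples; the interior is exact
    assert np.allclose(feats[2:-2, 2], alpha, atol=1e-6)


def test_sine_velocity_amplitude():
    fs, f0, A = 30.0, 1.0, 10.0
    t = np.arange(600) / fs
    feats = pk.angular_features(_angles_dict(A * np.sin(2 * np.pi * f0 * t)), fs)
    vmax = np.abs(feats[2:-2, 1]).max()
    # central differences underestimate by sin(wh)/(wh) = sinc(2 f0/fs)
    expected = A * 2 * np.pi * f0 * np.sinc(2 * f0 / fs)
    assert vmax == pytest.approx(expected, rel=1e-3)


def test_feature_order_contract():
    assert len(pk.FEATURE_ORDER) == 18
    assert pk.FEATURE_ORDER[0] == ("hip", "left", "angle")
    assert pk.FEATURE_ORDER[-1] == ("ankle", "right", "acceleration")
    joints = [j for j, _, _ in pk.FEATURE_ORDER]
    assert joints == sorted(joints, key=("hip", "knee", "ankle").index)


def test_angular_features_require_three_frames():
    with pytest.raises(ValueError):
        pk.angular_features(_angles_dict(np.zeros(2)), 14.0)


# ---------------------------------------------------------------------------
# calibration / keypoint I/O adapters

def test_camera_yaml_round_trip(tmp_path):
    import yaml

    cam = make_camera((0.2, -0.1, 0.0))
    path = tmp_path / "cam.yaml"
    with open(path, "w") as f:
        yaml.safe_dump(dict(intrinsics=cam.intrinsics.tolist(),
                            rotation=cam.rotation.tolist(),
                            translation=cam.translation.tolist()), f)
    back = pk.load_camera(path)
    assert np.allclose(back.projection, cam.projection)


def test_keypoint_csv_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    px = rng.uniform(0, 640, (5, 33, 2))
    valid = rng.random((5, 33)) > 0.2
    px[~valid] = np.nan
    ts = np.arange(5) / 30.0
    path = tmp_path / "kp.csv"
    pk.keypoints_to_csv(path, px, valid, ts)
    px2, valid2, ts2 = pk.keypoints_from_csv(path)
    np.testing.assert_array_equal(valid2, valid)
    np.testing.assert_allclose(px2[valid], px[valid], atol=1e-9)
    np.testing.assert_allclose(ts2, ts, atol=1e-12)
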