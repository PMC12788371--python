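"""Synthetic cohort, balance-trial dynamics, pressure rendering and the
projected skeleton."""

import numpy as np
import pytest
from scipy import signal

import copmat.pose_kinematics as pk
import copmat.sensor_sim as sim
import copmat.tactile_pipeline as tp


# ---------------------------------------------------------------------------
# cohort

def test_cohort_is_deterministic():
    a = sim.make_cohort(5, seed=11)
    b = sim.make_cohort(5, seed=11)
    assert a == b


def test_cohort_single_subject_repeatable():
    assert sim.make_cohort(1, seed=0)[0] == sim.make_cohort(1, seed=0)[0]


def test_cohort_rejects_empty():
    with pytest.raises(ValueError):
        sim.make_cohort(0, seed=1)


def test_cohort_height_moments_at_study_size():
    means = [np.mean([s.height for s in sim.make_cohort(23, seed=k)])
             for k in range(5)]
    assert abs(np.mean(means) - 171.6) < 5.0


def test_cohort_height_sd_converges():
    heights = [s.height for s in sim.make_cohort(1000, seed=1)]
    assert abs(np.std(heights) - 7.8) / 7.8 < 0.10


def test_profile_invariants_hold():
    for s in sim.make_cohort(50, seed=2):
        assert 0.4 < s.waist_hip_ratio < 1.5
        assert s.foot_length < s.height
        assert s.weight > 0 and s.lean_mass > 0
        assert s.gender in ("M", "F")


# ---------------------------------------------------------------------------
# trial dynamics

@pytest.fixture(scope="module")
def geom():
    return tp.SensorGeometry()


@pytest.fixture(scope="module")
def subj():
    return sim.make_cohort(1, seed=42)[0]


def _protocol(pid, duration=12.0, window=8.0, **sway):
    base = dict(sim._DEFAULT_SWAY[pid])
    base.update(sway)
    return sim.ProtocolSpec(protocol_id=pid,
                            is_dynamic=pid in sim.DYNAMIC_PROTOCOLS,
                            duration_s=duration, analysis_window_s=window,
                            sway_params=base)


def test_one_leg_zero_sway_constant_at_support_center(subj, geom):
    proto = _protocol("one_leg", sway_sd_ml_mm=0.0, sway_sd_ap_mm=0.0)
    trial = sim.simulate_trial(subj, proto, sim.NoiseModel.ideal(), geom, seed=1)
    assert np.ptp(trial.truth_cop, axis=0).max() < 1e-9
    np.testing.assert_allclose(trial.truth_cop.mean(axis=0),
                               trial.foot_centers[0, 0], atol=1e-9)


def test_squat_psd_peak_at_one_third_hz(subj, geom):
    proto = _protocol("squat", duration=30.0, window=24.0)
    trial = sim.simulate_trial(subj, proto, sim.NoiseModel.ideal(), geom, seed=2)
    ap = trial.truth_cop[:, 1] - trial.truth_cop[:, 1].mean()
    f, p = signal.welch(ap, fs=1000.0, nperseg=16384)
    assert f[np.argmax(p)] == pytest.approx(1.0 / 3.0, abs=0.05)


def test_walk_equal_loads_average_ml_at_midpoint(subj, geom):
    proto = _protocol("walk_in_place", duration=12.0, window=8.0,
                      sway_sd_ml_mm=0.0, sway_sd_ap_mm=0.0)
    trial = sim.simulate_trial(subj, proto, sim.NoiseModel.ideal(), geom, seed=3)
    cadence = proto.sway_params["cadence_hz"]
    n_per = int(1000 / cadence)
    n_full = (len(trial.truth_cop) // n_per) * n_per
    avg_ml = trial.truth_cop[:n_full, 0].mean()
    midpoint = trial.foot_centers[0, :, 0].mean()
    assert avg_ml == pytest.approx(midpoint, abs=0.5)


def test_unknown_protocol_rejected():
    with pytest.raises(ValueError):
        sim.ProtocolSpec(protocol_id="hopping", is_dynamic=True)


def test_dynamic_protocols_have_larger_cop_range(subj, geom):
    ranges = {}
    for pid in sim.PROTOCOL_IDS:
        trial = sim.simulate_trial(subj, _protocol(pid, duration=20.0, window=16.0),
                                   sim.NoiseModel.ideal(), geom, seed=7)
        ranges[pid] = np.ptp(trial.truth_cop, axis=0).max()
    static_max = max(ranges["one_leg"], ranges["tandem"])
    assert ranges["squat"] > static_max
    assert ranges["walk_in_place"] > static_max


def test_trial_determinism(subj, geom):
    p = _protocol("walk_in_place")
    n = sim.NoiseModel.default_nonlinear()
    t1 = sim.simulate_trial(subj, p, n, geom, seed=9)
    t2 = sim.simulate_trial(subj, p, n, geom, seed=9)
    np.testing.assert_array_equal(t1.truth_cop, t2.truth_cop)
    np.testing.assert_array_equal(t1.tactile_modules, t2.tactile_modules)
    np.testing.assert_array_equal(t1.keypoints_2d["cam_a"], t2.keypoints_2d["cam_a"])


def test_default_schedule_eight_trials_per_subject():
    schedule = sim.default_trial_schedule()
    assert len(schedule) == 8  # 4 tasks x 2 repetitions
    assert {p.protocol_id for p, _ in schedule} == set(sim.PROTOCOL_IDS)


# ---------------------------------------------------------------------------
# pressure rendering

def _stitched(trial, geom):
    return np.stack([tp.stitch_modules(list(m), geom) for m in trial.tactile_modules])


def test_ideal_rendering_centroid_tracks_truth(subj, geom):
    proto = _protocol("tandem")
    trial = sim.simulate_trial(subj, proto, sim.NoiseModel.ideal(), geom, seed=5)
    frames = _stitched(trial, geom)
    truth_at = np.stack([
        np.interp(trial.tactile_times, trial.truth_times, trial.truth_cop[:, a])
        for a in (0, 1)], axis=1)
    err_ml, err_ap = [], []
    for f, tr in zip(frames, truth_at):
        cop = tp.wma_cop(f, geom)
        err_ml.append(abs(cop.ml_mm - tr[0]))
        err_ap.append(abs(cop.ap_mm - tr[1]))
    assert max(err_ml) <= geom.pitch_width_mm / 2
    assert max(err_ap) <= geom.pitch_length_mm / 2


def test_ideal_rendering_conserves_load(subj, geom):
    proto = _protocol("squat")
    trial = sim.simulate_trial(subj, proto, sim.NoiseModel.ideal(), geom, seed=6)
    frames = _stitched(trial, geom)
    assert frames.max() < tp.SATURATION_KPA  # saturation off
    total = frames.sum(axis=(1, 2)) * geom.cell_area_mm2
    load_at = np.interp(trial.tactile_times, trial.truth_times,
                        trial.foot_loads.sum(axis=1))
    ratio = total / load_at
    assert np.ptp(ratio) / ratio.mean() < 0.01


def test_gamma_biases_wma_toward_lighter_foot(subj, geom):
    # two unequal loads: gamma < 1 compresses the heavier blob more, so
    # the measured centroid moves toward the lighter foot
    proto = _protocol("walk_in_place", sway_sd_ml_mm=0.0, sway_sd_ap_mm=0.0,
                      load_swing=0.6)
    ideal = sim.simulate_trial(subj, proto, sim.NoiseModel.ideal(), geom, seed=8)
    gamma = sim.simulate_trial(subj, proto, sim.NoiseModel(gamma=0.7), geom, seed=8)
    f_i = _stitched(ideal, geom)
    f_g = _stitched(gamma, geom)
    # pick the frame with the most unbalanced load
    loads = np.stack([np.interp(ideal.tactile_times, ideal.truth_times,
                                ideal.foot_loads[:, f]) for f in range(2)], axis=1)
    k = np.argmax(loads[:, 0] - loads[:, 1])  # left foot heavy
    cop_i = tp.wma_cop(f_i[k], geom).ml_mm
    cop_g = tp.wma_cop(f_g[k], geom).ml_mm
    lighter_ml = ideal.foot_centers[0, 1, 0]
    direction = np.sign(lighter_ml - cop_i)
    assert np.sign(cop_g - cop_i) == direction
    # numeric oracle: recompute the centroid of the gamma-compressed frame
    oracle = tp.wma_cop((f_i[k] / tp.SATURATION_KPA) ** 0.7, geom).ml_mm
    assert cop_g == pytest.approx(oracle, abs=1e-6)


def test_salt_pepper_changes_bounded_fraction_of_cells(subj, geom):
    proto = _protocol("tandem")
    rate = 0.01
    clean = sim.simulate_trial(subj, proto, sim.NoiseModel.ideal(), geom, seed=10)
    noisy = sim.simulate_trial(subj, proto, sim.NoiseModel(sp_noise_rate=rate),
                               geom, seed=10)
    diff = (clean.tactile_modules != noisy.tactile_modules).mean()
    assert diff <= 2 * rate  # binomial mean with generous margin


def test_frame_drops_remove_frames(subj, geom):
    proto = _protocol("tandem")
    full = sim.simulate_trial(subj, proto, sim.NoiseModel.ideal(), geom, seed=11)
    dropped = sim.simulate_trial(subj, proto, sim.NoiseModel(drop_rate=0.3),
                                 geom, seed=11)
    assert len(dropped.tactile_times) < len(full.tactile_times)
    assert np.all(np.diff(dropped.tactile_times) > 0)


def test_baseline_offsets_recovered_by_calibration(geom):
    noise = sim.NoiseModel(module_baseline=(0.5, 0.2, 0.1, 0.4))
    frames = sim.render_no_load_frames(noise, geom, n_frames=200,
                                       rng=np.random.default_rng(0))
    baseline = tp.calibrate_baseline(frames)
    quads = tp.split_modules(baseline.values, geom)
    for q, expected in zip(quads, noise.module_baseline):
        assert q.mean() == pytest.approx(expected, abs=0.01)


# ---------------------------------------------------------------------------
# skeleton and projection

def test_exactly_33_keypoints_per_frame_per_view(ideal_walk_trial):
    for view in ("cam_a", "cam_b"):
        assert ideal_walk_trial.keypoints_2d[view].shape[1:] == (33, 2)
        assert ideal_walk_trial.keypoints_valid[view].shape[1] == 33


def test_noiseless_projection_triangulates_back(subj, geom, cameras):
    proto = _protocol("squat")
    trial = sim.simulate_trial(subj, proto, sim.NoiseModel.ideal(), geom, seed=12,
                               cam_a=cameras[0], cam_b=cameras[1])
    ka = trial.keypoints_2d["cam_a"][:20]
    kb = trial.keypoints_2d["cam_b"][:20]
    va = trial.keypoints_valid["cam_a"][:20]
    vb = trial.keypoints_valid["cam_b"][:20]
    pos, ok = pk.triangulate_tracks(ka, kb, va, vb, *cameras)
    assert ok.all()
    # verify reprojection consistency of the recovered 3D skeleton
    for cam, kp in ((cameras[0], ka), (cameras[1], kb)):
        reproj = cam.project(pos.reshape(-1, 3)).reshape(kp.shape)
        assert np.abs(reproj - kp).max() < 1e-6


def test_squat_knee_angle_period_three_seconds(ideal_squat_trial):
    knee = ideal_squat_trial.truth_kinematics[("knee", "left")]
    knee = knee - knee.mean()
    f, p = signal.welch(knee, fs=30.0, nperseg=256)
    peak = f[np.argmax(p)]
    assert peak == pytest.approx(1.0 / 3.0, abs=0.06)


def test_keypoint_behind_camera_marked_invalid(subj, geom):
    # a camera looking away from the scene sees nothing valid
    K = np.array([[800.0, 0, 320], [0, 800.0, 240], [0, 0, 1.0]])
    R = np.diag([1.0, -1.0, -1.0])  # flips the optical axis
    away = pk.CameraModel(K, R, np.array([0.0, 0.0, -50.0]))
    proto = _protocol("tandem")
    trial = sim.simulate_trial(subj, proto, sim.NoiseModel.ideal(), geom, seed=13,
                               cam_a=away, cam_b=sim.default_camera_pair(geom)[1])
    assert not trial.keypoints_valid["cam_a"].any()
    assert trial.keypoints_valid["cam_b"].all()
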