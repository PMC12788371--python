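"""Tactile preprocessing chain: stitching, calibration, quantization,
denoising, drop filling and the weighted-mean CoP."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import copmat.tactile_pipeline as tp


@pytest.fixture
def geom():
    return tp.SensorGeometry()


# ---------------------------------------------------------------------------
# stitching

def test_stitch_places_modules_in_tile_order(geom):
    mods = [np.full((32, 32), v, dtype=float) for v in (1, 2, 3, 4)]
    out = tp.stitch_modules(mods, geom)
    assert out.shape == (64, 64)
    assert out[0, 0] == 1 and out[0, 63] == 2
    assert out[63, 0] == 3 and out[63, 63] == 4


def test_stitch_split_round_trip(geom):
    rng = np.random.default_rng(0)
    mods = [rng.random((32, 32)) for _ in range(4)]
    back = tp.split_modules(tp.stitch_modules(mods, geom), geom)
    for a, b in zip(mods, back):
        np.testing.assert_array_equal(a, b)


def test_stitch_rejects_bad_inputs(geom):
    with pytest.raises(ValueError):
        tp.stitch_modules([np.zeros((32, 32))] * 3, geom)
    with pytest.raises(ValueError):
        tp.stitch_modules([np.zeros((16, 32))] * 4, geom)


# ---------------------------------------------------------------------------
# baseline calibration / correction

def test_baseline_self_subtraction():
    frames = np.full((20, 64, 64), 3.7)
    baseline = tp.calibrate_baseline(frames)
    assert baseline.n_frames_used == 20
    corrected = tp.apply_correction(frames[0], baseline, threshold=0.0)
    assert np.all(corrected == 0.0)


def test_correction_piecewise_definition():
    baseline = tp.BaselineMap(np.full((1, 1), 3.0), 1)
    assert tp.apply_correction(np.array([[10.0]]), baseline, 2.0)[0, 0] == 7.0
    assert tp.apply_correction(np.array([[4.0]]), baseline, 2.0)[0, 0] == 0.0


def test_correction_matches_bruteforce_oracle():
    rng = np.random.default_rng(1)
    frames = rng.uniform(0, 14, (20, 64, 64))
    frame = rng.uniform(0, 14, (64, 64))
    thr = 0.3
    baseline = tp.calibrate_baseline(frames)
    got = tp.apply_correction(frame, baseline, thr)
    # independent per-cell mean/subtract/clip reimplementation
    exp = np.empty((64, 64))
    for r in range(64):
        for c in range(64):
            m = sum(frames[k][r, c] for k in range(20)) / 20.0
            v = max(frame[r, c] - m, 0.0)
            exp[r, c] = v if v >= thr else 0.0
    np.testing.assert_array_equal(got, exp)


def test_empty_calibration_rejected():
    with pytest.raises(ValueError):
        tp.calibrate_baseline(np.empty((0, 64, 64)))


# ---------------------------------------------------------------------------
# normalization / quantization

def test_minmax_endpoints_map_to_0_and_255():
    vals = np.zeros((2, 64, 64))
    vals[1, 0, 0] = 50.0
    seq = tp.PressureSequence(vals, [0.0, 1.0], stage="corrected")
    gray, consts = tp.normalize_quantize(seq)
    assert gray.stage == "gray8"
    assert gray.values[1, 0, 0] == 255
    assert gray.values[0, 0, 0] == 0
    assert consts.vmax == 50.0


def test_constant_dataset_yields_zeros_with_warning():
    seq = tp.PressureSequence(np.full((3, 64, 64), 2.0), [0, 1, 2], stage="corrected")
    with pytest.warns(UserWarning):
        gray, _ = tp.normalize_quantize(seq)
    assert np.all(gray.values == 0)


def test_dequantization_error_bounded():
    rng = np.random.default_rng(2)
    vals = rng.uniform(0, 9.3, (5, 64, 64))
    seq = tp.PressureSequence(vals, np.arange(5.0), stage="corrected")
    gray, consts = tp.normalize_quantize(seq)
    back = consts.dequantize(gray.values)
    span = consts.vmax - consts.vmin
    assert np.max(np.abs(back - vals)) <= span / 255.0 / 2 + 1e-12


# ---------------------------------------------------------------------------
# denoising

def test_median_constant_frame_unchanged():
    frame = np.full((64, 64), 7, dtype=np.uint8)
    np.testing.assert_array_equal(tp.denoise(frame), frame)


def test_median_removes_isolated_spike():
    frame = np.zeros((64, 64), dtype=np.uint8)
    frame[10, 10] = 255
    assert tp.denoise(frame)[10, 10] == 0


def test_median_matches_bruteforce_oracle():
    rng = np.random.default_rng(3)
    frame = rng.integers(0, 256, (20, 20)).astype(np.uint8)
    got = tp.denoise(frame)
    exp = np.empty_like(frame)
    for r in range(20):
        for c in range(20):
            neigh = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr = min(max(r + dr, 0), 19)  # edge replication
                    cc = min(max(c + dc, 0), 19)
                    neigh.append(frame[rr, cc])
            exp[r, c] = np.median(neigh)
    np.testing.assert_array_equal(got, exp)


# ---------------------------------------------------------------------------
# frame-drop filling

def test_fill_midpoint_and_noop():
    vals = np.stack([np.zeros((64, 64)), np.full((64, 64), 10.0)])
    seq = tp.PressureSequence(vals, [0.0, 2.0], stage="corrected")
    filled = tp.fill_dropped_frames(seq, [0.0, 1.0, 2.0])
    assert np.allclose(filled.values[1], 5.0)
    same = tp.fill_dropped_frames(seq, [0.0, 2.0])
    np.testing.assert_allclose(same.values, vals)


def test_fill_exact_on_linear_signals():
    rng = np.random.default_rng(4)
    T = 50
    t_full = np.arange(T, dtype=float)
    slope = rng.uniform(-1, 1, (64, 64))
    icept = rng.uniform(60, 80, (64, 64))  # stays positive over the ramp
    vals = icept[None] + slope[None] * t_full[:, None, None]
    keep = rng.random(T) >= 0.2
    keep[[0, -1]] = True
    seq = tp.PressureSequence(vals[keep], t_full[keep], stage="corrected")
    filled = tp.fill_dropped_frames(seq, t_full)
    np.testing.assert_allclose(filled.values, vals, atol=1e-9)


def test_fill_requires_two_frames():
    seq = tp.PressureSequence(np.zeros((1, 64, 64)), [0.0], stage="raw")
    with pytest.raises(ValueError):
        tp.fill_dropped_frames(seq, [0.0, 1.0])


# ---------------------------------------------------------------------------
# WMA CoP

def test_wma_single_cell_at_far_edge(geom):
    frame = np.zeros((64, 64))
    frame[0, 63] = 5.0  # column index 64 (1-based) on the 600 mm ML axis
    cop = tp.wma_cop(frame, geom)
    assert cop.ml_mm == pytest.approx(600.0)


def test_wma_uniform_frame(geom):
    cop = tp.wma_cop(np.ones((64, 64)), geom)
    assert cop.ml_mm == pytest.approx(32.5 * 600.0 / 64)  # 304.6875
    assert cop.ap_mm == pytest.approx(32.5 * 800.0 / 64)


def test_wma_matches_double_loop_oracle(geom):
    rng = np.random.default_rng(5)
    for _ in range(20):
        frame = rng.uniform(0, 1, (64, 64))
        cop = tp.wma_cop(frame, geom)
        num_ml = num_ap = den = 0.0
        for r in range(64):
            for c in range(64):
                w = frame[r, c]
                den += w
                num_ml += (c + 1) * w
                num_ap += (r + 1) * w
        assert cop.ml_mm == pytest.approx(num_ml / den * 600.0 / 64, rel=1e-12)
        assert cop.ap_mm == pytest.approx(num_ap / den * 800.0 / 64, rel=1e-12)


def test_wma_no_load_marker(geom):
    out = tp.wma_cop(np.zeros((64, 64)), geom, timestamp=1.5)
    assert isinstance(out, tp.NoLoad)
    assert out.timestamp == 1.5


def test_wma_translation_equivariance(geom):
    rng = np.random.default_rng(6)
    frame = np.zeros((64, 64))
    frame[20:30, 20:30] = rng.uniform(0.1, 1.0, (10, 10))
    c0 = tp.wma_cop(frame, geom)
    shifted = np.roll(frame, (5, 7), axis=(0, 1))
    c1 = tp.wma_cop(shifted, geom)
    assert c1.ml_mm - c0.ml_mm == pytest.approx(7 * geom.pitch_width_mm, abs=1e-9)
    assert c1.ap_mm - c0.ap_mm == pytest.approx(5 * geom.pitch_length_mm, abs=1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(scale=st.floats(min_value=1e-3, max_value=1e3), seed=st.integers(0, 100))
def test_wma_scale_invariance(scale, seed):
    geom = tp.SensorGeometry()
    frame = np.random.default_rng(seed).uniform(0, 1, (64, 64)) + 1e-6
    c0 = tp.wma_cop(frame, geom)
    c1 = tp.wma_cop(frame * scale, geom)
    assert c1.ml_mm == pytest.approx(c0.ml_mm, rel=1e-9)
    assert c1.ap_mm == pytest.approx(c0.ap_mm, rel=1e-9)


def test_strict_printed_axes_swaps_extents():
    strict = tp.SensorGeometry(strict_printed_axes=True)
    frame = np.ones((64, 64))
    cop = tp.wma_cop(frame, strict)
    # printed form multiplies the ML coordinate by L/64 (the 800 mm length)
    assert cop.ml_mm == pytest.approx(32.5 * 800.0 / 64)
    assert cop.ap_mm == pytest.approx(32.5 * 600.0 / 64)


def test_full_chain_preserves_shape_and_nonnegativity():
    rng = np.random.default_rng(7)
    T = 6
    mods = rng.uniform(0, 10, (T, 4, 32, 32))
    gray, consts = tp.preprocess_raw_modules(
        mods, np.arange(T) / 14.0, rng.uniform(0, 0.1, (20, 64, 64)))
    assert gray.values.shape == (T, 64, 64)
    assert gray.values.dtype == np.uint8
    assert gray.stage == "denoised"


def test_gray8_frame_image_export(tmp_path):
    from PIL import Image

    frame = np.arange(64 * 64, dtype=np.uint32).reshape(64, 64) % 256
    frame = frame.astype(np.uint8)
    path = tmp_path / "frame.png"
    tp.save_frame_image(frame, path)
    back = np.asarray(Image.open(path))
    np.testing.assert_array_equal(back, frame)
    with pytest.raises(ValueError):
        tp.save_frame_image(frame.astype(float), tmp_path / "bad.png")
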