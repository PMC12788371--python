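"""Stereo keypoint triangulation and lower-limb joint kinematics.

Two calibrated pinhole cameras observe a 33-keypoint skeleton (the
topology of common RGB pose estimators: nose, eyes, ..., hips 23/24,
knees 25/26, ankles 27/28, heels 29/30, foot indices 31/32).  Each
keypoint seen validly in both views is triangulated by the Direct
Linear Transformation (DLT); the 3D tracks are zero-phase low-pass
filtered, and hip/knee/ankle joint angles with their first and second
temporal derivatives form an 18-dimensional per-frame kinematic
feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

N_KEYPOINTS = 33

# landmark indices of the 33-point pose topology used for joint angles
LANDMARK = {
    "left_shoulder": 11, "right_shoulder": 12,
    "left_hip": 23, "right_hip": 24,
    "left_knee": 25, "right_knee": 26,
    "left_ankle": 27, "right_ankle": 28,
    "left_heel": 29, "right_heel": 30,
    "left_foot_index": 31, "right_foot_index": 32,
}

#: joint -> (outer point, vertex, inner point); angle measured at the vertex
JOINT_TRIPLETS = {
    ("hip", "left"): ("left_shoulder", "left_hip", "left_knee"),
    ("hip", "right"): ("right_shoulder", "right_hip", "right_knee"),
    ("knee", "left"): ("left_hip", "left_knee", "left_ankle"),
    ("knee", "right"): ("right_hip", "right_knee", "right_ankle"),
    ("ankle", "left"): ("left_knee", "left_ankle", "left_foot_index"),
    ("ankle", "right"): ("right_knee", "right_ankle", "right_foot_index"),
}

#: deterministic 18-feature order: joints x sides x (angle, velocity, accel)
FEATURE_ORDER = [
    (joint, side, qty)
    for joint in ("hip", "knee", "ankle")
    for side in ("left", "right")
    for qty in ("angle", "velocity", "acceleration")
]


@dataclass(frozen=True)
class CameraModel:
    """Calibrated pinhole camera: intrinsics K, rotation R, translation t."""

    intrinsics: np.ndarray
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        K = np.asarray(self.intrinsics, dtype=float)
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "intrinsics", K)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if K.shape != (3, 3) or R.shape != (3, 3):
            raise ValueError("K and R must be 3x3")
        if not np.allclose(np.tril(K, -1), 0.0) or np.any(np.diag(K)[:2] <= 0):
            raise ValueError("intrinsics must be upper-triangular with positive focals")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal to 1e-9")

    @property
    def projection(self) -> np.ndarray:
        """3x4 projection matrix P = K [R | t]."""
        return self.intrinsics @ np.hstack([self.rotation, self.translation[:, None]])

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project (..., 3) world points to (..., 2) pixels."""
        pts = np.asarray(points, dtype=float)
        h = np.concatenate([pts, np.ones((*pts.shape[:-1], 1))], axis=-1)
        uvw = h @ self.projection.T
        return uvw[..., :2] / uvw[..., 2:3]

    def depth(self, points: np.ndarray) -> np.ndarray:
        """Signed depth along the optical axis (negative = behind camera)."""
        pts = np.asarray(points, dtype=float)
        return (pts @ self.rotation[2]) + self.translation[2]


def projection_matrix(camera: CameraModel) -> np.ndarray:
    return camera.projection


def camera_from_dict(d: dict) -> CameraModel:
    """Build a camera from a plain mapping (YAML/JSON calibration file)."""
    return CameraModel(
        np.asarray(d["intrinsics"], dtype=float),
        np.asarray(d["rotation"], dtype=float),
        np.asarray(d["translation"], dtype=float),
    )


def load_camera(path) -> CameraModel:
    """Read a camera calibration from a YAML (or JSON) file."""
    import yaml

    with open(path) as f:
        return camera_from_dict(yaml.safe_load(f))


def keypoints_to_csv(path, pixels: np.ndarray, valid: np.ndarray,
                     timestamps: np.ndarray) -> None:
    """Write a (T, 33, 2) 2D keypoint track as a tidy CSV.

    This is the adapter seam for a real pose-estimator: any tool that
    produces per-frame 33-keypoint pixel coordinates can exchange data
    through this format.
    """
    import pandas as pd

    T, K, _ = pixels.shape
    t_idx, k_idx = np.meshgrid(np.arange(T), np.arange(K), indexing="ij")
    pd.DataFrame({
        "timestamp": np.repeat(timestamps, K),
        "frame": t_idx.ravel(),
        "keypoint": k_idx.ravel(),
        "u": pixels[..., 0].ravel(),
        "v": pixels[..., 1].ravel(),
        "valid": valid.ravel().astype(int),
    }).to_csv(path, index=False)


def keypoints_from_csv(path):
    """Inverse of :func:`keypoints_to_csv`: returns (pixels, valid, timestamps)."""
    import pandas as pd

    df = pd.read_csv(path)
    T = int(df["frame"].max()) + 1
    K = int(df["keypoint"].max()) + 1
    pixels = np.full((T, K, 2), np.nan)
    valid = np.zeros((T, K), dtype=bool)
    pixels[df["frame"], df["keypoint"], 0] = df["u"]
    pixels[df["frame"], df["keypoint"], 1] = df["v"]
    valid[df["frame"], df["keypoint"]] = df["valid"].astype(bool)
    timestamps = df.drop_duplicates("frame").sort_values("frame")["timestamp"].values
    return pixels, valid, timestamps


def triangulate_dlt(
    pt_a, pt_b, P_a: np.ndarray, P_b: np.ndarray
) -> tuple[np.ndarray, float, bool]:
    """DLT triangulation of one point from two views.

    Solves the homogeneous system by the smallest singular vector of

        [u_a p3_a - p1_a; v_a p3_a - p2_a; u_b p3_b - p1_b; v_b p3_b - p2_b]

    Returns ``(point_3d, rms_reprojection_residual_px, valid)``; the
    point is flagged invalid on a degenerate (rank-deficient) geometry.
    """
    pt_a = np.asarray(pt_a, float)
    pt_b = np.asarray(pt_b, float)
    A = np.empty((4, 4))
    for i, (pt, P) in enumerate(((pt_a, P_a), (pt_b, P_b))):
        A[2 * i] = pt[0] * P[2] - P[0]
        A[2 * i + 1] = pt[1] * P[2] - P[1]
    _, s, vh = np.linalg.svd(A)
    X = vh[-1]
    if abs(X[3]) < 1e-12 or s[-2] < 1e-12:
        return np.full(3, np.nan), np.inf, False
    X = X[:3] / X[3]
    res = []
    for pt, P in ((pt_a, P_a), (pt_b, P_b)):
        uvw = P @ np.append(X, 1.0)
        if abs(uvw[2]) < 1e-12:
            return np.full(3, np.nan), np.inf, False
        res.append(uvw[:2] / uvw[2] - pt)
    residual = float(np.sqrt(np.mean(np.concatenate(res) ** 2)))
    return X, residual, True


def triangulate_tracks(
    kp_a: np.ndarray,
    kp_b: np.ndarray,
    valid_a: np.ndarray,
    valid_b: np.ndarray,
    cam_a: CameraModel,
    cam_b: CameraModel,
):
    """Triangulate (T, 33, 2) keypoint tracks from two views.

    A keypoint is triangulated only when valid in both views; others
    are NaN with validity False.
    """
    P_a, P_b = cam_a.projection, cam_b.projection
    T, K = kp_a.shape[0], kp_a.shape[1]
    pos = np.full((T, K, 3), np.nan)
    ok = np.zeros((T, K), dtype=bool)
    both = np.asarray(valid_a, bool) & np.asarray(valid_b, bool)
    ti, ki = np.nonzero(both)
    if len(ti) == 0:
        return pos, ok
    pa = np.asarray(kp_a, float)[ti, ki]  # (M, 2)
    pb = np.asarray(kp_b, float)[ti, ki]
    A = np.empty((len(ti), 4, 4))
    A[:, 0] = pa[:, 0, None] * P_a[2] - P_a[0]
    A[:, 1] = pa[:, 1, None] * P_a[2] - P_a[1]
    A[:, 2] = pb[:, 0, None] * P_b[2] - P_b[0]
    A[:, 3] = pb[:, 1, None] * P_b[2] - P_b[1]
    _, s, vh = np.linalg.svd(A)
    X = vh[:, -1, :]
    good = (np.abs(X[:, 3]) > 1e-12) & (s[:, -2] > 1e-12)
    Xc = np.where(good[:, None], X[:, :3] / np.where(good, X[:, 3], 1.0)[:, None], np.nan)
    pos[ti, ki] = Xc
    ok[ti, ki] = good
    return pos, ok


@dataclass
class KeypointTrack3D:
    """T x 33 x 3 world-frame keypoint positions with validity flags."""

    positions: np.ndarray
    validity: np.ndarray
    fs: float = 30.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.positions.shape[1] != N_KEYPOINTS:
            raise ValueError(f"expected {N_KEYPOINTS} keypoints")
        if self.validity.shape != self.positions.shape[:2]:
            raise ValueError("validity shape mismatch")


def fill_invalid_keypoints(
    track: KeypointTrack3D, max_gap: int = 10
) -> tuple[KeypointTrack3D, bool]:
    """Linearly interpolate invalid-keypoint gaps; flag gaps over the cap."""
    pos = track.positions.copy()
    ok = track.validity
    flagged = False
    T = pos.shape[0]
    idx = np.arange(T)
    for k in range(pos.shape[1]):
        good = ok[:, k]
        if good.all():
            continue
        if not good.any():
            flagged = True
            continue
        bad_runs = np.flatnonzero(~good)
        splits = np.split(bad_runs, np.flatnonzero(np.diff(bad_runs) > 1) + 1)
        if any(len(s) > max_gap for s in splits if len(s)):
            flagged = True
        for d in range(3):
            pos[~good, k, d] = np.interp(idx[~good], idx[good], pos[good, k, d])
    filled = KeypointTrack3D(pos, np.ones_like(ok, dtype=bool), fs=track.fs)
    return filled, flagged


def lowpass_track(
    track: KeypointTrack3D, cutoff: float = 2.0, order: int = 4
) -> KeypointTrack3D:
    """Zero-phase Butterworth low-pass of every coordinate track."""
    if track.fs <= 2 * cutoff:
        raise ValueError("sampling rate must exceed twice the cutoff")
    sos = signal.butter(order, cutoff, fs=track.fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if track.positions.shape[0] <= padlen:
        raise ValueError(f"track too short: need > {padlen} frames")
    flat = track.positions.reshape(track.positions.shape[0], -1)
    out = signal.sosfiltfilt(sos, flat, axis=0)
    return KeypointTrack3D(
        out.reshape(track.positions.shape), track.validity.copy(), fs=track.fs
    )


def joint_angle(a, b, c) -> float:
    """Angle (degrees) at vertex ``b`` between limb vectors b->a and b->c.

    The cosine is clamped into [-1, 1] before arccos; a zero-length
    limb yields NaN (marked invalid, never raised per-frame).
    """
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return float("nan")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def joint_angle_tracks(track: KeypointTrack3D) -> dict[tuple[str, str], np.ndarray]:
    """Per-frame hip/knee/ankle angles of both legs, degrees."""
    out = {}
    pos = track.positions
    for (joint, side), (na, nb, nc) in JOINT_TRIPLETS.items():
        ia, ib, ic = LANDMARK[na], LANDMARK[nb], LANDMARK[nc]
        u = pos[:, ia] - pos[:, ib]
        v = pos[:, ic] - pos[:, ib]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
        ang = np.degrees(np.arccos(cosang))
        ang[(nu == 0) | (nv == 0)] = np.nan
        out[(joint, side)] = ang
    return out


def derivative(x: np.ndarray, fs: float) -> np.ndarray:
    """Central differences interior, one-sided at the ends."""
    return np.gradient(np.asarray(x, float), 1.0 / fs, axis=0)


def angular_features(
    angles: dict[tuple[str, str], np.ndarray], fs: float
) -> np.ndarray:
    """Stack angles + first/second temporal derivatives into (T, 18).

    Column order follows :data:`FEATURE_ORDER`.
    """
    some = next(iter(angles.values()))
    if len(some) < 3:
        raise ValueError("need at least 3 frames for derivatives")
    cols = {}
    for key, ang in angles.items():
        vel = derivative(ang, fs)
        acc = derivative(vel, fs)
        cols[(*key, "angle")] = ang
        cols[(*key, "velocity")] = vel
        cols[(*key, "acceleration")] = acc
    return np.stack([cols[k] for k in FEATURE_ORDER], axis=1)


def kinematic_features_from_track(track: KeypointTrack3D) -> np.ndarray:
    """Convenience: angles -> (T, 18) features at the track's rate."""
    return angular_features(joint_angle_tracks(track), track.fs)
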