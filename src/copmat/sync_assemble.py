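"""Multi-rate synchronization and the per-trial HDF5 container.

The force plate (1000 Hz), pressure mat (~14 Hz) and stereo cameras
(30 Hz) are aligned by post-processing: the ground-truth CoP is
zero-phase low-pass filtered at 10 Hz, a spectral-energy check verifies
that resampling to 14 Hz aliases negligibly, and every modality is
linearly interpolated onto a common 14 Hz reference grid anchored at
the start of the middle analysis window.  Each trial's synchronized
bundle (gray8 pressure frames, weighted-mean CoP, truth CoP, 18
kinematic features, subject characteristics, experimental settings) is
stored in one HDF5 file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np
from scipy import signal

from . import pose_kinematics as pk
from . import tactile_pipeline as tp
from .sensor_sim import SyntheticTrial, PROTOCOL_IDS

SCHEMA_VERSION = "1.0"
REFERENCE_FS = 14.0


@dataclass
class TimedStream:
    """Timestamped payload stream (scalar, vector or frame per timestamp)."""

    timestamps: np.ndarray
    values: np.ndarray
    fs_nominal: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps/values length mismatch")
        if len(self.timestamps) >= 2 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")


def lowpass_truth_cop(cop: TimedStream, cutoff: float = 10.0, order: int = 4) -> TimedStream:
    """Zero-phase Butterworth low-pass of the reference CoP, per axis."""
    if cop.fs_nominal <= 2 * cutoff:
        raise ValueError("sampling rate must exceed twice the cutoff")
    sos = signal.butter(order, cutoff, fs=cop.fs_nominal, output="sos")
    if len(cop.timestamps) <= 3 * (2 * order + 1):
        raise ValueError("stream too short for zero-phase filtering")
    out = signal.sosfiltfilt(sos, cop.values, axis=0)
    return TimedStream(cop.timestamps.copy(), out, cop.fs_nominal)


def psd_energy_fraction(sig: TimedStream, f_upper: float) -> float:
    """Fraction of Welch-PSD energy below ``f_upper``."""
    x = np.asarray(sig.values, dtype=float)
    if x.ndim > 1:
        x = x.reshape(len(x), -1)
    n = len(x)
    if n < 64:
        raise ValueError("need at least 64 samples for a PSD estimate")
    if f_upper >= sig.fs_nominal / 2:
        warnings.warn("f_upper at or above Nyquist; fraction is trivially 1")
        return 1.0
    nperseg = min(1024, n)
    f, p = signal.welch(x, fs=sig.fs_nominal, window="hann", nperseg=nperseg, axis=0)
    total = p.sum()
    if total <= 0:
        return 1.0
    return float(p[f <= f_upper].sum() / total)


def resample_to_reference(
    stream: TimedStream,
    ref_timestamps,
    categorical: bool = False,
    tolerance: float | None = None,
) -> np.ndarray:
    """Linearly interpolate stream values at the reference timestamps.

    Frames are interpolated per cell; ``categorical=True`` switches to
    nearest-neighbor.  References outside the stream's span by more
    than ``tolerance`` (default: one nominal interval) are rejected.
    """
    ref = np.asarray(ref_timestamps, dtype=float)
    t = stream.timestamps
    if tolerance is None:
        tolerance = 1.0 / stream.fs_nominal
    low, high = t[0] - tolerance, t[-1] + tolerance
    bad = (ref < low) | (ref > high)
    if np.any(bad):
        raise ValueError(
            f"reference timestamp {ref[bad][0]:.4f}s outside stream span "
            f"[{t[0]:.4f}, {t[-1]:.4f}] beyond tolerance {tolerance:.4f}s"
        )
    vals = stream.values
    if categorical:
        idx = np.clip(np.searchsorted(t, ref), 1, len(t) - 1)
        left_closer = (ref - t[idx - 1]) < (t[idx] - ref)
        return vals[np.where(left_closer, idx - 1, idx)]
    flat = vals.reshape(len(vals), -1).astype(float)
    out = np.empty((len(ref), flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(ref, t, flat[:, j])
    out = out.reshape(len(ref), *vals.shape[1:])
    return out


def sync_mismatch_bound(fs_a: float, fs_b: float) -> float:
    """Worst-case trigger mismatch in ms: half of each sampling interval.

    Manual triggers are stamped at the nearest acquired frame of each
    device, so the expected mismatch is ``(1/fs_a + 1/fs_b) / 2``
    (about 52 ms for a 14 Hz mat and a 30 Hz camera).
    """
    if fs_a <= 0 or fs_b <= 0:
        raise ValueError("sampling rates must be positive")
    return (1.0 / fs_a + 1.0 / fs_b) / 2.0 * 1000.0


def reference_grid(duration_s: float, window_s: float, fs: float = REFERENCE_FS) -> np.ndarray:
    """The common timestamp grid: symmetric middle window, 1/fs spacing."""
    if window_s > duration_s:
        raise ValueError("analysis window exceeds trial duration")
    start = (duration_s - window_s) / 2.0
    n = int(round(window_s * fs))
    return start + np.arange(n) / fs


# ---------------------------------------------------------------------------
# trial container

@dataclass
class TrialRecord:
    """One trial's synchronized 14 Hz multimodal bundle."""

    tactile_gray8: np.ndarray  # (T, 64, 64) uint8
    tactile_wma_cop: np.ndarray  # (T, 2) mm [ML, AP]
    truth_cop: np.ndarray  # (T, 2) mm [ML, AP]
    angular_features: np.ndarray  # (T, 18) deg, deg/s, deg/s^2
    subject_features: np.ndarray  # (S,)
    subject_id: str
    protocol_id: int  # 1..4
    sensor_width_mm: float
    sensor_length_mm: float
    timestamps: np.ndarray  # (T,) s

    def __post_init__(self) -> None:
        lengths = {
            "tactile_gray8": len(self.tactile_gray8),
            "tactile_wma_cop": len(self.tactile_wma_cop),
            "truth_cop": len(self.truth_cop),
            "angular_features": len(self.angular_features),
            "timestamps": len(self.timestamps),
        }
        if len(set(lengths.values())) != 1:
            raise ValueError(f"dataset length mismatch: {lengths}")
        if not 1 <= self.protocol_id <= len(PROTOCOL_IDS):
            raise ValueError("protocol_id must be in 1..4")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def protocol_name(self) -> str:
        return PROTOCOL_IDS[self.protocol_id - 1]

    def settings_vector(self) -> np.ndarray:
        """Protocol one-hot plus the sensor's physical width and length."""
        onehot = np.zeros(len(PROTOCOL_IDS))
        onehot[self.protocol_id - 1] = 1.0
        return np.concatenate([onehot, [self.sensor_width_mm, self.sensor_length_mm]])


def build_trial_record(
    streams: dict,
    subject_features: np.ndarray,
    subject_id: str,
    protocol_id: int,
    sensor_width_mm: float,
    sensor_length_mm: float,
    timestamps: np.ndarray,
) -> TrialRecord:
    """Assemble already-synchronized streams into a validated record."""
    return TrialRecord(
        tactile_gray8=np.asarray(streams["tactile_gray8"], dtype=np.uint8),
        tactile_wma_cop=np.asarray(streams["tactile_wma_cop"], dtype=float),
        truth_cop=np.asarray(streams["truth_cop"], dtype=float),
        angular_features=np.asarray(streams["angular_features"], dtype=float),
        subject_features=np.asarray(subject_features, dtype=float),
        subject_id=subject_id,
        protocol_id=int(protocol_id),
        sensor_width_mm=float(sensor_width_mm),
        sensor_length_mm=float(sensor_length_mm),
        timestamps=np.asarray(timestamps, dtype=float),
    )


def write_trial_record(record: TrialRecord, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["subject_id"] = record.subject_id
        f.attrs["protocol_id"] = record.protocol_id
        f.attrs["sensor_width_mm"] = record.sensor_width_mm
        f.attrs["sensor_length_mm"] = record.sensor_length_mm
        f.create_dataset("tactile_gray8", data=record.tactile_gray8, dtype="uint8")
        for name, units in (
            ("tactile_wma_cop", "mm"),
            ("truth_cop", "mm"),
            ("angular_features", "deg, deg/s, deg/s^2"),
            ("subject_features", "mixed"),
            ("timestamps", "s"),
        ):
            d = f.create_dataset(name, data=getattr(record, name), dtype="float64")
            d.attrs["units"] = units


def read_trial_record(path) -> TrialRecord:
    with h5py.File(path, "r") as f:
        return TrialRecord(
            tactile_gray8=f["tactile_gray8"][()],
            tactile_wma_cop=f["tactile_wma_cop"][()],
            truth_cop=f["truth_cop"][()],
            angular_features=f["angular_features"][()],
            subject_features=f["subject_features"][()],
            subject_id=str(f.attrs["subject_id"]),
            protocol_id=int(f.attrs["protocol_id"]),
            sensor_width_mm=float(f.attrs["sensor_width_mm"]),
            sensor_length_mm=float(f.attrs["sensor_length_mm"]),
            timestamps=f["timestamps"][()],
        )


# ---------------------------------------------------------------------------
# full assembly of a simulated trial

def assemble_trial(
    trial: SyntheticTrial,
    geometry: tp.SensorGeometry | None = None,
    cam_a: pk.CameraModel | None = None,
    cam_b: pk.CameraModel | None = None,
    noise=None,
    baseline_frames: np.ndarray | None = None,
    threshold: float | None = None,
    norm_constants: tp.NormalizationConstants | None = None,
) -> TrialRecord:
    """Run the full preprocessing + synchronization chain on one trial.

    Tactile: stitch -> baseline-correct -> normalize/quantize ->
    denoise -> fill dropped frames -> WMA CoP -> resample to the
    reference grid.  Pose: triangulate both views -> fill invalid
    gaps -> 2 Hz zero-phase low-pass -> joint angles -> resample ->
    derivatives at 14 Hz.  Truth: 10 Hz zero-phase low-pass -> sampled
    on the reference grid.
    """
    from .sensor_sim import default_camera_pair, render_no_load_frames

    geometry = geometry or tp.SensorGeometry()
    if cam_a is None or cam_b is None:
        cam_a, cam_b = default_camera_pair(geometry)
    if baseline_frames is None:
        baseline_frames = render_no_load_frames(
            noise, geometry=geometry, rng=np.random.default_rng(trial.seed + 3)
        )

    ref = reference_grid(trial.protocol.duration_s, trial.protocol.analysis_window_s)

    # --- tactile chain
    gray, _ = tp.preprocess_raw_modules(
        trial.tactile_modules, trial.tactile_times, baseline_frames,
        geometry=geometry, threshold=threshold, constants=norm_constants,
    )
    t0 = trial.tactile_times[0]
    expected = np.arange(t0, trial.protocol.duration_s, 1.0 / 14.0)
    gray = tp.fill_dropped_frames(gray, expected)
    wma = tp.wma_cop_sequence(gray, geometry)
    gray_stream = TimedStream(gray.timestamps, gray.values, 14.0)
    wma_stream = TimedStream(gray.timestamps, wma, 14.0)
    tactile_ref = np.clip(np.round(resample_to_reference(gray_stream, ref)), 0, 255)
    wma_ref = resample_to_reference(wma_stream, ref)

    # --- truth chain
    truth = TimedStream(trial.truth_times, trial.truth_cop, 1000.0)
    truth = lowpass_truth_cop(truth)
    truth_ref = resample_to_reference(truth, ref)

    # --- pose chain
    pos3d, ok = pk.triangulate_tracks(
        trial.keypoints_2d["cam_a"], trial.keypoints_2d["cam_b"],
        trial.keypoints_valid["cam_a"], trial.keypoints_valid["cam_b"],
        cam_a, cam_b,
    )
    track = pk.KeypointTrack3D(pos3d, ok, fs=30.0)
    track, flagged = pk.fill_invalid_keypoints(track)
    track = pk.lowpass_track(track, cutoff=2.0, order=4)
    angles = pk.joint_angle_tracks(track)
    angle_mat = np.stack([angles[(j, s)] for j in ("hip", "knee", "ankle")
                          for s in ("left", "right")], axis=1)
    angle_stream = TimedStream(trial.camera_times, angle_mat, 30.0)
    angles_ref = resample_to_reference(angle_stream, ref)
    angles_ref_dict = {
        (j, s): angles_ref[:, i]
        for i, (j, s) in enumerate(
            (j, s) for j in ("hip", "knee", "ankle") for s in ("left", "right")
        )
    }
    feats = pk.angular_features(angles_ref_dict, fs=REFERENCE_FS)

    record = build_trial_record(
        streams=dict(
            tactile_gray8=tactile_ref.astype(np.uint8),
            tactile_wma_cop=wma_ref,
            truth_cop=truth_ref,
            angular_features=feats,
        ),
        subject_features=trial.subject.static_features(),
        subject_id=trial.subject.subject_id,
        protocol_id=trial.protocol.numeric_id,
        sensor_width_mm=geometry.width_mm,
        sensor_length_mm=geometry.length_mm,
        timestamps=ref,
    )
    if flagged:
        warnings.warn(f"trial {trial.subject.subject_id}: long invalid-keypoint gap")
    return record
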