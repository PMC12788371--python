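"""Seeded synthetic cohorts, balance trials and raw multi-rate sensor streams.

Stands in for a private human cohort: anthropometrics are drawn from the
published cohort moments, four balance protocols (one-leg stance, tandem
stance, squat at one repetition per 3 s, walking-in-place) drive foot
load schedules and sway trajectories, and ground-truth CoP is the
analytic load-weighted centroid of the simulated foot loads:

    cop(t) = sum_f load_f(t) * center_f(t) / sum_f load_f(t)

Pressure frames render each foot as a truncated anisotropic Gaussian
blob over the foot ellipse, then apply the sensor defect model in the
order: gamma nonlinearity -> per-module gain/offset -> salt-and-pepper
noise -> frame drops.  A 33-keypoint skeleton, kinematically phase-locked
to the protocol (squat knee flexion follows the AP CoP oscillation,
walking-in-place leg lifts follow the load alternation), is projected to
two pinhole cameras at 30 Hz.

All coordinates are in the mat frame used by the weighted-mean CoP: cell
``i`` (1-based) sits at ``i * pitch`` along its axis, ML along the mat
width, AP along the length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .pose_kinematics import (
    N_KEYPOINTS,
    LANDMARK,
    CameraModel,
)
from .tactile_pipeline import SATURATION_KPA, SensorGeometry

GRAVITY = 9.81  # m/s^2
TACTILE_FS = 14.0  # Hz, native pressure-mat rate
CAMERA_FS = 30.0  # Hz
TRUTH_FS = 1000.0  # Hz, force-plate reference rate

PROTOCOL_IDS = ("one_leg", "tandem", "squat", "walk_in_place")
DYNAMIC_PROTOCOLS = ("squat", "walk_in_place")

# cohort moments: mean age 22.7 +/- 1.6 y, height 171.6 +/- 7.8 cm,
# weight 73.4 +/- 13.5 kg, 15:8 male:female
COHORT_MOMENTS = {"age": (22.7, 1.6), "height": (171.6, 7.8), "weight": (73.4, 13.5)}
MALE_FRACTION = 15 / 23


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    gender: str  # "M" | "F"
    age: float  # years
    height: float  # cm
    weight: float  # kg
    lean_mass: float  # kg
    upper_limb_length: float  # cm
    lower_limb_length: float  # cm
    waist_hip_ratio: float
    foot_length: float  # cm
    foot_width: float  # cm
    dominant_foot: str  # "L" | "R"

    def __post_init__(self) -> None:
        for name in ("age", "height", "weight", "lean_mass", "upper_limb_length",
                     "lower_limb_length", "foot_length", "foot_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.4 < self.waist_hip_ratio < 1.5:
            raise ValueError("waist_hip_ratio outside (0.4, 1.5)")
        if self.foot_length >= self.height:
            raise ValueError("foot_length must be smaller than height")
        if self.gender not in ("M", "F") or self.dominant_foot not in ("L", "R"):
            raise ValueError("bad categorical field")

    def static_features(self) -> np.ndarray:
        """The six default subject characteristics, gender one-hot first."""
        return np.array([
            1.0 if self.gender == "M" else 0.0,
            self.weight,
            self.lean_mass,
            self.upper_limb_length,
            self.lower_limb_length,
            self.waist_hip_ratio,
        ])


@dataclass(frozen=True)
class ProtocolSpec:
    protocol_id: str
    is_dynamic: bool
    duration_s: float = 90.0
    analysis_window_s: float = 80.0
    sway_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protocol_id not in PROTOCOL_IDS:
            raise ValueError(f"unknown protocol {self.protocol_id!r}")
        if self.analysis_window_s > self.duration_s:
            raise ValueError("analysis window exceeds trial duration")
        if self.is_dynamic != (self.protocol_id in DYNAMIC_PROTOCOLS):
            raise ValueError("is_dynamic inconsistent with protocol_id")

    @property
    def numeric_id(self) -> int:
        return PROTOCOL_IDS.index(self.protocol_id) + 1


# sway/trajectory defaults; the paper-scale protocol timing (90 s trials,
# middle 80 s, squat period 3 s) with invented sway magnitudes echoing
# clinical postural-sway scales
_DEFAULT_SWAY = {
    "one_leg": dict(sway_sd_ml_mm=8.0, sway_sd_ap_mm=10.0, sway_lowpass_hz=1.0),
    "tandem": dict(sway_sd_ml_mm=12.0, sway_sd_ap_mm=6.0, sway_lowpass_hz=1.0),
    "squat": dict(sway_sd_ml_mm=3.0, sway_sd_ap_mm=3.0, sway_lowpass_hz=1.0,
                  squat_amp_ap_mm=60.0, squat_period_s=3.0, load_mod=0.2),
    "walk_in_place": dict(sway_sd_ml_mm=4.0, sway_sd_ap_mm=4.0, sway_lowpass_hz=1.0,
                          cadence_hz=1.0, load_swing=0.9, lift_m=0.05),
}


def default_protocols(duration_s: float = 90.0, analysis_window_s: float = 80.0):
    """The four balance protocols with default trajectory parameters."""
    return {
        pid: ProtocolSpec(
            protocol_id=pid,
            is_dynamic=pid in DYNAMIC_PROTOCOLS,
            duration_s=duration_s,
            analysis_window_s=analysis_window_s,
            sway_params=dict(_DEFAULT_SWAY[pid]),
        )
        for pid in PROTOCOL_IDS
    }


def default_trial_schedule(protocols=None, reps: int = 2):
    """The per-subject trial list: every protocol, ``reps`` repetitions."""
    protocols = protocols or default_protocols()
    return [(protocols[pid], r) for pid in PROTOCOL_IDS for r in range(reps)]


@dataclass(frozen=True)
class NoiseModel:
    """Sensor defect model of the pressure mat.

    ``gamma=1``, unit gains, zero offsets and zero rates define the
    ideal linear mode.  Measured pressure follows
    ``true ** gamma`` (on the saturation-normalized scale), then
    per-module gain/offset, salt-and-pepper noise and frame drops.
    """

    module_baseline: tuple = (0.0, 0.0, 0.0, 0.0)  # raw units (kPa)
    module_gain: tuple = (1.0, 1.0, 1.0, 1.0)
    gamma: float = 1.0
    sp_noise_rate: float = 0.0  # per cell per frame
    drop_rate: float = 0.0  # per tactile frame
    drift_rate: float = 0.0  # baseline units per minute
    keypoint_noise_px: float = 0.0  # Gaussian pixel noise on 2D keypoints
    # fixed-pattern cell-to-cell sensitivity spread of the piezoresistive
    # array; the gain map is frozen by cell_gain_seed (a sensor property,
    # identical across trials)
    cell_gain_sd: float = 0.0
    cell_gain_seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        for r in (self.sp_noise_rate, self.drop_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @classmethod
    def ideal(cls) -> "NoiseModel":
        return cls()

    @classmethod
    def default_nonlinear(cls, rng: np.random.Generator | None = None) -> "NoiseModel":
        """The default imperfect sensor: gamma 0.7, +/-20% module gains."""
        rng = rng or np.random.default_rng(0)
        gains = tuple(rng.uniform(0.8, 1.2, size=4))
        return cls(module_gain=gains, gamma=0.7, sp_noise_rate=0.002,
                   drop_rate=0.01, keypoint_noise_px=0.5,
                   cell_gain_sd=0.25, cell_gain_seed=int(rng.integers(2**31)))


@dataclass
class SyntheticTrial:
    """One simulated trial: raw multi-rate streams plus analytic truth."""

    subject: SubjectProfile
    protocol: ProtocolSpec
    seed: int
    # truth at 1000 Hz
    truth_times: np.ndarray  # (N,)
    truth_cop: np.ndarray  # (N, 2) [ML, AP] mm
    foot_centers: np.ndarray  # (N, n_feet, 2) mm
    foot_loads: np.ndarray  # (N, n_feet) N
    # raw tactile (with drops): module streams
    tactile_times: np.ndarray  # (Tt,)
    tactile_modules: np.ndarray  # (Tt, 4, 32, 32) raw units
    # two-camera 2D keypoints at 30 Hz
    camera_times: np.ndarray  # (Tc,)
    keypoints_2d: dict  # {"cam_a": (Tc,33,2), "cam_b": ...}
    keypoints_valid: dict  # {"cam_a": (Tc,33) bool, ...}
    truth_kinematics: dict  # {(joint, side): (Tc,) degrees}
    metadata: dict = field(default_factory=dict)
    # pressure-lobe layout actually rendered (heel/forefoot bimodal by
    # default); truth_cop is the exact load centroid of these components
    render_centers: np.ndarray | None = None
    render_loads: np.ndarray | None = None


# ---------------------------------------------------------------------------
# cohort generation

def _truncated_normal(rng, mean, sd, size, lower=1e-6):
    x = rng.normal(mean, sd, size=size)
    while np.any(x <= lower):
        bad = x <= lower
        x[bad] = rng.normal(mean, sd, size=bad.sum())
    return x


def make_cohort(n_subjects: int, seed: int) -> list[SubjectProfile]:
    """Draw a cohort from the stated anthropometric distributions.

    Ages, heights and weights are normal with the cohort moments,
    truncated to positive values; derived measures (lean mass, limb
    lengths, foot dimensions, waist-hip ratio) follow standard
    anthropometric proportions with individual scatter.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    genders = np.where(rng.random(n_subjects) < MALE_FRACTION, "M", "F")
    age = _truncated_normal(rng, *COHORT_MOMENTS["age"], n_subjects)
    height = _truncated_normal(rng, *COHORT_MOMENTS["height"], n_subjects)
    weight = _truncated_normal(rng, *COHORT_MOMENTS["weight"], n_subjects)
    profiles = []
    for i in range(n_subjects):
        male = genders[i] == "M"
        lean_frac = rng.normal(0.80 if male else 0.70, 0.03)
        lean_frac = float(np.clip(lean_frac, 0.5, 0.95))
        whr = float(np.clip(rng.normal(0.88 if male else 0.78, 0.04), 0.5, 1.2))
        foot_len = float(np.clip(rng.normal(0.152 * height[i], 0.6), 18.0, 35.0))
        profiles.append(SubjectProfile(
            subject_id=f"S{i:03d}",
            gender=str(genders[i]),
            age=float(age[i]),
            height=float(height[i]),
            weight=float(weight[i]),
            lean_mass=float(lean_frac * weight[i]),
            upper_limb_length=float(rng.normal(0.44 * height[i], 1.5)),
            lower_limb_length=float(rng.normal(0.53 * height[i], 1.5)),
            waist_hip_ratio=whr,
            foot_length=foot_len,
            foot_width=float(np.clip(rng.normal(0.38 * foot_len, 0.4), 6.0, 14.0)),
            dominant_foot="R" if rng.random() < 0.9 else "L",
        ))
    return profiles


# ---------------------------------------------------------------------------
# trial dynamics

def _lowpassed_sway(rng, n, fs, sd_mm, cutoff_hz):
    """Gaussian white noise low-passed at ``cutoff_hz``, rescaled to sd.

    Excursions are softly bounded at 3 sd (tanh) — postural sway is
    limited by the base of support, while the narrowband process would
    otherwise produce 6-8 sd ranges over a trial.
    """
    if sd_mm == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = signal.butter(2, cutoff_hz, fs=fs, output="sos")
    s = signal.sosfiltfilt(sos, white)
    s = s - s.mean()
    std = s.std()
    if std == 0:
        return np.zeros(n)
    s = s / std * sd_mm
    return 3.0 * sd_mm * np.tanh(s / (3.0 * sd_mm))


def _foot_positions(protocol: ProtocolSpec, subject: SubjectProfile,
                    geometry: SensorGeometry) -> np.ndarray:
    """Nominal foot-center positions (n_feet, 2) [ML, AP] mm."""
    cml = geometry.ml_extent_mm / 2.0
    cap = geometry.ap_extent_mm / 2.0
    fl = subject.foot_length * 10.0  # cm -> mm
    pid = protocol.protocol_id
    if pid == "one_leg":
        return np.array([[cml, cap]])
    if pid == "tandem":
        # dominant foot in front (larger AP), rear toe touching front heel
        return np.array([[cml, cap + fl / 2], [cml, cap - fl / 2]])
    # squat / walking-in-place: side-by-side, shoulder-width stance
    half = 100.0
    return np.array([[cml - half, cap], [cml + half, cap]])


def simulate_trial(
    subject: SubjectProfile,
    protocol: ProtocolSpec,
    noise: NoiseModel,
    geometry: SensorGeometry | None = None,
    seed: int = 0,
    cam_a: CameraModel | None = None,
    cam_b: CameraModel | None = None,
    bimodal_feet: bool = True,
) -> SyntheticTrial:
    """Simulate one trial: truth CoP, raw tactile frames, 2D keypoints.

    The ground-truth CoP at 1000 Hz is exactly the load-weighted
    centroid of the per-foot loads; total vertical load equals subject
    weight (phase-modulated for the dynamic protocols).
    """
    geometry = geometry or SensorGeometry()
    if protocol.duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    p = protocol.sway_params
    n = int(round(protocol.duration_s * TRUTH_FS))
    t = np.arange(n) / TRUTH_FS
    centers0 = _foot_positions(protocol, subject, geometry)
    n_feet = len(centers0)
    # per-trial stance placement: subjects do not stand at the exact same
    # spot; Gaussian offsets truncated so every pressure lobe stays on-mat
    sig_ml_mm = subject.foot_width * 10.0 / 4.0
    sig_ap_lobe = subject.foot_length * 10.0 / 8.0
    margin_ml = 2.5 * sig_ml_mm + 25.0
    margin_ap = 0.25 * subject.foot_length * 10.0 + 2.5 * sig_ap_lobe + 60.0
    off = rng.normal(0.0, (30.0, 40.0))
    off[0] = np.clip(off[0], margin_ml - centers0[:, 0].min(),
                     geometry.ml_extent_mm - margin_ml - centers0[:, 0].max())
    off[1] = np.clip(off[1], margin_ap - centers0[:, 1].min(),
                     geometry.ap_extent_mm - margin_ap - centers0[:, 1].max())
    centers0 = centers0 + off
    total_n = subject.weight * GRAVITY

    sway_ml = _lowpassed_sway(rng, n, TRUTH_FS, p.get("sway_sd_ml_mm", 0.0),
                              p.get("sway_lowpass_hz", 1.0))
    sway_ap = _lowpassed_sway(rng, n, TRUTH_FS, p.get("sway_sd_ap_mm", 0.0),
                              p.get("sway_lowpass_hz", 1.0))

    centers = np.broadcast_to(centers0, (n, n_feet, 2)).copy()
    centers[:, :, 0] += sway_ml[:, None]
    centers[:, :, 1] += sway_ap[:, None]

    pid = protocol.protocol_id
    if pid == "squat":
        period = p.get("squat_period_s", 3.0)
        amp = p.get("squat_amp_ap_mm", 40.0)
        osc = np.cos(2 * np.pi * t / period)
        centers[:, :, 1] += amp * osc[:, None]
        loads = np.full((n, n_feet), 1.0 / n_feet)
        total = total_n * (1.0 + p.get("load_mod", 0.2) * np.sin(2 * np.pi * t / period))
    elif pid == "walk_in_place":
        cadence = p.get("cadence_hz", 1.0)
        swing = p.get("load_swing", 0.9)
        s = np.sin(2 * np.pi * cadence * t)
        loads = np.stack([(1 + swing * s) / 2, (1 - swing * s) / 2], axis=1)
        total = total_n * (1.0 + 0.05 * np.sin(4 * np.pi * cadence * t))
    else:
        loads = np.full((n, n_feet), 1.0 / n_feet)
        total = np.full(n, total_n)

    foot_loads = loads * total[:, None]

    if bimodal_feet:
        # two pressure lobes (heel / forefoot) per foot at fixed AP offsets;
        # the load split between lobes is solved so that each foot's load
        # centroid equals its commanded CoP exactly
        d = 0.25 * subject.foot_length * 10.0  # lobe half-separation, mm
        n_lobes = 2 * n_feet
        lobe_centers = np.empty((n, n_lobes, 2))
        lobe_loads = np.empty((n, n_lobes))
        for f in range(n_feet):
            base_ap = centers0[f, 1]
            c_ap = centers[:, f, 1]
            alpha = np.clip((base_ap + d - c_ap) / (2 * d), 0.02, 0.98)  # heel share
            for k, (off, share) in enumerate(((-d, alpha), (d, 1 - alpha))):
                lobe_centers[:, 2 * f + k, 0] = centers[:, f, 0]
                lobe_centers[:, 2 * f + k, 1] = base_ap + off
                lobe_loads[:, 2 * f + k] = foot_loads[:, f] * share
        render_centers, render_loads = lobe_centers, lobe_loads
        sigma_ap = subject.foot_length * 10.0 / 8.0
    else:
        render_centers, render_loads = centers, foot_loads
        sigma_ap = subject.foot_length * 10.0 / 4.0

    truth_cop = (np.einsum("nf,nfa->na", render_loads, render_centers)
                 / render_loads.sum(axis=1)[:, None])

    lo = np.zeros(2)
    hi = np.array([geometry.ml_extent_mm, geometry.ap_extent_mm])
    if np.any(truth_cop < lo) or np.any(truth_cop > hi):
        raise ValueError("truth CoP left the mat extent; check sway parameters")

    trial = SyntheticTrial(
        subject=subject, protocol=protocol, seed=seed,
        truth_times=t, truth_cop=truth_cop,
        foot_centers=centers, foot_loads=foot_loads,
        tactile_times=np.empty(0), tactile_modules=np.empty((0, 4, 32, 32)),
        camera_times=np.empty(0), keypoints_2d={}, keypoints_valid={},
        truth_kinematics={},
        metadata=dict(
            sigma_ml_mm=subject.foot_width * 10.0 / 4.0,
            sigma_ap_mm=sigma_ap,
        ),
    )
    trial.render_centers = render_centers
    trial.render_loads = render_loads
    render_pressure_sequence(trial, noise, geometry,
                             rng=np.random.default_rng(rng.integers(2**31)))
    if cam_a is None or cam_b is None:
        cam_a, cam_b = default_camera_pair(geometry)
    simulate_skeleton_and_project(
        trial, cam_a, cam_b, geometry,
        pixel_noise_px=noise.keypoint_noise_px,
        rng=np.random.default_rng(rng.integers(2**31)),
    )
    return trial


# ---------------------------------------------------------------------------
# pressure rendering

def _sample_hf(times: np.ndarray, t_hf: np.ndarray, centers_hf: np.ndarray,
               loads_hf: np.ndarray):
    """Interpolate per-component centers/loads from the 1000 Hz truth grid."""
    nf = centers_hf.shape[1]
    centers = np.stack([
        np.stack([np.interp(times, t_hf, centers_hf[:, f, a]) for a in (0, 1)], axis=1)
        for f in range(nf)
    ], axis=1)
    loads = np.stack([np.interp(times, t_hf, loads_hf[:, f]) for f in range(nf)], axis=1)
    return centers, loads


def _render_frame(centers, loads, sig_ml, sig_ap, geometry, pressure_scale):
    """One stitched 64x64 frame of truncated-Gaussian pressure lobes, kPa."""
    g = geometry
    ml = (np.arange(g.n_cols) + g.index_base) * g.ml_extent_mm / g.n_cols
    ap = (np.arange(g.n_rows) + g.index_base) * g.ap_extent_mm / g.n_rows
    ML, AP = np.meshgrid(ml, ap)  # (rows, cols): rows index AP
    frame = np.zeros((g.n_rows, g.n_cols))
    truncated = False
    for (cml, cap), load in zip(centers, loads):
        if load <= 0:
            continue
        d2 = ((ML - cml) / sig_ml) ** 2 + ((AP - cap) / sig_ap) ** 2
        blob = np.where(d2 <= 2.5**2, np.exp(-0.5 * d2), 0.0)
        mass = blob.sum() * g.cell_area_mm2  # mm^2
        if mass <= 0:
            truncated = True
            continue
        # load [N] / mm^2 = MPa -> kPa, times the sensor's response scale
        frame += blob * (load / mass) * 1000.0 * pressure_scale
        if (cml - 2.5 * sig_ml < ml[0] or cml + 2.5 * sig_ml > ml[-1]
                or cap - 2.5 * sig_ap < ap[0] or cap + 2.5 * sig_ap > ap[-1]):
            truncated = True
    return frame, truncated


def reference_pressure_scale(geometry: SensorGeometry | None = None) -> float:
    """Sensor response scale: peak cell ~60% of saturation for 73 kg.

    Calibrated on the worst-case stance: the full reference weight on
    one foot (26 cm x 9.9 cm) with a 75% heel/forefoot load shift; the
    peak raw lobe pressure is ``load / (2 pi sig_ml sig_ap)``.
    """
    sig_ml, sig_ap = 99.0 / 4.0, 260.0 / 8.0
    peak_raw_kpa = (0.75 * 73.0 * GRAVITY) / (2 * np.pi * sig_ml * sig_ap) * 1000.0
    return 0.6 * SATURATION_KPA / peak_raw_kpa


def render_pressure_sequence(
    trial: SyntheticTrial,
    noise: NoiseModel,
    geometry: SensorGeometry | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the raw four-module tactile streams of a trial, in place.

    Applies the defect model in order (gamma -> gain/offset -> salt &
    pepper -> frame drops) and returns ``(timestamps, modules)`` with
    modules shaped (T, 4, 32, 32).  The acquisition start is jittered
    within one tactile frame interval (manual-trigger emulation).
    """
    geometry = geometry or SensorGeometry()
    rng = rng or np.random.default_rng(trial.seed + 1)
    scale = reference_pressure_scale(geometry)
    jitter = rng.uniform(0, 1.0 / TACTILE_FS)
    times = np.arange(jitter, trial.protocol.duration_s, 1.0 / TACTILE_FS)
    chf = trial.render_centers if trial.render_centers is not None else trial.foot_centers
    lhf = trial.render_loads if trial.render_loads is not None else trial.foot_loads
    centers, loads = _sample_hf(times, trial.truth_times, chf, lhf)
    sig_ml = trial.metadata.get("sigma_ml_mm", trial.subject.foot_width * 10.0 / 4.0)
    sig_ap = trial.metadata.get("sigma_ap_mm", trial.subject.foot_length * 10.0 / 4.0)

    frames = np.empty((len(times), geometry.n_rows, geometry.n_cols))
    truncated_any = False
    for i in range(len(times)):
        frames[i], trunc = _render_frame(centers[i], loads[i], sig_ml, sig_ap,
                                         geometry, scale)
        truncated_any = truncated_any or trunc
    if truncated_any:
        import warnings

        warnings.warn("foot blob extends off-mat; pressure truncated")
        trial.metadata["truncated"] = True
    np.clip(frames, 0.0, SATURATION_KPA, out=frames)

    # gamma nonlinearity on the saturation-normalized scale
    if noise.gamma != 1.0:
        frames = (frames / SATURATION_KPA) ** noise.gamma * SATURATION_KPA
    # fixed-pattern cell sensitivity map (same across trials of a sensor)
    if noise.cell_gain_sd > 0:
        cell_rng = np.random.default_rng(noise.cell_gain_seed)
        cell_gain = np.clip(
            1.0 + noise.cell_gain_sd * cell_rng.standard_normal(
                (geometry.n_rows, geometry.n_cols)), 0.1, None)
        frames = frames * cell_gain
    # per-module gain / offset (+ slow baseline drift)
    mr, mc = geometry.module_shape
    for k in range(4):
        r, c = divmod(k, geometry.module_tiling[1])
        sl = np.s_[:, r * mr:(r + 1) * mr, c * mc:(c + 1) * mc]
        drift = noise.drift_rate * times / 60.0
        frames[sl] = frames[sl] * noise.module_gain[k] + noise.module_baseline[k] \
            + drift[:, None, None]
    np.clip(frames, 0.0, None, out=frames)
    # salt-and-pepper
    if noise.sp_noise_rate > 0:
        mask = rng.random(frames.shape) < noise.sp_noise_rate
        salt = rng.random(frames.shape) < 0.5
        frames[mask & salt] = SATURATION_KPA
        frames[mask & ~salt] = 0.0
    # frame drops (first/last kept so interpolation has anchors)
    keep = rng.random(len(times)) >= noise.drop_rate
    keep[0] = keep[-1] = True
    times, frames = times[keep], frames[keep]

    modules = np.empty((len(times), 4, mr, mc), dtype=frames.dtype)
    for k in range(4):
        r, c = divmod(k, geometry.module_tiling[1])
        modules[:, k] = frames[:, r * mr:(r + 1) * mr, c * mc:(c + 1) * mc]
    trial.tactile_times = times
    trial.tactile_modules = modules
    return times, modules


def render_no_load_frames(
    noise: NoiseModel | None = None,
    geometry: SensorGeometry | None = None,
    n_frames: int = 20,
    rng: np.random.Generator | None = None,
    jitter_kpa: float = 0.02,
) -> np.ndarray:
    """Stitched no-load calibration frames (default 20) for baselining.

    Each frame is the per-module baseline offset plus small electronic
    jitter — what the mat reads with nothing placed on it.
    """
    noise = noise or NoiseModel.ideal()
    geometry = geometry or SensorGeometry()
    rng = rng or np.random.default_rng(0)
    mr, mc = geometry.module_shape
    frames = rng.normal(0.0, jitter_kpa, size=(n_frames, geometry.n_rows, geometry.n_cols))
    for k in range(4):
        r, c = divmod(k, geometry.module_tiling[1])
        frames[:, r * mr:(r + 1) * mr, c * mc:(c + 1) * mc] += noise.module_baseline[k]
    return np.clip(frames, 0.0, None)


# ---------------------------------------------------------------------------
# skeleton synthesis and stereo projection

def default_camera_pair(geometry: SensorGeometry | None = None):
    """Two cameras ~2 m in front of the mat, 1 m apart, facing the subject."""
    geometry = geometry or SensorGeometry()
    cx = geometry.ml_extent_mm / 2000.0  # m
    cy = geometry.ap_extent_mm / 2000.0
    K = np.array([[800.0, 0.0, 320.0], [0.0, 800.0, 240.0], [0.0, 0.0, 1.0]])

    def lookat(eye, target, up=(0, 0, 1.0)):
        eye = np.asarray(eye, float)
        fwd = np.asarray(target, float) - eye
        fwd /= np.linalg.norm(fwd)
        right = np.cross(fwd, np.asarray(up, float))
        right /= np.linalg.norm(right)
        down = np.cross(fwd, right)
        R = np.stack([right, down, fwd])
        # re-orthonormalize against rounding
        u, _, vt = np.linalg.svd(R)
        R = u @ vt
        return CameraModel(K, R, -R @ eye)

    target = (cx, cy, 0.9)
    return (
        lookat((cx - 0.5, cy - 2.0, 1.2), target),
        lookat((cx + 0.5, cy - 2.0, 1.2), target),
    )


def _skeleton_frames(trial: SyntheticTrial, times: np.ndarray,
                     geometry: SensorGeometry, rng: np.random.Generator):
    """World-frame (T, 33, 3) skeleton consistent with the protocol."""
    subj = trial.subject
    p = trial.protocol.sway_params
    pid = trial.protocol.protocol_id
    leg_m = subj.lower_limb_length / 100.0  # m
    thigh, shank = 0.46 * leg_m, 0.44 * leg_m
    torso = 0.30 * subj.height / 100.0
    foot_m = subj.foot_length / 100.0

    centers, loads = _sample_hf(times, trial.truth_times, trial.foot_centers,
                                trial.foot_loads)
    T = len(times)
    # per-leg knee flexion deviation delta(t): interior knee angle = 180 - 2*delta
    delta = np.zeros((T, 2))
    lift = np.zeros((T, 2))
    if pid == "squat":
        period = p.get("squat_period_s", 3.0)
        phase = (1 - np.cos(2 * np.pi * times / period)) / 2  # 0 at top
        delta[:, 0] = delta[:, 1] = np.radians(5 + 45 * phase)
    elif pid == "walk_in_place":
        cadence = p.get("cadence_hz", 1.0)
        s = np.sin(2 * np.pi * cadence * times)
        # a leg flexes and lifts while unloaded (left unloaded when s < 0)
        delta[:, 0] = np.radians(5 + 40 * np.clip(-s, 0, 1))
        delta[:, 1] = np.radians(5 + 40 * np.clip(s, 0, 1))
        lift[:, 0] = p.get("lift_m", 0.05) * np.clip(-s, 0, 1)
        lift[:, 1] = p.get("lift_m", 0.05) * np.clip(s, 0, 1)
    else:
        delta[:] = np.radians(5.0)
        if pid == "one_leg":
            # lifted non-dominant leg held flexed
            delta[:, 0 if subj.dominant_foot == "R" else 1] = np.radians(45.0)
            lift[:, 0 if subj.dominant_foot == "R" else 1] = 0.15
    delta += np.radians(0.3) * rng.standard_normal((T, 2))

    # ankle ML/AP positions follow the foot centers (mm -> m); single-support
    # protocols reuse the support-foot column for the lifted foot
    if centers.shape[1] == 1:
        centers = np.repeat(centers, 2, axis=1)
        li = 0 if subj.dominant_foot == "R" else 1  # lifted (non-dominant) leg
        centers[:, li, 0] += -90.0 if li == 0 else 90.0
    ankle_ml = centers[:, :, 0] / 1000.0
    ankle_ap = centers[:, :, 1] / 1000.0
    ankle_z = 0.08 + lift

    pts = np.zeros((T, N_KEYPOINTS, 3))

    def setp(name, xyz):
        pts[:, LANDMARK[name]] = xyz

    sides = {"left": 0, "right": 1}
    knee = np.zeros((T, 2, 3))
    hip = np.zeros((T, 2, 3))
    for side, i in sides.items():
        d = delta[:, i]
        ank = np.stack([ankle_ml[:, i], ankle_ap[:, i], ankle_z[:, i]], axis=1)
        kne = ank + np.stack([np.zeros(T), shank * np.sin(d), shank * np.cos(d)], axis=1)
        hp = kne + np.stack([np.zeros(T), -thigh * np.sin(d), thigh * np.cos(d)], axis=1)
        knee[:, i] = kne
        hip[:, i] = hp
        setp(f"{side}_ankle", ank)
        setp(f"{side}_knee", kne)
        setp(f"{side}_hip", hp)
        setp(f"{side}_heel", ank + np.array([0.0, -0.06, -0.05]))
        setp(f"{side}_foot_index", ank + np.array([0.0, 0.7 * foot_m, -0.05]))
    # keep hips a fixed pelvic width apart around their midpoint
    mid = hip.mean(axis=1)
    hw = 0.09
    for side, i in sides.items():
        hp = mid.copy()
        hp[:, 0] += -hw if side == "left" else hw
        hp[:, 2] = hip[:, i, 2]
        pts[:, LANDMARK[f"{side}_hip"]] = hp
    shoulder_mid = mid.copy()
    shoulder_mid[:, 2] = np.maximum(hip[:, 0, 2], hip[:, 1, 2]) + torso
    for side, i in sides.items():
        sh = shoulder_mid.copy()
        sh[:, 0] += -0.17 if side == "left" else 0.17
        pts[:, LANDMARK[f"{side}_shoulder"]] = sh
    head = shoulder_mid + np.array([0.0, 0.02, 0.25])
    # face landmarks 0..10 clustered at the head; arm/hand landmarks hang
    # from the shoulders — plausible placeholders, not used by kinematics
    for k in range(0, 11):
        pts[:, k] = head + 0.02 * np.array([(k % 3) - 1, 0.2, (k % 2)])
    for side, i in sides.items():
        sh = pts[:, LANDMARK[f"{side}_shoulder"]]
        elbow = sh + np.array([0.0, 0.02, -0.28])
        wrist = elbow + np.array([0.0, 0.04, -0.25])
        base = 13 if side == "left" else 14
        pts[:, base] = elbow
        pts[:, base + 2] = wrist
        for j, off in ((17, 0.06), (19, 0.08), (21, 0.05)):
            idx = j if side == "left" else j + 1
            pts[:, idx] = wrist + np.array([0.0, 0.02, -off])
    return pts


def simulate_skeleton_and_project(
    trial: SyntheticTrial,
    cam_a: CameraModel,
    cam_b: CameraModel,
    geometry: SensorGeometry | None = None,
    pixel_noise_px: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Project the protocol-consistent skeleton to both camera views.

    Exactly 33 keypoints per frame per view; points behind a camera are
    marked invalid and not projected.  Results are stored on the trial
    and returned as ``(times, {view: pixels}, {view: validity})``.
    """
    geometry = geometry or SensorGeometry()
    rng = rng or np.random.default_rng(trial.seed + 2)
    jitter = rng.uniform(0, 1.0 / CAMERA_FS)
    times = np.arange(jitter, trial.protocol.duration_s, 1.0 / CAMERA_FS)
    pts = _skeleton_frames(trial, times, geometry, rng)

    from .pose_kinematics import joint_angle_tracks, KeypointTrack3D

    kp2d, valid = {}, {}
    for name, cam in (("cam_a", cam_a), ("cam_b", cam_b)):
        depth = cam.depth(pts.reshape(-1, 3)).reshape(pts.shape[:2])
        ok = depth > 1e-6
        px = np.full((*pts.shape[:2], 2), np.nan)
        px[ok] = cam.project(pts[ok])
        if pixel_noise_px > 0:
            px[ok] += rng.normal(0, pixel_noise_px, size=px[ok].shape)
        kp2d[name] = px
        valid[name] = ok
    trial.camera_times = times
    trial.keypoints_2d = kp2d
    trial.keypoints_valid = valid
    track = KeypointTrack3D(pts, np.ones(pts.shape[:2], bool), fs=CAMERA_FS)
    trial.truth_kinematics = joint_angle_tracks(track)
    return times, kp2d, valid
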