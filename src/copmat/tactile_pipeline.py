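"""Tactile pressure-image preprocessing and the weighted-mean-approach (WMA) CoP.

The processing chain mirrors a piezoresistive pressure-mat acquisition
pipeline: four 32x32 sensor modules are stitched into one 64x64 grid,
a no-load baseline is subtracted, sub-threshold readings are zeroed,
the session's data are min-max normalized and quantized to 8-bit
grayscale, salt-and-pepper artifacts are median-filtered away, dropped
frames are filled by linear interpolation, and the CoP of each frame is
computed as the pressure-weighted mean of cell coordinates:

    CoP_axis = (sum_i idx_i * w_i / sum_i w_i) * extent / 64

with 1-based cell indices ``idx_i``, pressures ``w_i`` and the physical
extent of that axis.  By default the mediolateral (ML) axis maps to the
mat width (grid columns) and the anteroposterior (AP) axis to the mat
length (grid rows).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger("copmat")

#: Saturation pressure of one sensing cell, kPa.
SATURATION_KPA = 14.0

#: Fraction of the post-correction full scale zeroed as sub-threshold, default.
DEFAULT_THRESHOLD_FRACTION = 0.02

STAGES = ("raw", "corrected", "normalized", "gray8", "denoised")


class NoLoad:
    """Typed marker returned when a frame carries no pressure at all.

    Distinct from a CoP value; the caller decides whether to skip the
    frame or hold the previous CoP.
    """

    __slots__ = ("timestamp",)

    def __init__(self, timestamp: float = 0.0):
        self.timestamp = timestamp

    def __repr__(self) -> str:  # pragma: no cover
        return f"NoLoad(t={self.timestamp})"


@dataclass(frozen=True)
class SensorGeometry:
    """Physical layout of the stitched pressure mat.

    The default mat is four 40 cm x 30 cm modules tiled 2x2, i.e. an
    80 cm (length) x 60 cm (width) surface read as a 64x64 grid.  Grid
    rows (axis 0) run along the length, grid columns (axis 1) along the
    width.  ``ml_axis`` selects which physical extent scales the ML
    coordinate; ``strict_printed_axes`` reproduces the alternative
    pairing ML <- length, AP <- width verbatim.
    """

    n_rows: int = 64
    n_cols: int = 64
    module_shape: tuple[int, int] = (32, 32)
    module_tiling: tuple[int, int] = (2, 2)
    length_mm: float = 800.0
    width_mm: float = 600.0
    ml_axis: str = "width"
    index_base: int = 1
    cell_center: bool = False
    strict_printed_axes: bool = False

    def __post_init__(self) -> None:
        tr, tc = self.module_tiling
        mr, mc = self.module_shape
        if self.n_rows != tr * mr or self.n_cols != tc * mc:
            raise ValueError(
                f"grid {self.n_rows}x{self.n_cols} does not match "
                f"{tr}x{tc} tiling of {mr}x{mc} modules"
            )
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ValueError("physical extents must be positive")
        if self.ml_axis not in ("width", "length"):
            raise ValueError("ml_axis must be 'width' or 'length'")

    @property
    def pitch_length_mm(self) -> float:
        """Cell pitch along the length (row) axis, mm."""
        return self.length_mm / self.n_rows

    @property
    def pitch_width_mm(self) -> float:
        """Cell pitch along the width (column) axis, mm."""
        return self.width_mm / self.n_cols

    @property
    def ml_extent_mm(self) -> float:
        if self.strict_printed_axes:
            return self.length_mm
        return self.width_mm if self.ml_axis == "width" else self.length_mm

    @property
    def ap_extent_mm(self) -> float:
        if self.strict_printed_axes:
            return self.width_mm
        return self.length_mm if self.ml_axis == "width" else self.width_mm

    @property
    def cell_area_mm2(self) -> float:
        return self.pitch_length_mm * self.pitch_width_mm


@dataclass
class PressureSequence:
    """A stack of timestamped pressure frames with a processing-stage tag."""

    values: np.ndarray  # (T, n_rows, n_cols), non-negative
    timestamps: np.ndarray  # (T,), seconds
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (T, rows, cols)")
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and frames disagree in length")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if np.any(self.values < 0):
            raise ValueError("pressure values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BaselineMap:
    """Per-cell mean no-load response of the stitched mat."""

    values: np.ndarray
    n_frames_used: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_frames_used < 1:
            raise ValueError("baseline needs at least one frame")
        if np.any(self.values < 0):
            raise ValueError("baseline must be non-negative")


@dataclass(frozen=True)
class CoPSample:
    ml_mm: float
    ap_mm: float
    timestamp: float = 0.0


@dataclass
class NormalizationConstants:
    """Min-max constants of a session, recorded so gray8 frames invert."""

    vmin: float
    vmax: float

    def dequantize(self, gray8: np.ndarray) -> np.ndarray:
        return gray8.astype(float) / 255.0 * (self.vmax - self.vmin) + self.vmin


# ---------------------------------------------------------------------------
# stitching

def stitch_modules(modules, geometry: SensorGeometry | None = None) -> np.ndarray:
    """Stitch per-module frames into the unified grid.

    ``modules`` is a sequence of four 32x32 arrays in row-major tile
    order: (top-left, top-right, bottom-left, bottom-right) for the
    default 2x2 tiling.
    """
    geometry = geometry or SensorGeometry()
    tr, tc = geometry.module_tiling
    mr, mc = geometry.module_shape
    modules = [np.asarray(m) for m in modules]
    if len(modules) != tr * tc:
        raise ValueError(f"expected {tr * tc} modules, got {len(modules)}")
    for m in modules:
        if m.shape != (mr, mc):
            raise ValueError(f"module shape {m.shape} != {(mr, mc)}")
    out = np.empty((geometry.n_rows, geometry.n_cols), dtype=modules[0].dtype)
    for k, m in enumerate(modules):
        r, c = divmod(k, tc)
        out[r * mr:(r + 1) * mr, c * mc:(c + 1) * mc] = m
    return out


def split_modules(frame: np.ndarray, geometry: SensorGeometry | None = None):
    """Inverse of :func:`stitch_modules` (quadrant slicing)."""
    geometry = geometry or SensorGeometry()
    tr, tc = geometry.module_tiling
    mr, mc = geometry.module_shape
    frame = np.asarray(frame)
    return [
        frame[r * mr:(r + 1) * mr, c * mc:(c + 1) * mc].copy()
        for r in range(tr)
        for c in range(tc)
    ]


# ---------------------------------------------------------------------------
# baseline calibration and correction

def calibrate_baseline(no_load_frames) -> BaselineMap:
    """Average no-load frames (default protocol: 20 of them) into a baseline."""
    if isinstance(no_load_frames, PressureSequence):
        frames = no_load_frames.values
    else:
        frames = np.asarray(no_load_frames)
    if frames.ndim == 2:
        frames = frames[None]
    if len(frames) == 0:
        raise ValueError("empty calibration sequence")
    return BaselineMap(values=frames.mean(axis=0), n_frames_used=len(frames))


def apply_correction(
    frame: np.ndarray,
    baseline: BaselineMap,
    threshold: float | None = None,
    full_scale: float = SATURATION_KPA,
) -> np.ndarray:
    """Baseline-subtract, clip at zero, zero sub-threshold cells.

    ``corrected = max(raw - baseline, 0)``; cells below ``threshold``
    (default 2% of ``full_scale``) are then set to zero so only
    substantial pressure survives.
    """
    if threshold is None:
        threshold = DEFAULT_THRESHOLD_FRACTION * full_scale
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    corrected = np.maximum(np.asarray(frame, dtype=float) - baseline.values, 0.0)
    corrected[corrected < threshold] = 0.0
    return corrected


def correct_sequence(
    seq: PressureSequence,
    baseline: BaselineMap,
    threshold: float | None = None,
) -> PressureSequence:
    out = np.stack([apply_correction(f, baseline, threshold) for f in seq.values])
    return PressureSequence(out, seq.timestamps.copy(), stage="corrected")


# ---------------------------------------------------------------------------
# normalization / quantization

def normalize_quantize(
    seq: PressureSequence,
    constants: NormalizationConstants | None = None,
) -> tuple[PressureSequence, NormalizationConstants]:
    """Min-max scale the whole sequence to [0, 1] and quantize to 8 bits.

    The scaling constants are computed over the entire collected dataset
    (or reused from a stored session via ``constants``) and returned for
    inversion.  A degenerate all-constant dataset maps to all zeros.
    """
    if seq.stage not in ("raw", "corrected"):
        raise ValueError("normalize_quantize expects raw/corrected input")
    v = seq.values.astype(float)
    if constants is None:
        constants = NormalizationConstants(vmin=float(v.min()), vmax=float(v.max()))
    span = constants.vmax - constants.vmin
    if span <= 0:
        warnings.warn("constant dataset: min-max span is zero, emitting zeros")
        gray = np.zeros_like(v, dtype=np.uint8)
    else:
        unit = np.clip((v - constants.vmin) / span, 0.0, 1.0)
        gray = np.round(unit * 255.0).astype(np.uint8)
    return PressureSequence(gray, seq.timestamps.copy(), stage="gray8"), constants


# ---------------------------------------------------------------------------
# denoising

def denoise(frame: np.ndarray) -> np.ndarray:
    """3x3 median filter with edge replication — removes salt-and-pepper."""
    return ndimage.median_filter(np.asarray(frame), size=3, mode="nearest")


def denoise_sequence(seq: PressureSequence) -> PressureSequence:
    if seq.stage != "gray8":
        raise ValueError("denoise expects gray8 input")
    out = np.stack([denoise(f) for f in seq.values])
    return PressureSequence(out, seq.timestamps.copy(), stage="denoised")


# ---------------------------------------------------------------------------
# frame-drop filling

def fill_dropped_frames(
    seq: PressureSequence, expected_timestamps
) -> PressureSequence:
    """Fill missing timestamps by per-cell linear interpolation.

    Missing frames between surviving neighbors are linearly interpolated
    per cell; leading/trailing gaps take the nearest surviving frame
    (``np.interp`` end behavior).
    """
    expected = np.asarray(expected_timestamps, dtype=float)
    if len(seq) < 2:
        raise ValueError("need at least two surviving frames to interpolate")
    t = seq.timestamps
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    T = len(expected)
    flat = seq.values.reshape(len(seq), -1).astype(float)
    out = np.empty((T, flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(expected, t, flat[:, j])
    out = out.reshape(T, *seq.values.shape[1:])
    if np.issubdtype(seq.values.dtype, np.integer):
        out = np.round(out).astype(seq.values.dtype)
    return PressureSequence(out, expected, stage=seq.stage)


# ---------------------------------------------------------------------------
# WMA CoP (Eq-1 style weighted mean)

def wma_cop(
    frame: np.ndarray,
    geometry: SensorGeometry | None = None,
    timestamp: float = 0.0,
) -> CoPSample | NoLoad:
    """Pressure-weighted mean CoP of one stitched frame.

    Per axis: ``(sum(idx * w) / sum(w)) * extent / 64`` with 1-based
    indices (or cell centers ``(idx - 0.5) * pitch`` when the geometry
    requests them).  An all-zero frame yields a :class:`NoLoad` marker.
    """
    geometry = geometry or SensorGeometry()
    w = np.asarray(frame, dtype=float)
    total = w.sum()
    if total <= 0:
        return NoLoad(timestamp)
    rows = np.arange(geometry.n_rows, dtype=float) + geometry.index_base
    cols = np.arange(geometry.n_cols, dtype=float) + geometry.index_base
    if geometry.cell_center:
        rows -= 0.5
        cols -= 0.5
    row_mean = (w.sum(axis=1) @ rows) / total
    col_mean = (w.sum(axis=0) @ cols) / total
    # column index scales with the width extent, row index with length
    ml_idx, ap_idx = (col_mean, row_mean) if geometry.ml_axis == "width" else (row_mean, col_mean)
    ml = ml_idx * geometry.ml_extent_mm / geometry.n_cols
    ap = ap_idx * geometry.ap_extent_mm / geometry.n_rows
    return CoPSample(ml_mm=float(ml), ap_mm=float(ap), timestamp=timestamp)


def wma_cop_sequence(
    seq: PressureSequence, geometry: SensorGeometry | None = None
) -> np.ndarray:
    """WMA CoP of every frame as a (T, 2) [ML, AP] mm array.

    No-load frames hold the previous CoP (the mat-center for a leading
    run of empty frames).
    """
    geometry = geometry or SensorGeometry()
    out = np.empty((len(seq), 2))
    last = (geometry.ml_extent_mm / 2.0, geometry.ap_extent_mm / 2.0)
    for i, (f, t) in enumerate(zip(seq.values, seq.timestamps)):
        s = wma_cop(f, geometry, timestamp=float(t))
        if isinstance(s, NoLoad):
            out[i] = last
        else:
            last = (s.ml_mm, s.ap_mm)
            out[i] = last
    return out


def save_frame_image(frame: np.ndarray, path) -> None:
    """Export one gray8 frame as an 8-bit grayscale image (PNG/PGM)."""
    from PIL import Image

    arr = np.asarray(frame)
    if arr.dtype != np.uint8:
        raise ValueError("expected a gray8 frame")
    Image.fromarray(arr, mode="L").save(path)


def preprocess_raw_modules(
    module_streams,
    timestamps,
    baseline_frames,
    geometry: SensorGeometry | None = None,
    threshold: float | None = None,
    apply_denoise: bool = True,
    constants: NormalizationConstants | None = None,
):
    """Full raw-to-gray8 chain for one trial.

    ``module_streams`` is a (T, 4, 32, 32) array (or list of 4-module
    frame lists).  Returns the denoised gray8 :class:`PressureSequence`
    and the normalization constants used.
    """
    geometry = geometry or SensorGeometry()
    module_streams = np.asarray(module_streams)
    stitched = np.stack(
        [stitch_modules(list(frame), geometry) for frame in module_streams]
    )
    raw = PressureSequence(stitched, np.asarray(timestamps, float), stage="raw")
    baseline = calibrate_baseline(baseline_frames)
    corrected = correct_sequence(raw, baseline, threshold)
    gray, constants = normalize_quantize(corrected, constants)
    if apply_denoise:
        gray = denoise_sequence(gray)
    return gray, constants
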