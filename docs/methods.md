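# Methods

`copmat` reconstructs, end to end and on synthetic data, a tactile-mat
body center-of-pressure (CoP) estimation study: a 64x64 piezoresistive
pressure mat (four 32x32 modules, 80 cm x 60 cm, ~14 Hz, 14 kPa
saturation) observes a standing subject, two RGB cameras (30 Hz)
provide a 33-keypoint skeleton for lower-limb kinematics, and a
1000 Hz force-plate CoP serves as ground truth.  Encoder-decoder
neural networks regress the per-frame CoP from pressure-image
sequences, the weighted-mean CoP, joint kinematics and subject
characteristics, and are compared under leave-one-subject-out
cross-validation (LOOCV).

## Coordinate conventions

Grid rows run along the mat length (anteroposterior, AP; 800 mm),
columns along the width (mediolateral, ML; 600 mm).  The weighted-mean
approach (WMA) computes, per axis,

    CoP = (sum_i idx_i * w_i / sum_i w_i) * extent / 64

with 1-based cell indices, so cell `i` sits at coordinate `i * pitch`;
the simulator renders in the same frame, making the WMA of an ideal
frame agree with the analytic centroid up to discretization.  A
`cell_center` flag switches to `(i - 0.5) * pitch`, and
`strict_printed_axes` reproduces the alternative pairing in which the
ML coordinate is scaled by the 800 mm length — both pairings are
implemented because the mat is longer than it is wide while ML
physically spans the width; neither is asserted as the only valid
reading.

## Synthetic cohort and trials

Anthropometrics are drawn from the cohort moments age 22.7 +/- 1.6 y,
height 171.6 +/- 7.8 cm, weight 73.4 +/- 13.5 kg with a 15:8
male:female ratio, truncated to positive values; limb lengths, foot
dimensions and waist-hip ratio follow standard body proportions with
individual scatter.  Each subject performs four balance protocols
(one-leg stance, tandem stance, squat at one repetition per 3 s,
walking-in-place), nominally 90 s per trial with the middle 80 s
analyzed, twice per protocol (8 trials/subject).

Per-protocol CoP dynamics:

- **Static stances** — Gaussian white noise low-passed at 1 Hz,
  rescaled to per-protocol SDs (one-leg: 8 mm ML / 10 mm AP; tandem:
  12 mm ML / 6 mm AP) and softly bounded at 3 SD with a tanh squash.
  The bound reflects the base-of-support limit: the narrowband process
  otherwise produces 6-8 SD excursions over a trial, which is not
  physiologic and erases the static/dynamic range separation.
- **Squat** — a deterministic AP oscillation (default amplitude 60 mm,
  period 3 s) plus small residual sway; total vertical load modulated
  +/-20% at the same period.
- **Walking-in-place** — foot loads alternate sinusoidally at a 1 Hz
  cadence with a 0.9 swing fraction, producing large ML shifts between
  the foot centers.

Stance placement is randomized per trial (Gaussian offsets, SD
30 mm ML / 40 mm AP, truncated so all pressure stays on-mat): subjects
do not stand on the identical spot, and a model must generalize across
placements rather than memorize cell positions.

**Feet** are rendered as two truncated anisotropic Gaussian lobes
(heel and forefoot) at fixed +/-0.25 foot-length AP offsets; the load
split between lobes is solved in closed form so that each foot's load
centroid equals its commanded CoP exactly, and the trial's ground
truth is the exact load-weighted centroid of all lobes.  Bimodality
matters: with a single symmetric blob per foot, the AP weighted mean
is unbiased under any radially symmetric distortion and there is
nothing for a learned model to correct in that direction.

The pressure scale maps load to cell kPa such that the worst-case
stance (full 73 kg reference weight on one foot with a 75% heel/toe
shift) peaks at ~60% of the 14 kPa saturation.

**Sensor defects**, applied in order: gamma nonlinearity on the
saturation-normalized scale (`measured = true^gamma`); a frozen
per-cell sensitivity map (fixed-pattern gain, SD 0.25 — cell-to-cell
spread is the canonical defect of piezoresistive arrays); per-module
gain/offset and slow baseline drift; salt-and-pepper noise; frame
drops.  The default imperfect sensor uses gamma 0.7, per-module gains
drawn uniformly in [0.8, 1.2], salt-and-pepper rate 0.002, drop rate
0.01 and 0.5 px keypoint noise.  `NoiseModel.ideal()` switches all of
this off.

**Skeleton**: ankles follow the foot centers; knee/hip flexion is
phase-locked to the protocol (squat flexion follows the AP
oscillation; walking-in-place legs flex and lift while unloaded), so
the 18 kinematic features genuinely carry CoP-relevant signal, most
strongly in ML during walking.  Landmarks not used by the joint-angle
computation (face, arms) are plausible placeholders.  Both cameras sit
~2 m in front of the mat, 1 m apart; 2D keypoints are exact pinhole
projections plus optional pixel noise, with points behind a camera
marked invalid.

## Preprocessing and synchronization

- Baseline: mean of 20 no-load frames per session, subtracted and
  clipped at zero; cells below a threshold (default 2% of the 14 kPa
  full scale) are zeroed.
- Min-max normalization uses constants of the whole collected dataset
  (stored, reusable at inference), then `round(v * 255)` to 8-bit
  grayscale.
- Denoising: 3x3 median filter with edge replication (the standard
  salt-and-pepper remedy); configurable off.
- Frame drops are filled by per-cell linear interpolation at the
  nominal 14 Hz stamps; an all-zero frame yields a typed no-load
  marker rather than NaN coordinates (the sequence API holds the last
  CoP).
- Ground-truth CoP: zero-phase 4th-order Butterworth at 10 Hz;
  keypoint tracks: the same filter at 2 Hz after triangulation, with
  invalid-keypoint gaps linearly interpolated (gaps over 10 frames
  flag the trial).  A Welch PSD check (Hann, segment 1024 at 1000 Hz)
  verifies that the filtered truth keeps >99% of its energy below
  7 Hz, so resampling to 14 Hz aliases negligibly.
- The common reference grid is 1/14 s spaced, anchored at the start of
  the symmetric middle analysis window ([5 s, 85 s] of a 90 s trial,
  giving 1120 frames); every modality is linearly interpolated onto
  it.  Acquisition starts are jittered within one device frame
  interval to emulate manual triggering; the worst-case trigger
  mismatch is `(1/14 + 1/30)/2 ~ 52 ms`.
- Joint angles use the vector dot product at the joint vertex
  (hip: shoulder-hip-knee; knee: hip-knee-ankle; ankle:
  knee-ankle-foot_index), clamped into [-1, 1] before arccos;
  derivatives are central differences taken at the synchronized 14 Hz
  rate, after the 2 Hz filter.

Each trial's synchronized bundle is stored in one HDF5 file (gray8
frames, WMA CoP, truth CoP, 18 angular features, subject
characteristics, settings; units in dataset attributes, schema
version stamped).

## Models

No deep-learning framework is assumed: `copmat.nn` is a compact
reverse-mode autodiff engine over numpy (float32, im2col convolutions
as single BLAS GEMMs) providing exactly the needed operators, Adam
and a step-decay schedule.  Training is seeded and single-threaded
deterministic.

Four architectures share one forward contract:

1. **encoder** per frame: `cnn2d` (stacked stride-2 3x3 convolutions),
   `resnet` (the same widths with identity-shortcut residual blocks;
   every downsampling is a strided convolution — the inventory
   contains no pooling operator), or `none` (the 64x64 frame flattened
   to 4096).  Convolutional encoders project the final feature map
   linearly to `encoder_dim` D.  A global average pool was rejected
   here: pooled features are translation-invariant and cannot encode
   where on the mat the load sits, which is required to correct
   module- and cell-level gain effects.
2. per-frame fusion: the WMA CoP (always) and the 18 angular features
   (the WA condition; omitted in OT) concatenated to the encoder
   output.
3. **decoder**: LSTM or Bi-LSTM (`n_layers` deep; bidirectional output
   width 2H).
4. subject characteristics (gender, weight, lean mass, upper/lower
   limb lengths, waist-hip ratio) and settings (protocol one-hot, mat
   width/length) concatenated to each frame's decoder output, then a
   fully connected head emits (CoP_ML, CoP_AP) in mm.

Input/target scaling: frames /255; static features z-scored with
training-fold statistics (constant columns untouched); CoP targets
standardized per direction with training-fold statistics and inverted
at prediction; the WMA input shares the target's standardization — it
is the same physical quantity, which makes the identity mapping
directly representable and stops the network from fitting placement
through weaker proxies.  Angular features use fixed scales (1/180,
1/500, 1/5000 for angle/velocity/acceleration).  The loss is MSE
(reported in mm^2); training windows are fixed-length frame windows
that never span trials and carry their subject id for fold
bookkeeping.  Hyperparameters are selected by exhaustive grid search
with identical ranges per architecture and an inner whole-subject
validation split.

## Evaluation

Metrics per direction: RMSE (mm); NRMSE = RMSE / ground-truth range x
100, with the range taken per validation subject per stratum; R^2.
Constant ground truth yields typed undefined (None) NRMSE/R^2, never
NaN.  Folds are leave-one-subject-out; a subject's trial vectors are
concatenated within stratum (overall; static = one-leg+tandem;
dynamic = squat+walking) before metric computation.  Summaries report
mean (SD) across folds; the directional gap is ML minus AP.

The two-way repeated-measures ANOVA (factors Model x Input Condition,
subject as block) decomposes sums of squares with
`F = MS_effect / MS_(effect x subject)`; uncorrected p is primary and
the Greenhouse-Geisser corrected p (epsilon from the contrast-projected
covariance) is reported alongside.  Exact ties (all cells equal up to
float roundoff) report F = 0, p = 1.  Missing cells raise — no
imputation.

## Desk-scale study sizes

The default `ExperimentConfig` reproduces the experimental design at
desk scale: 8 subjects x 4 protocols x 2 repetitions, 14 s trials with
the middle 10 s analyzed, slim encoders (channels 4-8-16, stem stride
4, D = 32, hidden 32) and 8 epochs of Adam (lr 3e-3, halved every 4
epochs) on 1 s windows.  These sizes were chosen so a full LOOCV
comparison (3 training seeds) completes on one CPU core in well under
half an hour; `ExperimentConfig.paper_scale()` restores 23 subjects,
90 s trials and the full-size architectures.  The model-ordering study
(`model_ordering_experiment`) trains ResNet-Bi-LSTM (WA and OT) and
the no-encoder Bi-LSTM per fold and compares them with the untrained
WMA baseline; the scalar per fold is the RMS of the ML and AP RMSEs.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the study — multi-rate
streams, sensor defects, protocol-dependent CoP dynamics, kinematic
coupling — but not human variability: no real sway spectra, no foot
morphology beyond two Gaussian lobes, no creep/hysteresis or silicone
mat mechanics, no pose-estimator failure modes.  Passing tests
demonstrate that the pipeline is internally consistent and that the
learned models can correct the modeled sensor distortions better than
the closed-form weighted mean; absolute RMSE values on synthetic
trials are not comparable to values measured on human data.

## Known limitations

- The numpy NN engine is CPU-only and unoptimized for large batches;
  paper-scale architectures train slowly.
- Fixed-pattern cell gains are learnable precisely because they are
  frozen; a sensor whose defects drift between sessions would need
  recalibration or domain adaptation, which is not modeled.
- The ANOVA assumes a complete balanced within-subject design, as in
  the emulated study.
- Camera geometry is fixed and near-ideal; severe occlusion is only
  modeled as per-keypoint invalidity.
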