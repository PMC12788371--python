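"""Multimodal encoder-decoder CoP regressors and their training loop.

Four architectures share one forward contract: a spatial encoder turns
each 64x64 pressure frame into a per-frame feature vector (a plain 2D
CNN, a ResNet whose every downsampling is a stride-2 convolution —
no pooling layers — or no encoder at all, which flattens the frame to
4096 values); the weighted-mean CoP (and optionally the 18 lower-limb
kinematic features) is concatenated per frame; a recurrent decoder
(LSTM or Bi-LSTM) models the temporal pattern; subject characteristics
and experimental settings join the decoder output; and a fully
connected head emits per-frame (CoP_ML, CoP_AP) in mm.  Training
minimizes MSE with Adam under a step-decay learning-rate schedule;
hyperparameters are chosen by an exhaustive grid search with identical
ranges for every architecture.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .sync_assemble import TrialRecord

ENCODERS = ("cnn2d", "resnet", "none")
DECODERS = ("lstm", "bilstm")
FLAT_DIM = 64 * 64  # per-frame feature size without an encoder
N_ANGULAR = 18

# fixed input scalings: gray8 frames /255; the WMA CoP shares the target's
# train-fold standardization (it is the same physical quantity, so the
# identity map is directly representable); angles /180 deg, velocities
# /500 deg/s, accelerations /5000 deg/s^2
ANGULAR_SCALE = np.concatenate([np.tile([1 / 180.0, 1 / 500.0, 1 / 5000.0], 6)])


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one encoder/decoder architecture.

    The four reference models are (resnet, bilstm), (cnn2d, bilstm),
    (cnn2d, lstm) and (none, bilstm).
    """

    encoder: str = "resnet"
    decoder: str = "bilstm"
    encoder_dim: int = 128  # per-frame feature size D out of the encoder
    encoder_channels: tuple = (16, 32, 64, 128)
    blocks_per_stage: int = 2
    stem_stride: int = 2  # stride of the first downsampling convolution
    hidden_dim: int = 128
    n_layers: int = 1
    use_angular: bool = True
    head_dims: tuple = (64,)

    def __post_init__(self) -> None:
        if self.encoder not in ENCODERS:
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if self.decoder not in DECODERS:
            raise ValueError(f"unknown decoder {self.decoder!r}")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")

    @property
    def feature_dim(self) -> int:
        """Per-frame feature width entering the fusion stage."""
        return FLAT_DIM if self.encoder == "none" else self.encoder_dim

    def final_map_cells(self, input_size: int = 64) -> int:
        """Spatial cells of the last encoder feature map on a 64x64 frame."""
        size = input_size
        for i in range(len(self.encoder_channels)):
            stride = self.stem_stride if i == 0 else 2
            size = (size + 1) // stride if size % stride else size // stride
        return size * size


def paper_model_specs(use_angular: bool = True, **overrides) -> dict[str, ModelSpec]:
    """The four compared architectures, best-first order."""
    base = dict(use_angular=use_angular, **overrides)
    return {
        "ResNet-Bi-LSTM": ModelSpec(encoder="resnet", decoder="bilstm", **base),
        "CNN-Bi-LSTM": ModelSpec(encoder="cnn2d", decoder="bilstm", **base),
        "CNN-LSTM": ModelSpec(encoder="cnn2d", decoder="lstm", **base),
        "Bi-LSTM": ModelSpec(encoder="none", decoder="bilstm", **base),
    }


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    step_size: int = 10
    gamma: float = 0.5
    epochs: int = 50
    batch_size: int = 16
    window_len: int = 28  # 2 s at 14 Hz
    window_stride: int = 14
    seed: int = 0
    loss: str = "mse"

    def __post_init__(self) -> None:
        if self.lr <= 0 or not 0 < self.gamma <= 1 or self.window_len < 2:
            raise ValueError("invalid training configuration")


# ---------------------------------------------------------------------------
# model modules

class CNNEncoder(nn.Module):
    """Stacked strided convolutions + ReLU; the final feature map is
    projected linearly to the D-dimensional per-frame feature."""

    def __init__(self, channels, rng, stem_stride: int, out_dim: int, map_cells: int):
        cin = 1
        self.convs = []
        for i, c in enumerate(channels):
            stride = stem_stride if i == 0 else 2
            self.convs.append(nn.Conv2d(cin, c, k=3, stride=stride, padding=1, rng=rng))
            cin = c
        self.flat_dim = channels[-1] * map_cells
        self.proj = nn.Linear(self.flat_dim, out_dim, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        for conv in self.convs:
            x = nn.relu(conv(x))
        return self.proj(nn.reshape(x, (x.shape[0], self.flat_dim)))


class ResidualBlock(nn.Module):
    """Two 3x3 convolutions with an identity shortcut (stride 1)."""

    def __init__(self, channels, rng):
        self.conv1 = nn.Conv2d(channels, channels, 3, 1, 1, rng)
        self.conv2 = nn.Conv2d(channels, channels, 3, 1, 1, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        y = self.conv2(nn.relu(self.conv1(x)))
        return nn.relu(nn.add(x, y))


class ResNetEncoder(nn.Module):
    """Residual stages; all downsampling via strided convolutions.

    Contains no pooling operators: spatial reduction is learnable
    throughout, and the final spatial map is projected linearly into
    the D-dimensional per-frame feature.
    """

    def __init__(self, channels, blocks_per_stage, rng, stem_stride: int,
                 out_dim: int, map_cells: int):
        cin = 1
        self.stages = []
        for i, c in enumerate(channels):
            stage = [nn.Conv2d(cin, c, 3, stem_stride if i == 0 else 2, 1, rng)]
            stage += [ResidualBlock(c, rng) for _ in range(blocks_per_stage)]
            self.stages.append(stage)
            cin = c
        self.flat_dim = channels[-1] * map_cells
        self.proj = nn.Linear(self.flat_dim, out_dim, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        for stage in self.stages:
            x = nn.relu(stage[0](x))
            for block in stage[1:]:
                x = block(x)
        return self.proj(nn.reshape(x, (x.shape[0], self.flat_dim)))

    def parameters(self):
        params = []
        for stage in self.stages:
            for m in stage:
                params.extend(m.parameters())
        params.extend(self.proj.parameters())
        return params


class CoPModel(nn.Module):
    """Encoder -> per-frame fusion -> recurrent decoder -> static fusion -> FC."""

    def __init__(self, spec: ModelSpec, static_dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.static_dim = static_dim
        cells = spec.final_map_cells()
        if spec.encoder == "cnn2d":
            self.encoder = CNNEncoder(spec.encoder_channels, rng, spec.stem_stride,
                                      spec.encoder_dim, cells)
        elif spec.encoder == "resnet":
            self.encoder = ResNetEncoder(spec.encoder_channels, spec.blocks_per_stage,
                                         rng, spec.stem_stride, spec.encoder_dim, cells)
        else:
            self.encoder = None
        fusion_dim = spec.feature_dim + 2 + (N_ANGULAR if spec.use_angular else 0)
        self.fusion_dim = fusion_dim
        self.decoders = []
        din = fusion_dim
        for _ in range(spec.n_layers):
            if spec.decoder == "bilstm":
                self.decoders.append(nn.BiLSTM(din, spec.hidden_dim, rng))
                din = 2 * spec.hidden_dim
            else:
                self.decoders.append(nn.LSTM(din, spec.hidden_dim, rng))
                din = spec.hidden_dim
        self.decoder_out_dim = din
        self.head = []
        hin = din + static_dim
        for h in spec.head_dims:
            self.head.append(nn.Linear(hin, h, rng))
            hin = h
        self.out = nn.Linear(hin, 2, rng)
        # train-fold statistics for static-feature z-scoring and target
        # standardization (inverted at prediction time)
        self.static_mean = np.zeros(static_dim)
        self.static_std = np.ones(static_dim)
        self.target_mean = np.zeros(2)
        self.target_std = np.ones(2)

    def forward(self, frames, wma, angular, static) -> nn.Tensor:
        """frames (B,T,64,64) in [0,1]; wma (B,T,2) mm; angular (B,T,18);
        static (B,S) already z-scored.  Returns (B,T,2) mm."""
        B, T = frames.shape[:2]
        if self.encoder is None:
            feat = nn.reshape(nn.Tensor(frames), (B, T, FLAT_DIM))
        else:
            x = nn.Tensor(frames.reshape(B * T, 1, *frames.shape[2:]))
            feat = nn.reshape(self.encoder(x), (B, T, self.spec.encoder_dim))
        wma_n = (np.asarray(wma) - self.target_mean) / self.target_std
        parts = [feat, nn.Tensor(wma_n)]
        if self.spec.use_angular:
            if angular is None:
                raise ValueError("spec requests angular features but batch has none")
            parts.append(nn.Tensor(np.asarray(angular) * ANGULAR_SCALE))
        x = nn.concat(parts, axis=-1)
        for dec in self.decoders:
            x = dec(x)
        stat = np.broadcast_to(np.asarray(static)[:, None, :], (B, T, self.static_dim))
        x = nn.concat([x, nn.Tensor(stat)], axis=-1)
        for lin in self.head:
            x = nn.relu(lin(x))
        return self.out(x)

    def predict(self, frames_u8, wma, angular, static_raw) -> np.ndarray:
        """Numpy-in / numpy-out inference with the stored normalizations."""
        static = (np.asarray(static_raw) - self.static_mean) / self.static_std
        out = self.forward(np.asarray(frames_u8, float) / 255.0, wma,
                           angular if self.spec.use_angular else None, static)
        return out.data * self.target_std + self.target_mean

    def parameters(self):
        params = [] if self.encoder is None else list(self.encoder.parameters())
        for dec in self.decoders:
            params.extend(dec.parameters())
        for lin in self.head:
            params.extend(lin.parameters())
        params.extend(self.out.parameters())
        return params


def build_model(spec: ModelSpec, static_dim: int = 12, seed: int = 0) -> CoPModel:
    """Instantiate one architecture with seeded initialization."""
    return CoPModel(spec, static_dim, seed)


# ---------------------------------------------------------------------------
# windowing

@dataclass
class WindowedDataset:
    """Overlapping fixed-length windows drawn from whole trials.

    Frames stay uint8 until batching; no window spans two trials, and
    each window carries its subject id for fold bookkeeping.
    """

    frames: np.ndarray  # (N, Tw, 64, 64) uint8
    wma: np.ndarray  # (N, Tw, 2) mm
    angular: np.ndarray  # (N, Tw, 18)
    static: np.ndarray  # (N, S) raw (un-normalized)
    target: np.ndarray  # (N, Tw, 2) mm
    subject_ids: np.ndarray  # (N,) str
    trial_index: np.ndarray  # (N,) int

    def __len__(self) -> int:
        return len(self.frames)


def trial_static_vector(record: TrialRecord) -> np.ndarray:
    """Subject characteristics + settings (protocol one-hot, mat size)."""
    return np.concatenate([record.subject_features, record.settings_vector()])


def window_dataset(trials: list[TrialRecord], config: TrainConfig) -> WindowedDataset:
    """Cut every trial into overlapping windows of ``window_len`` frames."""
    Tw, stride = config.window_len, config.window_stride
    shortest = min(t.n_frames for t in trials)
    if Tw > shortest:
        raise ValueError(f"window_len {Tw} exceeds shortest trial ({shortest} frames)")
    frames, wma, ang, stat, targ, sids, tidx = [], [], [], [], [], [], []
    for ti, rec in enumerate(trials):
        sv = trial_static_vector(rec)
        for start in range(0, rec.n_frames - Tw + 1, stride):
            sl = slice(start, start + Tw)
            frames.append(rec.tactile_gray8[sl])
            wma.append(rec.tactile_wma_cop[sl])
            ang.append(rec.angular_features[sl])
            targ.append(rec.truth_cop[sl])
            stat.append(sv)
            sids.append(rec.subject_id)
            tidx.append(ti)
    return WindowedDataset(
        frames=np.stack(frames).astype(np.uint8),
        wma=np.stack(wma),
        angular=np.stack(ang),
        static=np.stack(stat),
        target=np.stack(targ),
        subject_ids=np.array(sids),
        trial_index=np.array(tidx),
    )


# ---------------------------------------------------------------------------
# training

def train_model(
    model: CoPModel,
    dataset: WindowedDataset,
    config: TrainConfig,
    verbose: bool = False,
) -> list[float]:
    """Seeded MSE training with Adam + step-decayed learning rate.

    Returns the per-epoch mean training loss (mm^2).  Aborts with
    diagnostics if the loss turns non-finite.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    # train-fold static normalization (constant columns left unscaled)
    mean = dataset.static.mean(axis=0)
    std = dataset.static.std(axis=0)
    std[std < 1e-9] = 1.0
    model.static_mean, model.static_std = mean, std
    # standardize targets per direction for well-scaled gradients;
    # predictions are mapped back to mm
    tmean = dataset.target.reshape(-1, 2).mean(axis=0)
    tstd = np.maximum(dataset.target.reshape(-1, 2).std(axis=0), 1.0)
    model.target_mean, model.target_std = tmean, tstd
    target_n = (dataset.target - tmean) / tstd
    mm2_scale = float((tstd**2).mean())  # standardized MSE -> mm^2

    params = model.parameters()
    opt = nn.Adam(params, lr=config.lr)
    sched = nn.StepLR(opt, config.step_size, config.gamma)
    history = []
    n = len(dataset)
    static_n = (dataset.static - mean) / std
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            frames = dataset.frames[idx].astype(np.float64) / 255.0
            pred = model.forward(
                frames, dataset.wma[idx],
                dataset.angular[idx] if model.spec.use_angular else None,
                static_n[idx],
            )
            loss = nn.mse_loss(pred, target_n[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN loss at epoch {epoch} (lr={opt.lr:.2e}, "
                    f"batch mean target={dataset.target[idx].mean():.1f})"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * mm2_scale)
        sched.step()
        history.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs}  loss {history[-1]:.2f}  lr {opt.lr:.1e}")
    return history


def lr_schedule(config: TrainConfig) -> list[float]:
    """The learning rate used in each epoch under the step decay."""
    return [
        config.lr * config.gamma ** (epoch // config.step_size)
        for epoch in range(config.epochs)
    ]


def predict_record(model: CoPModel, record: TrialRecord, config: TrainConfig) -> np.ndarray:
    """Per-frame CoP prediction for one whole trial.

    The trial is covered with non-overlapping windows plus one tail
    window anchored at the end; overlapping predictions are averaged.
    """
    T, Tw = record.n_frames, config.window_len
    starts = list(range(0, T - Tw + 1, Tw))
    if starts[-1] != T - Tw:
        starts.append(T - Tw)
    sv = trial_static_vector(record)
    out = np.zeros((T, 2))
    counts = np.zeros(T)
    frames = [record.tactile_gray8[s:s + Tw] for s in starts]
    wma = [record.tactile_wma_cop[s:s + Tw] for s in starts]
    ang = [record.angular_features[s:s + Tw] for s in starts]
    pred = model.predict(
        np.stack(frames), np.stack(wma), np.stack(ang),
        np.tile(sv, (len(starts), 1)),
    )
    for k, s in enumerate(starts):
        out[s:s + Tw] += pred[k]
        counts[s:s + Tw] += 1
    return out / counts[:, None]


# ---------------------------------------------------------------------------
# grid search

def grid_search(
    grid: dict,
    trials: list[TrialRecord],
    specs: dict[str, ModelSpec] | None = None,
    base_config: TrainConfig | None = None,
    val_fraction: float = 0.25,
    seed: int = 0,
):
    """Exhaustive grid search with identical ranges for every architecture.

    ``grid`` maps parameter names (``lr``, ``hidden_dim``, ``n_layers``,
    ...) to candidate lists; TrainConfig keys configure training and
    ModelSpec keys configure the architecture.  The inner validation
    split holds out whole subjects.  Returns ``(best_spec, best_config,
    table)`` where the table has one row per architecture x combination.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty grid")
    specs = specs or {"ResNet-Bi-LSTM": ModelSpec()}
    base_config = base_config or TrainConfig()
    subjects = sorted({t.subject_id for t in trials})
    if len(subjects) < 2:
        raise ValueError("grid search needs >= 2 subjects for an inner split")
    n_val = max(1, int(round(val_fraction * len(subjects))))
    val_subjects = set(subjects[-n_val:])
    train_trials = [t for t in trials if t.subject_id not in val_subjects]
    val_trials = [t for t in trials if t.subject_id in val_subjects]

    config_keys = set(TrainConfig.__dataclass_fields__)
    rows = []
    best = None
    keys = sorted(grid)
    for arch_name, spec in specs.items():
        for combo in itertools.product(*(grid[k] for k in keys)):
            params = dict(zip(keys, combo))
            cfg = replace(base_config,
                          **{k: v for k, v in params.items() if k in config_keys},
                          seed=seed)
            sp = replace(spec, **{k: v for k, v in params.items() if k not in config_keys})
            ds = window_dataset(train_trials, cfg)
            model = build_model(sp, static_dim=ds.static.shape[1], seed=seed)
            try:
                train_model(model, ds, cfg)
                errs = []
                for rec in val_trials:
                    pred = predict_record(model, rec, cfg)
                    errs.append(np.sqrt(np.mean((pred - rec.truth_cop) ** 2)))
                rmse = float(np.mean(errs))
            except RuntimeError:
                rmse = float("inf")  # diverged combination
            rows.append({"architecture": arch_name, **params, "val_rmse": rmse})
            if best is None or rmse < best[2]:
                best = (sp, cfg, rmse)
    table = pd.DataFrame(rows)
    return best[0], best[1], table
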