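"""Convolutional-recurrent mixture-density model of hourly discharge counts.

A 9-hour window of paired behavioral grids (all-app and Social JIDs,
50x50x2 per hour) is mapped to a 3-component Gaussian mixture over the
z-scored hourly count of each output channel (raw and 24-h detrended
counts per detector).  A shared convolutional extractor embeds each
hourly frame; a 3-layer LSTM (50 units, recurrent dropout 0.4)
integrates the 9 embeddings; per-channel linear heads emit the 9
mixture values (3 means, 3 standard deviations, 3 mixing weights).
Training minimizes mixture negative log-likelihood with l2 (1e-3) on
convolutional weights and l1 (1e-3) on the output heads, using Adam.

Two context alignments are supported: *centered* (hours t-4 .. t+4,
the reconstruction model) and *preceding* (hours t-9 .. t-1, the
time-causal forecasting variant, which by construction never reads the
target hour or anything after it).

Context windows overlap hour by hour, so within each minibatch every
distinct hour's frame is embedded exactly once and gathered into the
windows that use it (gradients scatter-add back); this is what makes
season-length training runs tractable on a single CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detrend import DetectorSeries, DetrendedSeries
from .features import HourlyFeatureSeries
from .mdn import MixtureParams, point_estimate
from .nn.autodiff import Tensor, no_grad
from .nn.layers import Adam, Dense, LSTMLayer, ResNet50Extractor, SmallExtractor

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "ContextWindow",
    "ContextWindowSet",
    "make_context_windows",
    "MDNModel",
    "build_model",
    "train_model",
    "predict_series",
    "PredictionResult",
    "save_model",
    "load_model",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
WINDOW_LEN = 9


@dataclass
class ModelConfig:
    extractor: str = "small"             # "small" (128-d) | "resnet50" (1024-d)
    lstm_layers: int = 3
    lstm_units: int = 50
    n_mixture: int = 3
    n_output_channels: int = 2           # 2 x active detectors (raw + detrended)
    l2_conv: float = 1e-3
    l1_head: float = 1e-3
    dropout_recurrent: float = 0.4
    batch_norm: bool = True

    def __post_init__(self):
        if self.n_output_channels not in (2, 4, 6, 8):
            raise ValueError("n_output_channels must be one of {2, 4, 6, 8}")
        if self.extractor not in ("small", "resnet50"):
            raise ValueError("extractor must be 'small' or 'resnet50'")


@dataclass
class TrainConfig:
    train_frac: float = 0.8              # 20% *subsequent* data for testing
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 64
    clip_grad_norm: float = 5.0          # 0 disables clipping
    lr_schedule: str = "constant"        # "constant" | "cosine" (anneal to 0)
    seed: int = 0


@dataclass
class ContextWindow:
    """One training/evaluation example (a view into a ContextWindowSet)."""

    frame_hours: np.ndarray      # (9,) epoch hours of the context frames
    presence: np.ndarray         # (9, 2) present flags per feature space
    target_hour: int
    targets: np.ndarray          # (C,) raw-scale targets (counts + detrended)
    alignment: str

    @property
    def any_present(self) -> bool:
        return bool(self.presence[:, 0].any())


@dataclass
class ContextWindowSet:
    """All context windows over a subject's hour grid, column-oriented."""

    frame_idx: np.ndarray        # (N, 9) indices into the feature hour grid
    presence: np.ndarray         # (N, 9, 2)
    target_idx: np.ndarray       # (N,) indices into the hour grid
    hours: np.ndarray            # (N,) epoch hours of the targets
    targets: np.ndarray          # (N, C) float64, raw scale
    alignment: str
    channel_names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.target_idx)

    def __getitem__(self, i: int) -> ContextWindow:
        return ContextWindow(
            frame_hours=self.hours[i] + self.offsets(),
            presence=self.presence[i],
            target_hour=int(self.hours[i]),
            targets=self.targets[i],
            alignment=self.alignment,
        )

    def offsets(self) -> np.ndarray:
        return _alignment_offsets(self.alignment)

    @property
    def any_present(self) -> np.ndarray:
        return self.presence[:, :, 0].any(axis=1)


def _alignment_offsets(alignment: str) -> np.ndarray:
    if alignment == "centered":
        return np.arange(-4, 5)
    if alignment == "preceding":
        return np.arange(-9, 0)
    raise ValueError("alignment must be 'centered' or 'preceding'")


def make_context_windows(
    features: HourlyFeatureSeries,
    detector: DetectorSeries,
    detrended: DetrendedSeries,
    alignment: str = "centered",
) -> ContextWindowSet:
    """One window per target hour with full 9-hour context.

    ``centered`` windows span hours t-4 .. t+4; ``preceding`` windows
    span t-9 .. t-1 and never touch hour t or later.  Windows whose 9
    bins are all absent are kept (the model still predicts there) and
    flagged via ``any_present`` for exclusion from correlations.
    """
    if not np.array_equal(features.hours, detector.hours):
        raise ValueError("feature and detector hour grids are misaligned")
    if not np.array_equal(detector.hours, detrended.hours):
        raise ValueError("detector and detrended hour grids are misaligned")
    offsets = _alignment_offsets(alignment)
    H = len(features.hours)
    t_idx = np.arange(H)
    ok = (t_idx + offsets.min() >= 0) & (t_idx + offsets.max() < H)
    t_idx = t_idx[ok]
    frame_idx = t_idx[:, None] + offsets[None, :]
    targets = np.concatenate(
        [detector.counts.astype(np.float64), detrended.residual], axis=1
    )
    names = [f"{lab}" for lab in detector.detector_labels] + [
        f"{lab}-24h-d" for lab in detector.detector_labels
    ]
    return ContextWindowSet(
        frame_idx=frame_idx,
        presence=features.present[frame_idx],
        target_idx=t_idx,
        hours=features.hours[t_idx],
        targets=targets[t_idx],
        alignment=alignment,
        channel_names=names,
    )


class MDNModel:
    """The assembled extractor + LSTM + mixture-head network."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        if config.extractor == "small":
            self.extractor = SmallExtractor(rng, config.batch_norm)
        else:
            self.extractor = ResNet50Extractor(rng, config.batch_norm)
        emb = self.extractor.embedding_dim
        self.lstms = []
        for i in range(config.lstm_layers):
            n_in = emb if i == 0 else config.lstm_units
            self.lstms.append(LSTMLayer(rng, n_in, config.lstm_units))
        self.heads = [
            Dense(rng, config.lstm_units, 3 * config.n_mixture)
            for _ in range(config.n_output_channels)
        ]
        # target scaling constants, fixed by train_model from the train split
        C = config.n_output_channels
        self.target_mean = np.zeros(C)
        self.target_std = np.ones(C)
        self.channel_names = [f"ch{i}" for i in range(C)]
        self.trained = False

    # -- plumbing -------------------------------------------------------------
    def _modules(self):
        return [self.extractor] + self.lstms + self.heads

    def parameters(self):
        out = []
        for m in self._modules():
            out.extend(m.parameters())
        return out

    def set_training(self, flag: bool):
        for m in self._modules():
            m.set_training(flag)

    def zero_grad(self):
        for m in self._modules():
            m.zero_grad()

    # -- forward --------------------------------------------------------------
    def _sequence_heads(self, steps: list[Tensor], rng=None) -> list[Tensor]:
        """LSTM stack over the 9 embedding steps -> per-channel raw (B, 9)."""
        p = self.config.dropout_recurrent
        B = steps[0].shape[0]
        for li, lstm in enumerate(self.lstms):
            steps = lstm(steps)
            last_layer = li == len(self.lstms) - 1
            if rng is not None and p > 0 and not last_layer:
                # per-timestep inverted dropout between stacked recurrent
                # layers (masks independent across timesteps)
                steps = [
                    h
                    * Tensor(
                        ((rng.random((B, self.config.lstm_units)) >= p) / (1 - p)).astype(
                            np.float32
                        )
                    )
                    for h in steps
                ]
        h_last = steps[-1]
        return [head(h_last) for head in self.heads]

    def forward_deduplicated(
        self, frames: Tensor, gather: np.ndarray, rng=None
    ) -> list[Tensor]:
        """frames: (U, 2, 50, 50) unique-hour frames; gather: (B, 9) indices
        into them.  Returns per-channel raw mixture outputs (B, 9)."""
        emb = self.extractor(frames)
        steps = [emb.take(gather[:, t]) for t in range(gather.shape[1])]
        return self._sequence_heads(steps, rng)

    def forward_windows(self, frames: Tensor, rng=None) -> list[Tensor]:
        """frames: (B, 9, 2, 50, 50) per-window frames (no deduplication;
        used where per-window input gradients are needed)."""
        B, T = frames.shape[0], frames.shape[1]
        emb = self.extractor(frames.reshape(B * T, *frames.shape[2:]))
        emb = emb.reshape(B, T, -1)
        steps = [emb[:, t, :] for t in range(T)]
        return self._sequence_heads(steps, rng)

    # -- mixture transform ----------------------------------------------------
    def split_raw(self, raw: Tensor):
        """raw (B, 9) -> (mu, sigma, log_w) Tensors, each (B, 3)."""
        K = self.config.n_mixture
        mu = raw[:, :K]
        sigma = raw[:, K : 2 * K].softplus() + 1e-4
        logits = raw[:, 2 * K :]
        log_w = logits - logits.logsumexp(axis=-1, keepdims=True)
        return mu, sigma, log_w

    def raw_to_params(self, raw: np.ndarray) -> MixtureParams:
        """Numpy version for inference; raw (..., 9) -> MixtureParams in
        z-units."""
        K = self.config.n_mixture
        mu = raw[..., :K]
        s = np.logaddexp(raw[..., K : 2 * K], 0.0) + 1e-4  # softplus
        logits = raw[..., 2 * K :]
        w = np.exp(logits - logits.max(axis=-1, keepdims=True))
        w = w / w.sum(axis=-1, keepdims=True)
        return MixtureParams(mu, s, w)

    def nll_loss(self, raws: list[Tensor], targets_z: np.ndarray) -> Tensor:
        """Mean mixture NLL over windows and channels; targets_z (B, C)."""
        per_channel = []
        for c, raw in enumerate(raws):
            mu, sigma, log_w = self.split_raw(raw)
            t = Tensor(targets_z[:, c : c + 1].astype(np.float32))
            z = (t - mu) / sigma
            log_comp = log_w - sigma.log() - 0.5 * z.square() - 0.5 * _LOG_2PI
            per_channel.append(-log_comp.logsumexp(axis=-1).mean() * (1.0 / len(raws)))
        total = per_channel[0]
        for term in per_channel[1:]:
            total = total + term
        return total

    def regularization(self) -> Tensor:
        reg = Tensor(np.zeros(()))
        if self.config.l2_conv > 0:
            for w in self.extractor.conv_params():
                reg = reg + w.square().sum() * self.config.l2_conv
        if self.config.l1_head > 0:
            for head in self.heads:
                reg = reg + head.W.abs().sum() * self.config.l1_head
        return reg


def build_model(config: ModelConfig, seed: int = 0) -> MDNModel:
    return MDNModel(config, seed)


def _clip_grad_norm(params, max_norm: float):
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    total = np.sqrt(total)
    if total > max_norm:
        scale = np.float32(max_norm / (total + 1e-12))
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def _zscore_setup(model: MDNModel, targets: np.ndarray, train_mask: np.ndarray):
    mean = targets[train_mask].mean(axis=0)
    std = targets[train_mask].std(axis=0)
    std[std == 0] = 1.0
    model.target_mean, model.target_std = mean, std


def train_model(
    model: MDNModel,
    windows: ContextWindowSet,
    features: HourlyFeatureSeries,
    config: TrainConfig,
) -> dict:
    """Train on the first 80% of windows; the final 20% (strictly later
    in time) is the held-out split reported in the history.

    Targets are z-scored per channel with training-split statistics
    (stored on the model and inverted at prediction time).  Returns
    ``{"train_nll": [...], "val_nll": [...], "split_index": cut}``.
    """
    N = len(windows)
    if N == 0:
        raise ValueError("no training windows")
    if windows.targets.shape[1] != model.config.n_output_channels:
        raise ValueError(
            f"windows carry {windows.targets.shape[1]} target channels, model "
            f"expects {model.config.n_output_channels}"
        )
    cut = int(round(config.train_frac * N))
    cut = max(1, min(cut, N))
    train_mask = np.zeros(N, dtype=bool)
    train_mask[:cut] = True
    _zscore_setup(model, windows.targets, train_mask)
    targets_z = (windows.targets - model.target_mean) / model.target_std

    frames_all = features.frames()
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = {"train_nll": [], "val_nll": [], "split_index": cut}
    train_idx = np.arange(cut)
    for epoch in range(config.epochs):
        if config.lr_schedule == "cosine":
            # short desk-scale runs benefit from annealing to a converged
            # snapshot; the long-run default keeps the rate constant
            opt.lr = config.learning_rate * 0.5 * (1 + np.cos(np.pi * epoch / config.epochs))
        model.set_training(True)
        # minibatches are contiguous blocks of windows taken in shuffled
        # order (with a random phase each epoch): neighboring windows share
        # 8 of their 9 frames, so contiguous blocks keep the number of
        # distinct frames per batch ~ batch_size/8 + 9, which is what makes
        # CPU training of season-length records tractable.
        phase = int(rng.integers(0, config.batch_size))
        edges = np.arange(phase % config.batch_size, cut + config.batch_size,
                          config.batch_size)
        edges = np.unique(np.clip(np.concatenate([[0], edges]), 0, cut))
        blocks = [train_idx[a:b] for a, b in zip(edges[:-1], edges[1:]) if b > a]
        epoch_nll, n_seen = 0.0, 0
        for bi in rng.permutation(len(blocks)):
            batch = blocks[bi]
            fidx = windows.frame_idx[batch]
            uniq, inv = np.unique(fidx.ravel(), return_inverse=True)
            gather = inv.reshape(fidx.shape)
            frames = Tensor(frames_all[uniq])
            model.zero_grad()
            raws = model.forward_deduplicated(frames, gather, rng)
            nll = model.nll_loss(raws, targets_z[batch])
            loss = nll + model.regularization()
            loss.backward()
            if config.clip_grad_norm > 0:
                _clip_grad_norm(model.parameters(), config.clip_grad_norm)
            opt.step()
            epoch_nll += float(nll.data) * len(batch)
            n_seen += len(batch)
        history["train_nll"].append(epoch_nll / max(n_seen, 1))
        history["val_nll"].append(
            _validation_nll(model, windows, frames_all, targets_z, ~train_mask)
        )
    model.trained = True
    model.channel_names = windows.channel_names or model.channel_names
    return history


def _validation_nll(model, windows, frames_all, targets_z, mask) -> float:
    idx = np.where(mask)[0]
    if len(idx) == 0:
        return float("nan")
    model.set_training(False)
    total, n = 0.0, 0
    with no_grad():
        for b0 in range(0, len(idx), 256):
            batch = idx[b0 : b0 + 256]
            fidx = windows.frame_idx[batch]
            uniq, inv = np.unique(fidx.ravel(), return_inverse=True)
            raws = model.forward_deduplicated(
                Tensor(frames_all[uniq]), inv.reshape(fidx.shape)
            )
            nll = model.nll_loss(raws, targets_z[batch])
            total += float(nll.data) * len(batch)
            n += len(batch)
    return total / n


@dataclass
class PredictionResult:
    hours: np.ndarray            # (N,) target epoch hours
    point: np.ndarray            # (N, C) mixture modes, count scale
    params: MixtureParams        # (N, C, 3), count scale
    all_absent: np.ndarray       # (N,) True where no behavioral data in context
    channel_names: list[str]


def predict_series(
    model: MDNModel,
    features: HourlyFeatureSeries,
    windows: ContextWindowSet,
    batch_size: int = 256,
) -> PredictionResult:
    """Mixture parameters and point estimates for every window.

    Hours whose whole context is behavior-free are flagged (their
    prediction collapses toward the model's unconditional output and is
    excluded from correlation-based evaluation downstream).
    """
    if not model.trained:
        raise ValueError("model has not been trained")
    frames_all = features.frames()
    model.set_training(False)
    N = len(windows)
    C = model.config.n_output_channels
    raw_all = np.empty((N, C, 3 * model.config.n_mixture), dtype=np.float64)
    with no_grad():
        for b0 in range(0, N, batch_size):
            sl = slice(b0, min(b0 + batch_size, N))
            fidx = windows.frame_idx[sl]
            uniq, inv = np.unique(fidx.ravel(), return_inverse=True)
            raws = model.forward_deduplicated(
                Tensor(frames_all[uniq]), inv.reshape(fidx.shape)
            )
            for c, raw in enumerate(raws):
                raw_all[sl, c, :] = raw.data
    params_z = model.raw_to_params(raw_all)
    point_z = point_estimate(params_z)
    scale = model.target_std[None, :]
    shift = model.target_mean[None, :]
    params = MixtureParams(
        params_z.means * scale[..., None] + shift[..., None],
        params_z.stds * scale[..., None],
        params_z.weights,
    )
    return PredictionResult(
        hours=windows.hours.copy(),
        point=point_z * scale + shift,
        params=params,
        all_absent=~windows.any_present,
        channel_names=list(model.channel_names),
    )


def save_model(model: MDNModel, path: str | Path):
    """Parameters as an .npz plus a JSON metadata sidecar."""
    path = Path(path)
    state = {}
    for mi, m in enumerate(model._modules()):
        for k, v in m.state_arrays().items():
            state[f"m{mi}::{k}"] = v
    np.savez_compressed(path.with_suffix(".npz"), **state)
    meta = {
        "config": model.config.__dict__,
        "target_mean": model.target_mean.tolist(),
        "target_std": model.target_std.tolist(),
        "channel_names": model.channel_names,
        "trained": model.trained,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> MDNModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    model = MDNModel(ModelConfig(**meta["config"]))
    with np.load(path.with_suffix(".npz")) as data:
        for mi, m in enumerate(model._modules()):
            prefix = f"m{mi}::"
            state = {
                k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)
            }
            m.load_state_arrays(state)
    model.target_mean = np.array(meta["target_mean"])
    model.target_std = np.array(meta["target_std"])
    model.channel_names = meta["channel_names"]
    model.trained = meta["trained"]
    return model
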