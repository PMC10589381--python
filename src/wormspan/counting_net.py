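"""Sequence-to-sequence live-worm counting network.

Input is the full assay as a sequence of simplified-domain frames, output
one live count per day.  Whether a worm is alive is encoded in *movement*
between days, so the architecture is: a three-block convolutional feature
extractor applied per frame (valid 5x5 convolutions, batch norm, leaky ReLU,
non-overlapping max pooling), a sequence block (LSTM, GRU or transformer
encoder) mixing information across days, and a fully connected head that
consumes the flattened whole-sequence feature block and emits the per-day
count vector.  On 256x256 frames the spatial trace is
256 -> 252 -> 84 -> 80 -> 20 -> 16 -> 8 with channels 4, 8, 16, giving a
1024-long per-frame feature.

Training minimizes the mean squared error between predicted and true counts
over all frames in a batch, with plain SGD.  The default regime (600
epochs, lr 0.001, batch 16) matches full-scale training on 57-day
sequences; the ``tiny`` spec (64x64 frames, 10-day sequences) is a
first-class reduced configuration for CPU-scale runs and tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from . import nn
from .blob_world import LifespanSample

__all__ = [
    "NetSpec",
    "TrainConfig",
    "CountPrediction",
    "conv_trace",
    "mse_loss",
    "build_model",
    "CountingNetwork",
    "train",
    "predict",
    "evaluate_mae",
    "make_optimizer",
    "save_checkpoint",
    "load_checkpoint",
    "load_checkpoint_with_optimizer",
]

VARIANTS = ("lstm", "gru", "transformer")


@dataclass(frozen=True)
class NetSpec:
    """Architecture hyperparameters for the counting network."""

    variant: str = "lstm"
    seq_length: int = 57
    image_size: int = 256
    conv_channels: tuple[int, int, int] = (4, 8, 16)
    kernel: int = 5
    pool_sizes: tuple[int, int, int] = (3, 4, 2)
    head_widths: tuple[int, int, int] = (2000, 2000, 750)
    rnn_hidden: int = 1024
    rnn_layers: int = 2
    tf_depth: int = 2
    tf_heads: int = 8
    tf_mlp_dim: int = 2048
    tf_dim_head: int = 64

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")

    @classmethod
    def tiny(cls, variant: str = "lstm") -> "NetSpec":
        """Reduced configuration for CPU-scale training: 64x64 frames, 10 days."""
        return cls(variant=variant, seq_length=10, image_size=64,
                   pool_sizes=(3, 2, 2), head_widths=(256, 256, 128),
                   rnn_hidden=128, tf_heads=4, tf_mlp_dim=256, tf_dim_head=16)

    @property
    def feature_length(self) -> int:
        sizes, _ = conv_trace(self.image_size, self.kernel, self.pool_sizes)
        return self.conv_channels[-1] * sizes[-1] * sizes[-1]


@dataclass(frozen=True)
class TrainConfig:
    """SGD training regime; defaults follow the full-scale recipe."""

    epochs: int = 600
    lr: float = 0.001
    batch_size: int = 16
    momentum: float = 0.9
    weight_decay: float = 0.0
    batches_per_epoch: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.batches_per_epoch) < 1 or self.lr <= 0:
            raise ValueError("epochs, batch_size, batches_per_epoch must be >=1 and lr > 0")


@dataclass(frozen=True)
class CountPrediction:
    """Raw regression outputs and their clamped integer rounding."""

    raw: np.ndarray
    rounded: np.ndarray


def conv_trace(image_size: int, kernel: int = 5,
               pool_sizes: tuple[int, ...] = (3, 4, 2)) -> tuple[list[int], list[int]]:
    """Spatial sizes after each conv (valid, stride 1) and each pool.

    Returns ``(all_sizes, conv_sizes)`` where ``all_sizes`` interleaves
    conv/pool outputs, e.g. 256 -> [252, 84, 80, 20, 16, 8].
    """
    sizes = []
    s = image_size
    for k in pool_sizes:
        s = s - (kernel - 1)
        if s < 1:
            raise ValueError(f"image size {image_size} too small for this conv stack")
        sizes.append(s)
        s = s // k
        sizes.append(s)
    return sizes, sizes[::2]


def mse_loss(pred, truth):
    """Mean squared error over all frames in the batch: (1/N) sum (y_hat - y)^2."""
    if isinstance(pred, nn.Tensor):
        t = truth if isinstance(truth, nn.Tensor) else nn.Tensor(
            np.asarray(truth, dtype=pred.data.dtype))
        if pred.shape != t.shape:
            raise ValueError(f"shape mismatch: {pred.shape} vs {t.shape}")
        return ((pred - t) ** 2).mean()
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return float(np.mean((pred - truth) ** 2))


class CountingNetwork(nn.Module):
    """CNN feature extractor + sequence block + fully connected count head."""

    def __init__(self, spec: NetSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        c1, c2, c3 = spec.conv_channels
        p1, p2, p3 = spec.pool_sizes
        k = spec.kernel
        self.conv1 = nn.Conv2d(1, c1, k, rng)
        self.bn1 = nn.BatchNorm(c1)
        self.pool1 = nn.MaxPool2d(p1)
        self.conv2 = nn.Conv2d(c1, c2, k, rng)
        self.bn2 = nn.BatchNorm(c2)
        self.pool2 = nn.MaxPool2d(p2)
        self.conv3 = nn.Conv2d(c2, c3, k, rng)
        self.bn3 = nn.BatchNorm(c3)
        self.pool3 = nn.MaxPool2d(p3)

        feat = spec.feature_length
        if spec.variant == "lstm":
            self.seq = nn.LSTM(feat, spec.rnn_hidden, spec.rnn_layers, rng)
            seq_out = spec.rnn_hidden
        elif spec.variant == "gru":
            self.seq = nn.GRU(feat, spec.rnn_hidden, spec.rnn_layers, rng)
            seq_out = spec.rnn_hidden
        else:
            self.seq = nn.TransformerEncoder(feat, spec.tf_depth, spec.tf_heads,
                                             spec.tf_mlp_dim, spec.tf_dim_head,
                                             spec.seq_length, rng)
            seq_out = feat
        self.seq_out_dim = seq_out

        h1, h2, h3 = spec.head_widths
        self.fc1 = nn.Linear(spec.seq_length * seq_out, h1, rng)
        self.fc_bn1 = nn.BatchNorm(h1)
        self.fc2 = nn.Linear(h1, h2, rng)
        self.fc_bn2 = nn.BatchNorm(h2)
        self.fc3 = nn.Linear(h2, h3, rng)
        self.fc_bn3 = nn.BatchNorm(h3)
        self.fc4 = nn.Linear(h3, spec.seq_length, rng)

    def extract_features(self, x: nn.Tensor) -> nn.Tensor:
        """Per-frame conv features: (B*T, 1, H, W) -> (B*T, feature_length)."""
        x = self.pool1(self.bn1(self.conv1(x)).leaky_relu())
        x = self.pool2(self.bn2(self.conv2(x)).leaky_relu())
        x = self.pool3(self.bn3(self.conv3(x)).leaky_relu())
        return x.reshape(x.shape[0], -1)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """(B, T, 1, H, W) normalized frames -> (B, T) real counts."""
        b, t = x.shape[0], x.shape[1]
        feats = self.extract_features(x.reshape(b * t, 1, x.shape[3], x.shape[4]))
        feats = feats.reshape(b, t, -1)
        seq_out = self.seq(feats)
        h = seq_out.reshape(b, t * self.seq_out_dim)
        h = self.fc_bn1(self.fc1(h)).leaky_relu()
        h = self.fc_bn2(self.fc2(h)).leaky_relu()
        h = self.fc_bn3(self.fc3(h)).leaky_relu()
        return self.fc4(h)


def build_model(spec: NetSpec, seed: int = 0) -> CountingNetwork:
    """Construct a counting network with seed-reproducible initialization."""
    return CountingNetwork(spec, np.random.default_rng(seed))


def _to_batch(samples: list[LifespanSample], spec: NetSpec) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into normalized (B, T, 1, H, W) inputs and (B, T) labels."""
    x = np.stack([s.images for s in samples]).astype(np.float32) / 255.0
    y = np.stack([s.labels for s in samples]).astype(np.float32)
    if x.shape[1] != spec.seq_length or x.shape[2] != spec.image_size:
        raise ValueError(
            f"samples of shape {x.shape[1:]} do not match spec "
            f"(seq {spec.seq_length}, image {spec.image_size})")
    return x[:, :, None, :, :], y


def make_optimizer(model: CountingNetwork, cfg: TrainConfig) -> "nn.SGD":
    return nn.SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                  weight_decay=cfg.weight_decay)


def train(model: CountingNetwork, dataset: Iterator[LifespanSample],
          cfg: TrainConfig, checkpoint_dir: str | Path | None = None,
          log=None, optimizer: "nn.SGD | None" = None
          ) -> tuple[CountingNetwork, list[float]]:
    """Run the SGD regime on an online sample stream.

    Each epoch consumes ``batches_per_epoch * batch_size`` fresh samples from
    the stream.  Returns the model and the per-epoch mean loss history.
    Pass ``optimizer`` (e.g. restored from a checkpoint) to resume a run with
    its momentum state intact.  Training aborts with ``FloatingPointError``
    if the loss goes non-finite.
    """
    spec = model.spec
    opt = optimizer if optimizer is not None else make_optimizer(model, cfg)
    history: list[float] = []
    model.train()
    for epoch in range(cfg.epochs):
        losses = []
        for _ in range(cfg.batches_per_epoch):
            samples = [next(dataset) for _ in range(cfg.batch_size)]
            x, y = _to_batch(samples, spec)
            opt.zero_grad()
            out = model(nn.Tensor(x))
            loss = mse_loss(out, y)
            if not (np.isfinite(loss.data) and np.isfinite(out.data).all()):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.data}")
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
        if log is not None:
            log(epoch, history[-1])
        if checkpoint_dir is not None:
            save_checkpoint(Path(checkpoint_dir) / "last.npz", model, cfg,
                            history, optimizer=opt)
    return model, history


def predict(model: CountingNetwork, images: np.ndarray) -> CountPrediction:
    """Per-day live-count prediction for one padded frame sequence.

    ``images``: (seq_length, H, W) 8-bit frames.  Raw outputs are rounded
    half-up and clamped at zero.
    """
    spec = model.spec
    images = np.asarray(images)
    if images.shape != (spec.seq_length, spec.image_size, spec.image_size):
        raise ValueError(
            f"expected frames of shape {(spec.seq_length, spec.image_size, spec.image_size)}, "
            f"got {images.shape}")
    x = images.astype(np.float32)[None, :, None, :, :] / 255.0
    was_training = model.training
    model.eval()
    raw = model(nn.Tensor(x)).data[0].astype(float)
    model.train(was_training)
    rounded = np.maximum(0, np.floor(raw + 0.5)).astype(int)
    return CountPrediction(raw=raw, rounded=rounded)


def evaluate_mae(model: CountingNetwork, samples: Iterable[LifespanSample]) -> float:
    """Mean absolute count error over all frames of the given samples."""
    errs = []
    for s in samples:
        pred = predict(model, s.images)
        errs.append(np.abs(pred.raw - s.labels.astype(float)))
    return float(np.mean(np.concatenate(errs)))


def save_checkpoint(path: str | Path, model: CountingNetwork, cfg: TrainConfig,
                    history: list[float], optimizer: "nn.SGD | None" = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps({"spec": asdict(model.spec), "train": asdict(cfg),
                       "history": list(history)})
    extras = {}
    if optimizer is not None:
        extras = {f"__vel__{i}": v for i, v in enumerate(optimizer._velocity)}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **extras, **model.state_dict())


def load_checkpoint(path: str | Path
                    ) -> tuple[CountingNetwork, TrainConfig, list[float]]:
    model, cfg, history, _ = load_checkpoint_with_optimizer(path)
    return model, cfg, history


def load_checkpoint_with_optimizer(path: str | Path):
    """Restore model, train config, loss history and a resumable optimizer."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files
                 if k != "__meta__" and not k.startswith("__vel__")}
        vel = [data[f"__vel__{i}"]
               for i in range(sum(k.startswith("__vel__") for k in data.files))]
    spec_d = meta["spec"]
    for key in ("conv_channels", "pool_sizes", "head_widths"):
        spec_d[key] = tuple(spec_d[key])
    spec = NetSpec(**spec_d)
    model = build_model(spec, seed=0)
    model.load_state_dict(state)
    cfg = TrainConfig(**meta["train"])
    opt = make_optimizer(model, cfg)
    if vel:
        opt._velocity = [v.copy() for v in vel]
    return model, cfg, meta["history"], opt
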