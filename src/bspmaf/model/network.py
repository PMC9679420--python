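"""The 3D CNN recurrence classifier with a temporal-attention block.

Architecture (channels-first, input ``(N, 1, T, H, W)``):

* contracting path — five 3x3x3 convolutions, three of them stride-2, the
  channel count doubling at each down-sampling step (c, 2c, 4c, 8c, 8c);
  batch normalization and a rectifier after every convolution.  The output
  of the fifth convolution is fusion tap F1 and hosts the temporal-attention
  block.
* expansive path — three 2x2x2 stride-2 up-convolutions, each halving the
  channel count and concatenating the matching contracting feature map
  (U-Net skip connection); the concatenated maps are fusion taps F2-F4.
* head — F1-F4 are global-average-pooled, concatenated, passed through
  dropout and three fully connected layers (Dense 256 first), and a softmax
  over the two outcome classes.  Eight convolutional layers and three fully
  connected layers in total.

The temporal-attention block re-weights frames: the feature map is squeezed
to one channel by a 1x1x1 convolution, per-frame statistics are taken by
spatial average pooling and spatial max pooling, mean-centered across
frames (so the gate responds to a frame's salience relative to the rest of
the window, and a time-constant input receives the neutral uniform gate),
passed through a shared bias-free two-layer perceptron (hidden width T/r),
summed, and a sigmoid yields the gate M_T in (0,1)^T which multiplies the
input frame-wise.  Variants: A1 uses the max statistic only; A2 and A3 skip
the 1x1x1 squeeze and instead concatenate per-channel statistics (max for
A2, average and max for A3) before the perceptron.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigurationError, InvalidParameterError, ShapeError
from .autodiff import Tensor, concat
from .layers import (
    Adam,
    BatchNorm3d,
    Conv3d,
    ConvTranspose3d,
    Dropout,
    Linear,
    Module,
    global_avg_pool,
    softmax,
)

ATTENTION_VARIANTS = ("block", "A1", "A2", "A3")


@dataclass
class AttentionConfig:
    reduction_r: int = 4
    variant: str = "block"

    def validate(self) -> None:
        if self.reduction_r < 1:
            raise InvalidParameterError("reduction_r must be >= 1")
        if self.variant not in ATTENTION_VARIANTS:
            raise InvalidParameterError(f"unknown attention variant {self.variant!r}")


@dataclass
class NetworkConfig:
    """Hyperparameters of the recurrence classifier."""

    input_hwt: tuple[int, int, int] = (32, 32, 128)  # H, W, T of the sequence
    base_channels: int = 16  # channel schedule c, 2c, 4c, 8c
    fusion_taps: tuple[str, ...] = ("F1", "F2", "F3", "F4")
    dense_dim: int = 256
    dense_hidden: int = 32
    dropout_rate: float = 0.5
    use_attention: bool = True
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    loss: str = "focal"
    alpha: float = 0.25
    gamma: float = 2.0

    def validate(self) -> None:
        h, w, t = self.input_hwt
        if any(d % 8 != 0 for d in (h, w, t)):
            raise ConfigurationError(
                f"input dims {self.input_hwt} must be divisible by the 8x down-sampling"
            )
        if not self.fusion_taps or not set(self.fusion_taps) <= {"F1", "F2", "F3", "F4"}:
            raise InvalidParameterError("fusion_taps must be a subset of F1..F4")
        if self.loss not in ("focal", "cross-entropy"):
            raise InvalidParameterError(f"unknown loss {self.loss!r}")
        self.attention.validate()


class TemporalAttention(Module):
    """Frame-wise squeeze-excitation gate along the time axis."""

    def __init__(self, channels: int, t_frames: int, cfg: AttentionConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg.validate()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.channels, self.t_frames = channels, t_frames
        hidden = max(1, t_frames // cfg.reduction_r)
        self.hidden = hidden
        in_dim = t_frames if cfg.variant in ("block", "A1") else channels * t_frames
        # bias-free shared perceptron (SENet convention)
        self.w1 = Tensor(rng.normal(0.0, np.sqrt(2.0 / in_dim), (in_dim, hidden)),
                         requires_grad=True)
        self.w2 = Tensor(rng.normal(0.0, np.sqrt(2.0 / hidden), (hidden, t_frames)),
                         requires_grad=True)
        if cfg.variant in ("block", "A1"):
            self.squeeze = Conv3d(channels, 1, kernel=1, pad=0, rng=rng)

    def _mlp(self, s: Tensor) -> Tensor:
        return (s @ self.w1).relu() @ self.w2

    @staticmethod
    def _center(s: Tensor, channels: int) -> Tensor:
        """Mean-center each channel's statistics across frames.

        The gate thereby encodes *relative* frame salience: a time-constant
        input centers to zero and yields the neutral uniform gate sigmoid(0),
        regardless of the perceptron weights.
        """
        n, ct = s.shape
        t = ct // channels
        s3 = s.reshape(n, channels, t)
        return (s3 - s3.mean(axis=2, keepdims=True)).reshape(n, ct)

    def gate(self, x: Tensor) -> Tensor:
        """Compute M_T in (0,1)^T for a feature map (N, C, T, H, W)."""
        n, c, t, h, w = x.shape
        if c != self.channels or t != self.t_frames:
            raise ShapeError("attention block built for different (C, T)")
        v = self.cfg.variant
        if v in ("block", "A1"):
            f = self.squeeze(x).reshape(n, t, h * w)  # single-channel map
            stats = [f.max(axis=2)] if v == "A1" else [f.mean(axis=2), f.max(axis=2)]
            stats = [self._center(s, 1) for s in stats]
        else:
            f = x.reshape(n, c * t, h * w)  # per-channel statistics, concatenated
            stats = [f.max(axis=2)] if v == "A2" else [f.mean(axis=2), f.max(axis=2)]
            stats = [self._center(s, c) for s in stats]
        score = self._mlp(stats[0])
        for s in stats[1:]:
            score = score + self._mlp(s)
        return score.sigmoid()  # (N, T)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, t, h, w = x.shape
        m = self.gate(x)
        return x * m.reshape(n, 1, t, 1, 1)


def focal_loss(p: Tensor, y: np.ndarray, alpha: float = 0.25, gamma: float = 2.0) -> Tensor:
    """Focal loss for binary labels.

    ``p`` is the predicted probability of the positive (recurrence) class and
    ``y`` the ground truth in {+1, -1} (0 is accepted as an alias of -1):

        y = +1:  -alpha       * (1 - p)^gamma * log(p)
        y = -1:  -(1 - alpha) * p^gamma       * log(1 - p)

    returned as the batch mean.  With gamma = 0 and alpha = 0.5 this is half
    the binary cross-entropy.  Probabilities are clamped to [1e-7, 1 - 1e-7].
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    pos = (y > 0).astype(float)
    neg = 1.0 - pos
    pc = p.reshape(-1).clip(1e-7, 1.0 - 1e-7)
    loss_pos = (1.0 - pc) ** gamma * pc.log() * (-alpha)
    loss_neg = pc**gamma * (1.0 - pc).log() * (-(1.0 - alpha))
    return (Tensor(pos) * loss_pos + Tensor(neg) * loss_neg).mean()


def cross_entropy_loss(p: Tensor, y: np.ndarray) -> Tensor:
    """Plain binary cross-entropy on the positive-class probability."""
    y = np.asarray(y, dtype=float).reshape(-1)
    pos = (y > 0).astype(float)
    pc = p.reshape(-1).clip(1e-7, 1.0 - 1e-7)
    return -(Tensor(pos) * pc.log() + Tensor(1.0 - pos) * (1.0 - pc).log()).mean()


class RecurrenceNet3D(Module):
    """U-Net-style 3D CNN with deep-shallow fusion and temporal attention."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c = cfg.base_channels
        h, w, t = cfg.input_hwt

        self.conv1 = Conv3d(1, c, 3, 1, rng=rng)
        self.bn1 = BatchNorm3d(c)
        self.conv2 = Conv3d(c, 2 * c, 3, 2, rng=rng)
        self.bn2 = BatchNorm3d(2 * c)
        self.conv3 = Conv3d(2 * c, 4 * c, 3, 2, rng=rng)
        self.bn3 = BatchNorm3d(4 * c)
        self.conv4 = Conv3d(4 * c, 8 * c, 3, 2, rng=rng)
        self.bn4 = BatchNorm3d(8 * c)
        self.conv5 = Conv3d(8 * c, 8 * c, 3, 1, rng=rng)
        self.bn5 = BatchNorm3d(8 * c)
        if cfg.use_attention:
            self.attention = TemporalAttention(8 * c, t // 8, cfg.attention, rng=rng)
        self.up1 = ConvTranspose3d(8 * c, 4 * c, rng=rng)
        self.bnu1 = BatchNorm3d(4 * c)
        self.up2 = ConvTranspose3d(8 * c, 2 * c, rng=rng)
        self.bnu2 = BatchNorm3d(2 * c)
        self.up3 = ConvTranspose3d(4 * c, c, rng=rng)
        self.bnu3 = BatchNorm3d(c)

        tap_dims = {"F1": 8 * c, "F2": 8 * c, "F3": 4 * c, "F4": 2 * c}
        feat = sum(tap_dims[f] for f in cfg.fusion_taps)
        self.dropout = Dropout(cfg.dropout_rate, rng=np.random.default_rng(seed + 1))
        self.fc1 = Linear(feat, cfg.dense_dim, rng=rng)
        self.fc2 = Linear(cfg.dense_dim, cfg.dense_hidden, rng=rng)
        self.fc3 = Linear(cfg.dense_hidden, 2, rng=rng)

    # counted over the backbone; the attention block's 1x1x1 squeeze is gate
    # plumbing, not a feature-extraction layer
    def count_layers(self) -> tuple[int, int]:
        convs = sum(isinstance(m, (Conv3d, ConvTranspose3d)) for m in self._modules.values())
        fcs = sum(isinstance(m, Linear) for m in self._modules.values())
        return convs, fcs

    def contract(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        """Contracting path; returns the skip maps x1-x3 and the deep map F1."""
        h, w, t = self.cfg.input_hwt
        if x.shape[1:] != (1, t, h, w):
            raise ShapeError(f"expected input (N, 1, {t}, {h}, {w}), got {x.shape}")
        x1 = self.bn1(self.conv1(x)).relu()
        x2 = self.bn2(self.conv2(x1)).relu()
        x3 = self.bn3(self.conv3(x2)).relu()
        x4 = self.bn4(self.conv4(x3)).relu()
        f1 = self.bn5(self.conv5(x4)).relu()
        return x1, x2, x3, f1

    def forward(self, x: Tensor) -> Tensor:
        x1, x2, x3, f1 = self.contract(x)
        deep = self.attention(f1) if self.cfg.use_attention else f1
        u1 = self.bnu1(self.up1(deep)).relu()
        f2 = concat([u1, x3], axis=1)
        u2 = self.bnu2(self.up2(f2)).relu()
        f3 = concat([u2, x2], axis=1)
        u3 = self.bnu3(self.up3(f3)).relu()
        f4 = concat([u3, x1], axis=1)

        taps = {"F1": f1, "F2": f2, "F3": f3, "F4": f4}
        feats = concat([global_avg_pool(taps[f]) for f in self.cfg.fusion_taps], axis=1)
        z = self.dropout(feats)
        z = self.fc1(z).relu()
        z = self.fc2(z).relu()
        return self.fc3(z)

    def predict_proba(self, x: Tensor) -> Tensor:
        return softmax(self.forward(x))

    def loss(self, probs: Tensor, y: np.ndarray) -> Tensor:
        # column 1 is the recurrence class
        p_pos = (probs * Tensor(np.array([0.0, 1.0]))).sum(axis=1)
        if self.cfg.loss == "focal":
            return focal_loss(p_pos, y, self.cfg.alpha, self.cfg.gamma)
        return cross_entropy_loss(p_pos, y)


def build_network(cfg: NetworkConfig, seed: int = 0) -> RecurrenceNet3D:
    """Construct the classifier with deterministic seed-driven initialization."""
    return RecurrenceNet3D(cfg, seed=seed)


def sequences_to_batch(sequences: np.ndarray) -> Tensor:
    """(N, H, W, T) stacks -> network input (N, 1, T, H, W)."""
    arr = np.asarray(sequences, dtype=np.float64)
    if arr.ndim != 4:
        raise ShapeError(f"expected (N, H, W, T), got {arr.shape}")
    return Tensor(arr.transpose(0, 3, 1, 2)[:, None, :, :, :])


def predict(model: RecurrenceNet3D, sequences: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Class probabilities (N, 2) for a stack of H x W x T sequences.

    Column 1 is the probability of recurrence.  The model is run in
    evaluation mode (batch-norm running statistics, no dropout).
    """
    was_training = model.training
    model.eval()
    probs = []
    arr = np.asarray(sequences, dtype=np.float64)
    for i in range(0, len(arr), batch_size):
        x = sequences_to_batch(arr[i : i + batch_size])
        probs.append(model.predict_proba(x).data)
    model.train(was_training)
    return np.concatenate(probs, axis=0)


__all__ = [
    "Adam",
    "AttentionConfig",
    "NetworkConfig",
    "RecurrenceNet3D",
    "TemporalAttention",
    "build_network",
    "cross_entropy_loss",
    "focal_loss",
    "predict",
    "sequences_to_batch",
]
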