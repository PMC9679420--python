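"""Neural-network layers for 3D feature maps, built on the autodiff core.

Feature maps are channels-first: ``(N, C, T, H, W)`` with T the frame (time)
axis of the isopotential sequence.  Convolutions are implemented as
im2col + matmul; the up-convolution is a 2x2x2 stride-2 transposed
convolution expressed with reshape/transpose/matmul so its gradient comes
from the generic ops.
"""

from __future__ import annotations

import numpy as np

from ..errors import ShapeError
from .autodiff import Tensor, conv_output_shape, im2col


class Module:
    """Tiny module base: auto-registers parameters, buffers and submodules."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {prefix + k: v.data.copy() for k, v in self._params.items()}
        state.update({prefix + k: v.copy() for k, v in self._buffers.items()})
        for name, m in self._modules.items():
            state.update(m.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, v in self._params.items():
            v.data = state[prefix + k].copy()
        for k in self._buffers:
            self._buffers[k] = state[prefix + k].copy()
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), shape), requires_grad=True)


class Conv3d(Module):
    """3D convolution, kernel k^3, optional stride, 'same'-style padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.pad = pad if pad is not None else kernel // 2
        ck = in_ch * kernel**3
        self.weight = _he_init(rng, (out_ch, ck), ck)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, c = x.shape[:2]
        if c != self.in_ch:
            raise ShapeError(f"expected {self.in_ch} channels, got {c}")
        k = (self.kernel,) * 3
        cols = im2col(x, k, self.stride, self.pad)  # (N, CK, L)
        out = self.weight @ cols  # (N, out_ch, L)
        to, ho, wo = conv_output_shape((c, *x.shape[2:]), k, self.stride, self.pad)
        out = out + self.bias.reshape(1, self.out_ch, 1)
        return out.reshape(n, self.out_ch, to, ho, wo)


class ConvTranspose3d(Module):
    """2x2x2 stride-2 up-convolution: doubles T, H, W."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = _he_init(rng, (in_ch, out_ch * 8), in_ch)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, t, h, w = x.shape
        if c != self.in_ch:
            raise ShapeError(f"expected {self.in_ch} channels, got {c}")
        flat = x.reshape(n, c, t * h * w).transpose(0, 2, 1)  # (N, THW, C)
        y = flat @ self.weight  # (N, THW, out*8)
        y = y.reshape(n, t, h, w, self.out_ch, 2, 2, 2)
        y = y.transpose(0, 4, 1, 5, 2, 6, 3, 7)  # (N, out, T,2, H,2, W,2)
        y = y.reshape(n, self.out_ch, 2 * t, 2 * h, 2 * w)
        return y + self.bias.reshape(1, self.out_ch, 1, 1, 1)


class BatchNorm3d(Module):
    """Batch normalization over batch and spatio-temporal axes, per channel."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self._buffers["running_mean"] = np.zeros(channels)
        self._buffers["running_var"] = np.ones(channels)

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        shape = (1, c, 1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3, 4), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.reshape(c)
            )
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var.data.reshape(c)
            )
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(shape))
            var = Tensor(self._buffers["running_var"].reshape(shape))
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = _he_init(rng, (in_dim, out_dim), in_dim)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.uniform(size=x.shape) < keep) / keep
        return x * Tensor(mask)


def softmax(logits: Tensor) -> Tensor:
    """Numerically stable softmax over the last axis."""
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))  # constant, no grad path
    e = (logits - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, T, H, W) -> (N, C)."""
    return x.mean(axis=(2, 3, 4))


class Adam:
    """Adam with 1/t learning-rate decay: lr_t = lr0 / (1 + decay * t)."""

    def __init__(self, params: list[Tensor], lr0: float = 1e-3, decay: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr0, self.decay = lr0, decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        lr = self.lr0 / (1.0 + self.decay * self.t)
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
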