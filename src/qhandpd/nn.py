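"""Neural-network layers, convolutions and optimisers on the autodiff engine.

Covers exactly what the dual-track classifier needs: strided/depthwise
convolutions (im2col), batch/layer normalisation, pooling, linear layers, Adam
and a reduce-on-plateau learning-rate schedule.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module", "Parameter", "Conv2d", "DepthwiseConv2d", "Linear",
    "BatchNorm2d", "LayerNorm", "Sequential", "Identity",
    "conv2d", "depthwise_conv2d", "max_pool2d", "global_avg_pool",
    "softmax", "log_softmax", "Adam", "ReduceLROnPlateau",
]


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class with recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for mod in self.modules():
            for v in mod.__dict__.values():
                candidates = v if isinstance(v, (list, tuple)) else [v]
                for c in candidates:
                    if isinstance(c, Tensor) and c.requires_grad and id(c) not in seen:
                        seen.add(id(c))
                        params.append(c)
        return params

    def count_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                candidates = v if isinstance(v, (list, tuple)) else [v]
                for j, c in enumerate(candidates):
                    if isinstance(c, Tensor):
                        state[f"{i}.{k}.{j}"] = c.data.copy()
                    elif isinstance(c, np.ndarray):
                        state[f"{i}.{k}.{j}"] = c.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, m in enumerate(self.modules()):
            for k, v in list(m.__dict__.items()):
                candidates = v if isinstance(v, (list, tuple)) else [v]
                for j, c in enumerate(candidates):
                    key = f"{i}.{k}.{j}"
                    if key not in state:
                        continue
                    if isinstance(c, Tensor):
                        c.data = state[key].copy()
                    elif isinstance(c, np.ndarray):
                        m.__dict__[k] = state[key].copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """(N,C,Hp,Wp) -> windows (N, C, Ho, Wo, kh, kw) as a strided view."""
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return view[:, :, ::stride, ::stride]


def pad2d_edge(x: Tensor, pad: int) -> Tensor:
    """Replicate-pad the two trailing axes (edge values repeated).

    Exam canvases have a white background; zero padding would surround every
    feature map with an artificial dark border that convolution filters (and
    later, saliency maps) latch onto.  Implemented as clipped-index gathers so
    gradients scatter-add back onto the border pixels.
    """
    if pad == 0:
        return x
    h, w = x.shape[2], x.shape[3]
    ridx = np.clip(np.arange(-pad, h + pad), 0, h - 1)
    cidx = np.clip(np.arange(-pad, w + pad), 0, w - 1)
    return x.take(ridx, axis=2).take(cidx, axis=3)


def _pad(x: Tensor, pad: int, mode: str) -> Tensor:
    if mode == "zero":
        return x.pad2d(pad)
    if mode == "edge":
        return pad2d_edge(x, pad)
    raise ValueError(f"unknown padding mode '{mode}'")


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0,
           pad_mode: str = "zero") -> Tensor:
    """Standard 2-D convolution (cross-correlation), NCHW layout."""
    cout, cin, kh, kw = weight.shape
    xp = _pad(x, padding, pad_mode)
    n, c, hp, wp = xp.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    view = _im2col(xp.data, kh, kw, stride)
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, ho * wo, c * kh * kw)
    wmat = weight.data.reshape(cout, -1)
    out = cols @ wmat.T                      # (N, L, Cout)
    out = out.transpose(0, 2, 1).reshape(n, cout, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    parents = (xp, weight) + ((bias,) if bias is not None else ())

    def backward(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(n, ho * wo, cout)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.einsum("nlc,nlk->ck", g2, cols, optimize=True)
            weight._accum(gw.reshape(weight.shape))
        if xp.requires_grad:
            gcols = (g2 @ wmat).reshape(n, ho, wo, c, kh, kw)
            gxp = np.zeros((n, c, hp, wp), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * ho:stride,
                        j:j + stride * wo:stride] += \
                        gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            xp._accum(gxp)

    return Tensor._make(out, parents, backward)


def depthwise_conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
                     stride: int = 1, padding: int = 0,
                     pad_mode: str = "zero") -> Tensor:
    """Depthwise convolution; ``weight`` is (C, mult, kh, kw), output C*mult."""
    c, mult, kh, kw = weight.shape
    xp = _pad(x, padding, pad_mode)
    n, cx, hp, wp = xp.shape
    if cx != c:
        raise ValueError(f"depthwise weight expects {c} channels, got {cx}")
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    view = _im2col(xp.data, kh, kw, stride)  # (N,C,Ho,Wo,kh,kw)
    out = np.einsum("nchwij,cmij->ncmhw", view, weight.data, optimize=True)
    out = out.reshape(n, c * mult, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, c * mult, 1, 1)

    parents = (xp, weight) + ((bias,) if bias is not None else ())

    def backward(g):
        g5 = g.reshape(n, c, mult, ho, wo)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.einsum("ncmhw,nchwij->cmij", g5, view, optimize=True)
            weight._accum(gw)
        if xp.requires_grad:
            gview = np.einsum("ncmhw,cmij->nchwij", g5, weight.data,
                              optimize=True)
            gxp = np.zeros((n, c, hp, wp), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * ho:stride,
                        j:j + stride * wo:stride] += gview[:, :, :, :, i, j]
            xp._accum(gxp)

    return Tensor._make(out, parents, backward)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping max pooling; trailing rows/cols are cropped."""
    n, c, h, w = x.shape
    ho, wo = h // k, w // k
    xc = x[:, :, :ho * k, :wo * k] if (h % k or w % k) else x
    xr = xc.reshape(n, c, ho, k, wo, k)
    return xr.max(axis=5).max(axis=3)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C)"""
    return x.mean(axis=(2, 3))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2d(Module):
    """Conv layer; replicate padding by default (white-canvas inputs — zero
    padding would add an artificial dark frame to every map)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 pad_mode: str = "edge",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        std = math.sqrt(2.0 / fan_in)  # He init, ReLU networks
        self.weight = Parameter(rng.normal(
            0.0, std, (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding
        self.pad_mode = pad_mode

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.pad_mode)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, multiplier: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 pad_mode: str = "edge",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = kernel_size * kernel_size
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(
            0.0, std, (channels, multiplier, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(channels * multiplier)) if bias else None
        self.stride = stride
        self.padding = padding
        self.pad_mode = pad_mode

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.weight, self.bias, self.stride,
                                self.padding, self.pad_mode)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = math.sqrt(6.0 / (in_features + out_features))  # Glorot
        self.weight = Parameter(rng.uniform(
            -bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(c))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(c))
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(1, c, 1, 1) \
            + self.beta.reshape(1, c, 1, 1)


class LayerNorm(Module):
    """Normalise over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Halve (by ``factor``) the optimiser's lr when the monitored loss stalls."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 3,
                 min_lr: float = 1e-7):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = math.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> bool:
        """Returns True when the lr was reduced this call."""
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            new_lr = max(self.optimizer.lr * self.factor, self.min_lr)
            reduced = new_lr < self.optimizer.lr
            self.optimizer.lr = new_lr
            self.bad_epochs = 0
            return reduced
        return False
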