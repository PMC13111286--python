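"""Ghost convolutions, attention operators and the CDAB bottleneck block.

A CDAB (cross-dimensional attention bottleneck) block runs a ghost module —
a primary convolution producing a fraction of the output channels plus cheap
depthwise maps for the rest — through either coordinate attention followed by
squeeze-and-excite (early stages) or triplet attention (late stages), with a
residual path that projects by a strided 1×1 convolution whenever shape or
stride would otherwise break the skip connection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate, stack
from . import nn

__all__ = ["GhostModule", "CoordinateAttention", "SqueezeExcite",
           "TripletAttention", "CDABBlock", "BlockConfig"]


@dataclass
class BlockConfig:
    in_channels: int
    out_channels: int
    stride: int = 1
    attention_variant: str = "CA_SE"     # "CA_SE" | "TRIPLET"
    ghost_ratio: int = 2
    se_reduction: int = 8
    ca_reduction: int = 8

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.attention_variant not in ("CA_SE", "TRIPLET"):
            raise ValueError(
                f"unknown attention variant '{self.attention_variant}'")
        if self.ghost_ratio < 2:
            raise ValueError("ghost_ratio must be >= 2")
        if self.out_channels % self.ghost_ratio:
            raise ValueError("out_channels must be divisible by ghost_ratio")


class GhostModule(nn.Module):
    """Primary 3×3 convolution for ``out/ratio`` channels; the remaining
    channels are cheap depthwise maps of the primary outputs."""

    def __init__(self, in_channels: int, out_channels: int, ratio: int = 2,
                 stride: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        if ratio < 2 or out_channels % ratio:
            raise ValueError("out_channels must be divisible by ratio >= 2")
        primary = out_channels // ratio
        self.primary = nn.Conv2d(in_channels, primary, 3, stride=stride,
                                 padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(primary)
        self.cheap = nn.DepthwiseConv2d(primary, ratio - 1, 3, padding=1,
                                        rng=rng)
        self.bn2 = nn.BatchNorm2d(primary * (ratio - 1))

    def forward(self, x: Tensor) -> Tensor:
        p = self.bn1(self.primary(x)).relu()
        c = self.bn2(self.cheap(p)).relu()
        return concatenate([p, c], axis=1)


class SqueezeExcite(nn.Module):
    """Channel gates from a global-average-pooled bottleneck MLP."""

    def __init__(self, channels: int, reduction: int = 8,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if reduction >= channels:
            raise ValueError("reduction must be < channel count")
        mid = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, mid, rng=rng)
        self.fc2 = nn.Linear(mid, channels, rng=rng)

    def gates(self, x: Tensor) -> Tensor:
        z = nn.global_avg_pool(x)                     # (N, C)
        return self.fc2(self.fc1(z).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[:2]
        return x * self.gates(x).reshape(n, c, 1, 1)


class CoordinateAttention(nn.Module):
    """Position-aware channel gates from per-axis pooled descriptors.

    x is average-pooled along W (giving a C×H profile) and along H (C×W);
    the two profiles share a reducing 1×1 convolution, then per-axis 1×1
    convolutions + sigmoid give gates broadcast over the other axis.
    """

    def __init__(self, channels: int, reduction: int = 8,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if reduction >= channels:
            raise ValueError("reduction must be < channel count")
        mid = max(1, channels // reduction)
        self.conv_shared = nn.Conv2d(channels, mid, 1, rng=rng)
        self.conv_h = nn.Conv2d(mid, channels, 1, rng=rng)
        self.conv_w = nn.Conv2d(mid, channels, 1, rng=rng)

    def gates(self, x: Tensor) -> tuple[Tensor, Tensor]:
        n, c, h, w = x.shape
        ph = x.mean(axis=3, keepdims=True)                       # (N,C,H,1)
        pw = x.mean(axis=2, keepdims=True).transpose((0, 1, 3, 2))  # (N,C,W,1)
        y = self.conv_shared(concatenate([ph, pw], axis=2)).relu()
        yh, yw = y[:, :, :h, :], y[:, :, h:, :]
        gate_h = self.conv_h(yh).sigmoid()                       # (N,C,H,1)
        gate_w = self.conv_w(yw).sigmoid().transpose((0, 1, 3, 2))  # (N,C,1,W)
        return gate_h, gate_w

    def forward(self, x: Tensor) -> Tensor:
        gate_h, gate_w = self.gates(x)
        return x * gate_h * gate_w


def z_pool(x: Tensor, axis: int = 1) -> Tensor:
    """Stack max and mean over ``axis`` into a 2-channel map."""
    return stack([x.max(axis=axis), x.mean(axis=axis)], axis=1)


class TripletAttention(nn.Module):
    """Three-branch attention over the (H,W), (C,W) and (C,H) planes.

    Each branch rotates one spatial axis onto the channel axis, Z-pools it,
    gates through a 7×7 convolution + sigmoid, and rotates back; the block
    output is the mean of the three gated maps.
    """

    def __init__(self, kernel_size: int = 7,
                 rng: np.random.Generator | None = None):
        super().__init__()
        pad = kernel_size // 2
        self.conv_hw = nn.Conv2d(2, 1, kernel_size, padding=pad, rng=rng)
        self.conv_cw = nn.Conv2d(2, 1, kernel_size, padding=pad, rng=rng)
        self.conv_ch = nn.Conv2d(2, 1, kernel_size, padding=pad, rng=rng)

    @staticmethod
    def _branch(x: Tensor, conv: nn.Conv2d) -> Tensor:
        gate = conv(z_pool(x, axis=1)).sigmoid()  # (N,1,H',W')
        return x * gate

    def forward(self, x: Tensor) -> Tensor:
        b1 = self._branch(x, self.conv_hw)
        # H onto the channel axis
        xr = x.transpose((0, 2, 1, 3))
        b2 = self._branch(xr, self.conv_ch).transpose((0, 2, 1, 3))
        # W onto the channel axis
        xr = x.transpose((0, 3, 2, 1))
        b3 = self._branch(xr, self.conv_cw).transpose((0, 3, 2, 1))
        return (b1 + b2 + b3) * (1.0 / 3.0)


class CDABBlock(nn.Module):
    """Ghost module → attention → batch norm, summed with a (projected)
    residual and passed through ReLU."""

    def __init__(self, config: BlockConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = config
        self.config = cfg
        self.ghost = GhostModule(cfg.in_channels, cfg.out_channels,
                                 ratio=cfg.ghost_ratio, stride=cfg.stride,
                                 rng=rng)
        if cfg.attention_variant == "CA_SE":
            self.attn = nn.Sequential(
                CoordinateAttention(cfg.out_channels, cfg.ca_reduction, rng=rng),
                SqueezeExcite(cfg.out_channels, cfg.se_reduction, rng=rng))
        else:
            self.attn = TripletAttention(rng=rng)
        self.bn = nn.BatchNorm2d(cfg.out_channels)
        if cfg.stride != 1 or cfg.in_channels != cfg.out_channels:
            self.shortcut: nn.Module = nn.Conv2d(
                cfg.in_channels, cfg.out_channels, 1, stride=cfg.stride,
                rng=rng)
        else:
            self.shortcut = nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        main = self.bn(self.attn(self.ghost(x)))
        res = self.shortcut(x)
        if main.shape != res.shape:
            raise ValueError(
                f"residual shape {res.shape} cannot join main path "
                f"{main.shape}")
        return (main + res).relu()
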