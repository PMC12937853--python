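"""Convolutional building blocks: the dense separable-convolution detail
extractor and the two multi-scale depth-wise convolution blocks.

* `DenseDetailBlock` sits at the shallowest encoder stage and densely
  extracts high-frequency spatial detail before any downsampling: each
  internal layer sees the channel concatenation of the block input and
  every previous layer's output.
* `MultiScaleParallelBlock` runs depth-wise convolutions of several
  kernel sizes in parallel and merges them by summation, covering the
  scale range from the narrow notch to the surrounding condyles.
* `LargeKernelSerialBlock` is a bottleneck that chains large-kernel
  depth-wise convolutions inside a pointwise expansion, growing the
  receptive field to 1 + sum(k_i - 1) without large dense kernels.

All convolution units carry batch normalisation + ReLU unless the block
is built with `use_norm=False`, which the test suite uses to freeze
blocks into exact identity mappings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from . import tensor as T
from .tensor import Tensor


@dataclass
class DetailBlockConfig:
    in_channels: int = 32
    growth_channels: int = 16
    n_layers: int = 4
    out_channels: int = 32
    use_norm: bool = True

    def __post_init__(self):
        if self.n_layers < 2:
            raise ValueError("dense connectivity needs n_layers >= 2")
        for f in ("in_channels", "growth_channels", "n_layers", "out_channels"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be positive")


@dataclass
class MultiScaleConfig:
    channels: int = 32
    kernel_sizes: tuple = (3, 5, 7)
    expansion: float = 2.0
    use_norm: bool = True

    def __post_init__(self):
        if any(k % 2 == 0 or k < 1 for k in self.kernel_sizes):
            raise ValueError(
                f"kernel sizes must be odd and positive, got {self.kernel_sizes}"
            )
        if self.channels < 1 or self.expansion <= 0:
            raise ValueError("channels must be positive and expansion > 0")


class SeparableConv(nn.Module):
    """Depth-wise k x k followed by pointwise 1x1 (optionally + BN + ReLU)."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 use_norm: bool = True):
        super().__init__()
        self.depthwise = nn.DepthwiseConv2d(in_ch, k, rng, bias=not use_norm)
        self.pointwise = nn.Conv2d(in_ch, out_ch, 1, rng, bias=not use_norm)
        self.post = (
            nn.Sequential(nn.BatchNorm2d(out_ch), nn.ReLU())
            if use_norm
            else nn.Identity()
        )

    def forward(self, x):
        return self.post(self.pointwise(self.depthwise(x)))


class DenseDetailBlock(nn.Module):
    """Densely connected separable-convolution detail extractor."""

    def __init__(self, cfg: DetailBlockConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.layers = nn.ModuleList()
        ch = cfg.in_channels
        for _ in range(cfg.n_layers):
            self.layers.append(
                SeparableConv(ch, cfg.growth_channels, 3, rng, cfg.use_norm)
            )
            ch += cfg.growth_channels
        self.project = nn.Conv2d(ch, cfg.out_channels, 1, rng)

    def layer_input_channels(self, j: int) -> int:
        """Channel count seen by internal layer j (dense concatenation)."""
        return self.cfg.in_channels + j * self.cfg.growth_channels

    def forward(self, x):
        x = T.as_tensor(x)
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}"
            )
        feats = [x]
        for layer in self.layers:
            inp = feats[0] if len(feats) == 1 else T.concat(feats, axis=1)
            feats.append(layer(inp))
        return self.project(T.concat(feats, axis=1))


class MultiScaleParallelBlock(nn.Module):
    """Parallel depth-wise branches of different kernel sizes, merged by
    summation, mixed by a pointwise convolution, with a residual path."""

    def __init__(self, cfg: MultiScaleConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.branches = nn.ModuleList(
            [nn.DepthwiseConv2d(cfg.channels, k, rng) for k in cfg.kernel_sizes]
        )
        self.mix = nn.Conv2d(cfg.channels, cfg.channels, 1, rng,
                             bias=not cfg.use_norm)
        self.post = (
            nn.Sequential(nn.BatchNorm2d(cfg.channels), nn.ReLU())
            if cfg.use_norm
            else nn.Identity()
        )

    def forward(self, x):
        x = T.as_tensor(x)
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"expected {self.cfg.channels} channels, got {x.shape[1]}"
            )
        merged = self.branches[0](x)
        for br in list(self.branches)[1:]:
            merged = merged + br(x)
        return self.post(self.mix(merged)) + x


class LargeKernelSerialBlock(nn.Module):
    """Bottleneck: pointwise expansion, sequential large-kernel depth-wise
    convolutions, pointwise projection, residual connection."""

    def __init__(self, cfg: MultiScaleConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        mid = max(1, int(round(cfg.channels * cfg.expansion)))
        self.mid_channels = mid

        def post(ch):
            return (
                nn.Sequential(nn.BatchNorm2d(ch), nn.ReLU())
                if cfg.use_norm
                else nn.Identity()
            )

        self.expand = nn.Conv2d(cfg.channels, mid, 1, rng, bias=not cfg.use_norm)
        self.expand_post = post(mid)
        self.chain = nn.ModuleList(
            [nn.DepthwiseConv2d(mid, k, rng) for k in cfg.kernel_sizes]
        )
        self.chain_post = nn.ModuleList([post(mid) for _ in cfg.kernel_sizes])
        self.project = nn.Conv2d(mid, cfg.channels, 1, rng, bias=not cfg.use_norm)

    @property
    def receptive_field(self) -> int:
        """Theoretical receptive field of the depth-wise chain."""
        return 1 + sum(k - 1 for k in self.cfg.kernel_sizes)

    def forward(self, x):
        x = T.as_tensor(x)
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"expected {self.cfg.channels} channels, got {x.shape[1]}"
            )
        y = self.expand_post(self.expand(x))
        for dw, post in zip(self.chain, self.chain_post):
            y = post(dw(y))
        return self.project(y) + x


# -- functional wrappers --------------------------------------------------


def detail_block_forward(x, block: DenseDetailBlock) -> Tensor:
    return block(x)


def multiscale_parallel_forward(x, block: MultiScaleParallelBlock) -> Tensor:
    return block(x)


def multiscale_serial_forward(x, block: LargeKernelSerialBlock) -> Tensor:
    return block(x)
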