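"""Single-level Haar wavelet analysis/synthesis and the wavelet fusion block.

The block splits a feature map into one low-frequency approximation (LL)
and three high-frequency detail bands (LH, HL, HH) at half resolution,
denoises the detail bands with a soft threshold, processes the two
frequency ranges along separate learnable pathways, and fuses them back
into a single feature map.  LL carries the coarse anatomy (the bright
femoral mass that localises the notch); LH/HL/HH carry the horizontal,
vertical and diagonal edge structure on which the notch boundary lives.

Convention
----------
The transform is *orthonormal*: for one 2x2 block [[a, b], [c, d]],

    ll = (a + b + c + d) / 2      lh = (a + b - c - d) / 2
    hl = (a - b + c - d) / 2      hh = (a - b - c + d) / 2

so the analysis step preserves energy (Parseval) and the synthesis step
is its exact inverse.  `lh` responds to variation *across rows*
(horizontal edges), `hl` to variation across columns, `hh` to diagonal
texture.  Odd spatial dimensions are reflect-padded by one pixel on the
trailing edge before analysis and cropped after synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from . import tensor as T
from .tensor import Tensor


@dataclass
class WaveletBands:
    """One level of 2D Haar coefficients, each at half resolution."""

    ll: object
    lh: object
    hl: object
    hh: object

    def __iter__(self):
        return iter((self.ll, self.lh, self.hl, self.hh))

    @property
    def shape(self):
        return self.ll.shape


@dataclass
class WaveletFusionConfig:
    """Configuration of one wavelet fusion block."""

    soft_threshold: float = 0.05
    fused_channels: int = 32
    use_norm: bool = True

    def __post_init__(self):
        if self.soft_threshold < 0:
            raise ValueError("soft_threshold must be nonnegative")


def _wrap(x):
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def haar_decompose(x) -> WaveletBands:
    """Orthonormal single-level 2D Haar analysis over the last two axes.

    Accepts a NumPy array or engine Tensor with any leading axes
    (e.g. (H, W), (C, H, W) or (N, C, H, W)); returns bands of the same
    kind at half spatial resolution.
    """
    t, is_tensor = _wrap(x)
    H, W = t.shape[-2], t.shape[-1]
    t = T.pad_reflect(t, H % 2, W % 2)
    a = t[..., 0::2, 0::2]
    b = t[..., 0::2, 1::2]
    c = t[..., 1::2, 0::2]
    d = t[..., 1::2, 1::2]
    ll = (a + b + c + d) * 0.5
    lh = (a + b - c - d) * 0.5
    hl = (a - b + c - d) * 0.5
    hh = (a - b - c + d) * 0.5
    if is_tensor:
        return WaveletBands(ll, lh, hl, hh)
    return WaveletBands(ll.data, lh.data, hl.data, hh.data)


def haar_reconstruct(bands: WaveletBands, out_shape: tuple | None = None):
    """Exact inverse of :func:`haar_decompose`.

    `out_shape` (H, W) crops the trailing edge when the original input
    had odd spatial dimensions.
    """
    parts = [_wrap(p) for p in bands]
    is_tensor = parts[0][1]
    ll, lh, hl, hh = (p[0] for p in parts)
    shapes = {p[0].shape for p in parts}
    if len(shapes) != 1:
        raise ValueError(f"wavelet bands disagree in shape: {sorted(shapes)}")
    a = (ll + lh + hl + hh) * 0.5
    b = (ll + lh - hl - hh) * 0.5
    c = (ll - lh + hl - hh) * 0.5
    d = (ll - lh - hl + hh) * 0.5
    out = _interleave(a, b, c, d)
    if out_shape is not None:
        out = out[..., : out_shape[-2], : out_shape[-1]]
    return out if is_tensor else out.data


def _interleave(a, b, c, d) -> Tensor:
    """Place four half-resolution quadrant-phase tensors back on the full
    grid (inverse of the polyphase split)."""
    lead = a.shape[:-2]
    h, w = a.shape[-2], a.shape[-1]
    # rows: stack (a|b) and (c|d) phases then interleave via transpose
    top = T.stack([a, b], axis=-1).reshape(*lead, h, 2 * w)
    bot = T.stack([c, d], axis=-1).reshape(*lead, h, 2 * w)
    full = T.stack([top, bot], axis=-2).reshape(*lead, 2 * h, 2 * w)
    return full


def soft_threshold(band, t: float):
    """Shrinkage operator sign(v) * max(|v| - t, 0), elementwise."""
    if t < 0:
        raise ValueError("soft threshold must be nonnegative")
    if isinstance(band, Tensor):
        return (band - t).relu() - (-band - t).relu()
    v = np.asarray(band, dtype=np.float64)
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


class WaveletFusionBlock(nn.Module):
    """Learnable dual-path processing and fusion of one wavelet level.

    Parameters
    ----------
    in_channels : channels of the feature map that is decomposed.
    partner_channels : channels of the encoder feature fused with LL.
    cfg : WaveletFusionConfig with the detail-band threshold and output width.
    """

    def __init__(self, in_channels: int, partner_channels: int, cfg: WaveletFusionConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        fc = cfg.fused_channels

        def unit(ci, co, k):
            if cfg.use_norm:
                return nn.conv_bn_relu(ci, co, k, rng)
            return nn.Sequential(nn.Conv2d(ci, co, k, rng), nn.ReLU())

        # high-frequency path: two 3x3 conv units on the thresholded,
        # concatenated detail bands
        self.high_conv = nn.Sequential(
            unit(3 * in_channels, fc, 3), unit(fc, fc, 3)
        )
        # low-frequency path: 1x1 projection of LL + encoder feature
        self.low_conv = unit(in_channels + partner_channels, fc, 1)
        # final high-low fusion: 1x1 compression
        self.fuse_conv = unit(2 * fc, fc, 1)

    # -- the three pathway operations ------------------------------------

    def highfreq_path(self, bands: WaveletBands) -> Tensor:
        lh = soft_threshold(T.as_tensor(bands.lh), self.cfg.soft_threshold)
        hl = soft_threshold(T.as_tensor(bands.hl), self.cfg.soft_threshold)
        hh = soft_threshold(T.as_tensor(bands.hh), self.cfg.soft_threshold)
        return self.high_conv(T.concat([lh, hl, hh], axis=1))

    def lowfreq_path(self, ll, encoder_feature) -> Tensor:
        ll = T.as_tensor(ll)
        enc = T.as_tensor(encoder_feature)
        if ll.shape[-2:] != enc.shape[-2:]:
            ll = T.resize_bilinear(ll, enc.shape[-2], enc.shape[-1])
        return self.low_conv(T.concat([ll, enc], axis=1))

    def fuse(self, fh: Tensor, fl: Tensor) -> Tensor:
        fh, fl = T.as_tensor(fh), T.as_tensor(fl)
        (Hh, Wh), (Hl, Wl) = fh.shape[-2:], fl.shape[-2:]
        if Hh < Hl or Wh < Wl:
            raise ValueError(
                f"high-frequency map {Hh}x{Wh} is smaller than the "
                f"low-frequency map {Hl}x{Wl}"
            )
        if (Hh, Wh) != (Hl, Wl):
            if Hh % Hl or Wh % Wl or Hh // Hl != Wh // Wl:
                raise ValueError(
                    f"cannot align {Hh}x{Wh} to {Hl}x{Wl} by integer pooling"
                )
            fh = T.avg_pool2d(fh, Hh // Hl)
        return self.fuse_conv(T.concat([fh, fl], axis=1))

    def forward(self, x, encoder_feature) -> Tensor:
        """Decompose `x`, run both pathways, fuse; output at half of `x`'s
        resolution (the resolution of `encoder_feature`)."""
        bands = haar_decompose(T.as_tensor(x))
        fh = self.highfreq_path(bands)
        fl = self.lowfreq_path(bands.ll, encoder_feature)
        return self.fuse(fh, fl)


# -- functional wrappers matching the operation-level contracts -----------


def highfreq_path(bands: WaveletBands, block: WaveletFusionBlock) -> Tensor:
    return block.highfreq_path(bands)


def lowfreq_path(ll, encoder_feature, block: WaveletFusionBlock) -> Tensor:
    return block.lowfreq_path(ll, encoder_feature)


def wavelet_fuse(fh, fl, block: WaveletFusionBlock) -> Tensor:
    return block.fuse(fh, fl)
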