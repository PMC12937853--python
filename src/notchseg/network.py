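"""Assembly of the wavelet multi-scale contextual attention network.

The network is a U-shaped encoder-decoder over single-channel 2D slices:

* a backbone encoder (residual CNN or hierarchical window-transformer
  family) producing features at /1, /2, /4, /8 plus a /16 bottleneck;
* the dense detail extractor at the full-resolution stage;
* wavelet fusion blocks on stages 2-4: each stage feature, concatenated
  with the pooled detail feature, is Haar-decomposed and its bands fused
  with the next-deeper encoder feature, yielding frequency-aware skip
  connections at /4, /8 and /16;
* a large-kernel serial block at the bottleneck and parallel multi-scale
  blocks in the decoder;
* an uncertainty-attention gate at each decoder fusion, driven by the
  sigmoid saliency head of the preceding (deeper) stage, with deep
  supervision on all four decoder heads.

Every component is a toggle; a disabled module is replaced by a
parameter-free identity so that each row of the component-ablation grid
is constructible, and enabling any module strictly adds parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from . import tensor as T
from .attention import AttentionGateConfig, UncertaintyAttentionGate
from .blocks import (
    DenseDetailBlock,
    LargeKernelSerialBlock,
    MultiScaleConfig,
    MultiScaleParallelBlock,
    DetailBlockConfig,
)
from .tensor import Tensor
from .wavelets import WaveletFusionBlock, WaveletFusionConfig

BACKBONES = ("residual_cnn", "window_transformer")


@dataclass
class NetworkConfig:
    backbone: str = "residual_cnn"
    stage_channels: tuple = (32, 64, 128, 256)
    use_detail: bool = True
    use_wavelet: bool = True
    use_multiscale: bool = True
    use_attention: bool = True
    n_classes: int = 2
    deep_supervision: bool = True
    input_size_px: int = 64
    detail_channels: int = 32
    soft_threshold: float = 0.05
    attention_resolution_cap: int = 4096
    multiscale_parallel_kernels: tuple = (3, 5, 7)
    multiscale_serial_kernels: tuple = (7, 9)
    multiscale_expansion: float = 2.0

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"backbone must be one of {BACKBONES}")
        if len(self.stage_channels) != 4:
            raise ValueError("stage_channels must list 4 stage widths")
        if self.input_size_px % 16:
            raise ValueError(
                f"input_size_px must be divisible by 16 (four 2x stages), "
                f"got {self.input_size_px}"
            )
        if self.n_classes not in (2, 5):
            raise ValueError("n_classes must be 2 or 5")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for k in ("stage_channels", "multiscale_parallel_kernels", "multiscale_serial_kernels"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SegOutputs:
    """Logits at input resolution plus per-decoder-stage saliency maps
    (deep-to-shallow order, values in [0, 1])."""

    logits: Tensor
    aux_saliency: list


class ResidualBlock(nn.Module):
    def __init__(self, ch: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(ch, ch, 3, rng, bias=False)
        self.bn1 = nn.BatchNorm2d(ch)
        self.conv2 = nn.Conv2d(ch, ch, 3, rng, bias=False)
        self.bn2 = nn.BatchNorm2d(ch)

    def forward(self, x):
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        return (y + x).relu()


class ResidualCNNEncoder(nn.Module):
    """Compact four-stage residual CNN (ResNet-family structure)."""

    def __init__(self, channels: tuple, rng):
        super().__init__()
        c1, c2, c3, c4 = channels
        self.stem = nn.Sequential(
            nn.conv_bn_relu(1, c1, 3, rng), ResidualBlock(c1, rng)
        )
        self.down2 = nn.Sequential(
            nn.conv_bn_relu(c1, c2, 3, rng, stride=2), ResidualBlock(c2, rng)
        )
        self.down3 = nn.Sequential(
            nn.conv_bn_relu(c2, c3, 3, rng, stride=2), ResidualBlock(c3, rng)
        )
        self.down4 = nn.Sequential(
            nn.conv_bn_relu(c3, c4, 3, rng, stride=2), ResidualBlock(c4, rng)
        )
        self.down5 = nn.Sequential(
            nn.conv_bn_relu(c4, c4, 3, rng, stride=2), ResidualBlock(c4, rng)
        )

    def forward(self, x):
        x1 = self.stem(x)
        x2 = self.down2(x1)
        x3 = self.down3(x2)
        x4 = self.down4(x3)
        x5 = self.down5(x4)
        return x1, x2, x3, x4, x5


class WindowAttentionBlock(nn.Module):
    """Pre-norm single-head window attention + MLP on an NCHW map."""

    def __init__(self, ch: int, rng, window: int = 4, mlp_ratio: int = 2):
        super().__init__()
        self.window = window
        self.norm1 = nn.LayerNorm(ch)
        self.qkv = nn.Linear(ch, 3 * ch, rng)
        self.proj = nn.Linear(ch, ch, rng)
        self.norm2 = nn.LayerNorm(ch)
        self.mlp = nn.Sequential(
            nn.Linear(ch, mlp_ratio * ch, rng),
            nn.ReLU(),
            nn.Linear(mlp_ratio * ch, ch, rng),
        )

    def _window_size(self, H, W):
        for w in (self.window, 2, 1):
            if H % w == 0 and W % w == 0:
                return w
        return 1

    def forward(self, x):
        N, C, H, W = x.shape
        w = self._window_size(H, W)
        nh, nw = H // w, W // w
        # partition into (N*nh*nw, w*w, C) token groups
        t = x.reshape(N, C, nh, w, nw, w).transpose(0, 2, 4, 3, 5, 1)
        t = t.reshape(N * nh * nw, w * w, C)

        h = self.norm1(t)
        qkv = self.qkv(h)
        q = qkv[:, :, 0:C]
        k = qkv[:, :, C : 2 * C]
        v = qkv[:, :, 2 * C : 3 * C]
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(C))
        t = t + self.proj(scores.softmax(axis=-1) @ v)
        t = t + self.mlp(self.norm2(t))

        t = t.reshape(N, nh, nw, w, w, C).transpose(0, 5, 1, 3, 2, 4)
        return t.reshape(N, C, H, W)


class PatchMerge(nn.Module):
    """2x spatial reduction by space-to-depth + pointwise projection."""

    def __init__(self, in_ch: int, out_ch: int, rng):
        super().__init__()
        self.proj = nn.Conv2d(4 * in_ch, out_ch, 1, rng)

    def forward(self, x):
        N, C, H, W = x.shape
        t = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 3, 5, 2, 4)
        return self.proj(t.reshape(N, 4 * C, H // 2, W // 2))


class WindowTransformerEncoder(nn.Module):
    """Hierarchical window-transformer encoder with patch merging."""

    def __init__(self, channels: tuple, rng):
        super().__init__()
        c1, c2, c3, c4 = channels
        self.stem = nn.conv_bn_relu(1, c1, 3, rng)
        self.merge2 = PatchMerge(c1, c2, rng)
        self.block2 = WindowAttentionBlock(c2, rng)
        self.merge3 = PatchMerge(c2, c3, rng)
        self.block3 = WindowAttentionBlock(c3, rng)
        self.merge4 = PatchMerge(c3, c4, rng)
        self.block4 = WindowAttentionBlock(c4, rng)
        self.merge5 = PatchMerge(c4, c4, rng)
        self.block5 = WindowAttentionBlock(c4, rng)

    def forward(self, x):
        x1 = self.stem(x)
        x2 = self.block2(self.merge2(x1))
        x3 = self.block3(self.merge3(x2))
        x4 = self.block4(self.merge4(x3))
        x5 = self.block5(self.merge5(x4))
        return x1, x2, x3, x4, x5


class _SaliencyHead(nn.Module):
    def __init__(self, ch: int, rng):
        super().__init__()
        self.conv = nn.Conv2d(ch, 1, 1, rng)

    def forward(self, x):
        return self.conv(x).sigmoid()


class _DecoderStage(nn.Module):
    """Skip fusion -> attention gate -> multi-scale refinement -> saliency
    head -> upsample to the next (shallower) resolution."""

    def __init__(self, in_ch, skip_ch, out_ch, cfg: NetworkConfig, rng,
                 with_head: bool):
        super().__init__()
        self.fuse = nn.conv_bn_relu(in_ch + skip_ch, in_ch, 1, rng)
        if cfg.use_attention:
            self.gate = UncertaintyAttentionGate(
                AttentionGateConfig(channels=in_ch,
                           attention_resolution_cap=cfg.attention_resolution_cap),
                rng,
            )
        else:
            self.gate = nn.Identity()
        if cfg.use_multiscale:
            self.refine = MultiScaleParallelBlock(
                MultiScaleConfig(channels=in_ch,
                           kernel_sizes=cfg.multiscale_parallel_kernels), rng
            )
        else:
            self.refine = nn.Identity()
        self.head = _SaliencyHead(in_ch, rng) if with_head else None
        self.up = nn.conv_bn_relu(in_ch, out_ch, 3, rng)
        self.use_attention = cfg.use_attention

    def forward(self, x, skip, f_m):
        f = self.fuse(T.concat([x, skip], axis=1))
        if self.use_attention:
            f = self.gate(f_m, f)
        f = self.refine(f)
        sal = self.head(f) if self.head is not None else None
        H, W = f.shape[-2:]
        out = self.up(T.resize_bilinear(f, 2 * H, 2 * W))
        return out, sal


class SegmentationNetwork(nn.Module):
    """The full wavelet multi-scale contextual attention segmenter."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator | int = 0):
        super().__init__()
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        c1, c2, c3, c4 = cfg.stage_channels
        enc_cls = (
            ResidualCNNEncoder
            if cfg.backbone == "residual_cnn"
            else WindowTransformerEncoder
        )
        self.encoder = enc_cls(cfg.stage_channels, rng)

        cd = cfg.detail_channels
        if cfg.use_detail:
            self.detail = DenseDetailBlock(
                DetailBlockConfig(in_channels=c1, out_channels=cd), rng
            )
        else:
            self.detail = None

        # skip builders at /4, /8, /16 (from stages 2, 3, 4)
        extra = cd if cfg.use_detail else 0
        partner_ch = (c3, c4, c4)
        stage_ch = (c2, c3, c4)
        if cfg.use_wavelet:
            self.wavelet_skips = nn.ModuleList(
                [
                    WaveletFusionBlock(
                        sc + extra, pc,
                        WaveletFusionConfig(soft_threshold=cfg.soft_threshold,
                                   fused_channels=pc),
                        rng,
                    )
                    for sc, pc in zip(stage_ch, partner_ch)
                ]
            )
        elif cfg.use_detail:
            # detail injection keeps the detail branch live without the
            # wavelet skip blocks
            self.detail_inject = nn.ModuleList(
                [nn.Conv2d(pc + cd, pc, 1, rng) for pc in partner_ch]
            )

        if cfg.use_multiscale:
            self.bottleneck = LargeKernelSerialBlock(
                MultiScaleConfig(channels=c4, kernel_sizes=cfg.multiscale_serial_kernels,
                           expansion=cfg.multiscale_expansion), rng
            )
        else:
            self.bottleneck = nn.Identity()

        if cfg.use_attention:
            self.bottleneck_head = _SaliencyHead(c4, rng)

        with_heads = cfg.deep_supervision or cfg.use_attention
        self.dec1 = _DecoderStage(c4, c4, c3, cfg, rng, with_heads)  # /16
        self.dec2 = _DecoderStage(c3, c4, c2, cfg, rng, with_heads)  # /8
        self.dec3 = _DecoderStage(c2, c3, c1, cfg, rng, with_heads)  # /4
        self.dec4 = _DecoderStage(
            c1, c2, c1, cfg, rng, cfg.deep_supervision
        )  # /2
        self.final = nn.Conv2d(c1, cfg.n_classes, 1, rng)

    # -- forward ----------------------------------------------------------

    def _check_input(self, x: Tensor):
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(
                f"expected a (N, 1, H, W) single-channel batch, got {x.shape}"
            )
        H, W = x.shape[-2:]
        if H % 16 or W % 16:
            raise ValueError(
                f"spatial size {H}x{W} must be divisible by 16 "
                "(four 2x downsampling stages)"
            )

    def forward(self, x) -> SegOutputs:
        x = T.as_tensor(x)
        self._check_input(x)
        cfg = self.cfg
        x1, x2, x3, x4, x5 = self.encoder(x)

        detail = self.detail(x1) if self.detail is not None else None
        stage_feats = (x2, x3, x4)
        partners = (x3, x4, x5)
        skips = []
        for i, (xs, xp) in enumerate(zip(stage_feats, partners)):
            if cfg.use_wavelet:
                inp = xs
                if detail is not None:
                    pooled = T.avg_pool2d(detail, 2 ** (i + 1))
                    inp = T.concat([xs, pooled], axis=1)
                skips.append(self.wavelet_skips[i](inp, xp))
            elif detail is not None:
                pooled = T.avg_pool2d(detail, 2 ** (i + 2))
                skips.append(
                    self.detail_inject[i](T.concat([xp, pooled], axis=1))
                )
            else:
                skips.append(xp)
        s4, s8, s16 = skips

        b = self.bottleneck(x5)
        sal = self.bottleneck_head(b) if cfg.use_attention else None
        aux = []
        d, sal1 = self.dec1(b, s16, sal)
        d, sal2 = self.dec2(d, s8, sal1 if sal1 is not None else sal)
        d, sal3 = self.dec3(d, s4, sal2 if sal2 is not None else sal)
        d, sal4 = self.dec4(d, x2, sal3 if sal3 is not None else sal)
        logits = self.final(d)
        if cfg.deep_supervision:
            aux = [sal1, sal2, sal3, sal4]
        return SegOutputs(logits=logits, aux_saliency=aux)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Eval-mode class probabilities for a (N, H, W) image stack."""
        self.eval()
        with T.no_grad():
            out = self.forward(Tensor(np.asarray(images)[:, None]))
            return out.logits.softmax(axis=1).data

    def predict_mask(self, images: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(images), axis=1)

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_network(cfg: NetworkConfig, seed: int = 0) -> SegmentationNetwork:
    return SegmentationNetwork(cfg, np.random.default_rng(seed))


def forward(net: SegmentationNetwork, images) -> SegOutputs:
    """Functional forward on a (N, 1, H, W) batch (or (N, H, W) stack)."""
    arr = np.asarray(images) if not isinstance(images, Tensor) else images
    if not isinstance(arr, Tensor) and arr.ndim == 3:
        arr = arr[:, None]
    return net(T.as_tensor(arr))


def ablation_grid(cfg: NetworkConfig) -> list:
    """The six incremental component configurations of one backbone family:
    baseline; +detail; +wavelet; +detail+wavelet; +multi-scale; +attention."""
    rows = [
        dict(use_detail=False, use_wavelet=False, use_multiscale=False, use_attention=False),
        dict(use_detail=True, use_wavelet=False, use_multiscale=False, use_attention=False),
        dict(use_detail=False, use_wavelet=True, use_multiscale=False, use_attention=False),
        dict(use_detail=True, use_wavelet=True, use_multiscale=False, use_attention=False),
        dict(use_detail=True, use_wavelet=True, use_multiscale=True, use_attention=False),
        dict(use_detail=True, use_wavelet=True, use_multiscale=True, use_attention=True),
    ]
    return [dataclasses.replace(cfg, **row) for row in rows]


# -- checkpointing --------------------------------------------------------


def save_checkpoint(net: SegmentationNetwork, path):
    """Parameters + full config; the config round-trips bit-exactly."""
    state = net.state_dict()
    np.savez_compressed(
        path, __config__=json.dumps(net.cfg.to_dict()),
        **{k: v for k, v in state.items()},
    )


def load_checkpoint(path) -> SegmentationNetwork:
    with np.load(path, allow_pickle=False) as z:
        cfg = NetworkConfig.from_dict(json.loads(str(z["__config__"])))
        net = build_network(cfg, seed=0)
        net.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
    return net.eval()
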