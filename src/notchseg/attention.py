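"""Context-weighted attention over uncertain boundary regions.

A sigmoid saliency map F_m (from the deep-supervision head of the
preceding, deeper decoder stage) is decomposed around a threshold
(default 0.5) into

    m_f = max(F_m - t, 0)        confident foreground evidence
    m_b = max(t - F_m, 0)        confident background evidence
    m_u = t - |F_m - t|          uncertainty, maximal where F_m = t

The uncertainty map is added to the upsampled saliency, the enhanced map
is concatenated with the decoder feature, and single-head scaled
dot-product attention over spatial tokens propagates semantics from
confident anatomy into the uncertain boundary band.  A residual
connection from the decoder feature keeps early training stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from . import tensor as T
from .tensor import Tensor


@dataclass
class SaliencyDecomposition:
    """Foreground / background / uncertainty maps of one saliency map."""

    m_f: object
    m_b: object
    m_u: object
    threshold: float = 0.5


@dataclass
class AttentionGateConfig:
    channels: int = 32
    threshold: float = 0.5
    attention_resolution_cap: int = 4096

    def __post_init__(self):
        if self.attention_resolution_cap < 1:
            raise ValueError("attention_resolution_cap must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


def _check_saliency(data: np.ndarray):
    if not np.all(np.isfinite(data)):
        raise ValueError("saliency map contains non-finite values")
    if data.min() < 0.0 or data.max() > 1.0:
        raise ValueError(
            "saliency values must lie in [0, 1]; apply a sigmoid to logits first"
        )


def decompose_saliency(f_m, threshold: float = 0.5) -> SaliencyDecomposition:
    """Split a [0, 1] saliency map into foreground, background and
    uncertainty evidence.  Accepts arrays or engine Tensors."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if isinstance(f_m, Tensor):
        _check_saliency(f_m.data)
        m_f = (f_m - threshold).relu()
        m_b = (threshold - f_m).relu()
        m_u = threshold - (f_m - threshold).abs()
        return SaliencyDecomposition(m_f, m_b, m_u, threshold)
    f = np.asarray(f_m, dtype=np.float64)
    _check_saliency(f)
    return SaliencyDecomposition(
        np.maximum(f - threshold, 0.0),
        np.maximum(threshold - f, 0.0),
        threshold - np.abs(f - threshold),
        threshold,
    )


def enhance_uncertain(f_m_up, m_u):
    """Add the uncertainty mask elementwise to the upsampled saliency
    feature (m_u broadcasts across a channel axis if present)."""
    a, b = f_m_up, m_u
    sa = a.shape[-2:] if hasattr(a, "shape") else np.shape(a)[-2:]
    sb = b.shape[-2:] if hasattr(b, "shape") else np.shape(b)[-2:]
    if tuple(sa) != tuple(sb):
        raise ValueError(f"spatial shapes differ: {tuple(sa)} vs {tuple(sb)}")
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        return T.as_tensor(a) + T.as_tensor(b)
    return np.asarray(a, dtype=np.float64) + np.asarray(b, dtype=np.float64)


class UncertaintyAttentionGate(nn.Module):
    """Scaled dot-product attention gated by saliency uncertainty.

    When the token count H*W exceeds `cfg.attention_resolution_cap`, the
    key and value maps are average-pooled (by powers of two) down to the
    cap; the query grid, and hence the output resolution, is unchanged.
    This is a documented memory contract, never an error.
    """

    def __init__(self, cfg: AttentionGateConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c = cfg.channels
        self.q_proj = nn.Conv2d(c + 1, c, 1, rng)
        self.k_proj = nn.Conv2d(c + 1, c, 1, rng)
        self.v_proj = nn.Conv2d(c + 1, c, 1, rng)

    def _pool_factor(self, h: int, w: int) -> int:
        p = 1
        while (h // p) * (w // p) > self.cfg.attention_resolution_cap:
            if (h // p) % 2 or (w // p) % 2:
                break
            p *= 2
        return p

    def forward(self, f_m, f_l) -> Tensor:
        f_m, f_l = T.as_tensor(f_m), T.as_tensor(f_l)
        if not (np.all(np.isfinite(f_m.data)) and np.all(np.isfinite(f_l.data))):
            raise ValueError("non-finite values in attention inputs")
        _check_saliency(f_m.data)
        N, C, H, W = f_l.shape
        f_m_up = T.resize_bilinear(f_m, H, W)
        dec = decompose_saliency(f_m_up, self.cfg.threshold)
        enhanced = enhance_uncertain(f_m_up, dec.m_u)
        fprime = T.concat([enhanced, f_l], axis=1)

        q = self.q_proj(fprime)
        k = self.k_proj(fprime)
        v = self.v_proj(fprime)
        p = self._pool_factor(H, W)
        if p > 1:
            k = T.avg_pool2d(k, p)
            v = T.avg_pool2d(v, p)
        n = H * W
        m = k.shape[-2] * k.shape[-1]
        qt = q.reshape(N, C, n).transpose(0, 2, 1)          # (N, n, C)
        kt = k.reshape(N, C, m)                              # (N, C, m)
        vt = v.reshape(N, C, m).transpose(0, 2, 1)           # (N, m, C)
        scores = (qt @ kt) * (1.0 / np.sqrt(C))
        weights = scores.softmax(axis=-1)
        out = weights @ vt                                   # (N, n, C)
        out = out.transpose(0, 2, 1).reshape(N, C, H, W)
        return out + f_l

    def attention_weights(self, f_m, f_l) -> np.ndarray:
        """Row-stochastic attention matrix, for inspection and testing."""
        f_m, f_l = T.as_tensor(f_m), T.as_tensor(f_l)
        _check_saliency(f_m.data)
        N, C, H, W = f_l.shape
        f_m_up = T.resize_bilinear(f_m, H, W)
        dec = decompose_saliency(f_m_up, self.cfg.threshold)
        fprime = T.concat([enhance_uncertain(f_m_up, dec.m_u), f_l], axis=1)
        q, k = self.q_proj(fprime), self.k_proj(fprime)
        p = self._pool_factor(H, W)
        if p > 1:
            k = T.avg_pool2d(k, p)
        n = H * W
        m = k.shape[-2] * k.shape[-1]
        qt = q.reshape(N, C, n).transpose(0, 2, 1)
        kt = k.reshape(N, C, m)
        return ((qt @ kt) * (1.0 / np.sqrt(C))).softmax(axis=-1).data


def attention_gate_forward(f_m, f_l, gate: UncertaintyAttentionGate) -> Tensor:
    return gate(f_m, f_l)
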