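"""Haar analysis/synthesis correctness and the wavelet fusion block.

The in-package transform is cross-checked against PyWavelets as an
independent oracle on random inputs.
"""

import numpy as np
import pytest
import pywt

from notchseg import tensor as T
from notchseg.tensor import Tensor
from notchseg.wavelets import (
    WaveletFusionBlock,
    WaveletFusionConfig,
    haar_decompose,
    haar_reconstruct,
    soft_threshold,
)


class TestHaarTransform:
    def test_worked_2x2_example(self):
        b = haar_decompose(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert (b.ll.item(), b.lh.item(), b.hl.item(), b.hh.item()) == (
            5.0, -2.0, -1.0, 0.0,
        )

    def test_constant_input_has_zero_detail(self):
        b = haar_decompose(np.full((2, 8, 8), 3.7))
        for band in (b.lh, b.hl, b.hh):
            np.testing.assert_allclose(band, 0.0, atol=1e-12)
        np.testing.assert_allclose(b.ll, 7.4)

    @pytest.mark.parametrize("size", [4, 8, 16, 32, 64])
    def test_roundtrip_and_parseval(self, size, rng):
        x = rng.standard_normal((3, size, size))
        b = haar_decompose(x)
        assert b.ll.shape == (3, size // 2, size // 2)
        np.testing.assert_allclose(haar_reconstruct(b), x, atol=1e-6)
        energy = sum(float((np.asarray(v) ** 2).sum()) for v in b)
        assert energy == pytest.approx(float((x**2).sum()), rel=1e-5)

    def test_matches_pywavelets(self, rng):
        x = rng.standard_normal((2, 12, 16))
        b = haar_decompose(x)
        cA, (cH, cV, cD) = pywt.dwt2(x, "haar", axes=(-2, -1))
        np.testing.assert_allclose(b.ll, cA, atol=1e-10)
        np.testing.assert_allclose(b.lh, cH, atol=1e-10)
        np.testing.assert_allclose(b.hl, cV, atol=1e-10)
        np.testing.assert_allclose(b.hh, cD, atol=1e-10)

    def test_pure_approximation_reconstructs_half_constant(self):
        c = 6.0
        b = haar_decompose(np.zeros((4, 4)))
        b.ll[...] = c
        out = haar_reconstruct(b)
        np.testing.assert_allclose(out, c / 2.0)

    def test_zero_bands_reconstruct_zero(self):
        b = haar_decompose(np.zeros((6, 6)))
        np.testing.assert_allclose(haar_reconstruct(b), 0.0)

    def test_odd_dims_reflect_pad_roundtrip(self, rng):
        x = rng.standard_normal((5, 7))
        b = haar_decompose(x)
        assert b.ll.shape == (3, 4)
        np.testing.assert_allclose(
            haar_reconstruct(b, out_shape=x.shape), x, atol=1e-10
        )

    def test_mismatched_band_shapes_rejected(self):
        b = haar_decompose(np.zeros((4, 4)))
        b.hh = np.zeros((3, 3))
        with pytest.raises(ValueError, match="shape"):
            haar_reconstruct(b)

    def test_gradient_flows_through_transform(self, rng):
        x = Tensor(rng.standard_normal((1, 1, 4, 4)), requires_grad=True)
        b = haar_decompose(x)
        (b.lh**2).sum().backward()
        assert x.grad is not None and np.isfinite(x.grad).all()


class TestSoftThreshold:
    def test_pointwise_values(self):
        assert soft_threshold(np.array(0.0), 0.3) == 0.0
        assert soft_threshold(np.array(0.10), 0.05) == pytest.approx(0.05)
        assert soft_threshold(np.array(-0.03), 0.05) == 0.0
        assert soft_threshold(np.array(-0.10), 0.05) == pytest.approx(-0.05)

    def test_zero_threshold_is_identity(self, rng):
        v = rng.standard_normal((4, 4))
        np.testing.assert_allclose(soft_threshold(v, 0.0), v)

    def test_monotone_in_threshold(self, rng):
        v = rng.standard_normal(1000)
        t1, t2 = sorted(rng.uniform(0, 1, 2))
        assert (
            np.abs(soft_threshold(v, t1)) >= np.abs(soft_threshold(v, t2)) - 1e-15
        ).all()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.zeros(3), -0.1)

    def test_tensor_and_array_paths_agree(self, rng):
        v = rng.standard_normal((3, 3))
        np.testing.assert_allclose(
            soft_threshold(Tensor(v), 0.2).data, soft_threshold(v, 0.2)
        )


def _identity_conv(conv):
    """Freeze a Conv2d to a per-channel identity (center tap 1)."""
    w = conv.weight.data
    w[...] = 0.0
    k = w.shape[-1]
    for o in range(w.shape[0]):
        w[o, o % w.shape[1], k // 2, k // 2] = 1.0
    if conv.bias is not None:
        conv.bias.data[...] = 0.0


class TestWaveletFusionBlock:
    def test_highfreq_output_channels_and_shape(self, rng):
        blk = WaveletFusionBlock(4, 6, WaveletFusionConfig(fused_channels=8), rng)
        bands = haar_decompose(Tensor(rng.standard_normal((1, 4, 8, 8))))
        out = blk.highfreq_path(bands)
        assert out.shape == (1, 8, 4, 4)

    def test_highfreq_identity_construction(self, rng):
        # frozen identity conv units on nonnegative bands reproduce the
        # thresholded concatenated details exactly
        cfg = WaveletFusionConfig(soft_threshold=0.05, fused_channels=6, use_norm=False)
        blk = WaveletFusionBlock(2, 2, cfg, rng)
        for seq in blk.high_conv.layers:
            _identity_conv(seq.layers[0])
        from notchseg.wavelets import WaveletBands

        vals = rng.uniform(0, 1, (4, 1, 2, 4, 4))
        bands = WaveletBands(*(Tensor(v) for v in vals))
        out = blk.highfreq_path(bands)
        expected = np.concatenate(
            [np.maximum(v - 0.05, 0.0) for v in vals[1:]], axis=1
        )
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_lowfreq_shape_follows_encoder_feature(self, rng):
        blk = WaveletFusionBlock(4, 6, WaveletFusionConfig(fused_channels=8), rng)
        ll = Tensor(rng.standard_normal((1, 4, 8, 8)))
        enc = Tensor(rng.standard_normal((1, 6, 8, 8)))
        assert blk.lowfreq_path(ll, enc).shape == (1, 8, 8, 8)

    def test_lowfreq_zero_inputs_zero_output(self, rng):
        cfg = WaveletFusionConfig(fused_channels=4, use_norm=False)
        blk = WaveletFusionBlock(2, 3, cfg, rng)
        blk.low_conv.layers[0].bias.data[...] = 0.0
        out = blk.lowfreq_path(Tensor(np.zeros((1, 2, 4, 4))),
                               Tensor(np.zeros((1, 3, 4, 4))))
        np.testing.assert_allclose(out.data, 0.0)

    def test_fuse_aligns_and_is_nonnegative(self, rng):
        blk = WaveletFusionBlock(4, 6, WaveletFusionConfig(fused_channels=8), rng)
        fh = Tensor(rng.standard_normal((1, 8, 16, 16)))
        fl = Tensor(rng.standard_normal((1, 8, 8, 8)))
        out = blk.fuse(fh, fl)
        assert out.shape == (1, 8, 8, 8)
        assert out.data.min() >= 0.0

    def test_fuse_rejects_smaller_high_map(self, rng):
        blk = WaveletFusionBlock(4, 6, WaveletFusionConfig(fused_channels=8), rng)
        with pytest.raises(ValueError, match="smaller"):
            blk.fuse(Tensor(np.zeros((1, 8, 4, 4))),
                     Tensor(np.zeros((1, 8, 8, 8))))

    def test_fuse_average_kernel_equals_channel_mean(self, rng):
        cfg = WaveletFusionConfig(fused_channels=1, use_norm=False)
        blk = WaveletFusionBlock(1, 1, cfg, rng)
        conv = blk.fuse_conv.layers[0]
        conv.weight.data[...] = 1.0 / 2.0  # average of the 2 concat channels
        conv.bias.data[...] = 0.0
        fh = Tensor(rng.standard_normal((1, 1, 4, 4)))
        fl = Tensor(rng.standard_normal((1, 1, 4, 4)))
        out = blk.fuse(fh, fl)
        expected = np.maximum((fh.data + fl.data) / 2.0, 0.0)
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_forward_halves_resolution(self, rng):
        blk = WaveletFusionBlock(4, 6, WaveletFusionConfig(fused_channels=8), rng)
        x = Tensor(rng.standard_normal((2, 4, 16, 16)))
        enc = Tensor(rng.standard_normal((2, 6, 8, 8)))
        assert blk(x, enc).shape == (2, 8, 8, 8)
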