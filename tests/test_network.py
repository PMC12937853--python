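"""Network assembly: ablation grid, shape contracts, gradient coverage,
module liveness and checkpoint round trips."""

import dataclasses

import numpy as np
import pytest

from notchseg import nn
from notchseg import tensor as T
from notchseg.network import (
    NetworkConfig,
    ablation_grid,
    build_network,
    load_checkpoint,
    save_checkpoint,
)
from notchseg.phantom import PhantomConfig, generate_notch_phantom
from notchseg.tensor import Tensor
from notchseg.train import TrainConfig, training_loss


class TestConfig:
    def test_divisibility_rule_enforced(self):
        with pytest.raises(ValueError, match="divisible by 16"):
            NetworkConfig(input_size_px=60)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="backbone"):
            NetworkConfig(backbone="vgg")

    def test_roundtrips_through_dict(self, small_net_cfg):
        d = small_net_cfg.to_dict()
        assert NetworkConfig.from_dict(d) == small_net_cfg


class TestAblationGrid:
    def test_six_rows_baseline_to_full(self, small_net_cfg):
        grid = ablation_grid(small_net_cfg)
        assert len(grid) == 6
        first, last = grid[0], grid[-1]
        assert not any(
            [first.use_detail, first.use_wavelet, first.use_multiscale, first.use_attention]
        )
        assert all(
            [last.use_detail, last.use_wavelet, last.use_multiscale, last.use_attention]
        )

    def test_incremental_component_order(self, small_net_cfg):
        toggles = [
            (c.use_detail, c.use_wavelet, c.use_multiscale, c.use_attention)
            for c in ablation_grid(small_net_cfg)
        ]
        assert toggles == [
            (False, False, False, False),
            (True, False, False, False),
            (False, True, False, False),
            (True, True, False, False),
            (True, True, True, False),
            (True, True, True, True),
        ]


class TestForward:
    def test_baseline_plain_encoder_decoder_runs(self, small_net_cfg, rng):
        cfg = dataclasses.replace(
            small_net_cfg, use_detail=False, use_wavelet=False, use_multiscale=False,
            use_attention=False,
        )
        net = build_network(cfg, seed=0)
        out = net(Tensor(rng.random((1, 1, 64, 64))))
        assert out.logits.shape == (1, 2, 64, 64)

    def test_logit_shape_and_aux_maps(self, small_net_cfg, rng):
        net = build_network(small_net_cfg, seed=0)
        out = net(Tensor(rng.random((2, 1, 64, 64))))
        assert out.logits.shape == (2, 2, 64, 64)
        assert [a.shape[-1] for a in out.aux_saliency] == [4, 8, 16, 32]
        for a in out.aux_saliency:
            assert a.data.min() >= 0.0 and a.data.max() <= 1.0

    def test_bad_input_size_names_divisibility(self, small_net_cfg, rng):
        net = build_network(small_net_cfg, seed=0)
        with pytest.raises(ValueError, match="divisible by 16"):
            net(Tensor(rng.random((1, 1, 60, 60))))

    def test_eval_mode_is_deterministic(self, small_net_cfg, rng):
        net = build_network(small_net_cfg, seed=0).eval()
        x = rng.random((1, 1, 64, 64))
        with T.no_grad():
            a = net(Tensor(x)).logits.data
            b = net(Tensor(x)).logits.data
        np.testing.assert_array_equal(a, b)

    def test_param_count_grows_with_each_toggle(self, small_net_cfg):
        base = dataclasses.replace(
            small_net_cfg, use_detail=False, use_wavelet=False, use_multiscale=False,
            use_attention=False,
        )
        n_off = build_network(base, seed=0).parameter_count()
        for toggle in ("use_detail", "use_wavelet", "use_multiscale", "use_attention"):
            cfg = dataclasses.replace(base, **{toggle: True})
            assert build_network(cfg, seed=0).parameter_count() > n_off
        n_on = build_network(
            dataclasses.replace(base, use_detail=True, use_wavelet=True,
                                use_multiscale=True, use_attention=True),
            seed=0,
        ).parameter_count()
        assert n_on > n_off

    def test_each_toggle_changes_the_output(self, small_net_cfg, rng):
        x = Tensor(rng.random((1, 1, 64, 64)))
        ref = build_network(small_net_cfg, seed=0).eval()
        with T.no_grad():
            base_out = ref(x).logits.data
        for toggle in ("use_detail", "use_wavelet", "use_multiscale", "use_attention"):
            cfg = dataclasses.replace(small_net_cfg, **{toggle: False})
            net = build_network(cfg, seed=0).eval()
            with T.no_grad():
                out = net(x).logits.data
            assert not np.allclose(out, base_out), toggle


class TestTrainability:
    def test_every_parameter_receives_gradient(self, small_net_cfg, rng):
        net = build_network(small_net_cfg, seed=0)
        X = rng.random((2, 64, 64))
        y = (rng.random((2, 64, 64)) > 0.9).astype(np.int64)
        loss, _ = training_loss(net, X, y, TrainConfig(network=small_net_cfg))
        loss.backward()
        dead = [n for n, p in net.named_parameters() if p.grad is None]
        assert dead == []

    def test_all_ablation_rows_train_three_steps(self, small_net_cfg):
        """Every component configuration optimises 3 steps on 4 phantoms
        with finite loss (both backbone families via the grid test below
        cover building; here the CNN family trains)."""
        pcfg = PhantomConfig(image_size_px=32, pixel_spacing_mm=2.0)
        samples = [generate_notch_phantom(pcfg, s) for s in range(4)]
        X = np.stack([s.image for s in samples])
        y = np.stack([s.mask.astype(np.int64) for s in samples])
        small = dataclasses.replace(
            small_net_cfg, stage_channels=(4, 8, 8, 8), detail_channels=4,
            input_size_px=32,
        )
        tcfg = TrainConfig(network=small)
        for cfg in ablation_grid(small):
            net = build_network(cfg, seed=1)
            opt = nn.AdamW(net.parameters(), lr=1e-3)
            for _ in range(3):
                loss, _ = training_loss(net, X, y, dataclasses.replace(
                    tcfg, network=cfg))
                assert np.isfinite(float(loss.data))
                opt.zero_grad()
                loss.backward()
                opt.step()

    def test_repeated_steps_reduce_training_loss(self, small_net_cfg, rng):
        pcfg = PhantomConfig(image_size_px=32, pixel_spacing_mm=2.0)
        s = generate_notch_phantom(pcfg, 3)
        X, y = s.image[None], s.mask.astype(np.int64)[None]
        cfg = dataclasses.replace(
            small_net_cfg, stage_channels=(4, 8, 8, 8), detail_channels=4,
            input_size_px=32,
        )
        net = build_network(cfg, seed=0)
        opt = nn.AdamW(net.parameters(), lr=3e-3)
        tcfg = TrainConfig(network=cfg)
        first = None
        for _ in range(10):
            loss, _ = training_loss(net, X, y, tcfg)
            if first is None:
                first = float(loss.data)
            opt.zero_grad()
            loss.backward()
            opt.step()
        final, _ = training_loss(net, X, y, tcfg)
        assert float(final.data) < first


class TestCheckpoint:
    def test_roundtrip_preserves_outputs_and_config(self, tmp_path, rng):
        cfg = NetworkConfig(stage_channels=(4, 8, 8, 8), detail_channels=4,
                            input_size_px=32, attention_resolution_cap=64)
        net = build_network(cfg, seed=3).eval()
        x = rng.random((1, 1, 32, 32))
        with T.no_grad():
            want = net(Tensor(x)).logits.data
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, path)
        net2 = load_checkpoint(path)
        assert net2.cfg == cfg
        with T.no_grad():
            got = net2(Tensor(x)).logits.data
        np.testing.assert_array_equal(want, got)
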