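"""LS-Net, the C2R/R2C adapters, and the fused classifier."""

import numpy as np
import pytest

from hafusenet.models import C2R, R2C, HAFuseNet, LSNet, LsnetConfig, build_variant
from hafusenet.models.fusenet import VARIANTS
from hafusenet.nn import Tensor
from tests.conftest import tiny_model_config


def _x(rng, n=2, c=5, t=12):
    return Tensor(rng.standard_normal((n, c, t)).astype(np.float32))


class TestLSNet:
    def test_output_shape_h_by_t(self, rng):
        net = LSNet(5, LsnetConfig(n_layers=2, hidden=7), rng)
        assert net(_x(rng)).shape == (2, 7, 12)

    def test_single_layer_equals_lstm_then_scot(self, rng):
        cfg = LsnetConfig(n_layers=1, hidden=4)
        net = LSNet(5, cfg, rng)
        x = _x(rng)
        hs = net.layers[0](x.transpose(0, 2, 1))
        y = hs.transpose(0, 2, 1)
        expected = net.scots[0](y.reshape(2, 1, 4, 12)).reshape(2, 4, 12).data
        np.testing.assert_allclose(net(x).data, expected, rtol=1e-6)

    def test_zero_input_matches_hand_unrolled_recurrence(self, rng):
        """T=3, H=2 zero-input trajectory traced step by step by hand."""
        cfg = LsnetConfig(n_layers=1, hidden=2, use_scot=False)
        net = LSNet(3, cfg, rng)
        x = Tensor(np.zeros((1, 3, 3), dtype=np.float32))
        out = net(x).data[0]  # (H=2, T=3)
        wx, wh, b = (net.layers[0].wx.data, net.layers[0].wh.data, net.layers[0].b.data)

        def sig(z):
            return 1.0 / (1.0 + np.exp(-z))

        h = np.zeros(2)
        c = np.zeros(2)
        H = 2
        for t in range(3):
            z = h @ wh + b  # zero input contributes nothing
            c = sig(z[H : 2 * H]) * c + sig(z[:H]) * np.tanh(z[2 * H : 3 * H])
            h = sig(z[3 * H :]) * np.tanh(c)
            np.testing.assert_allclose(out[:, t], h, rtol=1e-5, atol=1e-6)

    def test_scot_toggle_changes_output(self, rng):
        x = _x(rng)
        on = LSNet(5, LsnetConfig(n_layers=1, hidden=4, use_scot=True), np.random.default_rng(3))
        off = LSNet(5, LsnetConfig(n_layers=1, hidden=4, use_scot=False), np.random.default_rng(3))
        assert not np.allclose(on(x).data, off(x).data)

    def test_time_pool_shortens_sequence(self, rng):
        net = LSNet(5, LsnetConfig(n_layers=1, hidden=4, time_pool=3), rng)
        assert net(_x(rng, t=12)).shape == (2, 4, 4)


class TestAdapters:
    def test_c2r_shape_contract(self, rng):
        mod = C2R(8, 22, 16, rng)
        f = Tensor(rng.standard_normal((1, 8, 22, 30)).astype(np.float32))
        assert mod(f).shape == (1, 16, 30)

    def test_c2r_identity_projection_reproduces_flattened_input(self, rng):
        mod = C2R(2, 3, 6, rng, bias=False)
        mod.proj.w.data = np.eye(6, dtype=np.float32)
        f = Tensor(rng.standard_normal((1, 2, 3, 4)).astype(np.float32))
        np.testing.assert_allclose(mod(f).data[0], f.data[0].reshape(6, 4), rtol=1e-6)

    def test_r2c_shape_contract(self, rng):
        mod = R2C(16, 4, 5, rng)
        s = Tensor(rng.standard_normal((2, 16, 30)).astype(np.float32))
        assert mod(s).shape == (2, 4, 5, 30)

    def test_r2c_zero_input_zero_output_biasfree(self, rng):
        mod = R2C(6, 2, 3, rng, bias=False)
        out = mod(Tensor(np.zeros((1, 6, 4), dtype=np.float32)))
        assert (out.data == 0).all()

    def test_pseudoinverse_round_trip_reconstructs(self, rng):
        """r2c with the pseudo-inverse of c2r's matrix inverts it when H >= D*C."""
        c2r = C2R(2, 3, 8, rng, bias=False)  # D*C = 6 <= H = 8
        r2c = R2C(8, 2, 3, rng, bias=False)
        r2c.proj.w.data = np.linalg.pinv(c2r.proj.w.data).astype(np.float32)
        f = Tensor(rng.standard_normal((1, 2, 3, 5)).astype(np.float32))
        np.testing.assert_allclose(r2c(c2r(f)).data, f.data, rtol=1e-3, atol=1e-4)

    def test_round_trip_shape(self, rng):
        c2r = C2R(3, 4, 6, rng)
        r2c = R2C(6, 3, 4, rng)
        f = Tensor(rng.standard_normal((2, 3, 4, 10)).astype(np.float32))
        assert r2c(c2r(f)).shape == f.shape


class TestFusion:
    def test_probabilities_valid(self, rng, tiny_cfg):
        model = HAFuseNet(tiny_cfg, rng=rng).eval()
        x = _x(rng, n=3, c=6, t=64)
        p = model(x).data
        assert p.shape == (3, 4)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_fused_depth_is_sum_of_branch_depths(self, rng, tiny_cfg):
        model = HAFuseNet(tiny_cfg, rng=rng)
        assert model.fuse_dw.w.shape[0] == model.disnet.feature_depth + tiny_cfg.fusion.target_depth

    def test_zeroed_ls_projection_equals_dis_only_head(self, rng, tiny_cfg):
        """Zero R2C -> output equals the fused head on (dis features, zero map)."""
        model = HAFuseNet(tiny_cfg, rng=rng).eval()
        model.r2c.proj.w.data[:] = 0.0
        model.r2c.proj.b.data[:] = 0.0
        x = _x(rng, n=2, c=6, t=64)
        mid, dis_f = model.disnet.features(x)
        zero_ls = Tensor(np.zeros((2, tiny_cfg.lsnet.hidden, 64 // tiny_cfg.lsnet.time_pool), dtype=np.float32))
        expected = model.fuse_and_classify(dis_f, zero_ls).data
        np.testing.assert_allclose(model(x).data, expected, rtol=1e-5, atol=1e-6)

    def test_eval_mode_determinism(self, rng, tiny_cfg):
        model = HAFuseNet(tiny_cfg, rng=rng).eval()
        x = _x(rng, n=2, c=6, t=64)
        assert (model(x).data == model(x).data).all()

    def test_c2r_input_mode_runs(self, rng):
        cfg = tiny_model_config()
        cfg.lsnet.input_mode = "c2r"
        model = HAFuseNet(cfg, rng=rng).eval()
        p = model(_x(rng, n=2, c=6, t=64)).data
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)


class TestAblationVariants:
    def test_all_six_variants_constructible_and_runnable(self, rng):
        x = _x(rng, n=2, c=6, t=64)
        for name in VARIANTS:
            model = build_variant(name, base=tiny_model_config(), rng=np.random.default_rng(0)).eval()
            p = model(x).data
            assert p.shape == (2, 4), name
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_scot_ablation_changes_output(self, rng):
        x = _x(rng, n=2, c=6, t=64)
        a = build_variant("dis_lstm", base=tiny_model_config(), rng=np.random.default_rng(0)).eval()
        b = build_variant("dis_lstm_scot", base=tiny_model_config(), rng=np.random.default_rng(0)).eval()
        assert not np.allclose(a(x).data, b(x).data)

    def test_gradients_flow_to_both_branches(self, rng, tiny_cfg):
        model = HAFuseNet(tiny_cfg, rng=rng)
        x = _x(rng, n=4, c=6, t=64)
        loss = (model(x) ** 2).sum()
        loss.backward()
        dis_norm = sum(np.linalg.norm(p.grad) for _, p in model.disnet.named_parameters() if p.grad is not None)
        ls_norm = sum(np.linalg.norm(p.grad) for _, p in model.lsnet.named_parameters() if p.grad is not None)
        assert dis_norm > 0 and ls_norm > 0


class TestCheckpoints:
    def test_round_trip_restores_identical_predictions(self, rng, tiny_cfg, tmp_path):
        from hafusenet.models import load_checkpoint, save_checkpoint

        cfg = tiny_cfg
        cfg.disnet.variant = "sg"  # exercises batch-norm running-stat buffers
        model = HAFuseNet(cfg, rng=rng)
        x = Tensor(rng.standard_normal((2, 6, 64)).astype(np.float32))
        model.train()
        model(x)  # update running stats
        model.eval()
        ref = model(x).data
        path = tmp_path / "model.npz"
        h = save_checkpoint(model, path, seed=7)
        restored = load_checkpoint(path)
        np.testing.assert_array_equal(restored(x).data, ref)
        from hafusenet.models import content_hash

        assert content_hash(restored) == h

    def test_tampered_checkpoint_rejected(self, rng, tiny_cfg, tmp_path):
        from hafusenet.models import load_checkpoint, save_checkpoint

        model = HAFuseNet(tiny_cfg, rng=rng)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        import numpy as _np

        with _np.load(path) as arc:
            data = {k: arc[k] for k in arc.files}
        key = next(k for k in data if k.startswith("param/") and data[k].size > 0)
        data[key] = data[key] + 1.0
        _np.savez(path, **data)
        with pytest.raises(ValueError, match="hash"):
            load_checkpoint(path)
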