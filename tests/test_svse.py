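"""svSE hybrid attention: weight-map contracts and composition oracles."""

import numpy as np
import pytest

from hafusenet.attention import SvSE
from hafusenet.nn import Tensor


@pytest.fixture
def svse(rng):
    return SvSE(depth=4, n_channels=3, rng=rng)


def _x(rng, d=4, c=3, t=5, n=2):
    return Tensor(rng.standard_normal((n, d, c, t)).astype(np.float32))


class TestChannelExcitation:
    def test_output_shape(self, rng):
        mod = SvSE(depth=8, n_channels=22, rng=rng)
        x = Tensor(rng.standard_normal((1, 8, 22, 750)).astype(np.float32))
        assert mod.cse_weights(x).shape == (1, 8, 1, 1)

    def test_weights_sum_to_one_over_depth(self, svse, rng):
        att = svse.cse_weights(_x(rng)).data
        np.testing.assert_allclose(att.sum(axis=1), 1.0, atol=1e-6)

    def test_depth_constant_input_gives_uniform_weights(self, svse):
        x = Tensor(np.broadcast_to(np.arange(15.0).reshape(1, 1, 3, 5), (1, 4, 3, 5)).copy())
        np.testing.assert_allclose(svse.cse_weights(x).data, 0.25, atol=1e-6)

    def test_identity_excitation_ranks_by_max(self, rng):
        """With the MLP frozen to identity, the largest-max map wins (3x2x2)."""
        mod = SvSE(depth=3, n_channels=2, rng=rng, reduction=1)
        h = mod.fc_reduce.w.data.shape[1]
        mod.fc_reduce.w.data = np.eye(1, h, dtype=np.float32) * 2.0  # bypass gelu curvature
        mod.fc_reduce.b.data[:] = 0
        mod.fc_expand.w.data = np.eye(h, 1, dtype=np.float32)
        mod.fc_expand.b.data[:] = 0
        x = np.zeros((1, 3, 2, 2), dtype=np.float32)
        x[0, 0] = [[0.1, 0.2], [0.0, 0.1]]
        x[0, 1] = [[1.5, 0.2], [0.3, 0.1]]  # largest max
        x[0, 2] = [[0.4, 0.9], [0.2, 0.5]]
        att = mod.cse_weights(Tensor(x)).data.ravel()
        # brute-force ranking of per-map maxima
        order = np.argsort([x[0, i].max() for i in range(3)])
        assert att.argmax() == order[-1] == 1

    def test_reduction_fallback_warns(self, rng, caplog):
        with caplog.at_level("WARNING"):
            SvSE(depth=1, n_channels=2, rng=rng, reduction=4)
        assert "falling back" in caplog.text


class TestVarianceBranch:
    def test_output_shape(self, svse, rng):
        assert svse.variance_weights(_x(rng)).shape == (2, 1, 3, 5)

    def test_depth_constant_input_has_zero_variance_plane(self, rng):
        mod = SvSE(depth=4, n_channels=3, rng=rng)
        base = rng.standard_normal((1, 1, 3, 5)).astype(np.float32)
        x = Tensor(np.broadcast_to(base, (1, 4, 3, 5)).copy())
        var = x.var(axis=1).data
        np.testing.assert_allclose(var, 0.0, atol=1e-7)

    def test_preactivation_equals_bruteforce_variance(self, rng):
        """1x1 conv fixed to select the variance plane reproduces np.var (4x3x5)."""
        mod = SvSE(depth=4, n_channels=3, rng=rng)
        mod.var_conv.w.data = np.array([[[0.0], [1.0]]], dtype=np.float32)
        mod.var_conv.b.data[:] = 0.0
        x = rng.standard_normal((2, 4, 3, 5)).astype(np.float32)
        xt = Tensor(x)
        mu = xt.mean(axis=1, keepdims=True)
        from hafusenet.nn import concat

        pooled = concat([mu, xt.var(axis=1, keepdims=True)], axis=1)
        pre = mod.var_conv(pooled).data
        np.testing.assert_allclose(pre[:, 0], x.var(axis=1), rtol=1e-4, atol=1e-5)

    def test_weights_sum_to_one_over_positions(self, svse, rng):
        att = svse.variance_weights(_x(rng)).data
        np.testing.assert_allclose(att.sum(axis=(2, 3)), 1.0, atol=1e-6)


class TestAxialBranch:
    def test_output_shape(self, svse, rng):
        assert svse.axial_weights(_x(rng)).shape == (2, 1, 3, 5)

    def test_outer_product_structure(self, rng):
        """att_s[c, t] = x_s[c] * x_t[t] exactly (C=3, T=4 brute force)."""
        mod = SvSE(depth=2, n_channels=3, rng=rng)
        x = _x(rng, d=2, c=3, t=4, n=1)
        att = mod.axial_weights(x).data[0, 0]
        x_sf = mod.sf_conv(x)
        from hafusenet.nn import concat

        pools = concat([x_sf.mean(axis=3, keepdims=True), x_sf.max(axis=3, keepdims=True)], axis=1)
        xs = mod.spool_conv(pools).softmax(axis=2).data[0, 0, :, 0]
        xt = mod.time_conv(x_sf).softmax(axis=3).data[0, 0, 0, :]
        np.testing.assert_allclose(att, np.outer(xs, xt), rtol=1e-6)

    def test_rank_one_for_random_inputs(self, rng):
        svse = SvSE(depth=4, n_channels=6, rng=rng)
        att = svse.axial_weights(_x(rng, c=6, t=9)).data
        for mat in att[:, 0]:
            s = np.linalg.svd(mat, compute_uv=False)
            assert s[1] < 1e-6 * max(s[0], 1e-12)

    def test_unit_left_factor_replicates_time_weights(self, rng):
        """If the electrode factor is uniform, every row of att_s equals x_t / C."""
        mod = SvSE(depth=2, n_channels=3, rng=rng)
        mod.spool_conv.w.data[:] = 0.0  # softmax of zeros -> uniform rows
        mod.spool_conv.b.data[:] = 0.0
        x = _x(rng, d=2, c=3, t=4, n=1)
        att = mod.axial_weights(x).data[0, 0]
        np.testing.assert_allclose(att[0], att[1], rtol=1e-6)
        np.testing.assert_allclose(att[1], att[2], rtol=1e-6)

    def test_weights_sum_to_one_over_positions(self, svse, rng):
        att = svse.axial_weights(_x(rng)).data
        np.testing.assert_allclose(att.sum(axis=(2, 3)), 1.0, atol=1e-6)


class TestApply:
    def test_zero_input_gives_zero_output(self, svse):
        out = svse(Tensor(np.zeros((1, 4, 3, 5), dtype=np.float32)))
        assert (out.data == 0).all()

    def test_shape_preserved(self, svse, rng):
        x = _x(rng)
        assert svse(x).shape == x.shape

    def test_equals_hand_chained_branches(self, rng):
        """Full forward equals the hand-chained three-branch gating (2x3x4)."""
        mod = SvSE(depth=2, n_channels=3, rng=rng)
        x = _x(rng, d=2, c=3, t=4, n=2)
        att_c = mod.cse_weights(x).data
        att_c = att_c / att_c.max(axis=1, keepdims=True)  # peak-1 gate
        att_vs = mod.variance_weights(x).data + mod.axial_weights(x).data
        att_vs = att_vs / att_vs.max(axis=(2, 3), keepdims=True)
        expected = att_vs * x.data + att_c * x.data
        np.testing.assert_allclose(mod(x).data, expected, rtol=1e-5, atol=1e-6)

    def test_residual_flag_adds_input(self, rng):
        plain = SvSE(depth=2, n_channels=3, rng=np.random.default_rng(0))
        res = SvSE(depth=2, n_channels=3, rng=np.random.default_rng(0), residual=True)
        x = _x(rng, d=2, c=3, t=4, n=1)
        np.testing.assert_allclose(res(x).data, plain(x).data + x.data, rtol=1e-6)

    def test_doubling_input_bounded_amplification(self, rng):
        """2x input with frozen weight nets scales the output by a factor in [1, 4]."""
        mod = SvSE(depth=3, n_channels=4, rng=rng)
        x = _x(rng, d=3, c=4, t=6, n=1)
        base = np.abs(mod(x).data).sum()
        doubled = np.abs(mod(x * 2.0).data).sum()
        assert 1.0 <= doubled / base <= 4.0 + 1e-6
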