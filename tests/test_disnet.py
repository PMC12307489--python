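"""DIS-Net backbone: shape contracts, parameter counts, ablation family."""

import numpy as np
import pytest

from hafusenet.models import DisnetConfig, DISNet, InvertedBottleneck, MultiscaleDenseBlock
from hafusenet.models.disnet import InvertedBottleneck
from hafusenet.nn import Tensor, count_parameters


def _cfg(**kw):
    base = dict(
        n_channels=6, n_times=64, stem_depth=4, stem_kernel=5,
        bottleneck_expansion=2, bottleneck_kernel=5, branch_kernels=(3, 5),
        branch_depth=2, pool_size=16, dropout=0.0,
    )
    base.update(kw)
    return DisnetConfig(**base)


class TestInvertedBottleneck:
    def test_depth_expands_and_projects_back(self, rng):
        mod = InvertedBottleneck(8, 4, 25, rng)
        x = Tensor(rng.standard_normal((1, 8, 3, 40)).astype(np.float32))
        assert mod.expand.w.shape[0] == 32  # intermediate depth 8 * 4
        assert mod(x).shape == (1, 8, 3, 40)

    def test_channels_and_time_preserved(self, rng):
        mod = InvertedBottleneck(4, 2, 9, rng)
        x = Tensor(rng.standard_normal((2, 4, 22, 100)).astype(np.float32))
        assert mod(x).shape == x.shape

    def test_parameter_count_closed_form(self, rng):
        d, e, k = 8, 4, 25
        mod = InvertedBottleneck(d, e, k, rng)
        mid = d * e
        expected = (d * mid + mid) + (mid * k + mid) + (mid * d + d)
        assert count_parameters(mod) == expected


class TestMultiscaleDenseBlock:
    def test_dense_concatenation_arithmetic(self, rng):
        cfg = _cfg(branch_kernels=(3, 5, 7, 9), branch_depth=8, stem_depth=8)
        block = MultiscaleDenseBlock(8, cfg, rng)
        x = Tensor(rng.standard_normal((1, 8, 6, 64)).astype(np.float32))
        assert block(x).shape == (1, 40, 6, 64)  # 4 branches x 8 + input 8

    def test_skipless_block_concatenates_branches_only(self, rng):
        cfg = _cfg(dense_skip=False)
        block = MultiscaleDenseBlock(4, cfg, rng)
        x = Tensor(rng.standard_normal((1, 4, 6, 64)).astype(np.float32))
        assert block(x).shape == (1, 4, 6, 64)  # 2 branches x 2

    def test_zero_input_zero_output_with_biasfree_branches(self, rng):
        cfg = _cfg()
        block = MultiscaleDenseBlock(4, cfg, rng)
        for br in block.branches:
            br.b.data[:] = 0.0
        x = Tensor(np.zeros((1, 4, 6, 64), dtype=np.float32))
        assert (block(x).data == 0).all()


class TestSpatialConv:
    def test_collapses_channel_axis(self, rng):
        model = DISNet(_cfg(), rng)
        x = Tensor(rng.standard_normal((2, 6, 64)).astype(np.float32))
        _, feats = model.features(x)
        assert feats.shape[2] == 1
        assert feats.shape[3] == 64  # T preserved until the head pool

    def test_separable_cheaper_than_full_spatial_temporal_conv(self, rng):
        d, c, k = 40, 22, 15
        model_params = d * c + d + d * d + d  # depthwise C kernel + pointwise
        full_params = d * (d * c * k) + d
        assert model_params < full_params

    def test_channel_mismatch_raises(self, rng):
        model = DISNet(_cfg(), rng)
        x = Tensor(rng.standard_normal((1, 5, 64)).astype(np.float32))
        with pytest.raises(ValueError, match="channels"):
            model.features(x)


class TestForward:
    def test_logits_shape_and_softmax(self, rng):
        model = DISNet(_cfg(), rng)
        x = Tensor(rng.standard_normal((3, 6, 64)).astype(np.float32))
        feats, logits = model(x)
        assert logits.shape == (3, 4)
        probs = logits.softmax(axis=1).data
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert feats.shape == (3, model.feature_depth, 1, 64)

    def test_every_stage_preserves_time_axis(self, rng):
        cfg = _cfg()
        model = DISNet(cfg, rng)
        x = Tensor(rng.standard_normal((1, 6, 64)).astype(np.float32))
        mid, feats = model.features(x)
        assert mid.shape[3] == feats.shape[3] == 64

    def test_eval_mode_forward_is_deterministic(self, rng):
        model = DISNet(_cfg(dropout=0.25), rng).eval()
        x = Tensor(rng.standard_normal((2, 6, 64)).astype(np.float32))
        _, a = model(x)
        _, b = model(x)
        assert (a.data == b.data).all()

    def test_receptive_field_grows_with_blocks(self, rng):
        rfs = [
            DISNet(_cfg(n_dense_blocks=n), rng).temporal_receptive_field()
            for n in (1, 2, 3)
        ]
        assert rfs[0] < rfs[1] < rfs[2]


class TestAblationFamily:
    def test_variant_switches_change_structure(self, rng):
        base = DISNet(_cfg(), rng)
        plain = DISNet(_cfg(use_bottleneck=False, dense_skip=False, use_svse=False,
                            n_dense_blocks=3), rng)
        assert base.bottleneck is not None and plain.bottleneck is None
        assert len(plain.blocks) == 3
        assert plain.block_svse == [] and plain.final_svse is None

    def test_feature_depth_property_matches_built_model(self, rng):
        for kw in ({}, {"dense_skip": False}, {"n_dense_blocks": 3}):
            cfg = _cfg(**kw)
            assert DISNet(cfg, rng).feature_depth == cfg.feature_depth


def test_even_branch_kernel_rejected():
    with pytest.raises(ValueError, match="odd"):
        _cfg(branch_kernels=(4, 5))
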