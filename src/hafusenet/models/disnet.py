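"""DIS-Net: the convolutional branch of the fusion classifier.

Pipeline: stem temporal convolution (raw trials enter as a 1 x C x T
map) -> inverted bottleneck -> [multi-scale dense block -> svSE] x 2 ->
axial depthwise-separable spatial convolution -> svSE -> temporal
pooling -> flatten -> linear head.  Branch kernels of the multi-scale
blocks are sized in samples relative to the sampling rate (the 25-sample
anchor spans 100 ms at 250 Hz, one mu cycle); the dense skip
concatenates each block's input with its branch outputs so deep layers
see shallow features.  Every stage preserves the time axis — only the
final pooling reduces temporal resolution.

The configuration switches reproduce the ablation family: plain
Inception stacking (no bottleneck, no dense skip, no svSE), adding the
bottleneck, adding dense skips, and adding svSE give the four
CNN-only model variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..nn import (
    BatchNorm,
    ChannelCollapseConv,
    DepthwiseTemporalConv,
    Dropout,
    Linear,
    Module,
    TemporalConv,
    Tensor,
    concat,
)
from ..nn import functional as F
from ..attention import SvSE
from .sg import SGModule, SgConfig

__all__ = ["DisnetConfig", "InvertedBottleneck", "MultiscaleDenseBlock", "DISNet"]


@dataclass
class DisnetConfig:
    n_channels: int = 22
    n_times: int = 750  # 3 s at 250 Hz
    stem_depth: int = 8
    stem_kernel: int = 15
    use_bottleneck: bool = True
    bottleneck_expansion: int = 4
    bottleneck_kernel: int = 25
    branch_kernels: tuple[int, ...] = (15, 25, 51, 65)  # 60-260 ms at 250 Hz
    branch_depth: int = 8
    n_dense_blocks: int = 2
    dense_skip: bool = True
    use_svse: bool = True
    svse_reduction: int = 2
    svse_residual: bool = False
    pool_size: int = 75
    pool_kind: str = "avg"
    dropout: float = 0.25
    use_batchnorm: bool = True  # conv -> BN -> activation, per stage
    n_classes: int = 4
    variant: str = "standard"  # "standard" | "sg"
    sg_ratio: float = 0.5

    def __post_init__(self):
        if any(k % 2 == 0 for k in self.branch_kernels):
            raise ValueError("branch kernels must be odd (symmetric same-padding)")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.pool_kind not in ("avg", "max"):
            raise ValueError("pool_kind must be 'avg' or 'max'")

    @property
    def feature_depth(self) -> int:
        """Depth of the feature map entering the spatial convolution."""
        d = self.stem_depth
        for _ in range(self.n_dense_blocks):
            width = len(self.branch_kernels) * self.branch_depth
            d = d + width if self.dense_skip else width
        return d


class InvertedBottleneck(Module):
    """1x1 expand + GELU -> depthwise temporal conv -> 1x1 project back."""

    def __init__(self, depth: int, expansion: int, kernel: int, rng):
        super().__init__()
        if expansion < 1:
            raise ValueError("expansion must be >= 1")
        mid = depth * expansion
        self.expand = TemporalConv(depth, mid, 1, rng)
        self.depthwise = DepthwiseTemporalConv(mid, kernel, rng)
        self.project = TemporalConv(mid, depth, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.project(self.depthwise(self.expand(x).gelu()))


class MultiscaleDenseBlock(Module):
    """Parallel temporal convolutions, depth-concatenated with the input."""

    def __init__(self, d_in: int, cfg: DisnetConfig, rng):
        super().__init__()
        self.dense_skip = cfg.dense_skip
        if cfg.variant == "sg":
            self.branches = [
                SGModule(
                    SgConfig(d_in, cfg.branch_depth, ratio=cfg.sg_ratio, kernel=k), rng
                )
                for k in cfg.branch_kernels
            ]
        else:
            self.branches = [
                TemporalConv(d_in, cfg.branch_depth, k, rng)
                for k in cfg.branch_kernels
            ]
        self.d_out = len(self.branches) * cfg.branch_depth + (
            d_in if cfg.dense_skip else 0
        )

    def forward(self, x: Tensor) -> Tensor:
        outs = [b(x).gelu() for b in self.branches]
        if self.dense_skip:
            outs = [x] + outs
        return concat(outs, axis=1)


class DISNet(Module):
    def __init__(self, cfg: DisnetConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.stem = TemporalConv(1, cfg.stem_depth, cfg.stem_kernel, rng)
        self.bottleneck = (
            InvertedBottleneck(
                cfg.stem_depth, cfg.bottleneck_expansion, cfg.bottleneck_kernel, rng
            )
            if cfg.use_bottleneck
            else None
        )
        self.stem_bn = BatchNorm(cfg.stem_depth) if cfg.use_batchnorm else None
        d = cfg.stem_depth
        self.blocks, self.block_svse, self.block_bn, self.block_drop = [], [], [], []
        for _ in range(cfg.n_dense_blocks):
            block = MultiscaleDenseBlock(d, cfg, rng)
            self.blocks.append(block)
            d = block.d_out
            if cfg.use_batchnorm:
                self.block_bn.append(BatchNorm(d))
            if cfg.use_svse:
                self.block_svse.append(
                    SvSE(
                        d,
                        cfg.n_channels,
                        rng,
                        reduction=cfg.svse_reduction,
                        residual=cfg.svse_residual,
                    )
                )
            self.block_drop.append(Dropout(cfg.dropout, rng))
        self.spatial = ChannelCollapseConv(d, cfg.n_channels, rng)
        self.pointwise = TemporalConv(d, d, 1, rng)
        self.spatial_bn = BatchNorm(d) if cfg.use_batchnorm else None
        self.final_svse = (
            SvSE(d, 1, rng, reduction=cfg.svse_reduction, residual=cfg.svse_residual)
            if cfg.use_svse
            else None
        )
        self.dropout = Dropout(cfg.dropout, rng)
        n_pool = cfg.n_times // cfg.pool_size
        if n_pool < 1:
            raise ValueError("pool_size exceeds the epoch length")
        self.head = Linear(d * n_pool, cfg.n_classes, rng)
        self.feature_depth = d

    def _pool(self, x: Tensor) -> Tensor:
        if self.cfg.pool_kind == "avg":
            return F.avg_pool_time(x, self.cfg.pool_size)
        size = self.cfg.pool_size
        t_keep = (x.shape[-1] // size) * size
        lead = x.shape[:-1]
        sl = (slice(None),) * (x.ndim - 1) + (slice(0, t_keep),)
        return x[sl].reshape(*lead, t_keep // size, size).max(axis=-1)

    def temporal_receptive_field(self) -> int:
        """Maximum temporal receptive field (samples) entering the pool."""
        rf = self.cfg.stem_kernel
        if self.cfg.use_bottleneck:
            rf += self.cfg.bottleneck_kernel - 1
        for _ in range(self.cfg.n_dense_blocks):
            rf += max(self.cfg.branch_kernels) - 1
        return rf

    def features(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return (pre-spatial map (N,D,C,T), pre-pool map (N,D,1,T))."""
        n, c, t = x.shape
        h = self.stem(x.reshape(n, 1, c, t))
        if self.stem_bn is not None:
            h = self.stem_bn(h)
        h = h.gelu()
        if self.bottleneck is not None:
            h = self.bottleneck(h)
        for i, block in enumerate(self.blocks):
            h = block(h)
            if self.block_bn:
                h = self.block_bn[i](h)
            if self.cfg.use_svse:
                h = self.block_svse[i](h)
            h = self.block_drop[i](h)
        mid = h
        h = self.pointwise(self.spatial(h))
        if self.spatial_bn is not None:
            h = self.spatial_bn(h)
        h = h.gelu()
        if self.final_svse is not None:
            h = self.final_svse(h)
        return mid, h

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Epochs (N, C, T) -> (pre-pool features (N, D, 1, T), logits (N, classes))."""
        _, feats = self.features(x)
        pooled = self.dropout(self._pool(feats))
        n = pooled.shape[0]
        logits = self.head(pooled.reshape(n, -1))
        return feats, logits
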