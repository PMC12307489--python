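"""Separable-Ghost (SG) convolution: a lightweight temporal conv block.

A fraction ``ratio`` of the output maps comes from a standard temporal
convolution (the primary path); the remaining maps are produced cheaply
from the primary maps by a depthwise 1 x k convolution (depth
unchanged), batch normalization, a 1 x 1 pointwise convolution to the
remaining depth, batch normalization and GELU.  Both groups are
depth-concatenated, so the output depth is exactly ``d_out`` for every
ratio in (0, 1]; at ratio = 1 the cheap path vanishes and the block
degenerates to the standard convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..nn import (
    BatchNorm,
    DepthwiseTemporalConv,
    Module,
    TemporalConv,
    Tensor,
    concat,
)

__all__ = ["SgConfig", "SGModule"]


@dataclass
class SgConfig:
    d_in: int
    d_out: int
    ratio: float = 0.5
    kernel: int = 25  # 100 ms at 250 Hz

    def __post_init__(self):
        if not 0 < self.ratio <= 1:
            raise ValueError("ratio must lie in (0, 1]")
        if self.primary_maps < 1:
            raise ValueError("round(d_out * ratio) must be at least 1")

    @property
    def primary_maps(self) -> int:
        return max(int(round(self.d_out * self.ratio)), 1)

    @property
    def cheap_maps(self) -> int:
        return self.d_out - self.primary_maps


class SGModule(Module):
    def __init__(self, cfg: SgConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.primary = TemporalConv(cfg.d_in, cfg.primary_maps, cfg.kernel, rng)
        if cfg.cheap_maps > 0:
            self.cheap_dw = DepthwiseTemporalConv(cfg.primary_maps, cfg.kernel, rng)
            self.bn1 = BatchNorm(cfg.primary_maps)
            self.cheap_pw = TemporalConv(cfg.primary_maps, cfg.cheap_maps, 1, rng)
            self.bn2 = BatchNorm(cfg.cheap_maps)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.d_in:
            raise ValueError(f"expected depth {self.cfg.d_in}, got {x.shape[1]}")
        prim = self.primary(x)
        if self.cfg.cheap_maps == 0:
            return prim
        cheap = self.bn2(self.cheap_pw(self.bn1(self.cheap_dw(prim)))).gelu()
        return concat([prim, cheap], axis=1)
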