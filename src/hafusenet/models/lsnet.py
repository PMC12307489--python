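"""LS-Net: the recurrent branch, plus the C2R/R2C fusion adapters.

LS-Net consumes a (C, T) map — raw electrode traces per time step by
default, or a C2R projection of a convolutional feature map — and runs
``n_layers`` LSTM passes.  After each layer the (H, T) hidden-state map
is refined by the SCoT global attention module with the hidden axis
treated as the channel dimension.  An optional non-overlapping average
pooling along time shortens the sequence before the recurrence; this is
the desk-scale knob for CPU training and defaults to off.

C2R flattens depth x channel per time step and projects linearly to H;
R2C is the reverse per-step projection, used to return the recurrent
features to map form for depth-dimension fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..attention import SCoT
from ..nn import Linear, LSTMLayer, Module, Tensor
from ..nn import functional as F

__all__ = ["LsnetConfig", "LSNet", "C2R", "R2C"]


@dataclass
class LsnetConfig:
    n_layers: int = 2
    hidden: int = 64
    use_scot: bool = True
    input_mode: str = "raw"  # "raw" | "c2r"
    time_pool: int = 1  # average-pool factor applied to the input sequence
    cot_kernel: int = 3
    nonlocal_residual: bool = True

    def __post_init__(self):
        if self.n_layers < 1 or self.hidden < 1:
            raise ValueError("n_layers and hidden must be >= 1")
        if self.input_mode not in ("raw", "c2r"):
            raise ValueError("input_mode must be 'raw' or 'c2r'")


class LSNet(Module):
    def __init__(self, d_in: int, cfg: LsnetConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.layers = [
            LSTMLayer(d_in if i == 0 else cfg.hidden, cfg.hidden, rng)
            for i in range(cfg.n_layers)
        ]
        self.scots = (
            [
                SCoT(
                    1,
                    rng,
                    cot_kernel=cfg.cot_kernel,
                    nonlocal_residual=cfg.nonlocal_residual,
                )
                for _ in range(cfg.n_layers)
            ]
            if cfg.use_scot
            else []
        )

    def forward(self, x: Tensor) -> Tensor:
        """(N, C, T) -> (N, H, T'); T' = T // time_pool."""
        if self.cfg.time_pool > 1:
            x = F.avg_pool_time(x, self.cfg.time_pool)
        n, _, t = x.shape
        seq = x.transpose(0, 2, 1)  # (N, T, C)
        y = None
        for i, layer in enumerate(self.layers):
            hs = layer(seq)  # (N, T, H)
            y = hs.transpose(0, 2, 1)  # (N, H, T)
            if self.cfg.use_scot:
                h = y.shape[1]
                y = self.scots[i](y.reshape(n, 1, h, t)).reshape(n, h, t)
            seq = y.transpose(0, 2, 1)
        return y


class C2R(Module):
    """(N, D, C, T) feature map -> (N, H, T) sequence by per-step projection."""

    def __init__(self, depth: int, n_channels: int, hidden: int, rng, bias=True):
        super().__init__()
        self.proj = Linear(depth * n_channels, hidden, rng, bias=bias)

    def forward(self, f: Tensor) -> Tensor:
        n, d, c, t = f.shape
        steps = f.reshape(n, d * c, t).transpose(0, 2, 1)  # (N, T, D*C)
        return self.proj(steps).transpose(0, 2, 1)


class R2C(Module):
    """(N, H, T) sequence -> (N, D, C, T) map by per-step projection."""

    def __init__(self, hidden: int, target_depth: int, target_channels: int, rng, bias=True):
        super().__init__()
        self.target_depth = target_depth
        self.target_channels = target_channels
        self.proj = Linear(hidden, target_depth * target_channels, rng, bias=bias)

    def forward(self, s: Tensor) -> Tensor:
        n, _, t = s.shape
        steps = self.proj(s.transpose(0, 2, 1))  # (N, T, D*C)
        return steps.transpose(0, 2, 1).reshape(
            n, self.target_depth, self.target_channels, t
        )
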