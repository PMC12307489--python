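"""SCoT: two-stage global self-attention over (channel, time) EEG maps.

Stage 1 (spatial) adapts the Non-local block: each electrode channel is
a token whose descriptor is its depth vector after mean-pooling over
time, so the similarity matrix is only C x C — appropriate for spatial
data with weak local correlation and few positions.  Query/key/value
come from per-token projections at half depth, similarities are
softmax-normalized row-wise, and the aggregated values are re-expanded
and added back as a residual broadcast over time.

Stage 2 (temporal) adapts the Contextual-Transformer block to the
time axis: a local 1 x k convolution (k = 3) forms the static-context
key K, the query is the input itself, the value is a 1 x 1 projection,
and an attention map A — two consecutive 1 x 1 convolutions on the
depth-concatenation of K and Q — gates the value.  The dynamic context
is the locally summed A * V over the kernel footprint, fused with the
static context by element-wise addition.

Computing attention per axis rather than jointly keeps the cost far
below a full (C*T) x (C*T) similarity matrix.
"""

from __future__ import annotations

import math

import numpy as np

from ..nn import Linear, Module, TemporalConv, Tensor, concat
from ..nn import functional as F

__all__ = ["NonLocalSpatial", "CoTTemporal", "SCoT"]


class NonLocalSpatial(Module):
    """Channel-token self-attention with half-depth compression."""

    def __init__(self, depth: int, rng, residual: bool = True):
        super().__init__()
        self.residual = residual
        d2 = max(math.ceil(depth / 2), 1)
        self.theta = Linear(depth, d2, rng)
        self.phi = Linear(depth, d2, rng)
        self.g = Linear(depth, d2, rng)
        self.expand = Linear(d2, depth, rng)
        self._last_similarity: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        n, d, c, t = x.shape
        tokens = x.mean(axis=3).transpose(0, 2, 1)  # (N, C, D)
        q = self.theta(tokens)
        k = self.phi(tokens)
        v = self.g(tokens)
        s = (q @ k.transpose(0, 2, 1)).softmax(axis=2)  # rows sum to 1
        self._last_similarity = s.data
        y = self.expand(s @ v)  # (N, C, D)
        y4 = y.transpose(0, 2, 1).reshape(n, d, c, 1)
        if self.residual:
            return x + y4
        return x * y4.sigmoid()


class CoTTemporal(Module):
    """Static (local-convolution key) plus dynamic (gated value) context."""

    def __init__(self, depth: int, rng, kernel: int = 3):
        super().__init__()
        self.kernel = kernel
        self.key_conv = TemporalConv(depth, depth, kernel, rng)
        self.val_conv = TemporalConv(depth, depth, 1, rng)
        mid = max(depth // 2, 1)
        self.att_conv1 = TemporalConv(2 * depth, mid, 1, rng)
        self.att_conv2 = TemporalConv(mid, depth, 1, rng)
        # fixed local-sum footprint for aggregating A * V
        self._ones = Tensor(np.ones((depth, kernel), dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        key = self.key_conv(x)  # static context
        value = self.val_conv(x)
        att = self.att_conv2(self.att_conv1(concat([key, x], axis=1)).gelu())
        dynamic = F.depthwise_temporal_conv(att * value, self._ones)
        return key + dynamic


class SCoT(Module):
    """Spatial Non-local stage followed by temporal CoT stage."""

    def __init__(
        self,
        depth: int,
        rng,
        cot_kernel: int = 3,
        nonlocal_residual: bool = True,
    ):
        super().__init__()
        self.spatial = NonLocalSpatial(depth, rng, residual=nonlocal_residual)
        self.temporal = CoTTemporal(depth, rng, kernel=cot_kernel)

    def forward(self, x: Tensor) -> Tensor:
        return self.temporal(self.spatial(x))


def joint_attention_macs(c: int, t: int) -> int:
    """Multiply-accumulate count of one full (C*T) x (C*T) attention product."""
    p = c * t
    return 2 * p * p  # similarity matrix + value aggregation


def scot_macs(depth: int, c: int, t: int, cot_kernel: int = 3) -> int:
    """Approximate MAC count of one SCoT pass (both stages, projections included)."""
    d2 = max(math.ceil(depth / 2), 1)
    mid = max(depth // 2, 1)
    spatial = 3 * c * depth * d2 + 2 * c * c * d2 + c * d2 * depth
    temporal = (
        depth * depth * cot_kernel * c * t  # key conv
        + depth * depth * c * t  # value conv
        + 2 * depth * mid * c * t + mid * depth * c * t  # two 1x1 attention convs
        + depth * c * t * cot_kernel  # local aggregation
    )
    return spatial + temporal
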