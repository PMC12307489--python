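"""svSE hybrid attention for (depth, channel, time) EEG feature maps.

Three weighting branches are combined:

* a channel-excitation branch (cSE with global *max* pooling, so salient
  depth maps dominate): squeeze over (C, T), a reduce-expand excitation
  MLP shared across depth maps, and a softmax over depth giving ``att_c``
  of shape (D, 1, 1); because the MLP is weight-tied over maps, equally
  salient maps get equal weights (uniform 1/D in the constant limit) and
  the softmax alone distributes attention between maps;
* a variance branch: per-position depth mean and population depth
  variance are stacked, mixed by a 1x1 convolution and softmax-normalized
  over the C*T positions, giving ``att_v`` of shape (1, C, T) — the
  variance plane tracks where the non-stationary signal is active;
* an axial branch: a depth-compressed map is pooled along time (average
  and max) into a per-electrode weight ``x_s`` (1, C, 1) and filtered
  along the electrode axis into a per-sample weight ``x_t`` (1, 1, T);
  their Kronecker (outer) product restores a (1, C, T) map ``att_s`` that
  is rank-1 by construction.

Softmax is applied along the axis each branch weights: depth for
``att_c``, and each axial factor along its own axis, so the outer
product itself sums to one over the C*T positions and stays rank-1.
The branch outputs gate the input as ``(att_v + att_s) * x + att_c * x``
with each gate rescaled to unit mean (see :meth:`SvSE.forward`).
"""

from __future__ import annotations

import logging

from ..nn import ChannelCollapseConv, Linear, Module, TemporalConv, Tensor, concat

logger = logging.getLogger(__name__)

__all__ = ["SvSE"]


class SvSE(Module):
    def __init__(
        self,
        depth: int,
        n_channels: int,
        rng,
        reduction: int = 2,
        residual: bool = False,
    ):
        super().__init__()
        self.depth = depth
        self.residual = residual
        if depth < reduction:
            logger.warning(
                "svSE reduction %d exceeds depth %d; falling back to r=1",
                reduction,
                depth,
            )
            reduction = 1
        hidden = max(depth // reduction, 1)
        # channel-excitation branch: a reduce-expand MLP shared (weight-tied)
        # across depth maps, so equally salient maps receive equal logits and
        # the depth softmax alone arbitrates between maps
        self.fc_reduce = Linear(1, hidden, rng)
        self.fc_expand = Linear(hidden, 1, rng)
        # variance branch: 1x1 aggregation of stacked (mean, variance)
        self.var_conv = TemporalConv(2, 1, 1, rng)
        # axial branch
        self.sf_conv = TemporalConv(depth, 1, 1, rng)  # depth compression
        self.spool_conv = TemporalConv(2, 1, 1, rng)  # fuse avg/max time pools
        self.time_conv = ChannelCollapseConv(1, n_channels, rng)

    # -- branch computations (exposed for inspection and testing) -----------
    def cse_weights(self, x: Tensor) -> Tensor:
        """Depth weights (N, D, 1, 1); softmax over depth sums to 1."""
        pooled = x.max(axis=(2, 3))  # global max pool -> (N, D)
        n, d = pooled.shape
        z = self.fc_expand(self.fc_reduce(pooled.reshape(n, d, 1)).gelu())
        att = z.reshape(n, d).softmax(axis=1)
        return att.reshape(n, d, 1, 1)

    def variance_weights(self, x: Tensor) -> Tensor:
        """Mean/variance-informed spatio-temporal weights (N, 1, C, T)."""
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)  # population convention
        pooled = concat([mu, var], axis=1)  # (N, 2, C, T)
        pre = self.var_conv(pooled)
        n, _, c, t = pre.shape
        return pre.reshape(n, 1, c * t).softmax(axis=2).reshape(n, 1, c, t)

    def axial_weights(self, x: Tensor) -> Tensor:
        """Rank-1 axial weights: outer product of electrode and time factors."""
        x_sf = self.sf_conv(x)  # (N, 1, C, T)
        x_avg = x_sf.mean(axis=3, keepdims=True)
        x_max = x_sf.max(axis=3, keepdims=True)
        x_spool = concat([x_avg, x_max], axis=1)  # (N, 2, C, 1)
        x_s = self.spool_conv(x_spool)  # (N, 1, C, 1)
        x_t = self.time_conv(x_sf)  # (N, 1, 1, T)
        x_s = x_s.softmax(axis=2)
        x_t = x_t.softmax(axis=3)
        return x_s * x_t  # Kronecker product over (C, T)

    def forward(self, x: Tensor) -> Tensor:
        # The softmax maps are distributions (they sum to 1 over their axis).
        # As multiplicative gates they are rescaled so the peak weight is 1:
        # a raw distribution gate shrinks activations by ~1/(C*T) and starves
        # downstream layers of gradient, while a mean-one rescale explodes
        # whenever the softmax concentrates.  Max-normalization keeps gates in
        # (0, 1] — the range of the sigmoid that softmax replaces — with the
        # softmax's relative weighting intact.
        att_c = self.cse_weights(x)
        att_c = att_c / att_c.max(axis=1, keepdims=True)
        att_vs = self.variance_weights(x) + self.axial_weights(x)
        att_vs = att_vs / att_vs.max(axis=(2, 3), keepdims=True)
        out = att_vs * x + att_c * x
        return out + x if self.residual else out
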