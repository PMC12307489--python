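"""Inspect the svSE and SCoT attention modules on a small feature map.

Shows the three svSE weight maps (channel excitation, variance branch,
rank-1 axial branch) and the row-stochastic Non-local similarity matrix
of SCoT's spatial stage.
"""

import numpy as np

from hafusenet.attention import SCoT, SvSE
from hafusenet.nn import Tensor

rng = np.random.default_rng(0)
x = Tensor(rng.standard_normal((1, 8, 6, 20)).astype(np.float32))  # (N, D, C, T)

svse = SvSE(depth=8, n_channels=6, rng=rng)
att_c = svse.cse_weights(x)
att_v = svse.variance_weights(x)
att_s = svse.axial_weights(x)
print(f"att_c {att_c.shape}: depth weights sum to {att_c.data.sum():.4f}")
print(f"att_v {att_v.shape}: position weights sum to {att_v.data.sum():.4f}")
s = np.linalg.svd(att_s.data[0, 0], compute_uv=False)
print(f"att_s {att_s.shape}: singular values {s[:3].round(6)} (rank 1)")
out = svse(x)
print(f"svSE output shape {out.shape} == input shape {x.shape}")

scot = SCoT(depth=8, rng=rng)
y = scot(x)
rows = scot.spatial._last_similarity.sum(axis=2)
print(f"SCoT output {y.shape}; Non-local similarity rows sum to {rows.round(6).max()}")
# svSE recalibrates a feature map multiplicatively without changing its shape;
# SCoT chains channel-token self-attention with temporal context attention.
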