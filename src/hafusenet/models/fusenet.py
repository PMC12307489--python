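"""HA-FuseNet: depth-dimension fusion of the DIS-Net and LS-Net branches.

Both branches see the same normalized epochs.  The recurrent branch's
(H, T) output is returned to map form by R2C and depth-concatenated
with DIS-Net's pre-pool feature map (temporal lengths are aligned by
parameter-free average pooling to the shorter one); a depthwise
separable convolution mixes the fused map, followed by pooling,
flattening and a linear head over the four classes.

All six ablation variants are pure configuration: the four CNN-only
models drop the recurrent branch entirely, "dis_lstm" adds LS-Net with
SCoT disabled, and "dis_lstm_scot" is the full model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..nn import (
    DepthwiseTemporalConv,
    Dropout,
    Linear,
    Module,
    TemporalConv,
    Tensor,
)
from ..nn import functional as F
from .disnet import DisnetConfig, DISNet
from .lsnet import C2R, LSNet, LsnetConfig, R2C

__all__ = ["FusionConfig", "ModelConfig", "HAFuseNet", "build_variant", "VARIANTS"]


@dataclass
class FusionConfig:
    target_depth: int = 8  # depth of the R2C-projected recurrent features
    kernel: int = 15  # depthwise separable mixing kernel
    dropout: float = 0.25


@dataclass
class ModelConfig:
    disnet: DisnetConfig = field(default_factory=DisnetConfig)
    lsnet: LsnetConfig = field(default_factory=LsnetConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    use_lstm: bool = True
    seed: int = 0


class HAFuseNet(Module):
    def __init__(self, cfg: ModelConfig, rng=None):
        super().__init__()
        self.cfg = cfg
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        dcfg = cfg.disnet
        self.disnet = DISNet(dcfg, rng)
        self.lsnet = None
        if cfg.use_lstm:
            if cfg.lsnet.input_mode == "raw":
                ls_in = dcfg.n_channels
                self.c2r = None
            else:
                self.c2r = C2R(
                    self.disnet.feature_depth, dcfg.n_channels, cfg.lsnet.hidden, rng
                )
                ls_in = cfg.lsnet.hidden
            self.lsnet = LSNet(ls_in, cfg.lsnet, rng)
            self.r2c = R2C(cfg.lsnet.hidden, cfg.fusion.target_depth, 1, rng)
            fused_depth = self.disnet.feature_depth + cfg.fusion.target_depth
            self.fuse_dw = DepthwiseTemporalConv(fused_depth, cfg.fusion.kernel, rng)
            self.fuse_pw = TemporalConv(fused_depth, fused_depth, 1, rng)
            self.fuse_dropout = Dropout(cfg.fusion.dropout, rng)
            n_pool = dcfg.n_times // dcfg.pool_size
            self.fuse_head = Linear(fused_depth * n_pool, dcfg.n_classes, rng)

    # -- fusion head ---------------------------------------------------------
    def fuse_and_classify(self, dis_f: Tensor, ls_s: Tensor) -> Tensor:
        """Pre-pool DIS features (N,D,1,T) + LS output (N,H,T') -> probabilities."""
        return self._fuse_scores(dis_f, ls_s).softmax(axis=1)

    def _fuse_scores(self, dis_f: Tensor, ls_s: Tensor) -> Tensor:
        if self.lsnet is None:
            raise RuntimeError("fusion head requires the recurrent branch")
        ls_map = self.r2c(ls_s)  # (N, Dr, 1, T')
        t_dis, t_ls = dis_f.shape[-1], ls_map.shape[-1]
        t_common = min(t_dis, t_ls)
        if t_dis != t_common:
            dis_f = F.avg_pool_time(dis_f, t_dis // t_common)
        if t_ls != t_common:
            ls_map = F.avg_pool_time(ls_map, t_ls // t_common)
        if dis_f.shape[-1] != ls_map.shape[-1]:
            raise ValueError(
                f"temporal alignment failed: {dis_f.shape[-1]} vs {ls_map.shape[-1]}"
            )
        from ..nn import concat

        fused = concat([dis_f, ls_map], axis=1)
        mixed = self.fuse_pw(self.fuse_dw(fused)).gelu()
        pool = max(self.cfg.disnet.pool_size // (t_dis // t_common), 1)
        pooled = self.fuse_dropout(F.avg_pool_time(mixed, pool))
        n = pooled.shape[0]
        return self.fuse_head(pooled.reshape(n, -1))

    def logits(self, x: Tensor) -> Tensor:
        """Unnormalized class scores (the training loss consumes these)."""
        if self.lsnet is None:
            _, dis_logits = self.disnet(x)
            return dis_logits
        mid, dis_f = self.disnet.features(x)
        ls_in = x if self.c2r is None else self.c2r(mid)
        ls_out = self.lsnet(ls_in)
        return self._fuse_scores(dis_f, ls_out)

    def forward(self, x: Tensor) -> Tensor:
        """Normalized epochs (N, C, T) -> class probabilities (N, n_classes)."""
        return self.logits(x).softmax(axis=1)


def content_hash(model: HAFuseNet) -> str:
    """SHA-256 over the model's config JSON and parameter bytes."""
    import dataclasses
    import hashlib
    import json

    cfg_json = json.dumps(dataclasses.asdict(model.cfg), sort_keys=True, default=list)
    state = model.state_dict()
    digest = hashlib.sha256(cfg_json.encode())
    for k in sorted(state):
        digest.update(k.encode())
        digest.update(state[k].tobytes())
    return digest.hexdigest()


def save_checkpoint(model: HAFuseNet, path, seed: int | None = None) -> str:
    """Write parameters + config + seed to one npz archive; returns content hash."""
    import dataclasses
    import json

    cfg_json = json.dumps(dataclasses.asdict(model.cfg), sort_keys=True, default=list)
    state = model.state_dict()
    chash = content_hash(model)
    np.savez(
        path,
        __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
        __hash__=np.frombuffer(chash.encode(), dtype=np.uint8),
        __seed__=np.array(-1 if seed is None else seed),
        **{f"param/{k}": v for k, v in state.items()},
    )
    return chash


def load_checkpoint(path) -> HAFuseNet:
    """Rebuild a model from a checkpoint archive (verifies the content hash)."""
    import json

    from .disnet import DisnetConfig
    from .lsnet import LsnetConfig

    with np.load(path) as arc:
        cfg_d = json.loads(bytes(arc["__config__"]).decode())
        stored_hash = bytes(arc["__hash__"]).decode()
        state = {
            k[len("param/"):]: arc[k] for k in arc.files if k.startswith("param/")
        }
    for key in ("branch_kernels",):
        if key in cfg_d["disnet"]:
            cfg_d["disnet"][key] = tuple(cfg_d["disnet"][key])
    cfg = ModelConfig(
        disnet=DisnetConfig(**cfg_d["disnet"]),
        lsnet=LsnetConfig(**cfg_d["lsnet"]),
        fusion=FusionConfig(**cfg_d["fusion"]),
        use_lstm=cfg_d["use_lstm"],
        seed=cfg_d["seed"],
    )
    model = HAFuseNet(cfg)
    model.load_state_dict(state)
    if content_hash(model) != stored_hash:
        raise ValueError("checkpoint content hash mismatch")
    return model.eval()


#: ablation family: name -> config switches
VARIANTS = {
    "inception": dict(
        use_lstm=False, use_bottleneck=False, dense_skip=False, use_svse=False,
        n_dense_blocks=3,
    ),
    "base_inception": dict(
        use_lstm=False, use_bottleneck=True, dense_skip=False, use_svse=False
    ),
    "bi_dense": dict(
        use_lstm=False, use_bottleneck=True, dense_skip=True, use_svse=False
    ),
    "di_svse": dict(
        use_lstm=False, use_bottleneck=True, dense_skip=True, use_svse=True
    ),
    "dis_lstm": dict(
        use_lstm=True, use_bottleneck=True, dense_skip=True, use_svse=True,
        use_scot=False,
    ),
    "dis_lstm_scot": dict(
        use_lstm=True, use_bottleneck=True, dense_skip=True, use_svse=True,
        use_scot=True,
    ),
}


def build_variant(
    name: str, base: ModelConfig | None = None, rng=None
) -> HAFuseNet:
    """Instantiate one of the six ablation variants from config switches alone."""
    import copy

    if name not in VARIANTS:
        raise KeyError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")
    cfg = copy.deepcopy(base) if base is not None else ModelConfig()
    switches = dict(VARIANTS[name])
    cfg.use_lstm = switches.pop("use_lstm")
    if "use_scot" in switches:
        cfg.lsnet.use_scot = switches.pop("use_scot")
    for key, val in switches.items():
        setattr(cfg.disnet, key, val)
    return HAFuseNet(cfg, rng=rng)
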