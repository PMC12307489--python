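"""Layer objects: parameter containers over the functional primitives."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module",
    "Linear",
    "TemporalConv",
    "DepthwiseTemporalConv",
    "ChannelCollapseConv",
    "BatchNorm",
    "Dropout",
    "LSTMLayer",
    "count_parameters",
]


class Module:
    """Base class: parameter discovery, train/eval mode, gradient reset."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield f"{prefix}{name}", val
        for name, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    #: attribute names of non-trainable arrays persisted in checkpoints
    buffer_names: tuple[str, ...] = ()

    def named_buffers(self, prefix: str = ""):
        for name in self.buffer_names:
            yield f"{prefix}{name}", getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix=f"{prefix}{name}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.named_parameters()}
        out.update({k: v.copy() for k, v in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(params) | set(buffers)) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(np.float32).copy()
        # buffers live on nested modules; walk again to assign in place
        self._assign_buffers(state, prefix="")

    def _assign_buffers(self, state: dict[str, np.ndarray], prefix: str):
        for name in self.buffer_names:
            setattr(self, name, state[f"{prefix}{name}"].astype(np.float32).copy())
        for name, child in self._children():
            child._assign_buffers(state, prefix=f"{prefix}{name}.")


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> Tensor:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias=True):
        super().__init__()
        self.w = _glorot(rng, (d_in, d_out), d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.w
        return out + self.b if self.b is not None else out


class TemporalConv(Module):
    """1 x k temporal convolution, same padding; k = 1 gives pointwise mixing."""

    def __init__(self, d_in, d_out, kernel, rng, bias=True):
        super().__init__()
        self.kernel = kernel
        fan = d_in * kernel
        self.w = _glorot(rng, (d_out, d_in, kernel), fan, d_out * kernel)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.temporal_conv(x, self.w, self.b)


class DepthwiseTemporalConv(Module):
    def __init__(self, depth, kernel, rng, bias=True):
        super().__init__()
        self.w = _glorot(rng, (depth, kernel), kernel, kernel)
        self.b = Tensor(np.zeros(depth), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.depthwise_temporal_conv(x, self.w, self.b)


class ChannelCollapseConv(Module):
    """Depthwise C x 1 spatial filter collapsing the electrode axis to 1."""

    def __init__(self, depth, n_channels, rng, bias=True):
        super().__init__()
        self.n_channels = n_channels
        self.w = _glorot(rng, (depth, n_channels), n_channels, 1)
        self.b = Tensor(np.zeros(depth), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] != self.n_channels:
            raise ValueError(
                f"expected {self.n_channels} electrode channels, got {x.shape[2]}"
            )
        return F.channel_collapse_conv(x, self.w, self.b)


class BatchNorm(Module):
    """Batch normalization per depth map over (batch, channel, time)."""

    buffer_names = ("running_mean", "running_var")

    def __init__(self, depth: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(depth), requires_grad=True)
        self.beta = Tensor(np.zeros(depth), requires_grad=True)
        self.running_mean = np.zeros(depth, dtype=np.float32)
        self.running_var = np.ones(depth, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, -1) + (1,) * (x.ndim - 2)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = x.var(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xn = (x - mu) / ((var + self.eps) ** 0.5)
        return xn * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(np.float32)
        return x * Tensor(keep / (1.0 - self.p))


class LSTMLayer(Module):
    """One LSTM layer over (N, T, I); forget-gate bias initialized to 1."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.wx = _glorot(rng, (d_in, 4 * hidden), d_in, hidden)
        self.wh = _glorot(rng, (hidden, 4 * hidden), hidden, hidden)
        b = np.zeros(4 * hidden, dtype=np.float32)
        b[hidden : 2 * hidden] = 1.0
        self.b = Tensor(b, requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.lstm(x, self.wx, self.wh, self.b)


def count_parameters(module: Module | None) -> int:
    """Exact count of trainable scalars in a module tree (0 for empty/None)."""
    if module is None:
        return 0
    return int(sum(p.size for p in module.parameters()))
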