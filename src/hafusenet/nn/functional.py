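"""Fused neural-network primitives with hand-written backward passes.

Feature maps follow the (N, D, C, T) layout used throughout the package:
batch, depth (feature maps), electrode channel, time sample.  Temporal
convolutions slide along T only and use "same" zero padding so T is
preserved; the channel-collapse convolution spans the full electrode
axis (a C x 1 kernel), which is how EEG nets mix spatial information.

The loops below are over kernel offsets, not samples, so every inner
step is a large BLAS-backed einsum; this keeps desk-scale training on a
single CPU practical.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "temporal_conv",
    "depthwise_temporal_conv",
    "channel_collapse_conv",
    "lstm",
    "avg_pool_time",
]


def _pad_time(x: np.ndarray, k: int) -> tuple[np.ndarray, int, int]:
    left, right = (k - 1) // 2, k // 2
    if k == 1:
        return x, 0, 0
    return np.pad(x, ((0, 0), (0, 0), (0, 0), (left, right))), left, right


# im2col buffers above this many elements fall back to the offset loop
_COL_BUDGET = 64_000_000


def temporal_conv(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """1 x k convolution along time: (N,Din,C,T) * (Dout,Din,k) -> (N,Dout,C,T).

    Lowered to a single im2col matmul when the unfolded buffer is small
    enough, otherwise to a loop over kernel offsets; both paths are exact.
    """
    N, Din, C, T = x.shape
    Dout, Din_w, k = w.shape
    if Din != Din_w:
        raise ValueError(f"depth mismatch: input {Din}, kernel expects {Din_w}")
    if N * C * T * Din * k <= _COL_BUDGET:
        return _temporal_conv_im2col(x, w, b)
    return _temporal_conv_loop(x, w, b)


def _temporal_conv_im2col(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    N, Din, C, T = x.shape
    Dout, _, k = w.shape
    xp, left, _ = _pad_time(x.data, k)
    xt = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))  # (N, C, Tp, Din)
    win = np.lib.stride_tricks.sliding_window_view(xt, k, axis=2)  # (N,C,T,Din,k)
    col = np.ascontiguousarray(win).reshape(N * C * T, Din * k)
    # col rows are laid out (Din, k), matching w.reshape(Dout, Din*k)
    wmat = np.ascontiguousarray(w.data.reshape(Dout, Din * k))
    out2 = col @ wmat.T  # (N*C*T, Dout)
    out = np.ascontiguousarray(out2.reshape(N, C, T, Dout).transpose(0, 3, 1, 2))
    if b is not None:
        out += b.data.reshape(1, Dout, 1, 1)

    x_needs_grad = x.requires_grad or bool(x._prev)

    def backward(g):
        gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * C * T, Dout)
        gw = (gt.T @ col).reshape(w.shape)
        gb = gt.sum(axis=0) if b is not None else None
        if not x_needs_grad:
            return None, gw, gb
        gcol = (gt @ wmat).reshape(N, C, T, Din, k)
        gxt = np.zeros_like(xt)
        for j in range(k):
            gxt[:, :, j : j + T, :] += gcol[:, :, :, :, j]
        gxp = gxt.transpose(0, 3, 1, 2)
        gx = gxp[:, :, :, left : left + T] if k > 1 else gxp
        return np.ascontiguousarray(gx), gw, gb

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def _temporal_conv_loop(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    N, Din, C, T = x.shape
    Dout, _, k = w.shape
    xp, left, _ = _pad_time(x.data, k)
    out = np.zeros((N, Dout, C, T), dtype=np.float32)
    for j in range(k):
        out += np.einsum(
            "oi,nict->noct", w.data[:, :, j], xp[:, :, :, j : j + T], optimize=True
        )
    if b is not None:
        out += b.data.reshape(1, Dout, 1, 1)

    def backward(g):
        gw = np.empty_like(w.data)
        gxp = np.zeros_like(xp)
        for j in range(k):
            seg = xp[:, :, :, j : j + T]
            gw[:, :, j] = np.einsum("noct,nict->oi", g, seg, optimize=True)
            gxp[:, :, :, j : j + T] += np.einsum(
                "oi,noct->nict", w.data[:, :, j], g, optimize=True
            )
        gx = gxp[:, :, :, left : left + T] if k > 1 else gxp
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return gx, gw, gb

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def depthwise_temporal_conv(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Per-depth-map 1 x k temporal convolution: kernel (D, k), depth unchanged."""
    N, D, C, T = x.shape
    D_w, k = w.shape
    if D != D_w:
        raise ValueError(f"depth mismatch: input {D}, kernel expects {D_w}")
    xp, left, _ = _pad_time(x.data, k)
    out = np.zeros((N, D, C, T), dtype=np.float32)
    for j in range(k):
        out += w.data[:, j].reshape(1, D, 1, 1) * xp[:, :, :, j : j + T]
    if b is not None:
        out += b.data.reshape(1, D, 1, 1)

    def backward(g):
        gw = np.empty_like(w.data)
        gxp = np.zeros_like(xp)
        for j in range(k):
            gw[:, j] = np.einsum(
                "ndct,ndct->d", g, xp[:, :, :, j : j + T], optimize=True
            )
            gxp[:, :, :, j : j + T] += w.data[:, j].reshape(1, D, 1, 1) * g
        gx = gxp[:, :, :, left : left + T] if k > 1 else gxp
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return gx, gw, gb

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def channel_collapse_conv(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Depthwise C x 1 convolution spanning the full electrode axis.

    (N, D, C, T) with kernel (D, C) -> (N, D, 1, T); each depth map gets its
    own spatial filter, collapsing the channel axis.
    """
    N, D, C, T = x.shape
    if w.shape != (D, C):
        raise ValueError(f"kernel {w.shape} does not match (D={D}, C={C})")
    out = np.einsum("ndct,dc->ndt", x.data, w.data, optimize=True)[:, :, None, :]
    if b is not None:
        out = out + b.data.reshape(1, D, 1, 1)

    def backward(g):
        g2 = g[:, :, 0, :]
        gx = np.einsum("ndt,dc->ndct", g2, w.data, optimize=True)
        gw = np.einsum("ndt,ndct->dc", g2, x.data, optimize=True)
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return gx, gw, gb

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out.astype(np.float32), parents, backward)


def lstm(x: Tensor, wx: Tensor, wh: Tensor, b: Tensor) -> Tensor:
    """Single-layer LSTM over (N, T, I) -> hidden states (N, T, H).

    Gate order in the stacked weight matrices is (input, forget, cell, output);
    initial hidden and cell states are zero.  Backward is full
    backpropagation-through-time on cached gate activations.
    """
    N, T, I = x.shape
    H = wh.shape[0]
    if wx.shape != (I, 4 * H) or wh.shape != (H, 4 * H) or b.shape != (4 * H,):
        raise ValueError("inconsistent LSTM weight shapes")

    hs = np.zeros((N, T, H), dtype=np.float32)
    cache = []
    h = np.zeros((N, H), dtype=np.float32)
    c = np.zeros((N, H), dtype=np.float32)
    for t in range(T):
        z = x.data[:, t, :] @ wx.data + h @ wh.data + b.data
        i_g = _sigmoid(z[:, :H])
        f_g = _sigmoid(z[:, H : 2 * H])
        g_g = np.tanh(z[:, 2 * H : 3 * H])
        o_g = _sigmoid(z[:, 3 * H :])
        c_prev = c
        c = f_g * c_prev + i_g * g_g
        tc = np.tanh(c)
        h = o_g * tc
        hs[:, t, :] = h
        cache.append((i_g, f_g, g_g, o_g, c_prev, tc))

    def backward(g):
        gx = np.zeros_like(x.data)
        gwx = np.zeros_like(wx.data)
        gwh = np.zeros_like(wh.data)
        gb = np.zeros_like(b.data)
        dh_next = np.zeros((N, H), dtype=np.float32)
        dc_next = np.zeros((N, H), dtype=np.float32)
        for t in range(T - 1, -1, -1):
            i_g, f_g, g_g, o_g, c_prev, tc = cache[t]
            dh = g[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o_g * (1.0 - tc**2) + dc_next
            di = dc * g_g
            df = dc * c_prev
            dg = dc * i_g
            dz = np.concatenate(
                [
                    di * i_g * (1.0 - i_g),
                    df * f_g * (1.0 - f_g),
                    dg * (1.0 - g_g**2),
                    do * o_g * (1.0 - o_g),
                ],
                axis=1,
            )
            gx[:, t, :] = dz @ wx.data.T
            gwx += x.data[:, t, :].T @ dz
            h_prev = hs[:, t - 1, :] if t > 0 else np.zeros((N, H), dtype=np.float32)
            gwh += h_prev.T @ dz
            gb += dz.sum(axis=0)
            dh_next = dz @ wh.data.T
            dc_next = dc * f_g
        return gx, gwx, gwh, gb

    return Tensor._make(hs, (x, wx, wh, b), backward)


def avg_pool_time(x: Tensor, size: int) -> Tensor:
    """Non-overlapping average pooling along the last (time) axis.

    Trailing samples that do not fill a window are dropped.  Composed from
    differentiable reshape/mean, so no custom backward is needed.
    """
    if size <= 1:
        return x
    T = x.shape[-1]
    T_keep = (T // size) * size
    if T_keep == 0:
        raise ValueError(f"pool size {size} exceeds time length {T}")
    lead = x.shape[:-1]
    sl = (slice(None),) * (x.ndim - 1) + (slice(0, T_keep),)
    xt = x[sl] if T_keep != T else x
    return xt.reshape(*lead, T_keep // size, size).mean(axis=-1)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
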