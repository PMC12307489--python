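"""Autodiff core: op correctness against numpy/scipy oracles and numeric gradients."""

import numpy as np
import pytest
from scipy import ndimage

from hafusenet.nn import (
    Adam,
    BatchNorm,
    Linear,
    Tensor,
    concat,
    count_parameters,
    functional as F,
)


def numeric_grad(f, a, eps=1e-3):
    g = np.zeros_like(a, dtype=np.float64)
    it = np.nditer(a, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = a[idx]
        a[idx] = orig + eps
        fp = f()
        a[idx] = orig - eps
        fm = f()
        a[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


@pytest.mark.parametrize(
    "build,shapes",
    [
        (lambda x, w: F.temporal_conv(x, w), [(2, 3, 2, 6), (4, 3, 3)]),
        (lambda x, w: F.depthwise_temporal_conv(x, w), [(2, 3, 2, 6), (3, 3)]),
        (lambda x, w: F.channel_collapse_conv(x, w), [(2, 3, 4, 5), (3, 4)]),
        (lambda x, w: (x.gelu() * w.sigmoid()).softmax(axis=1), [(2, 3, 4), (2, 3, 4)]),
        (lambda x, w: x.var(axis=1, keepdims=True) + w.max(axis=0), [(3, 4), (3, 4)]),
    ],
    ids=["temporal_conv", "depthwise_conv", "channel_conv", "pointwise_chain", "reductions"],
)
def test_gradients_match_finite_differences(build, shapes, rng):
    arrs = [rng.standard_normal(s).astype(np.float32) * 0.5 for s in shapes]
    ts = [Tensor(a, requires_grad=True) for a in arrs]
    loss = (build(*ts) ** 2).sum()
    loss.backward()
    for a, t in zip(arrs, ts):
        ng = numeric_grad(
            lambda: float((build(Tensor(arrs[0]), Tensor(arrs[1])).data ** 2).sum()), a
        )
        rel = np.abs(t.grad - ng).max() / (np.abs(ng).max() + 1e-8)
        assert rel < 2e-2


def test_temporal_conv_matches_scipy_correlate(rng):
    """Same-padded 1xk temporal convolution equals per-map scipy correlation."""
    x = rng.standard_normal((2, 3, 4, 16)).astype(np.float32)
    w = rng.standard_normal((5, 3, 7)).astype(np.float32)
    out = F.temporal_conv(Tensor(x), Tensor(w)).data
    for n in range(2):
        for o in range(5):
            ref = np.zeros((4, 16))
            for i in range(3):
                for c in range(4):
                    ref[c] += ndimage.correlate1d(
                        x[n, i, c].astype(np.float64), w[o, i], mode="constant"
                    )
            np.testing.assert_allclose(out[n, o], ref, rtol=1e-4, atol=1e-4)


def test_conv_paths_agree(rng):
    """The im2col and offset-loop lowerings produce identical results."""
    x = Tensor(rng.standard_normal((2, 4, 3, 20)).astype(np.float32))
    w = Tensor(rng.standard_normal((5, 4, 9)).astype(np.float32))
    a = F._temporal_conv_im2col(x, w, None).data
    b = F._temporal_conv_loop(x, w, None).data
    np.testing.assert_allclose(a, b, rtol=1e-5, atol=1e-5)


def test_lstm_matches_manual_recurrence(rng):
    """Fused LSTM equals a step-by-step hand recurrence (T=3, H=2)."""
    N, T, I, H = 2, 3, 4, 2
    x = rng.standard_normal((N, T, I)).astype(np.float32)
    wx = rng.standard_normal((I, 4 * H)).astype(np.float32) * 0.5
    wh = rng.standard_normal((H, 4 * H)).astype(np.float32) * 0.5
    b = rng.standard_normal(4 * H).astype(np.float32) * 0.1
    out = F.lstm(Tensor(x), Tensor(wx), Tensor(wh), Tensor(b)).data

    def sig(z):
        return 1.0 / (1.0 + np.exp(-z))

    h = np.zeros((N, H))
    c = np.zeros((N, H))
    for t in range(T):
        z = x[:, t] @ wx + h @ wh + b
        i_g, f_g = sig(z[:, :H]), sig(z[:, H : 2 * H])
        g_g, o_g = np.tanh(z[:, 2 * H : 3 * H]), sig(z[:, 3 * H :])
        c = f_g * c + i_g * g_g
        h = o_g * np.tanh(c)
        np.testing.assert_allclose(out[:, t], h, rtol=1e-5, atol=1e-6)


def test_avg_pool_time_drops_trailing_remainder(rng):
    x = Tensor(rng.standard_normal((2, 3, 11)).astype(np.float32))
    out = F.avg_pool_time(x, 4)
    assert out.shape == (2, 3, 2)
    np.testing.assert_allclose(out.data, x.data[..., :8].reshape(2, 3, 2, 4).mean(-1), rtol=1e-6)


def test_softmax_rows_sum_to_one(rng):
    z = Tensor(rng.standard_normal((5, 7)).astype(np.float32) * 10)
    p = z.softmax(axis=1).data
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert (p >= 0).all()


def test_batchnorm_normalizes_then_tracks_running_stats(rng):
    bn = BatchNorm(3)
    x = Tensor(rng.standard_normal((8, 3, 2, 10)).astype(np.float32) * 3 + 1)
    out = bn(x).data
    np.testing.assert_allclose(out.mean(axis=(0, 2, 3)), 0.0, atol=1e-5)
    np.testing.assert_allclose(out.std(axis=(0, 2, 3)), 1.0, atol=1e-3)
    bn.eval()
    out_eval = bn(x).data  # uses running stats, finite and close in scale
    assert np.isfinite(out_eval).all()


def test_adam_minimizes_quadratic():
    p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
    opt = Adam([p], lr=0.1)
    for _ in range(200):
        loss = (p * p).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.abs(p.data).max() < 1e-2


def test_count_parameters_closed_forms(rng):
    # bias-free 1x1 convolution, 4 -> 8 depth: 4 * 8 = 32 scalars
    from hafusenet.nn import TemporalConv

    conv = TemporalConv(4, 8, 1, rng, bias=False)
    assert count_parameters(conv) == 32
    lin = Linear(3, 5, rng)
    assert count_parameters(lin) == 3 * 5 + 5
    assert count_parameters(None) == 0
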