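"""Fused differentiable kernels: convolution, normalization, attention pieces.

Each function performs the forward pass with plain numpy (convolutions are
decomposed into one GEMM per kernel tap, which keeps peak memory at one
feature map instead of a full im2col buffer) and attaches a hand-derived
backward closure.  All kernels are exercised against central finite
differences in the test suite.
"""

from __future__ import annotations

import functools

import numpy as np

from .tensor import Tensor, _accum, _make


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation. x: (B,Cin,H,W); w: (Cout,Cin,Kh,Kw)."""
    B, Cin, H, W = x.data.shape
    Cout, Cin_w, Kh, Kw = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input has {Cin}, weight expects {Cin_w}")
    s, p, d = stride, padding, dilation
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[2:]
    Hout = (Hp - d * (Kh - 1) - 1) // s + 1
    Wout = (Wp - d * (Kw - 1) - 1) // s + 1
    if Hout < 1 or Wout < 1:
        raise ValueError("kernel does not fit input")
    L = Hout * Wout
    out = np.zeros((B, Cout, L), dtype=np.float32)
    for ki in range(Kh):
        for kj in range(Kw):
            xs = xp[:, :, ki * d: ki * d + (Hout - 1) * s + 1: s,
                    kj * d: kj * d + (Wout - 1) * s + 1: s]
            out += np.matmul(w.data[:, :, ki, kj], xs.reshape(B, Cin, L))
    out = out.reshape(B, Cout, Hout, Wout)
    if b is not None:
        out += b.data.reshape(1, Cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    res = _make(out, parents)
    if res.requires_grad:
        def bw(g):
            gl = g.reshape(B, Cout, L)
            if b is not None:
                _accum(b, g.sum(axis=(0, 2, 3)))
            gw = np.zeros_like(w.data)
            gxp = np.zeros_like(xp)
            for ki in range(Kh):
                for kj in range(Kw):
                    hsl = slice(ki * d, ki * d + (Hout - 1) * s + 1, s)
                    wsl = slice(kj * d, kj * d + (Wout - 1) * s + 1, s)
                    xs = xp[:, :, hsl, wsl].reshape(B, Cin, L)
                    # (B,Cout,L) @ (B,L,Cin) -> sum_B -> (Cout,Cin)
                    gw[:, :, ki, kj] = np.einsum("bol,bcl->oc", gl, xs,
                                                 optimize=True)
                    gxs = np.matmul(w.data[:, :, ki, kj].T, gl)
                    gxp[:, :, hsl, wsl] += gxs.reshape(B, Cin, Hout, Wout)
            _accum(w, gw)
            gx = gxp[:, :, p:Hp - p, p:Wp - p] if p else gxp
            _accum(x, gx)
        res._backward = bw
    return res


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Affine map over the last axis. x: (..., In); w: (Out, In)."""
    y = np.matmul(x.data, w.data.T)
    if b is not None:
        y += b.data
    parents = (x, w) if b is None else (x, w, b)
    out = _make(y, parents)
    if out.requires_grad:
        def bw(g):
            _accum(x, np.matmul(g, w.data))
            gflat = g.reshape(-1, w.data.shape[0])
            xflat = x.data.reshape(-1, w.data.shape[1])
            _accum(w, gflat.T @ xflat)
            if b is not None:
                _accum(b, gflat.sum(axis=0))
        out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = _make(xhat * gamma.data + beta.data, (x, gamma, beta))
    if out.requires_grad:
        def bw(g):
            axes = tuple(range(g.ndim - 1))
            _accum(gamma, (g * xhat).sum(axis=axes))
            _accum(beta, g.sum(axis=axes))
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            _accum(x, inv * (dxhat - m1 - xhat * m2))
        out._backward = bw
    return out


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
               eps: float = 1e-5) -> Tensor:
    """Group normalization for (B,C,H,W); gamma/beta per channel."""
    B, C, H, W = x.data.shape
    if C % groups:
        raise ValueError(f"groups ({groups}) must divide channels ({C})")
    xg = x.data.reshape(B, groups, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(B, C, H, W)
    out = _make(xhat * gamma.data.reshape(1, C, 1, 1)
                + beta.data.reshape(1, C, 1, 1), (x, gamma, beta))
    if out.requires_grad:
        def bw(g):
            _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
            _accum(beta, g.sum(axis=(0, 2, 3)))
            dxhat = (g * gamma.data.reshape(1, C, 1, 1)).reshape(B, groups, -1)
            xh = xhat.reshape(B, groups, -1)
            m1 = dxhat.mean(axis=2, keepdims=True)
            m2 = (dxhat * xh).mean(axis=2, keepdims=True)
            _accum(x, (inv * (dxhat - m1 - xh * m2)).reshape(B, C, H, W))
        out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = _make(y, (x,))
    if out.requires_grad:
        def bw(g):
            gy = g * y
            _accum(x, gy - y * gy.sum(axis=axis, keepdims=True))
        out._backward = bw
    return out


@functools.lru_cache(maxsize=64)
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (half-pixel-centres convention)."""
    if n_in == n_out:
        return np.eye(n_in, dtype=np.float32)
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.clip(np.floor(src).astype(int), 0, max(n_in - 2, 0))
    t = (src - i0).astype(np.float32)
    M = np.zeros((n_out, n_in), dtype=np.float32)
    rows = np.arange(n_out)
    M[rows, i0] += 1.0 - t
    M[rows, np.minimum(i0 + 1, n_in - 1)] += t
    return M


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resize of the last two axes of (B,C,H,W)."""
    B, C, H, W = x.data.shape
    if (H, W) == (out_h, out_w):
        return x
    Mh = _interp_matrix(H, out_h)
    Mw = _interp_matrix(W, out_w)
    y = np.matmul(np.matmul(Mh, x.data), Mw.T)
    out = _make(y, (x,))
    if out.requires_grad:
        out._backward = lambda g: _accum(x, np.matmul(np.matmul(Mh.T, g), Mw))
    return out


def bilinear_gather(grid: Tensor, ys: Tensor, xs: Tensor) -> Tensor:
    """Sample ``grid`` (N,C,H,W) at fractional points (ys, xs): (N,P) each.

    Returns (N,C,P).  Coordinates are clamped to the grid extent; the
    gradient flows to the grid values and, where not clamped, to the
    coordinates (standard differentiable bilinear sampling).
    """
    N, C, H, W = grid.data.shape
    yc = np.clip(ys.data, 0.0, H - 1.0)
    xc = np.clip(xs.data, 0.0, W - 1.0)
    ymask = ((ys.data >= 0) & (ys.data <= H - 1)).astype(np.float32)
    xmask = ((xs.data >= 0) & (xs.data <= W - 1)).astype(np.float32)
    y0 = np.clip(np.floor(yc).astype(np.int64), 0, max(H - 2, 0))
    x0 = np.clip(np.floor(xc).astype(np.int64), 0, max(W - 2, 0))
    ty = (yc - y0).astype(np.float32)
    tx = (xc - x0).astype(np.float32)
    flat = grid.data.reshape(N, C, H * W)
    idx00 = y0 * W + x0                      # (N,P)
    idx01 = idx00 + 1
    idx10 = idx00 + W
    idx11 = idx10 + 1

    def take(idx):
        return np.take_along_axis(flat, idx[:, None, :], axis=2)  # (N,C,P)

    v00, v01, v10, v11 = take(idx00), take(idx01), take(idx10), take(idx11)
    wy0 = (1.0 - ty)[:, None, :]
    wy1 = ty[:, None, :]
    wx0 = (1.0 - tx)[:, None, :]
    wx1 = tx[:, None, :]
    out_data = (wy0 * (wx0 * v00 + wx1 * v01) + wy1 * (wx0 * v10 + wx1 * v11))
    out = _make(out_data, (grid, ys, xs))
    if out.requires_grad:
        def bw(g):
            if grid.requires_grad:
                gflat = np.zeros((N * C, H * W), dtype=np.float32)
                for idx, wgt in ((idx00, wy0 * wx0), (idx01, wy0 * wx1),
                                 (idx10, wy1 * wx0), (idx11, wy1 * wx1)):
                    vals = (g * wgt).reshape(N * C, -1)
                    cols = np.broadcast_to(idx[:, None, :],
                                           (N, C, idx.shape[1])).reshape(N * C, -1)
                    np.add.at(gflat, (np.arange(N * C)[:, None], cols), vals)
                _accum(grid, gflat.reshape(N, C, H, W))
            if ys.requires_grad:
                dy = (wx0 * (v10 - v00) + wx1 * (v11 - v01))
                _accum(ys, (g * dy).sum(axis=1) * ymask)
            if xs.requires_grad:
                dx = (wy0 * (v01 - v00) + wy1 * (v11 - v10))
                _accum(xs, (g * dx).sum(axis=1) * xmask)
        out._backward = bw
    return out


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed directly from logits.

    Identical to BCE(sigmoid(z)) but numerically stable and with the exact
    gradient (sigmoid(z) - target) / N, which never saturates to zero the
    way a clamped-probability formulation does.
    """
    z = logits.data
    a = np.asarray(target, dtype=np.float32)
    if z.shape != a.shape:
        raise ValueError(f"shape mismatch: logits {z.shape} vs target {a.shape}")
    loss = np.maximum(z, 0) - z * a + np.log1p(np.exp(-np.abs(z)))
    out = _make(np.float32(loss.mean()), (logits,))
    if out.requires_grad:
        sig = np.empty_like(z)
        pos = z >= 0
        sig[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        sig[~pos] = ez / (1.0 + ez)
        out._backward = lambda g: _accum(logits, g * (sig - a) / z.size)
    return out


def take_last(x: Tensor, idx: np.ndarray) -> Tensor:
    """Differentiable gather along the last axis: out = x[..., idx]."""
    out = _make(x.data[..., idx], (x,))
    if out.requires_grad:
        def bw(g):
            lead = int(np.prod(x.data.shape[:-1], dtype=np.int64)) or 1
            gx = np.zeros((lead, x.data.shape[-1]), dtype=np.float32)
            np.add.at(gx, (np.arange(lead)[:, None], idx.reshape(-1)[None, :]),
                      g.reshape(lead, -1))
            _accum(x, gx.reshape(x.data.shape))
        out._backward = bw
    return out
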