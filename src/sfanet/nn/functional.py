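"""Differentiable operations for the tensor engine.

Convolutions are stride-1 with symmetric padding and arbitrary dilation,
implemented with a strided im2col view and ``tensordot``; the transpose
convolution is the fixed kernel-2/stride-2 upsampler the decoder uses, which
has non-overlapping output taps and therefore reduces to a single einsum.
"""

from __future__ import annotations

import numpy as np

from .tensor import DTYPE, Tensor, unbroadcast

# ---------------------------------------------------------------------------
# elementwise / algebra
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(unbroadcast(g, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(unbroadcast(g * a.data, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    def backward(g):
        a.accumulate(g * c)

    return Tensor._result(a.data * c, (a,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x.accumulate(g * mask)

    return Tensor._result(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x.accumulate(g * s * (1.0 - s))

    return Tensor._result(s, (x,), backward)


def log(x: Tensor) -> Tensor:
    def backward(g):
        x.accumulate(g / x.data)

    return Tensor._result(np.log(x.data), (x,), backward)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; the gradient is zero where the clamp is active."""
    mask = (x.data > lo) & (x.data < hi)

    def backward(g):
        x.accumulate(g * mask)

    return Tensor._result(np.clip(x.data, lo, hi), (x,), backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        x.accumulate(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    return Tensor._result(s, (x,), backward)


def l2_normalize(x: Tensor, axis: int = 1, eps: float = 1e-8) -> Tensor:
    """x / sqrt(sum x^2 + eps) along ``axis`` (smooth at the origin)."""
    sq = (x.data ** 2).sum(axis=axis, keepdims=True)
    inv = 1.0 / np.sqrt(sq + eps)
    y = x.data * inv

    def backward(g):
        dot = (g * x.data).sum(axis=axis, keepdims=True)
        x.accumulate(g * inv - x.data * dot * inv ** 3)

    return Tensor._result(y, (x,), backward)


def mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = x.data.mean(axis=axis, keepdims=keepdims)
    n = x.data.size / out_data.size

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x.accumulate(np.broadcast_to(g, x.data.shape) / n)

    return Tensor._result(out_data, (x,), backward)


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x.accumulate(np.broadcast_to(g, x.data.shape).copy())

    return Tensor._result(out_data, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    def backward(g):
        x.accumulate(g.reshape(x.data.shape))

    return Tensor._result(x.data.reshape(shape), (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.accumulate(g[tuple(idx)])

    return Tensor._result(out_data, tuple(tensors), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x (N, Cin) @ w.T (Cin, Cout) + b."""
    out_data = x.data @ w.data.T
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        if x.requires_grad:
            x.accumulate(g @ w.data)
        if w.requires_grad:
            w.accumulate(g.T @ x.data)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._result(out_data, parents, backward)


# ---------------------------------------------------------------------------
# spatial ops (NCHW)
# ---------------------------------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int, dh: int, dw: int, ho: int, wo: int):
    """Strided view (N, C, kh, kw, Ho, Wo) over the padded input — no copy."""
    n, c = xp.shape[:2]
    s = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, (n, c, kh, kw, ho, wo), (s[0], s[1], s[2] * dh, s[3] * dw, s[2], s[3])
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding: int, dilation: int = 1) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NCHW x (Cout,Cin,kh,kw)."""
    n, cin, h, wd = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input has {cin}, kernel expects {cin_w}")
    p, d = padding, dilation
    ho = h + 2 * p - d * (kh - 1)
    wo = wd + 2 * p - d * (kw - 1)
    if ho < 1 or wo < 1:
        raise ValueError("kernel does not fit input")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = _im2col(xp, kh, kw, d, d, ho, wo)
    # (Cout,Cin,kh,kw) x (N,Cin,kh,kw,Ho,Wo) -> (Cout,N,Ho,Wo)
    out_data = np.tensordot(w.data, cols, axes=([1, 2, 3], [1, 2, 3]))
    out_data = np.ascontiguousarray(out_data.transpose(1, 0, 2, 3))
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)

    def backward(g):
        gt = g.transpose(1, 0, 2, 3)  # (Cout, N, Ho, Wo)
        if w.requires_grad:
            w.accumulate(np.tensordot(gt, cols, axes=([1, 2, 3], [0, 4, 5])))
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            # d cols[n,c,i,j,:,:] = sum_o w[o,c,i,j] * g[n,o,:,:]
            dcols = np.einsum("ocij,nohw->ncijhw", w.data, g, optimize=True)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i * d : i * d + ho, j * d : j * d + wo] += dcols[:, :, i, j]
            if p:
                x.accumulate(dxp[:, :, p : p + h, p : p + wd])
            else:
                x.accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._result(out_data, parents, backward)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Kernel-2 stride-2 transpose convolution: doubles H and W exactly.

    Weight layout (Cin, Cout, 2, 2); taps do not overlap, so the op is one
    einsum and its adjoint.
    """
    n, cin, h, wd = x.data.shape
    if w.data.shape[0] != cin:
        raise ValueError("channel mismatch in transpose convolution")
    cout = w.data.shape[1]
    y6 = np.einsum("ncij,coab->noiajb", x.data, w.data, optimize=True)
    out_data = np.ascontiguousarray(y6.reshape(n, cout, 2 * h, 2 * wd))
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)

    def backward(g):
        g6 = g.reshape(n, cout, h, 2, wd, 2)
        if x.requires_grad:
            x.accumulate(np.einsum("noiajb,coab->ncij", g6, w.data, optimize=True))
        if w.requires_grad:
            w.accumulate(np.einsum("ncij,noiajb->coab", x.data, g6, optimize=True))
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._result(out_data, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 needs even spatial dimensions")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out_data = xr.max(axis=(3, 5))
    mask = xr == out_data[:, :, :, None, :, None]
    # break ties: keep only the first max in each 2x2 window
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    first = np.cumsum(flat, axis=-1) == 1
    mask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)

    def backward(g):
        gx = mask * g[:, :, :, None, :, None]
        x.accumulate(gx.reshape(n, c, h, w))

    return Tensor._result(out_data, (x,), backward)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Bilinear interpolation matrix, half-pixel-centre convention."""
    m = np.zeros((n_out, n_in), dtype=DTYPE)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        m[i, lo_c] += 1.0 - frac
        m[i, hi_c] += frac
    return m


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Bilinear upsampling by an integer factor (separable matrix form)."""
    if factor == 1:
        return x
    n, c, h, w = x.data.shape
    mh = _interp_matrix(h * factor, h)
    mw = _interp_matrix(w * factor, w)
    out_data = np.einsum("ab,ncbd,ed->ncae", mh, x.data, mw, optimize=True)

    def backward(g):
        x.accumulate(np.einsum("ab,ncae,ed->ncbd", mh, g, mw, optimize=True))

    return Tensor._result(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Spatial mean per channel: (N, C, H, W) -> (N, C)."""
    return mean(x, axis=(2, 3))


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (N, H, W) per channel; updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, -1, 1, 1)) * inv_std.reshape(1, -1, 1, 1)
    out_data = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = g * gamma.data.reshape(1, -1, 1, 1)
            if training:
                mean_gs = gs.mean(axis=(0, 2, 3), keepdims=True)
                mean_gs_xhat = (gs * xhat).mean(axis=(0, 2, 3), keepdims=True)
                dx = (gs - mean_gs - xhat * mean_gs_xhat) * inv_std.reshape(1, -1, 1, 1)
            else:
                dx = gs * inv_std.reshape(1, -1, 1, 1)
            x.accumulate(dx)

    return Tensor._result(out_data, (x, gamma, beta), backward)
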