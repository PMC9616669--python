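"""Independent reference implementations used as test oracles.

Everything here is written with plain numpy loops/array arithmetic, kept
deliberately separate from the package's tensor engine so block outputs can
be checked against an independently coded evaluation of the same equation
chain (reading only the blocks' parameter arrays).
"""

import numpy as np


def naive_conv2d(x, w, b=None, padding=1, dilation=1):
    """Sliding-window convolution, stride 1, NCHW; direct loop evaluation."""
    n, cin, h, wd = x.shape
    cout, _, kh, kw = w.shape
    p, d = padding, dilation
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    ho = h + 2 * p - d * (kh - 1)
    wo = wd + 2 * p - d * (kw - 1)
    out = np.zeros((n, cout, ho, wo))
    for i in range(ho):
        for j in range(wo):
            window = xp[:, :, i : i + d * (kh - 1) + 1 : d, j : j + d * (kw - 1) + 1 : d]
            out[:, :, i, j] = np.einsum("ncij,ocij->no", window, w)
    if b is not None:
        out += b.reshape(1, -1, 1, 1)
    return out


def bn_eval(x, gamma, beta, mean, var, eps=1e-5):
    """Batch norm in inference mode with the given statistics."""
    inv = 1.0 / np.sqrt(var + eps)
    return gamma.reshape(1, -1, 1, 1) * (x - mean.reshape(1, -1, 1, 1)) \
        * inv.reshape(1, -1, 1, 1) + beta.reshape(1, -1, 1, 1)


def convbn_oracle(x, cb):
    """Naive evaluation of a ConvBN module in eval mode."""
    y = naive_conv2d(x, cb.conv.weight.data, cb.conv.bias.data,
                     cb.conv.padding, cb.conv.dilation)
    y = bn_eval(y, cb.bn.weight.data, cb.bn.bias.data,
                cb.bn.running_mean, cb.bn.running_var, cb.bn.eps)
    return np.maximum(y, 0.0)


def channel_attention_oracle(x, att):
    """mean -> matmul -> relu -> matmul -> sigmoid, as dense algebra."""
    s = x.mean(axis=(2, 3))
    h = np.maximum(s @ att.fc1.weight.data.T + att.fc1.bias.data, 0.0)
    z = h @ att.fc2.weight.data.T + att.fc2.bias.data
    return 1.0 / (1.0 + np.exp(-z))


def softmax_channels(x):
    e = np.exp(x - x.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def rasf_oracle(x, blk):
    """Step-by-step evaluation of the residual atrous aggregation chain."""
    f1 = convbn_oracle(x, blk.branch1)
    f2 = convbn_oracle(x, blk.branch2)
    f3 = convbn_oracle(x, blk.branch3)
    f12 = f1 + f2
    f23 = f2 * f3
    f122 = convbn_oracle(f12, blk.fuse12)
    weights = channel_attention_oracle(f122, blk.attention)
    f1p = weights[:, :, None, None] * f1
    f123 = softmax_channels(f23)
    f2p = f123 * f3
    fused = np.concatenate([f1p, f2p], axis=1) if blk.combine == "concat" else f1p + f2p
    red = naive_conv2d(fused, blk.reduce.weight.data, blk.reduce.bias.data, 1, 1)
    return x + red


def aff_newlow_oracle(low1, low2, blk):
    """GAP -> broadcast multiply -> L2 normalize, in scalar/array code."""
    gate = convbn_oracle(low1, blk.project).mean(axis=(2, 3))
    gated = gate[:, :, None, None] * low2
    norm = np.sqrt((gated ** 2).sum(axis=1, keepdims=True) + blk.eps)
    return gated / norm


def naive_upsample_bilinear(x, factor):
    """Half-pixel-centre bilinear upsampling via explicit per-pixel loops."""
    if factor == 1:
        return x.copy()
    n, c, h, w = x.shape
    out = np.zeros((n, c, h * factor, w * factor))
    for i in range(h * factor):
        si = (i + 0.5) / factor - 0.5
        i0 = int(np.floor(si))
        fi = si - i0
        i0c, i1c = min(max(i0, 0), h - 1), min(max(i0 + 1, 0), h - 1)
        for j in range(w * factor):
            sj = (j + 0.5) / factor - 0.5
            j0 = int(np.floor(sj))
            fj = sj - j0
            j0c, j1c = min(max(j0, 0), w - 1), min(max(j0 + 1, 0), w - 1)
            out[:, :, i, j] = ((1 - fi) * (1 - fj) * x[:, :, i0c, j0c]
                               + (1 - fi) * fj * x[:, :, i0c, j1c]
                               + fi * (1 - fj) * x[:, :, i1c, j0c]
                               + fi * fj * x[:, :, i1c, j1c])
    return out


def mpf_oracle(xh1, xh2, xh3, blk):
    """softmax -> GAP -> activation gate, applied to the convolved finest map."""
    f1 = convbn_oracle(naive_upsample_bilinear(xh1, 1), blk.conv1)
    x1 = convbn_oracle(naive_upsample_bilinear(xh2, 2), blk.conv2)
    x2 = convbn_oracle(naive_upsample_bilinear(xh3, 4), blk.conv3)
    gate = softmax_channels(x1 * x2).mean(axis=(2, 3))
    if blk.activation == "relu":
        gate = np.maximum(gate, 0.0)
    else:
        gate = gate / np.sqrt((gate ** 2).sum(axis=1, keepdims=True) + 1e-8)
    return f1 * gate[:, :, None, None]


def mann_whitney_auc(scores, labels):
    """Brute-force pairwise AUC: P(score_pos > score_neg) with ties as 1/2."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))
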