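"""Building blocks of the segmentation network.

Four operators, all pure tensor-to-tensor with explicit shape contracts:

* :class:`ConvBN` — the elementary ``ReLU(BN(conv3x3(x)))`` unit used
  throughout the encoder and decoder.
* :class:`ChannelAttention` — squeeze-and-excitation style channel gate:
  global average pooling, a two-layer bottleneck MLP and a sigmoid.
* :class:`RASF` — residual atrous spatial feature aggregation: three
  parallel dilated 3x3 branches (rates 1, 3, 5) fused by summation and
  elementwise product, re-weighted by channel attention and a channel
  softmax, and added back to the input through a residual connection.
* :class:`AFF` — attention feature fusion for skip connections: a channel
  gate computed from the pre-subsampling feature recalibrates the
  post-subsampling feature (L2-normalized), which is concatenated with the
  raw skip and the transpose-convolved decoder feature.
* :class:`MPF` — multi-path fusion head: coarse decoder stages are
  upsampled, multiplied, softmax-normalized over channels and pooled into a
  per-channel gate that modulates the finest decoder stage.

Shapes are NCHW.  Every block preserves batch size and spatial size.
"""

from __future__ import annotations

import numpy as np

from .nn import BatchNorm2d, Conv2d, ConvTranspose2x2, Linear, Module, Sequential
from .nn import functional as F
from .nn.tensor import Tensor


class ConvBN(Module):
    """3x3 convolution + batch norm + ReLU; spatial size preserved."""

    def __init__(self, in_channels: int, out_channels: int, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        self.conv = Conv2d(in_channels, out_channels, kernel_size=3,
                           padding=dilation, dilation=dilation, rng=rng)
        self.bn = BatchNorm2d(out_channels)
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}")
        return F.relu(self.bn(self.conv(x)))


class ChannelAttention(Module):
    """GAP -> FC(C -> C/r) -> ReLU -> FC(C/r -> C) -> sigmoid.

    Returns per-channel weights in (0, 1), shape (N, C).
    """

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if reduction > channels:
            raise ValueError(f"reduction {reduction} exceeds channel count {channels}")
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        s = F.global_avg_pool(x)                     # (N, C)
        return F.sigmoid(self.fc2(F.relu(self.fc1(s))))


class RASF(Module):
    """Residual atrous spatial feature aggregation block.

    Input and output both have ``channels`` feature maps at unchanged
    resolution.  With every learned parameter set to zero the block is the
    identity map: the residual branch ends in a linear (non-normalized)
    reduction convolution, so a zero branch contributes exactly zero.
    """

    def __init__(self, channels: int, dilation_rates=(1, 3, 5), reduction: int = 16,
                 combine: str = "concat", rng: np.random.Generator | None = None):
        super().__init__()
        if any(d < 1 for d in dilation_rates):
            raise ValueError("dilation rates must be >= 1")
        if len(dilation_rates) != 3:
            raise ValueError("exactly three dilated branches are required")
        if combine not in ("concat", "sum"):
            raise ValueError("combine must be 'concat' or 'sum'")
        d1, d2, d3 = dilation_rates
        self.branch1 = ConvBN(channels, channels, dilation=d1, rng=rng)
        self.branch2 = ConvBN(channels, channels, dilation=d2, rng=rng)
        self.branch3 = ConvBN(channels, channels, dilation=d3, rng=rng)
        self.fuse12 = ConvBN(channels, channels, rng=rng)
        self.attention = ChannelAttention(channels, reduction, rng=rng)
        self.combine = combine
        reduce_in = 2 * channels if combine == "concat" else channels
        self.reduce = Conv2d(reduce_in, channels, kernel_size=3, padding=1, rng=rng)
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        f1 = self.branch1(x)
        f2 = self.branch2(x)
        f3 = self.branch3(x)
        f12 = f1 + f2                                   # tensor summation
        f23 = F.mul(f2, f3)                             # elementwise product
        f122 = self.fuse12(f12)
        weights = self.attention(f122)                  # (N, C) in (0,1)
        f1p = F.mul(F.reshape(weights, (*weights.shape, 1, 1)), f1)
        f123 = F.softmax(f23, axis=1)                   # channel softmax per pixel
        f2p = F.mul(f123, f3)
        if self.combine == "concat":
            fused = F.concat([f1p, f2p], axis=1)
        else:
            fused = f1p + f2p
        return x + self.reduce(fused)


class AFF(Module):
    """Attention feature fusion skip connection.

    ``low1`` is the feature entering the encoder level (before its convs),
    ``low2`` the encoder level's conv output, ``high`` the decoder feature one
    level below (half of ``low2``'s resolution).  A 3x3 conv projects
    ``low1`` to ``low2``'s channel count, a global average pool turns it into
    a channel gate that recalibrates ``low2``; the gated map is
    L2-normalized over channels and concatenated with ``low2`` and the
    transpose-convolved ``high``.  Output channels:
    ``2 * channels(low2) + up_channels``.
    """

    def __init__(self, low1_channels: int, low2_channels: int, high_channels: int,
                 up_channels: int | None = None, eps: float = 1e-8,
                 rng: np.random.Generator | None = None):
        super().__init__()
        up_channels = up_channels if up_channels is not None else low2_channels
        self.project = ConvBN(low1_channels, low2_channels, rng=rng)
        self.up = ConvTranspose2x2(high_channels, up_channels, rng=rng)
        self.up_bn = BatchNorm2d(up_channels)
        self.low1_channels = low1_channels
        self.low2_channels = low2_channels
        self.high_channels = high_channels
        self.out_channels = 2 * low2_channels + up_channels
        self.eps = eps

    def forward(self, low1: Tensor, low2: Tensor, high: Tensor) -> Tensor:
        if low1.shape[1] != self.low1_channels or low2.shape[1] != self.low2_channels:
            raise ValueError("channel mismatch on low-level inputs")
        if high.shape[2] * 2 != low2.shape[2] or high.shape[3] * 2 != low2.shape[3]:
            raise ValueError("high-level input must be at half of low2's resolution")
        gate = F.global_avg_pool(self.project(low1))           # (N, C_low2)
        gated = F.mul(F.reshape(gate, (*gate.shape, 1, 1)), low2)
        new_low = F.l2_normalize(gated, axis=1, eps=self.eps)  # F_newlow
        f_re = F.concat([low2, new_low], axis=1)
        up = F.relu(self.up_bn(self.up(high)))
        return F.concat([f_re, up], axis=1)


class MPF(Module):
    """Multi-path fusion of the three finest decoder stages.

    ``xh1`` is at full resolution, ``xh2`` at 1/2, ``xh3`` at 1/4.  The two
    coarse stages are bilinearly upsampled to full resolution, convolved to a
    common channel count, multiplied, softmax-normalized over channels and
    global-average-pooled into a per-channel gate (activated by ReLU by
    default, L2 normalization optionally) that multiplies the convolved
    finest stage.
    """

    def __init__(self, c1: int, c2: int, c3: int, common: int | None = None,
                 activation: str = "relu", rng: np.random.Generator | None = None):
        super().__init__()
        if activation not in ("relu", "l2norm"):
            raise ValueError("activation must be 'relu' or 'l2norm'")
        common = common if common is not None else c1
        self.conv1 = ConvBN(c1, common, rng=rng)
        self.conv2 = ConvBN(c2, common, rng=rng)
        self.conv3 = ConvBN(c3, common, rng=rng)
        self.activation = activation
        self.out_channels = common

    def forward(self, xh1: Tensor, xh2: Tensor, xh3: Tensor) -> Tensor:
        h, w = xh1.shape[2], xh1.shape[3]
        if xh2.shape[2] * 2 != h or xh3.shape[2] * 4 != h:
            raise ValueError("decoder stages must be at 1, 1/2 and 1/4 resolution")
        f1 = self.conv1(F.upsample_bilinear(xh1, 1))
        x1 = self.conv2(F.upsample_bilinear(xh2, 2))
        x2 = self.conv3(F.upsample_bilinear(xh3, 4))
        prod = F.softmax(F.mul(x1, x2), axis=1)
        gate = F.global_avg_pool(prod)                          # (N, C)
        if self.activation == "relu":
            gate = F.relu(gate)
        else:
            gate = F.l2_normalize(gate, axis=1)
        return F.mul(f1, F.reshape(gate, (*gate.shape, 1, 1)))
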