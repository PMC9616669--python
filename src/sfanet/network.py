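"""Full segmentation network assembly and its ablation variants.

A four-level U-shaped encoder-decoder: each encoder level is two ConvBN
units followed by 2x2 max-pooling, the bottleneck is two ConvBN units plus
(variant-dependent) a RASF block, each decoder level fuses its skip either
through an AFF block or a vanilla transpose-conv + concatenation, and the
head is either the MPF fusion of the three finest decoder stages or a plain
1x1 convolution, always followed by a sigmoid.

Five constructible variants mirror the ablation ladder:
``baseline`` (no extra blocks), ``rasf``, ``aff``, ``rasf_aff`` and
``full`` (RASF + AFF + MPF).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .blocks import AFF, MPF, RASF, ConvBN
from .nn import Conv2d, Module, ModuleList, Sequential
from .nn import functional as F
from .nn.tensor import Tensor

VARIANTS = ("baseline", "rasf", "aff", "rasf_aff", "full")


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``base_width`` is the channel count at the finest level and doubles at
    each of the four levels; the bottleneck therefore carries
    ``base_width * 16`` channels.  ``patch_size`` must be divisible by
    ``2**depth`` so that four poolings land on integer sizes.
    """

    in_channels: int = 1
    base_width: int = 32
    depth: int = 4
    growth: int = 2
    dilation_rates: tuple = (1, 3, 5)
    attention_ratio: int = 16
    variant: str = "full"
    patch_size: int = 96

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.depth != 4:
            raise ValueError("only depth 4 is supported")
        if self.patch_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"patch size {self.patch_size} not divisible by {2 ** self.depth}")
        if self.base_width < 4:
            raise ValueError("base width must be >= 4")
        if self.in_channels not in (1, 3):
            raise ValueError("in_channels must be 1 or 3")
        self.dilation_rates = tuple(self.dilation_rates)

    @property
    def use_rasf(self) -> bool:
        return self.variant in ("rasf", "rasf_aff", "full")

    @property
    def use_aff(self) -> bool:
        return self.variant in ("aff", "rasf_aff", "full")

    @property
    def use_mpf(self) -> bool:
        return self.variant == "full"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dilation_rates"] = list(self.dilation_rates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


class _ConvTransposeUp(Module):
    """Transpose-conv upsampler with BN+ReLU, used by the vanilla skip path."""

    def __init__(self, in_channels, out_channels, rng):
        super().__init__()
        from .nn import BatchNorm2d, ConvTranspose2x2

        self.up = ConvTranspose2x2(in_channels, out_channels, rng=rng)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x):
        return F.relu(self.bn(self.up(x)))


class SFANet(Module):
    """U-shaped vessel segmentation network with optional RASF/AFF/MPF blocks."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.config = config
        w = config.base_width
        g = config.growth
        widths = [w * g ** k for k in range(config.depth + 1)]  # c1..c4, bottleneck
        self.widths = widths

        # encoder: level k maps widths[k-1] channels in -> widths[k-1] out
        enc = []
        c_in = config.in_channels
        for k in range(config.depth):
            enc.append(Sequential(ConvBN(c_in, widths[k], rng=rng),
                                  ConvBN(widths[k], widths[k], rng=rng)))
            c_in = widths[k]
        self.encoder = ModuleList(enc)

        self.bottleneck = Sequential(ConvBN(widths[3], widths[4], rng=rng),
                                     ConvBN(widths[4], widths[4], rng=rng))
        self.rasf = (RASF(widths[4], config.dilation_rates,
                          config.attention_ratio, rng=rng)
                     if config.use_rasf else None)

        # decoder: level k (1-based, finest first) consumes high with widths[k]
        # channels after upsampling and the level-k skip
        skips, dec = [], []
        for k in range(config.depth):          # k = 0 -> level 1 (finest)
            c_k = widths[k]
            c_high = widths[k + 1]
            if config.use_aff:
                c_low1 = config.in_channels if k == 0 else widths[k - 1]
                skips.append(AFF(c_low1, c_k, c_high, up_channels=c_k, rng=rng))
                dec_in = 3 * c_k
            else:
                skips.append(_ConvTransposeUp(c_high, c_k, rng))
                dec_in = 2 * c_k
            dec.append(Sequential(ConvBN(dec_in, c_k, rng=rng),
                                  ConvBN(c_k, c_k, rng=rng)))
        self.skips = ModuleList(skips)
        self.decoder = ModuleList(dec)

        self.mpf = (MPF(widths[0], widths[1], widths[2], common=widths[0], rng=rng)
                    if config.use_mpf else None)
        self.head = Conv2d(widths[0], 1, kernel_size=1, padding=0, rng=rng)

    # -- forward --------------------------------------------------------------

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        n, c, h, w = x.shape
        if c != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, got {c}")
        if h % 16 or w % 16:
            raise ValueError("input spatial size must be divisible by 16")

        enc_outs, pre_pool_inputs = [], []
        cur = x
        for level in self.encoder:
            pre_pool_inputs.append(cur)   # tensor entering this level
            cur = level(cur)
            enc_outs.append(cur)
            cur = F.maxpool2x2(cur)

        cur = self.bottleneck(cur)
        if self.rasf is not None:
            cur = self.rasf(cur)

        dec_outs = [None] * self.config.depth
        for k in reversed(range(self.config.depth)):   # coarsest first
            if self.config.use_aff:
                fused = self.skips[k](pre_pool_inputs[k], enc_outs[k], cur)
            else:
                up = self.skips[k](cur)
                fused = F.concat([enc_outs[k], up], axis=1)
            cur = self.decoder[k](fused)
            dec_outs[k] = cur

        if self.mpf is not None:
            cur = self.mpf(dec_outs[0], dec_outs[1], dec_outs[2])
        else:
            cur = dec_outs[0]
        return F.sigmoid(self.head(cur))

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Eval-mode forward on a raw array; returns probabilities."""
        was_training = self.training
        self.eval()
        out = self.forward(Tensor(batch)).data
        self.train(was_training)
        return out

    # -- introspection --------------------------------------------------------

    def block_counts(self) -> dict:
        counts = {"rasf": 0, "aff": 0, "mpf": 0}
        for m in self.modules():
            if isinstance(m, RASF):
                counts["rasf"] += 1
            elif isinstance(m, AFF):
                counts["aff"] += 1
            elif isinstance(m, MPF):
                counts["mpf"] += 1
        return counts

    def summary(self) -> str:
        lines = [f"SFANet(variant={self.config.variant}, "
                 f"base_width={self.config.base_width}, "
                 f"in_channels={self.config.in_channels})"]
        for name, mod in self._modules.items():
            lines.append(f"  {name}: {type(mod).__name__} "
                         f"({mod.num_parameters():,} params)")
        lines.append(f"  total parameters: {self.num_parameters():,}")
        return "\n".join(lines)


def build(config: NetworkConfig, seed: int | None = None) -> SFANet:
    """Construct a network with reproducible initialization."""
    rng = np.random.default_rng(seed)
    return SFANet(config, rng=rng)


def count_parameters(net: SFANet) -> int:
    """Total number of trainable parameter entries."""
    return net.num_parameters()
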