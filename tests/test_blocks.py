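"""Block-level oracles: every equation chain is re-evaluated independently."""

import numpy as np
import pytest

from oracles import (
    aff_newlow_oracle,
    channel_attention_oracle,
    convbn_oracle,
    mpf_oracle,
    naive_conv2d,
    rasf_oracle,
)
from sfanet.blocks import AFF, MPF, RASF, ChannelAttention, ConvBN
from sfanet.nn.tensor import Tensor

RNG = np.random.default_rng(21)


def rng():
    return np.random.default_rng(33)


class TestConvBN:
    def test_output_nonnegative_and_shape_preserved(self):
        cb = ConvBN(3, 5, rng=rng())
        out = cb(Tensor(RNG.normal(size=(2, 3, 96, 96))))
        assert out.shape == (2, 5, 96, 96)
        assert (out.data >= 0).all()

    def test_eval_mode_matches_naive_convolution(self):
        cb = ConvBN(1, 2, rng=rng()).eval()
        x = RNG.normal(size=(1, 1, 5, 5))
        got = cb(Tensor(x)).data
        want = convbn_oracle(x, cb)     # sliding-window loop + frozen BN + ReLU
        assert np.allclose(got, want, atol=1e-10)

    def test_dilated_unit_matches_naive_convolution(self):
        cb = ConvBN(2, 2, dilation=3, rng=rng()).eval()
        x = RNG.normal(size=(1, 2, 9, 9))
        assert np.allclose(cb(Tensor(x)).data, convbn_oracle(x, cb), atol=1e-10)

    def test_channel_mismatch_raises(self):
        with pytest.raises(ValueError, match="channels"):
            ConvBN(3, 5, rng=rng())(Tensor(np.zeros((1, 4, 8, 8))))

    def test_invalid_dilation_raises(self):
        with pytest.raises(ValueError):
            ConvBN(3, 5, dilation=0)


class TestChannelAttention:
    def test_weights_strictly_inside_unit_interval(self):
        att = ChannelAttention(8, reduction=2, rng=rng())
        w = att(Tensor(RNG.normal(size=(3, 8, 6, 6)))).data
        assert ((w > 0) & (w < 1)).all()

    def test_gap_of_constant_input_is_the_constant(self):
        x = np.ones((1, 4, 8, 8)) * np.arange(1, 5).reshape(1, 4, 1, 1)
        from sfanet.nn import functional as F

        pooled = F.global_avg_pool(Tensor(x)).data
        assert np.allclose(pooled, [[1, 2, 3, 4]])
        assert np.allclose(pooled, x.mean(axis=(2, 3)))

    def test_matches_dense_algebra_oracle(self):
        att = ChannelAttention(4, reduction=2, rng=rng())
        x = RNG.normal(size=(2, 4, 8, 8))
        assert np.allclose(att(Tensor(x)).data,
                           channel_attention_oracle(x, att), atol=1e-12)

    def test_reduction_larger_than_channels_raises(self):
        with pytest.raises(ValueError, match="reduction"):
            ChannelAttention(4, reduction=8)


class TestRASF:
    def test_shape_closure(self):
        blk = RASF(4, reduction=2, rng=rng())
        x = Tensor(RNG.normal(size=(2, 4, 16, 16)))
        assert blk(x).shape == x.shape

    def test_zero_weights_give_exact_identity(self):
        blk = RASF(4, reduction=2, rng=rng())
        for p in blk.parameters():
            p.data[...] = 0.0
        x = RNG.normal(size=(2, 4, 8, 8))
        assert np.array_equal(blk(Tensor(x)).data, x)

    @pytest.mark.parametrize("combine", ["concat", "sum"])
    def test_full_chain_matches_step_by_step_oracle(self, combine):
        blk = RASF(2, reduction=2, combine=combine, rng=rng()).eval()
        x = RNG.integers(-2, 3, size=(1, 2, 4, 4)).astype(float)
        assert np.allclose(blk(Tensor(x)).data, rasf_oracle(x, blk), atol=1e-5)

    def test_channel_softmax_normalized_inside_chain(self):
        from sfanet.nn import functional as F

        x = Tensor(RNG.normal(size=(2, 6, 4, 4)))
        s = F.softmax(x, axis=1).data
        assert np.allclose(s.sum(axis=1), 1.0, atol=1e-5)

    def test_rejects_bad_dilations(self):
        with pytest.raises(ValueError):
            RASF(4, dilation_rates=(0, 3, 5), reduction=2)


class TestAFF:
    def make(self):
        return AFF(low1_channels=3, low2_channels=2, high_channels=4,
                   up_channels=2, rng=rng()).eval()

    def test_output_resolution_and_channel_arithmetic(self):
        blk = self.make()
        low1 = Tensor(RNG.normal(size=(1, 3, 8, 8)))
        low2 = Tensor(RNG.normal(size=(1, 2, 8, 8)))
        high = Tensor(RNG.normal(size=(1, 4, 4, 4)))
        out = blk(low1, low2, high)
        assert out.shape == (1, blk.out_channels, 8, 8)
        assert blk.out_channels == 2 + 2 + 2   # low2 + F_newlow + upsampled high

    def test_newlow_matches_scalar_oracle(self):
        blk = self.make()
        low1 = RNG.normal(size=(1, 3, 4, 4))
        low2 = RNG.normal(size=(1, 2, 4, 4))
        high = RNG.normal(size=(1, 4, 2, 2))
        out = blk(Tensor(low1), Tensor(low2), Tensor(high)).data
        newlow = out[:, 2:4]                   # concat slot after raw low2
        assert np.allclose(newlow, aff_newlow_oracle(low1, low2, blk), atol=1e-5)

    def test_resolution_mismatch_raises(self):
        blk = self.make()
        with pytest.raises(ValueError, match="resolution"):
            blk(Tensor(np.zeros((1, 3, 8, 8))), Tensor(np.zeros((1, 2, 8, 8))),
                Tensor(np.zeros((1, 4, 3, 3))))

    def test_channel_mismatch_raises(self):
        blk = self.make()
        with pytest.raises(ValueError, match="channel"):
            blk(Tensor(np.zeros((1, 5, 8, 8))), Tensor(np.zeros((1, 2, 8, 8))),
                Tensor(np.zeros((1, 4, 4, 4))))


class TestMPF:
    def make(self, activation="relu"):
        return MPF(c1=2, c2=3, c3=4, common=2, activation=activation,
                   rng=rng()).eval()

    def test_output_at_full_patch_resolution(self):
        blk = MPF(c1=4, c2=4, c3=4, common=4, rng=rng()).eval()
        out = blk(Tensor(RNG.normal(size=(1, 4, 96, 96))),
                  Tensor(RNG.normal(size=(1, 4, 48, 48))),
                  Tensor(RNG.normal(size=(1, 4, 24, 24))))
        assert out.shape == (1, 4, 96, 96)

    def test_gate_matches_scalar_oracle(self):
        for activation in ("relu", "l2norm"):
            blk = self.make(activation)
            xh1 = RNG.normal(size=(1, 2, 8, 8))
            xh2 = RNG.normal(size=(1, 3, 4, 4))
            xh3 = RNG.normal(size=(1, 4, 2, 2))
            got = blk(Tensor(xh1), Tensor(xh2), Tensor(xh3)).data
            assert np.allclose(got, mpf_oracle(xh1, xh2, xh3, blk), atol=1e-5)

    def test_wrong_pyramid_raises(self):
        blk = self.make()
        with pytest.raises(ValueError, match="resolution"):
            blk(Tensor(np.zeros((1, 2, 8, 8))), Tensor(np.zeros((1, 3, 5, 5))),
                Tensor(np.zeros((1, 4, 2, 2))))


class TestBlockProperties:
    def test_outputs_finite_for_finite_inputs(self):
        blk = RASF(4, reduction=2, rng=rng())
        out = blk(Tensor(RNG.normal(size=(3, 4, 8, 8)) * 10))
        assert np.isfinite(out.data).all()
        assert out.shape[0] == 3    # batch preserved

    @pytest.mark.parametrize("case", ["rasf", "aff", "mpf", "convbn"])
    def test_gradient_reaches_every_input(self, case):
        from sfanet.nn import functional as F

        if case == "rasf":
            blk = RASF(4, reduction=2, rng=rng())
            inputs = [Tensor(RNG.normal(size=(1, 4, 8, 8)), requires_grad=True)]
            out = blk(inputs[0])
        elif case == "aff":
            blk = AFF(3, 2, 4, rng=rng())
            inputs = [Tensor(RNG.normal(size=(1, 3, 8, 8)), requires_grad=True),
                      Tensor(RNG.normal(size=(1, 2, 8, 8)), requires_grad=True),
                      Tensor(RNG.normal(size=(1, 4, 4, 4)), requires_grad=True)]
            out = blk(*inputs)
        elif case == "mpf":
            blk = MPF(2, 3, 4, rng=rng())
            inputs = [Tensor(RNG.normal(size=(1, 2, 8, 8)), requires_grad=True),
                      Tensor(RNG.normal(size=(1, 3, 4, 4)), requires_grad=True),
                      Tensor(RNG.normal(size=(1, 4, 2, 2)), requires_grad=True)]
            out = blk(*inputs)
        else:
            blk = ConvBN(3, 4, rng=rng())
            inputs = [Tensor(RNG.normal(size=(1, 3, 8, 8)), requires_grad=True)]
            out = blk(inputs[0])
        F.tsum(F.mul(out, out)).backward()
        for t in inputs:
            assert t.grad is not None and np.any(t.grad != 0)
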