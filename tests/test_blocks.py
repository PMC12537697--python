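"""MixConv, DFEU and SK-fusion block behaviour."""

import numpy as np
import pytest

from dunet import nn
from dunet.blocks import (
    DFEU,
    DFEUParams,
    GatedConvBlock,
    MixConvBlock,
    MixConvParams,
    SKFusion,
    dfeu_reconstruct,
    mixconv_param_count,
)


def feature(rng, n=2, c=8, h=16, w=16):
    return nn.Tensor(rng.standard_normal((n, c, h, w)).astype(np.float32))


class TestMixConv:
    def test_shape_preserved_and_deterministic_in_eval(self, rng):
        block = MixConvBlock(MixConvParams(8), np.random.default_rng(0))
        block.eval()
        x = feature(rng)
        y1, y2 = block(x), block(x)
        assert y1.shape == x.shape
        np.testing.assert_array_equal(y1.data, y2.data)

    @pytest.mark.parametrize("shape", [(1, 8, 12, 20), (3, 8, 16, 16)])
    def test_shape_contract_across_inputs(self, rng, shape):
        block = MixConvBlock(MixConvParams(8), np.random.default_rng(0)).eval()
        x = nn.Tensor(rng.standard_normal(shape).astype(np.float32))
        assert block(x).shape == shape

    def test_zeroed_projection_reduces_to_identity(self, rng):
        block = MixConvBlock(MixConvParams(8), np.random.default_rng(0)).eval()
        block.proj.weight.data[:] = 0
        block.proj.bias.data[:] = 0
        x = feature(rng)
        np.testing.assert_array_equal(block(x).data, x.data)

    def test_gates_bounded_but_not_normalized(self, rng):
        """Sigmoid gates lie in (0,1) and, unlike SK weights, need not sum to 1."""
        block = MixConvBlock(MixConvParams(8), np.random.default_rng(2)).eval()
        w1, w2 = block.gates(feature(rng))
        for w in (w1, w2):
            assert np.all(w.data > 0) and np.all(w.data < 1)
        s = w1.data + w2.data
        assert np.max(np.abs(s - 1.0)) > 1e-3

    def test_channel_mismatch_raises(self, rng):
        block = MixConvBlock(MixConvParams(8), np.random.default_rng(0))
        with pytest.raises(ValueError):
            block(feature(rng, c=4))

    def test_param_count_formula_matches_engine(self):
        for c in (8, 24, 48):
            p = MixConvParams(c)
            block = MixConvBlock(p, np.random.default_rng(0))
            assert block.n_parameters() == mixconv_param_count(p)

    def test_gradients_flow_to_every_parameter(self, rng):
        block = MixConvBlock(MixConvParams(4), np.random.default_rng(0))
        y = block(feature(rng, c=4, h=8, w=8))
        (y * y).mean().backward()
        for name, p in block.named_parameters():
            assert p.grad is not None, name
            assert np.any(p.grad != 0) or "bn" in name, name


class TestGatedBlock:
    def test_matches_mixconv_interface(self, rng):
        block = GatedConvBlock(8, np.random.default_rng(0)).eval()
        x = feature(rng)
        assert block(x).shape == x.shape
        block.proj.weight.data[:] = 0
        block.proj.bias.data[:] = 0
        np.testing.assert_array_equal(block(x).data, x.data)


class TestDFEU:
    def test_branches_bounded_by_sigmoid(self, rng):
        unit = DFEU(DFEUParams(8), np.random.default_rng(0)).eval()
        x = feature(rng)
        a = unit.estimate_atmospheric(x)
        t = unit.estimate_transmission(x)
        for out in (a, t):
            assert out.shape == x.shape
            assert np.all(out.data > 0) and np.all(out.data < 1)

    def test_constant_input_gives_spatially_constant_transmission(self, rng):
        unit = DFEU(DFEUParams(8), np.random.default_rng(1)).eval()
        x = nn.Tensor(np.full((1, 8, 16, 16), 0.37, np.float32))
        t = unit.estimate_transmission(x).data
        assert np.ptp(t, axis=(2, 3)).max() < 1e-6

    def test_reconstruct_scalar_example_and_inverse(self, rng):
        i = nn.Tensor(np.full((1, 1, 2, 2), 0.5))
        a = nn.Tensor(np.full((1, 1, 2, 2), 0.2))
        t = nn.Tensor(np.full((1, 1, 2, 2), 0.5))
        np.testing.assert_allclose(dfeu_reconstruct(i, a, t, 0.0).data, 0.8,
                                   rtol=1e-12)
        # exact feature-space inversion for random fields
        j = nn.Tensor(rng.standard_normal((2, 4, 6, 6)))
        a = nn.Tensor(rng.uniform(0.05, 0.95, (2, 4, 6, 6)))
        t = nn.Tensor(rng.uniform(0.1, 1.0, (2, 4, 6, 6)))
        hazed = j * t + a * (1.0 - t)
        rec = dfeu_reconstruct(hazed, a, t, 0.0)
        assert np.max(np.abs(rec.data - j.data)) < 1e-6

    def test_unit_transmission_is_identity(self, rng):
        i = feature(rng)
        a = nn.Tensor(np.full(i.shape, 0.3, np.float32))
        t = nn.Tensor(np.ones(i.shape, np.float32))
        np.testing.assert_allclose(dfeu_reconstruct(i, a, t, 0.0).data, i.data,
                                   atol=1e-6)

    def test_monotone_in_input_feature(self, rng):
        a = nn.Tensor(rng.uniform(0, 1, (1, 2, 3, 3)))
        t = nn.Tensor(rng.uniform(0.1, 1, (1, 2, 3, 3)))
        i1 = nn.Tensor(rng.standard_normal((1, 2, 3, 3)))
        i2 = i1 + 0.25
        d = dfeu_reconstruct(i2, a, t, 0.0).data - dfeu_reconstruct(i1, a, t, 0.0).data
        assert np.all(d > 0)

    def test_saturated_transmission_recovers_input(self, rng):
        unit = DFEU(DFEUParams(8, epsilon=0.0), np.random.default_rng(0)).eval()
        unit.t_expand.bias.data[:] = 50.0  # sigmoid -> 1
        x = feature(rng)
        np.testing.assert_allclose(unit(x).data, x.data, atol=1e-3)

    def test_forward_shape_and_determinism(self, rng):
        unit = DFEU(DFEUParams(8), np.random.default_rng(3)).eval()
        x = feature(rng)
        y1, y2 = unit(x), unit(x)
        assert y1.shape == x.shape
        np.testing.assert_array_equal(y1.data, y2.data)

    def test_small_spatial_input_rejected(self, rng):
        unit = DFEU(DFEUParams(8), np.random.default_rng(0))
        with pytest.raises(ValueError):
            unit.estimate_transmission(feature(rng, h=3, w=3))

    def test_reconstruct_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            dfeu_reconstruct(feature(rng), feature(rng, c=4), feature(rng))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            DFEUParams(8, pyramid_sizes=(4, 2, 1))
        with pytest.raises(ValueError):
            DFEUParams(8, epsilon=-1e-3)


class TestSKFusion:
    def test_identical_inputs_are_a_fixpoint(self, rng):
        fuse = SKFusion(8, np.random.default_rng(0)).eval()
        x = feature(rng)
        np.testing.assert_allclose(fuse(x, x).data, x.data, atol=1e-6)

    def test_weights_sum_to_one_per_channel(self, rng):
        fuse = SKFusion(8, np.random.default_rng(1)).eval()
        w1, w2 = fuse.weights(feature(rng), feature(rng))
        np.testing.assert_allclose(w1.data + w2.data, 1.0, atol=1e-6)
        assert np.all(w1.data > 0) and np.all(w1.data < 1)

    def test_saturated_softmax_selects_skip_branch(self, rng):
        """With a constructed MLP whose branch-1 logits dominate by >> 20,
        the fusion returns the skip feature."""
        fuse = SKFusion(4, np.random.default_rng(2)).eval()
        fuse.reduce.weight.data[:] = 1.0   # bottleneck = sum of pooled channels
        fuse.expand.weight.data[:] = 0.0
        fuse.expand.weight.data[:4] = 5.0  # branch-1 logits large, branch-2 zero
        x1 = feature(rng, c=4)
        x2 = feature(rng, c=4)
        # make the pooled descriptor strictly positive so the gap survives ReLU
        x1 = x1 * 0.1 + 1.0
        y = fuse(x1, x2)
        np.testing.assert_allclose(y.data, x1.data, atol=1e-6)

    def test_output_is_convex_combination(self, rng):
        fuse = SKFusion(8, np.random.default_rng(3)).eval()
        x1, x2 = feature(rng), feature(rng)
        y = fuse(x1, x2).data
        lo = np.minimum(x1.data, x2.data)
        hi = np.maximum(x1.data, x2.data)
        assert np.all(y >= lo - 1e-6) and np.all(y <= hi + 1e-6)

    def test_shape_mismatch_raises(self, rng):
        fuse = SKFusion(8, np.random.default_rng(0))
        with pytest.raises(ValueError):
            fuse(feature(rng), feature(rng, h=8))
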