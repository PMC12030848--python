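"""Selective-kernel block: decomposition, pooling, masking, fusion and the
multi-head refinement, each against independent references."""

import numpy as np
import pytest

from lomlprnn._autograd import Tensor
from lomlprnn.lsk import (LSKBlock, MultiheadRefiner, decompose_large_kernel,
                          fuse_selected, lsk_block, multihead_refine,
                          pool_descriptors, selection_masks)


@pytest.fixture
def block():
    return LSKBlock(channels=3, improved=False, rng=np.random.default_rng(0))


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestDecompose:
    def test_shapes_preserved(self, block, rng):
        for h, w in [(1, 1), (3, 5), (8, 8)]:
            stack = decompose_large_kernel(Tensor(rng.normal(size=(2, 3, h, w))),
                                           block)
            assert stack.n == 2
            for u in stack.branches:
                assert u.shape == (2, 3, h, w)

    def test_zero_input_zero_biases_gives_zero(self, block):
        for b in block.dw_biases + block.proj_biases:
            b.data[:] = 0.0
        stack = decompose_large_kernel(Tensor(np.zeros((1, 3, 4, 4))), block)
        for u in stack.branches:
            np.testing.assert_array_equal(u.data, 0.0)

    def test_delta_kernels_identity_projection_pass_through(self, rng):
        """Delta depthwise taps + identity 1x1 projections → branch 1 = x."""
        block = LSKBlock(channels=2, improved=False,
                         rng=np.random.default_rng(1))
        for w, b in zip(block.dw_weights, block.dw_biases):
            w.data[:] = 0.0
            k = w.shape[-1]
            w.data[:, k // 2, k // 2] = 1.0
            b.data[:] = 0.0
        for w, b in zip(block.proj_weights, block.proj_biases):
            w.data[:] = np.eye(2)[:, :, None, None]
            b.data[:] = 0.0
        x = rng.normal(size=(1, 2, 5, 5))
        stack = decompose_large_kernel(Tensor(x), block)
        np.testing.assert_allclose(stack.branches[0].data, x, atol=1e-12)
        # the second branch sees the first branch's (identity) output
        np.testing.assert_allclose(stack.branches[1].data, x, atol=1e-12)


class TestDescriptorsAndMasks:
    def test_constant_tensor(self):
        u = Tensor(np.full((1, 4, 3, 3), 2.5))
        desc = pool_descriptors(u)
        np.testing.assert_array_equal(desc.sa_avg.data, 2.5)
        np.testing.assert_array_equal(desc.sa_max.data, 2.5)

    def test_two_channel_arithmetic(self):
        u = Tensor(np.array([1.0, 3.0]).reshape(1, 2, 1, 1))
        desc = pool_descriptors(u)
        assert desc.sa_avg.data.item() == 2.0
        assert desc.sa_max.data.item() == 3.0

    def test_max_dominates_avg(self, rng):
        desc = pool_descriptors(Tensor(rng.normal(size=(2, 6, 4, 4))))
        assert np.all(desc.sa_max.data >= desc.sa_avg.data)

    def test_sigmoid_masks(self, rng):
        raw = Tensor(np.array([[0.0, 2.0, -2.0, 50.0]]).reshape(1, 4, 1, 1))
        masks = selection_masks(raw)
        assert masks.masks[0].data.item() == 0.5
        for m in masks.masks:
            assert 0.0 < m.data.item() < 1.0
        # monotone in the raw value
        vals = [m.data.item() for m in selection_masks(
            Tensor(np.linspace(-3, 3, 5).reshape(1, 5, 1, 1))).masks]
        assert vals == sorted(vals)


class TestAttentionMaps:
    def test_zero_descriptors_zero_bias(self, block):
        from lomlprnn.lsk import SpatialDescriptors
        block.attn_bias.data[:] = 0.0
        block.attn_weight.data[:] = 1.0   # overwrite neutral zeros
        desc = SpatialDescriptors(Tensor(np.zeros((1, 1, 4, 4))),
                                  Tensor(np.zeros((1, 1, 4, 4))))
        raw = block.spatial_attention_maps(desc)
        assert raw.shape == (1, 2, 4, 4)
        np.testing.assert_array_equal(raw.data, 0.0)

    def test_hand_set_single_pixel(self):
        """attn kernel 1x1 → raw attentions are a 2x2→N matrix product."""
        from lomlprnn.lsk import SpatialDescriptors
        block = LSKBlock(channels=2, improved=False, attn_kernel=1,
                         rng=np.random.default_rng(2))
        w = np.array([[1.0, 2.0], [-1.0, 0.5]])     # (N=2, in=2)
        block.attn_weight.data = w[:, :, None, None]
        block.attn_bias.data[:] = 0.0
        desc = SpatialDescriptors(Tensor(np.full((1, 1, 1, 1), 3.0)),
                                  Tensor(np.full((1, 1, 1, 1), 4.0)))
        raw = block.spatial_attention_maps(desc).data.ravel()
        np.testing.assert_allclose(raw, w @ np.array([3.0, 4.0]), atol=1e-12)


class TestFusion:
    def test_identical_branches_distribute(self, block, rng):
        """Identical branches: pre-F tensor is (m1+m2)·U."""
        from lomlprnn.lsk import BranchStack, SelectionMasks
        u = rng.normal(size=(1, 3, 2, 2))
        m1 = sigmoid(rng.normal(size=(1, 1, 2, 2)))
        m2 = sigmoid(rng.normal(size=(1, 1, 2, 2)))
        block.fuse_weight.data = np.eye(3)[:, :, None, None]  # F = identity
        block.fuse_bias.data[:] = 0.0
        stack = BranchStack([Tensor(u), Tensor(u)])
        masks = SelectionMasks(Tensor(np.zeros((1, 2, 2, 2))),
                               [Tensor(m1), Tensor(m2)])
        out = fuse_selected(stack, masks, block).data
        np.testing.assert_allclose(out, (m1 + m2) * u, atol=1e-12)

    def test_vanishing_masks_leave_bias_map(self, block, rng):
        from lomlprnn.lsk import BranchStack, SelectionMasks
        block.fuse_bias.data = np.array([1.0, -2.0, 0.5])
        stack = BranchStack([Tensor(rng.normal(size=(1, 3, 2, 2)))
                             for _ in range(2)])
        masks = SelectionMasks(Tensor(np.zeros((1, 2, 2, 2))),
                               [Tensor(np.full((1, 1, 2, 2), 1e-300))
                                for _ in range(2)])
        out = fuse_selected(stack, masks, block).data
        np.testing.assert_allclose(
            out, block.fuse_bias.data[None, :, None, None]
            * np.ones((1, 3, 2, 2)), atol=1e-250)

    def test_count_mismatch_raises(self, block, rng):
        from lomlprnn.lsk import BranchStack, SelectionMasks
        stack = BranchStack([Tensor(np.zeros((1, 3, 2, 2)))] * 2)
        masks = SelectionMasks(Tensor(np.zeros((1, 1, 2, 2))),
                               [Tensor(np.full((1, 1, 2, 2), 0.5))])
        with pytest.raises(ValueError, match="mismatch"):
            fuse_selected(stack, masks, block)

    def test_full_selection_pipeline_vs_loop_reference(self, rng):
        """Mask-weighted fusion equals an independent nested-loop evaluation."""
        block = LSKBlock(channels=4, improved=False,
                         rng=np.random.default_rng(3))
        g = np.random.default_rng(4)
        block.attn_weight.data = g.normal(size=block.attn_weight.shape)
        block.attn_bias.data = g.normal(size=block.attn_bias.shape)
        block.fuse_weight.data = g.normal(size=block.fuse_weight.shape)
        block.fuse_bias.data = g.normal(size=block.fuse_bias.shape)
        x = rng.normal(size=(2, 4, 5, 5))
        out = block(Tensor(x)).data

        # ---- reference, nested loops throughout ----
        stack = block.decompose(Tensor(x))
        u = np.stack([b.data for b in stack.branches])      # (N, B, C, H, W)
        cat = np.concatenate([b.data for b in stack.branches], axis=1)
        sa = np.stack([cat.mean(axis=1), cat.max(axis=1)], axis=1)  # (B,2,H,W)
        n, _, kh, kw = block.attn_weight.shape
        pad = (kh - 1) // 2
        sp = np.pad(sa, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        bsz, _, h, w = x.shape
        raw = np.zeros((bsz, n, h, w))
        for bi in range(bsz):
            for o in range(n):
                for i in range(h):
                    for j in range(w):
                        raw[bi, o, i, j] = (np.sum(
                            sp[bi, :, i:i + kh, j:j + kw]
                            * block.attn_weight.data[o])
                            + block.attn_bias.data[o])
        weighted = sum(sigmoid(raw[:, i:i + 1]) * u[i] for i in range(n))
        fw = block.fuse_weight.data[:, :, 0, 0]
        ref = np.einsum("oc,bchw->bohw", fw, weighted) \
            + block.fuse_bias.data[None, :, None, None]
        assert np.max(np.abs(out - ref)) < 1e-5


class TestMultiheadRefine:
    def test_single_token_attention_is_one(self, rng):
        ref = MultiheadRefiner(channels=4, heads=2,
                               rng=np.random.default_rng(5))
        x = Tensor(rng.normal(size=(2, 4, 1, 1)))
        w = ref.attention_weights(x)
        np.testing.assert_allclose(w, 1.0, atol=1e-12)

    def test_attention_rows_sum_to_one(self, rng):
        ref = MultiheadRefiner(channels=4, heads=2,
                               rng=np.random.default_rng(6))
        w = ref.attention_weights(Tensor(rng.normal(size=(1, 4, 3, 3))))
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-9)

    def test_two_token_single_head_manual_oracle(self):
        """Hand-set projections vs an explicit scaled-dot-product evaluation."""
        ref = MultiheadRefiner(channels=2, heads=1,
                               rng=np.random.default_rng(7))
        def setl(lin, w, b):
            lin.weight.data = np.asarray(w, dtype=float)
            lin.bias.data = np.asarray(b, dtype=float)
        setl(ref.proj_in, np.eye(2), [0, 0])
        setl(ref.q, [[1.0, 0.0], [0.0, 2.0]], [0, 0])
        setl(ref.k, [[0.5, 0.0], [1.0, 1.0]], [0, 0])
        setl(ref.v, [[1.0, 1.0], [0.0, 1.0]], [0, 0])
        setl(ref.proj_out, np.eye(2), [0, 0])
        x = np.array([[1.0, 2.0], [3.0, -1.0]])            # tokens as rows
        q, k, v = x @ ref.q.weight.data, x @ ref.k.weight.data, \
            x @ ref.v.weight.data
        scores = q @ k.T / np.sqrt(2.0)
        attn = np.exp(scores - scores.max(axis=1, keepdims=True))
        attn /= attn.sum(axis=1, keepdims=True)
        expected = x + attn @ v
        # feed as (1, C=2, H=2, W=1): tokens = spatial positions
        xt = x.T.reshape(1, 2, 2, 1)
        out = ref(Tensor(xt)).data.reshape(2, 2).T
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_bad_heads_rejected(self):
        with pytest.raises(ValueError, match="heads"):
            MultiheadRefiner(channels=4, heads=0)


class TestBlockAssembly:
    @pytest.mark.parametrize("improved", [False, True])
    def test_output_shape_matches_input(self, improved, rng):
        x = rng.normal(size=(2, 3, 4, 6))
        out = lsk_block(Tensor(x), improved=improved,
                        rng=np.random.default_rng(8))
        assert out.shape == x.shape

    def test_plain_block_never_refines(self, rng, monkeypatch):
        block = LSKBlock(channels=3, improved=False,
                         rng=np.random.default_rng(9))
        assert block.refiner is None
        calls = []
        monkeypatch.setattr(MultiheadRefiner, "__call__",
                            lambda self, x: calls.append(1) or x)
        block(Tensor(rng.normal(size=(1, 3, 2, 2))))
        assert calls == []

    def test_zeroed_refiner_matches_plain_block(self, rng):
        """Improved and plain blocks differ only by the refinement stage."""
        imp = LSKBlock(channels=3, improved=True,
                       rng=np.random.default_rng(10))
        plain = LSKBlock(channels=3, improved=False,
                         rng=np.random.default_rng(11))
        # copy the shared-stage weights and zero the refinement output
        for attr in ("attn_weight", "attn_bias", "fuse_weight", "fuse_bias"):
            getattr(plain, attr).data = getattr(imp, attr).data.copy()
        for lst in ("dw_weights", "dw_biases", "proj_weights", "proj_biases"):
            for a, b in zip(getattr(plain, lst), getattr(imp, lst)):
                a.data = b.data.copy()
        imp.refiner.proj_out.weight.data[:] = 0.0
        imp.refiner.proj_out.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(2, 3, 3, 3)))
        np.testing.assert_allclose(imp(x).data, plain(x).data, atol=1e-12)

    def test_deterministic_repeat(self, rng):
        block = LSKBlock(channels=3, improved=True,
                         rng=np.random.default_rng(12))
        x = Tensor(rng.normal(size=(1, 3, 4, 4)))
        np.testing.assert_array_equal(block(x).data, block(x).data)

    def test_masks_never_saturate(self, rng):
        block = LSKBlock(channels=3, improved=False,
                         rng=np.random.default_rng(13))
        g = np.random.default_rng(14)
        block.attn_weight.data = g.normal(size=block.attn_weight.shape,
                                          scale=5.0)
        x = Tensor(rng.normal(size=(1, 3, 6, 6), scale=10.0))
        stack = block.decompose(x)
        raw = block.spatial_attention_maps(
            pool_descriptors(stack.concatenated))
        for m in selection_masks(raw).masks:
            assert np.all(m.data > 0.0) and np.all(m.data < 1.0)
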