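"""Improved large-selective-kernel (LSK) spatial attention block.

A large receptive field is decomposed into two serial depthwise branches
(5x5, then 7x7 with dilation 3 on the first branch's output), each followed
by a 1x1 channel projection. Channel-wise average and max pooling of the
concatenated branches give two spatial descriptors, a small convolution
turns them into one raw attention map per branch, sigmoid squashing yields
the spatial selection masks, and the mask-weighted branch sum is fused back
to the input width by a 1x1 convolution:

    U~ = [U~_1; U~_2]
    SA_avg = mean_c(U~),  SA_max = max_c(U~)
    SA^ = F_{2->N}([SA_avg; SA_max])
    SA~_i = sigmoid(SA^_i)
    S = F( sum_i SA~_i * U~_i )

The *improved* variant additionally refines the block input with token-wise
multi-head self-attention (spatial positions as tokens, channels embedded)
before the decomposition, with a residual connection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, as_tensor, concat
from ._layers import Linear, Module, conv2d, depthwise_conv2d, uniform_fan_in

__all__ = ["LSKBlock", "MultiheadRefiner", "BranchStack", "SpatialDescriptors",
           "SelectionMasks", "pool_descriptors", "selection_masks",
           "decompose_large_kernel", "spatial_attention_maps", "fuse_selected",
           "multihead_refine", "lsk_block"]


@dataclass
class BranchStack:
    """Branch feature maps sharing (batch, C, H, W), plus their concat."""

    branches: list[Tensor]

    @property
    def concatenated(self) -> Tensor:
        return concat(self.branches, axis=1)

    @property
    def n(self) -> int:
        return len(self.branches)


@dataclass
class SpatialDescriptors:
    sa_avg: Tensor   # (batch, 1, H, W)
    sa_max: Tensor   # (batch, 1, H, W)


@dataclass
class SelectionMasks:
    raw: Tensor            # (batch, N, H, W)
    masks: list[Tensor]    # N maps (batch, 1, H, W), values in (0, 1)


def pool_descriptors(u: Tensor) -> SpatialDescriptors:
    """Channel-wise mean and max, keeping a singleton channel axis."""
    u = as_tensor(u)
    return SpatialDescriptors(u.mean(axis=1, keepdims=True),
                              u.max(axis=1, keepdims=True))


def selection_masks(raw: Tensor) -> SelectionMasks:
    """Elementwise sigmoid per branch attention map.

    Masks live on the open interval (0, 1); values that would round to an
    endpoint in float64 are clamped to the nearest representable interior
    value so downstream code can rely on strict bounds.
    """
    raw = as_tensor(raw)
    n = raw.shape[1]
    lo = np.finfo(np.float64).tiny
    hi = 1.0 - np.finfo(np.float64).eps
    masks = []
    for i in range(n):
        m = raw[:, i:i + 1].sigmoid()
        np.clip(m.data, lo, hi, out=m.data)
        masks.append(m)
    return SelectionMasks(raw, masks)


class MultiheadRefiner(Module):
    """Token-wise multi-head self-attention over spatial positions.

    Channels are embedded to a width divisible by the head count, attended
    with scaled dot products, projected back, and added to the input.
    """

    def __init__(self, channels: int, heads: int = 4,
                 embed_dim: int | None = None,
                 rng: np.random.Generator | None = None):
        if heads <= 0:
            raise ValueError("heads must be positive")
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.heads = heads
        d = embed_dim if embed_dim is not None else -(-channels // heads) * heads
        if d % heads != 0:
            raise ValueError("embed_dim must be divisible by heads")
        self.embed_dim = d
        self.proj_in = Linear(channels, d, rng)
        self.q = Linear(d, d, rng)
        self.k = Linear(d, d, rng)
        self.v = Linear(d, d, rng)
        self.proj_out = Linear(d, channels, rng)
        # zero output projection: the refiner starts as the identity and the
        # residual pathway dominates until attention becomes useful
        self.proj_out.weight.data[:] = 0.0
        self.proj_out.bias.data[:] = 0.0

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        b, c, h, w = x.shape
        t = h * w
        d, nh = self.embed_dim, self.heads
        dh = d // nh
        tokens = x.reshape(b, c, t).transpose(0, 2, 1)          # (B, T, C)
        emb = self.proj_in(tokens)                              # (B, T, d)
        def split(z):  # (B, T, d) -> (B, nh, T, dh)
            return z.reshape(b, t, nh, dh).transpose(0, 2, 1, 3)
        q, k, v = split(self.q(emb)), split(self.k(emb)), split(self.v(emb))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)                          # rows sum to 1
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        refined = self.proj_out(ctx)                            # (B, T, C)
        return x + refined.transpose(0, 2, 1).reshape(b, c, h, w)

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Per-head token-attention matrices (B, heads, T, T), for inspection."""
        x = as_tensor(x)
        b, c, h, w = x.shape
        t = h * w
        d, nh = self.embed_dim, self.heads
        dh = d // nh
        tokens = x.reshape(b, c, t).transpose(0, 2, 1)
        emb = self.proj_in(tokens)
        def split(z):
            return z.reshape(b, t, nh, dh).transpose(0, 2, 1, 3)
        q, k = split(self.q(emb)), split(self.k(emb))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        return scores.softmax(axis=-1).data


class LSKBlock(Module):
    """Two-branch selective-kernel block; ``improved`` adds the refiner."""

    def __init__(self, channels: int, improved: bool = True,
                 branch_kernels: tuple = ((5, 1), (7, 3)),
                 attn_kernel: int = 7, heads: int = 4,
                 embed_dim: int | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        if len(branch_kernels) < 2:
            raise ValueError("at least two branches are required")
        self.channels = channels
        self.improved = bool(improved)
        self.branch_kernels = [(int(k), int(d)) for k, d in branch_kernels]
        self.attn_kernel = int(attn_kernel)
        c = channels
        self.dw_weights = []
        self.dw_biases = []
        self.proj_weights = []
        self.proj_biases = []
        for k, _ in self.branch_kernels:
            self.dw_weights.append(uniform_fan_in(rng, (c, k, k), k * k))
            self.dw_biases.append(uniform_fan_in(rng, (c,), k * k))
            self.proj_weights.append(uniform_fan_in(rng, (c, c, 1, 1), c))
            self.proj_biases.append(uniform_fan_in(rng, (c,), c))
        n = len(self.branch_kernels)
        ak = self.attn_kernel
        self.attn_weight = uniform_fan_in(rng, (n, 2, ak, ak), 2 * ak * ak)
        self.attn_bias = uniform_fan_in(rng, (n,), 2 * ak * ak)
        self.fuse_weight = uniform_fan_in(rng, (c, c, 1, 1), c)
        self.fuse_bias = uniform_fan_in(rng, (c,), c)
        # neutral start: selection masks open (~0.88) and the post-fusion
        # convolution zeroed, so the block contributes nothing until its
        # output pathway picks up gradient signal
        self.attn_weight.data[:] = 0.0
        self.attn_bias.data[:] = 2.0
        self.fuse_weight.data[:] = 0.0
        self.fuse_bias.data[:] = 0.0
        self.refiner = MultiheadRefiner(c, heads, embed_dim, rng) if improved else None

    # ----------------------------------------------------------- components
    def decompose(self, x: Tensor) -> BranchStack:
        """Serial depthwise decomposition with per-branch 1x1 projections."""
        x = as_tensor(x)
        if x.shape[1] != self.channels:
            raise ValueError(
                f"channel mismatch: got {x.shape[1]}, expected {self.channels}")
        branches = []
        carry = x
        for (k, dil), dw_w, dw_b, pj_w, pj_b in zip(
                self.branch_kernels, self.dw_weights, self.dw_biases,
                self.proj_weights, self.proj_biases):
            pad = dil * (k - 1) // 2
            carry = depthwise_conv2d(carry, dw_w, dw_b, padding=pad, dilation=dil)
            branches.append(conv2d(carry, pj_w, pj_b))
        return BranchStack(branches)

    def spatial_attention_maps(self, desc: SpatialDescriptors) -> Tensor:
        """2 -> N convolution over the concatenated descriptors."""
        stacked = concat([desc.sa_avg, desc.sa_max], axis=1)    # (B, 2, H, W)
        pad = (self.attn_kernel - 1) // 2
        return conv2d(stacked, self.attn_weight, self.attn_bias, padding=pad)

    def fuse(self, stack: BranchStack, masks: SelectionMasks) -> Tensor:
        if len(masks.masks) != stack.n:
            raise ValueError("branch/mask count mismatch")
        weighted = None
        for u_i, m_i in zip(stack.branches, masks.masks):
            term = u_i * m_i            # mask broadcast over channels
            weighted = term if weighted is None else weighted + term
        return conv2d(weighted, self.fuse_weight, self.fuse_bias)

    # -------------------------------------------------------------- forward
    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if self.improved:
            x = self.refiner(x)
        stack = self.decompose(x)
        desc = pool_descriptors(stack.concatenated)
        raw = self.spatial_attention_maps(desc)
        masks = selection_masks(raw)
        return self.fuse(stack, masks)


# --------------------------------------------------------- functional surface

def decompose_large_kernel(x: Tensor, block: LSKBlock) -> BranchStack:
    return block.decompose(x)


def spatial_attention_maps(desc: SpatialDescriptors, block: LSKBlock) -> Tensor:
    return block.spatial_attention_maps(desc)


def fuse_selected(stack: BranchStack, masks: SelectionMasks,
                  block: LSKBlock) -> Tensor:
    return block.fuse(stack, masks)


def multihead_refine(x, heads: int = 4,
                     refiner: MultiheadRefiner | None = None,
                     rng: np.random.Generator | None = None) -> Tensor:
    x = as_tensor(x)
    if refiner is None:
        refiner = MultiheadRefiner(x.shape[1], heads, rng=rng)
    return refiner(x)


def lsk_block(x, improved: bool = True,
              block: LSKBlock | None = None,
              rng: np.random.Generator | None = None, **kwargs) -> Tensor:
    x = as_tensor(x)
    if block is None:
        block = LSKBlock(x.shape[1], improved=improved, rng=rng, **kwargs)
    return block(x)
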