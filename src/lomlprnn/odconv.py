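"""Omni-dimensional dynamic convolution.

A bank of ``n`` candidate kernels is collapsed into one effective kernel per
input item by four attention vectors computed from the globally pooled
input: a spatial attention over the k x k taps, an input-channel attention,
an output-channel (filter) attention — each sigmoid-squashed — and a kernel
attention softmax-normalised over the ``n`` candidates, so the effective
kernel is a convex combination of attention-modulated candidates:

    y = ( sum_i  aw_i * (af_i ⊗ ac_i ⊗ as_i) ⊙ W_i ) * x

Attentions are computed per batch item, so the convolution adapts to each
input spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, as_tensor, concat
from ._layers import Linear, Module, conv2d, uniform_fan_in

__all__ = ["ODConv", "ODConvState", "AttentionBundle",
           "compute_attentions", "odconv_forward"]


@dataclass
class AttentionBundle:
    """Per-item attention vectors; leading axis is the batch."""

    alpha_s: Tensor   # (B, k*k)   in (0, 1)
    alpha_c: Tensor   # (B, C_in)  in (0, 1)
    alpha_f: Tensor   # (B, C_out) in (0, 1)
    alpha_w: Tensor   # (B, n)     non-negative, rows sum to 1

    @classmethod
    def identity(cls, batch: int, n: int, c_in: int, c_out: int,
                 k: int) -> "AttentionBundle":
        """All-ones bundle (kernel attention uniform), for reduction checks."""
        return cls(Tensor(np.ones((batch, k * k))),
                   Tensor(np.ones((batch, c_in))),
                   Tensor(np.ones((batch, c_out))),
                   Tensor(np.full((batch, n), 1.0 / n)))


class ODConv(Module):
    """Dynamic convolution layer; also usable through the functional API."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int = 1,
                 n_kernels: int = 4, reduction: int = 4,
                 temperature: float = 1.0,
                 rng: np.random.Generator | None = None, bias: bool = True):
        if n_kernels < 1:
            raise ValueError("n_kernels must be >= 1")
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_size
        self.n = n_kernels
        self.reduction = reduction
        self.temperature = float(temperature)
        fan = c_in * kernel_size * kernel_size
        self.kernels = uniform_fan_in(
            rng, (n_kernels, c_out, c_in, kernel_size, kernel_size), fan)
        self.bias = uniform_fan_in(rng, (c_out,), fan) if bias else None
        hidden = max(c_in // reduction, 1)
        self.fc = Linear(c_in, hidden, rng)
        self.head_s = Linear(hidden, kernel_size * kernel_size, rng)
        self.head_c = Linear(hidden, c_in, rng)
        self.head_f = Linear(hidden, c_out, rng)
        self.head_w = Linear(hidden, n_kernels, rng)
        # neutral gate start: sigmoid heads open (~0.88), kernel softmax
        # uniform, so the layer behaves like a static convolution until the
        # attention pathways pick up gradient signal
        for head in (self.head_s, self.head_c, self.head_f):
            head.weight.data[:] = 0.0
            head.bias.data[:] = 2.0
        self.head_w.weight.data[:] = 0.0
        self.head_w.bias.data[:] = 0.0
        if self.bias is not None:
            self.bias.data[:] = 0.0

    # the four-head attention body: GAP -> bottleneck FC -> ReLU -> heads
    def attentions(self, x: Tensor) -> AttentionBundle:
        x = as_tensor(x)
        if x.ndim != 4:
            raise ValueError("input must be (batch, C_in, H, W)")
        b, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"channel mismatch: got {c}, expected {self.c_in}")
        if h * w == 0:
            raise ValueError("input has empty spatial extent")
        pooled = x.mean(axis=(2, 3))                  # (B, C_in)
        z = self.fc(pooled).relu()
        alpha_s = self.head_s(z).sigmoid()
        alpha_c = self.head_c(z).sigmoid()
        alpha_f = self.head_f(z).sigmoid()
        alpha_w = (self.head_w(z) * (1.0 / self.temperature)).softmax(axis=1)
        return AttentionBundle(alpha_s, alpha_c, alpha_f, alpha_w)

    def forward_with(self, x: Tensor, bundle: AttentionBundle) -> Tensor:
        """Apply the dynamic convolution using a precomputed bundle."""
        x = as_tensor(x)
        b = x.shape[0]
        k = self.k
        pad = (k - 1) // 2
        outs = []
        for i in range(b):
            aw = bundle.alpha_w[i].reshape(self.n, 1, 1, 1, 1)
            af = bundle.alpha_f[i].reshape(1, self.c_out, 1, 1, 1)
            ac = bundle.alpha_c[i].reshape(1, 1, self.c_in, 1, 1)
            asp = bundle.alpha_s[i].reshape(1, 1, 1, k, k)
            w_eff = (self.kernels * aw * af * ac * asp).sum(axis=0)
            outs.append(conv2d(x[i:i + 1], w_eff, self.bias, padding=pad))
        return concat(outs, axis=0) if len(outs) > 1 else outs[0]

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward_with(x, self.attentions(x))


# ------------------------------------------------------------ functional API

@dataclass
class ODConvState:
    """Wraps an :class:`ODConv` layer as an explicit parameter state."""

    layer: ODConv

    @property
    def n(self) -> int:
        return self.layer.n

    @property
    def kernels(self) -> Tensor:
        return self.layer.kernels


def compute_attentions(x, state: ODConvState | ODConv) -> AttentionBundle:
    layer = state.layer if isinstance(state, ODConvState) else state
    return layer.attentions(as_tensor(x))


def odconv_forward(x, state: ODConvState | ODConv,
                   bundle: AttentionBundle | None = None) -> Tensor:
    layer = state.layer if isinstance(state, ODConvState) else state
    x = as_tensor(x)
    if bundle is None:
        bundle = layer.attentions(x)
    return layer.forward_with(x, bundle)
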