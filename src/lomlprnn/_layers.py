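"""Neural-network building blocks on top of the autodiff core.

Convolutions are composed from zero padding, slicing and matrix products so
that reverse-mode gradients require no dedicated backward rules. All layers
draw their initial weights from a caller-supplied :class:`numpy.random.Generator`
with the classic uniform fan-in scheme, so a single integer seed makes every
model build and training run bit-reproducible on one thread.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, concat

__all__ = ["Module", "Linear", "GRU", "conv2d", "depthwise_conv2d",
           "uniform_fan_in"]


def uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int) -> Tensor:
    """Trainable tensor ~ U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Module:
    """Tiny module base: recursive parameter collection and train/eval flag."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
        collect(self)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        """Flat name → array mapping, stable across builds of the same config."""
        out: dict[str, np.ndarray] = {}

        def walk(obj, prefix):
            if isinstance(obj, Tensor):
                if obj.requires_grad:
                    out[prefix] = obj.data
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    walk(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}.{i}")
        walk(self, "")
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        current = self._named_tensors()
        missing = set(current) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, tensor in current.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != tensor.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {tensor.shape}")
            tensor.data = arr.copy()

    def _named_tensors(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}

        def walk(obj, prefix):
            if isinstance(obj, Tensor):
                if obj.requires_grad:
                    out[prefix] = obj
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    walk(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}.{i}")
        walk(self, "")
        return out


class Linear(Module):
    """Affine map ``y = x @ W + b`` with uniform fan-in initialisation."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = uniform_fan_in(rng, (in_features, out_features), in_features)
        self.bias = uniform_fan_in(rng, (out_features,), in_features) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """Dense 2-D cross-correlation, stride 1.

    ``x``: (B, C_in, H, W); ``weight``: (C_out, C_in, kh, kw). Composed from
    autodiff primitives; with ``padding = dilation*(k-1)//2`` the spatial size
    is preserved for odd ``k``.
    """
    b, c_in, h, w = x.shape
    c_out, c_in_w, kh, kw = weight.shape
    if c_in != c_in_w:
        raise ValueError(f"channel mismatch: input has {c_in}, kernel expects {c_in_w}")
    xp = x.pad2d(padding, padding)
    hp, wp = xp.shape[-2:]
    h_out = hp - dilation * (kh - 1)
    w_out = wp - dilation * (kw - 1)
    if h_out < 1 or w_out < 1:
        raise ValueError("input smaller than dilated kernel; increase padding")
    out = None
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i * dilation:i * dilation + h_out,
                       j * dilation:j * dilation + w_out]
            # (B,Cin,H,W) x (Cout,Cin) -> (B,Cout,H,W)
            flat = patch.transpose(0, 2, 3, 1).reshape(b * h_out * w_out, c_in)
            wij = weight[:, :, i, j].transpose(1, 0)     # (Cin, Cout)
            term = (flat @ wij).reshape(b, h_out, w_out, c_out).transpose(0, 3, 1, 2)
            out = term if out is None else out + term
    if bias is not None:
        out = out + bias.reshape(1, c_out, 1, 1)
    return out


def depthwise_conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     padding: int = 0, dilation: int = 1) -> Tensor:
    """Per-channel 2-D cross-correlation; ``weight``: (C, kh, kw)."""
    b, c, h, w = x.shape
    c_w, kh, kw = weight.shape
    if c != c_w:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {c_w}")
    xp = x.pad2d(padding, padding)
    hp, wp = xp.shape[-2:]
    h_out = hp - dilation * (kh - 1)
    w_out = wp - dilation * (kw - 1)
    if h_out < 1 or w_out < 1:
        raise ValueError("input smaller than dilated kernel; increase padding")
    out = None
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i * dilation:i * dilation + h_out,
                       j * dilation:j * dilation + w_out]
            term = patch * weight[:, i, j].reshape(1, c, 1, 1)
            out = term if out is None else out + term
    if bias is not None:
        out = out + bias.reshape(1, c, 1, 1)
    return out


class GRUCell(Module):
    """Single gated recurrent unit layer.

    Gate layout follows the standard reset/update/candidate split:
    ``r = σ(W_ir x + W_hr h + b)``, ``z = σ(W_iz x + W_hz h + b)``,
    ``n = tanh(W_in x + r ⊙ (W_hn h + b_hn))``, ``h' = (1−z) n + z h``.
    """

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator):
        self.input_size = input_size
        self.hidden_size = hidden_size
        h = hidden_size
        self.w_ih = uniform_fan_in(rng, (input_size, 3 * h), h)
        self.w_hh = uniform_fan_in(rng, (h, 3 * h), h)
        self.b_ih = uniform_fan_in(rng, (3 * h,), h)
        self.b_hh = uniform_fan_in(rng, (3 * h,), h)

    def step(self, x_t: Tensor, h_prev: Tensor) -> Tensor:
        hs = self.hidden_size
        gi = x_t @ self.w_ih + self.b_ih
        gh = h_prev @ self.w_hh + self.b_hh
        r = (gi[:, :hs] + gh[:, :hs]).sigmoid()
        z = (gi[:, hs:2 * hs] + gh[:, hs:2 * hs]).sigmoid()
        n = (gi[:, 2 * hs:] + r * gh[:, 2 * hs:]).tanh()
        return (1.0 - z) * n + z * h_prev


class GRU(Module):
    """Stack of GRU layers consuming a (batch, time, features) sequence."""

    def __init__(self, input_size: int, hidden_size: int, num_layers: int,
                 rng: np.random.Generator):
        if num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        self.hidden_size = hidden_size
        self.layers = [
            GRUCell(input_size if i == 0 else hidden_size, hidden_size, rng)
            for i in range(num_layers)
        ]

    def __call__(self, seq: Tensor) -> Tensor:
        """Return the final hidden state of the top layer, shape (batch, hidden)."""
        b, t, _ = seq.shape
        states = [Tensor(np.zeros((b, self.hidden_size))) for _ in self.layers]
        for step in range(t):
            x_t = seq[:, step, :]
            for li, cell in enumerate(self.layers):
                states[li] = cell.step(x_t, states[li])
                x_t = states[li]
        return states[-1]
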