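"""The full pixel classifier: ODConv ∥ LSK → fuse → GRU → MLP → softmax.

The two feature branches run in parallel on the input cube and are fused by
elementwise addition (channel concatenation available by config). The fused
cube is reshaped so the spectral bands become a sequence — one GRU step per
band, the flattened spatial positions as the per-step feature vector — and
a two-layer GRU summarises the spectrum into a 128-wide hidden state. A
two-layer perceptron (128 → 256 → M, ReLU) produces class logits, and a
softmax the class probabilities.

Ablation switches ``use_odc`` / ``use_lsk`` / ``improved_lsk`` reproduce the
six module combinations studied for the architecture; a disabled branch is
replaced by the raw input (residual pass-through).
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass, field
from io import BytesIO
from pathlib import Path

import numpy as np

from ._autograd import Tensor, as_tensor, concat
from ._layers import GRU, Linear, Module
from .lsk import LSKBlock
from .odconv import ODConv

__all__ = ["NetworkConfig", "LOMLPRNN", "reshape_for_rnn",
           "save_checkpoint", "load_checkpoint"]

_CHECKPOINT_VERSION = 1


@dataclass
class NetworkConfig:
    """Architecture hyperparameters; defaults follow the deployed setup."""

    bands: int = 12
    n_classes: int = 7
    patch: int = 1
    gru_layers: int = 2
    gru_hidden: int = 128
    mlp_hidden: int = 256
    use_odc: bool = True
    use_lsk: bool = True
    improved_lsk: bool = True
    fusion: str = "add"              # "add" | "concat"
    head_activation: str = "relu"    # "relu" | "sigmoid"
    odconv: dict = field(default_factory=lambda: {
        "n_kernels": 4, "kernel_size": 1, "reduction": 4, "temperature": 1.0})
    lsk: dict = field(default_factory=lambda: {
        "branch_kernels": ((5, 1), (7, 3)), "attn_kernel": 7,
        "heads": 4, "embed_dim": None})

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.gru_layers < 1:
            raise ValueError("gru_layers must be >= 1")
        if self.fusion not in ("add", "concat"):
            raise ValueError("fusion must be 'add' or 'concat'")
        if self.head_activation not in ("relu", "sigmoid"):
            raise ValueError("head_activation must be 'relu' or 'sigmoid'")

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "lsk" in d and "branch_kernels" in d["lsk"]:
            d["lsk"] = dict(d["lsk"])
            d["lsk"]["branch_kernels"] = tuple(
                tuple(p) for p in d["lsk"]["branch_kernels"])
        return cls(**d)


def reshape_for_rnn(fused: Tensor) -> Tensor:
    """(batch, bands, H, W) → (batch, T=bands, H·W): bands become time steps."""
    fused = as_tensor(fused)
    b, bands, h, w = fused.shape
    return fused.reshape(b, bands, h * w)


class LOMLPRNN(Module):
    """The assembled classifier."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.bands
        self.odc = ODConv(c, c, rng=rng, **config.odconv) if config.use_odc else None
        self.lsk = (LSKBlock(c, improved=config.improved_lsk, rng=rng,
                             **config.lsk)
                    if config.use_lsk else None)
        feat_bands = 2 * c if config.fusion == "concat" else c
        self.gru = GRU(input_size=config.patch * config.patch,
                       hidden_size=config.gru_hidden,
                       num_layers=config.gru_layers, rng=rng)
        self._feat_bands = feat_bands
        self.fc1 = Linear(config.gru_hidden, config.mlp_hidden, rng)
        self.fc2 = Linear(config.mlp_hidden, config.n_classes, rng)

    # ------------------------------------------------------------ components
    def fuse_parallel(self, odc_feat: Tensor, lsk_feat: Tensor) -> Tensor:
        if self.config.fusion == "concat":
            return concat([odc_feat, lsk_feat], axis=1)
        if odc_feat.shape != lsk_feat.shape:
            raise ValueError(
                f"additive fusion requires equal shapes, got "
                f"{odc_feat.shape} vs {lsk_feat.shape}")
        return odc_feat + lsk_feat

    def mlp_head(self, hidden: Tensor) -> Tensor:
        if hidden.shape[-1] != self.config.gru_hidden:
            raise ValueError(
                f"hidden width {hidden.shape[-1]} != {self.config.gru_hidden}")
        z = self.fc1(hidden)
        z = z.relu() if self.config.head_activation == "relu" else z.sigmoid()
        return self.fc2(z)

    def features(self, x: Tensor) -> Tensor:
        """Parallel branch extraction and fusion.

        Each enabled branch is residual (``x + branch(x)``), so a disabled
        branch degenerates to the raw input and the fused feature always
        retains the spectral ordering the GRU consumes.
        """
        x = as_tensor(x)
        if x.ndim != 4 or x.shape[1] != self.config.bands:
            raise ValueError(
                f"expected (batch, {self.config.bands}, H, W), got {x.shape}")
        odc_feat = x + self.odc(x) if self.odc is not None else x
        lsk_feat = x + self.lsk(x) if self.lsk is not None else x
        return self.fuse_parallel(odc_feat, lsk_feat)

    def logits(self, x: Tensor) -> Tensor:
        fused = self.features(x)
        seq = reshape_for_rnn(fused)
        # per-step feature width is H*W; the GRU input layer is sized lazily
        if seq.shape[-1] != self.gru.layers[0].input_size:
            raise ValueError(
                f"GRU expects per-step width {self.gru.layers[0].input_size}, "
                f"got {seq.shape[-1]} (patch size mismatch)")
        hidden = self.gru(seq)
        return self.mlp_head(hidden)

    def __call__(self, x: Tensor) -> Tensor:
        """Class probabilities (batch, M); rows sum to 1."""
        return self.logits(x).softmax(axis=1)

    def predict(self, x) -> np.ndarray:
        """Argmax class labels 1..M; ties break toward the lowest class id."""
        probs = self(as_tensor(x)).data
        return probs.argmax(axis=1) + 1


# ------------------------------------------------------------- checkpointing

def save_checkpoint(model: LOMLPRNN, path: str | Path) -> Path:
    """Single-archive checkpoint: config JSON + named parameter arrays."""
    path = Path(path)
    state = model.state_dict()
    cfg = asdict(model.config)
    cfg["lsk"] = dict(cfg["lsk"])
    cfg["lsk"]["branch_kernels"] = [list(p) for p in
                                    model.config.lsk["branch_kernels"]]
    meta = {"version": _CHECKPOINT_VERSION, "config": cfg}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        buf = BytesIO()
        np.savez(buf, **state)
        zf.writestr("params.npz", buf.getvalue())
    return path


def load_checkpoint(path: str | Path,
                    expect_bands: int | None = None) -> LOMLPRNN:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("version") != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
        with np.load(BytesIO(zf.read("params.npz"))) as z:
            state = {k: z[k] for k in z.files}
    config = NetworkConfig.from_dict(meta["config"])
    if expect_bands is not None and config.bands != expect_bands:
        raise ValueError(
            f"checkpoint was trained on {config.bands} bands, data has "
            f"{expect_bands}")
    model = LOMLPRNN(config)
    model.load_state_dict(state)
    return model
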