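"""ResTransNet: a hybrid residual-CNN / transformer classifier.

A three-stage residual convolutional backbone (output channels 16, 32, 64,
each stage halving resolution) turns a 128x128 lesion patch into a 64x16x16
feature map.  The map is cut into a grid of patches, linearly projected to
embedding dimension d, a learned class token is prepended and learned position
embeddings are added.  A stack of pre-norm transformer blocks
(Z = MSA(LN(X)) + X, Y = MLP(LN(Z)) + Z, GELU MLP) mixes the sequence, and a
two-layer ReLU classifier reads the final class-token state Y(0) into two
logits (PD-1-negative / PD-1-positive).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    LayerNorm,
    Linear,
    Module,
    ModuleList,
    Tensor,
    concat,
)


@dataclass
class ModelConfig:
    channels: tuple[int, int, int] = (16, 32, 64)
    depth: int = 12            # number of transformer blocks
    embed_dim: int = 64        # d
    n_heads: int = 4
    patch_grid: int = 4        # patches per side of the feature map
    mlp_ratio: int = 4
    classifier_hidden: int | None = None  # default d // 2
    image_size: int = 128
    seed: int = 0

    def __post_init__(self):
        self.channels = tuple(self.channels)
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        feat = self.image_size // 8
        if feat % self.patch_grid:
            raise ValueError(
                f"patch_grid {self.patch_grid} does not divide the "
                f"{feat}x{feat} feature map")


def attention(q: Tensor, k: Tensor, v: Tensor) -> tuple[Tensor, np.ndarray]:
    """Scaled dot-product attention softmax(Q K^T / sqrt(d_k)) V.

    Works on (..., N, d_k) stacks; returns the attended values and the
    (detached) attention weight matrix, whose rows sum to 1.
    """
    d_k = q.shape[-1]
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * (
        1.0 / np.sqrt(d_k))
    weights = scores.softmax(axis=-1)
    return weights @ v, weights.data


def ce_loss(y_hat: Tensor | np.ndarray, y: np.ndarray,
            class_weights: np.ndarray | None = None,
            sample_weights: np.ndarray | None = None,
            reduction: str = "mean") -> Tensor:
    """Binary cross-entropy -(y log yhat + (1-y) log(1-yhat)).

    ``y_hat`` holds predicted PD-1-positive probabilities in (0, 1); values
    are clamped to [1e-7, 1 - 1e-7] for numerical safety.  Optional per-class
    weights implement loss re-weighting and per-sample weights implement the
    gradient penalty; reduction is 'mean' (default), 'sum', or 'none'.
    """
    if not isinstance(y_hat, Tensor):
        y_hat = Tensor(np.asarray(y_hat, dtype=np.float64))
    y_int = np.asarray(y).astype(int)
    y = y_int.astype(y_hat.data.dtype)
    eps = 1e-7
    p = y_hat.clip(eps, 1.0 - eps)
    per_sample = -(y * p.log() + (1.0 - y) * (1.0 - p).log())
    w = np.ones(len(y))
    if class_weights is not None:
        w = w * np.asarray(class_weights)[y_int]
    if sample_weights is not None:
        w = w * np.asarray(sample_weights)
    per_sample = per_sample * w.astype(per_sample.data.dtype)
    if reduction == "mean":
        return per_sample.mean()
    if reduction == "sum":
        return per_sample.sum()
    if reduction == "none":
        return per_sample
    raise ValueError(f"unknown reduction {reduction!r}")


class MultiHeadSelfAttention(Module):
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        self.d = d
        self.n_heads = n_heads
        self.d_k = d // n_heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.last_attn: np.ndarray | None = None  # (B, heads, N, N)

    def _split(self, t: Tensor, B: int, N: int) -> Tensor:
        return t.reshape(B, N, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        B, N, _ = x.shape
        q = self._split(self.wq(x), B, N)
        k = self._split(self.wk(x), B, N)
        v = self._split(self.wv(x), B, N)
        out, self.last_attn = attention(q, k, v)
        out = out.transpose(0, 2, 1, 3).reshape(B, N, self.d)
        return self.wo(out)


class TransformerBlock(Module):
    """Pre-norm residual block: Z = MSA(LN(X)) + X, Y = MLP(LN(Z)) + Z."""

    def __init__(self, d: int, n_heads: int, mlp_ratio: int,
                 rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(d)
        self.msa = MultiHeadSelfAttention(d, n_heads, rng)
        self.ln2 = LayerNorm(d)
        self.fc1 = Linear(d, mlp_ratio * d, rng)
        self.fc2 = Linear(mlp_ratio * d, d, rng)

    def forward(self, x: Tensor) -> Tensor:
        z = self.msa(self.ln1(x)) + x
        y = self.fc2(self.fc1(self.ln2(z)).gelu()) + z
        return y


class ResidualBlock(Module):
    """Two 3x3 conv + BN + ReLU with a projected shortcut when downsampling."""

    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, stride=1, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.proj = Conv2d(c_in, c_out, 1, stride=stride, padding=0, rng=rng)
            self.proj_bn = BatchNorm2d(c_out)
        else:
            self.proj = None

    def shortcut(self, x: Tensor) -> Tensor:
        return self.proj_bn(self.proj(x)) if self.proj is not None else x

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        return (h + self.shortcut(x)).relu()


class ConvBackbone(Module):
    """Three stride-2 residual stages; a 128x128 single-channel patch becomes
    a 16x16 map with channels[-1] channels (held channels-last internally)."""

    def __init__(self, channels: tuple[int, int, int], rng: np.random.Generator):
        super().__init__()
        c0, c1, c2 = channels
        self.block1 = ResidualBlock(1, c0, stride=2, rng=rng)
        self.block2 = ResidualBlock(c0, c1, stride=2, rng=rng)
        self.block3 = ResidualBlock(c1, c2, stride=2, rng=rng)

    def forward(self, x: Tensor, capture: dict | None = None) -> Tensor:
        # (B, 1, H, W) -> channels-last (B, H, W, 1); C=1 so this is a view
        B, C, H, W = x.shape
        x = x.reshape(B, H, W, C)
        for i, block in enumerate((self.block1, self.block2, self.block3), start=1):
            h = block.bn1(block.conv1(x)).relu()
            if capture is not None:
                capture[f"backbone.block{i}.conv1"] = h.data
            h = block.bn2(block.conv2(h))
            x = (h + block.shortcut(x)).relu()
            if capture is not None:
                capture[f"backbone.block{i}.conv2"] = x.data
        return x


class PatchEmbed(Module):
    """Cut the feature map into a patch grid, project, prepend the class
    token, and add position embeddings."""

    def __init__(self, c: int, feat_hw: int, grid: int, d: int,
                 rng: np.random.Generator):
        super().__init__()
        self.grid = grid
        self.patch_hw = feat_hw // grid
        self.n_patches = grid * grid
        self.proj = Linear(c * self.patch_hw**2, d, rng)
        from .nn.modules import _trunc_normal
        self.class_token = Tensor(
            _trunc_normal(rng, (1, 1, d)).astype(np.float32), requires_grad=True)
        self.pos_embed = Tensor(
            _trunc_normal(rng, (1, self.n_patches + 1, d)).astype(np.float32),
            requires_grad=True)

    def patchify(self, feature: Tensor) -> Tensor:
        """Channels-last (B, H, W, C) -> (B, n, ph * pw * C) raster-ordered
        patch vectors."""
        B, H, W, C = feature.shape
        g, ph = self.grid, self.patch_hw
        x = feature.reshape(B, g, ph, g, ph, C)
        x = x.transpose(0, 1, 3, 2, 4, 5)  # B, g, g, ph, pw, C
        return x.reshape(B, g * g, ph * ph * C)

    def forward(self, feature: Tensor) -> Tensor:
        B = feature.shape[0]
        tokens = self.proj(self.patchify(feature))
        cls = self.class_token.broadcast_to((B, 1, tokens.shape[-1]))
        seq = concat([cls, tokens], axis=1)
        return seq + self.pos_embed


class ClassifierHead(Module):
    """linear -> ReLU -> linear on the class-token state only."""

    def __init__(self, d: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(d, hidden, rng)
        self.fc2 = Linear(hidden, 2, rng)

    def forward(self, cls_state: Tensor) -> Tensor:
        return self.fc2(self.fc1(cls_state).relu())


class ResTransNet(Module):
    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        feat_hw = cfg.image_size // 8
        self.backbone = ConvBackbone(cfg.channels, rng)
        self.embed = PatchEmbed(cfg.channels[-1], feat_hw, cfg.patch_grid,
                                cfg.embed_dim, rng)
        self.blocks = ModuleList([
            TransformerBlock(cfg.embed_dim, cfg.n_heads, cfg.mlp_ratio, rng)
            for _ in range(cfg.depth)
        ])
        self.norm = LayerNorm(cfg.embed_dim)
        hidden = cfg.classifier_hidden or max(cfg.embed_dim // 2, 2)
        self.head = ClassifierHead(cfg.embed_dim, hidden, rng)
        self.activations: dict[str, np.ndarray] = {}

    # ------------------------------------------------------------ sub-passes
    def transformer_forward(self, seq: Tensor, capture: dict | None = None) -> Tensor:
        for k, block in enumerate(self.blocks):
            seq = block(seq)
            if capture is not None:
                capture[f"transformer.block{k}"] = seq.data
        return seq

    def head_forward(self, seq: Tensor) -> Tensor:
        cls_state = self.norm(seq)[:, 0, :]
        return self.head(cls_state)

    def forward(self, x, capture: bool = False) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2] != self.config.image_size:
            raise ValueError(f"expected (B, 1, {self.config.image_size}, "
                             f"{self.config.image_size}) input, got {x.shape}")
        cap = {} if capture else None
        feature = self.backbone(x, capture=cap)
        seq = self.embed(feature)
        seq = self.transformer_forward(seq, capture=cap)
        if capture:
            self.activations = cap
        return self.head_forward(seq)

    # ------------------------------------------------------------- inference
    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """PD-1-positive probability per image, eval mode, batched."""
        was_training = self.training
        self.eval()
        probs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size])
            probs.append(logits.softmax(axis=-1).data[:, 1])
        if was_training:
            self.train()
        return np.concatenate(probs) if probs else np.empty(0)

    # --------------------------------------------------- per-sample gradients
    def penalty_scope_parameters(self) -> list[tuple[str, Tensor]]:
        """Parameters whose per-sample gradients feed the gradient penalty:
        the last transformer block, the final norm, and the classifier head."""
        scope = []
        last = len(self.blocks) - 1
        for name, p in self.named_parameters():
            if (name.startswith(f"blocks.{last}.") or name.startswith("norm.")
                    or name.startswith("head.")):
                scope.append((name, p))
        return scope

    def per_sample_gradients(self, x: np.ndarray, y: np.ndarray,
                             scope: str = "penalty") -> np.ndarray:
        """Flattened per-sample loss gradients g_i, stacked as (n, P).

        scope='penalty' differentiates through the last transformer block and
        classifier head only (the sequence entering the last block is treated
        as data); scope='full' loops full batch-1 passes over every parameter.
        """
        if scope == "full":
            params = [p for _, p in self.named_parameters()]
            grads = []
            for i in range(len(x)):
                self.zero_grad()
                logits = self.forward(x[i:i + 1])
                probs = logits.softmax(axis=-1)[:, 1]
                ce_loss(probs, y[i:i + 1]).backward()
                grads.append(np.concatenate([
                    (p.grad if p.grad is not None else np.zeros_like(p.data)).ravel()
                    for p in params]))
            self.zero_grad()
            return np.stack(grads)
        if scope != "penalty":
            raise ValueError(f"unknown scope {scope!r}")

        xt = Tensor(np.asarray(x, dtype=np.float32))
        feature = self.backbone(xt)
        seq = self.embed(feature)
        for block in list(self.blocks)[:-1]:
            seq = block(seq)
        seq_data = seq.data
        params = [p for _, p in self.penalty_scope_parameters()]
        last_block = self.blocks[len(self.blocks) - 1]
        grads = []
        for i in range(len(x)):
            self.zero_grad()
            si = Tensor(seq_data[i:i + 1])
            out = self.head_forward(last_block(si))
            probs = out.softmax(axis=-1)[:, 1]
            ce_loss(probs, y[i:i + 1]).backward()
            grads.append(np.concatenate([
                (p.grad if p.grad is not None else np.zeros_like(p.data)).ravel()
                for p in params]))
        self.zero_grad()
        return np.stack(grads)


# ------------------------------------------------------------- checkpointing
def save_checkpoint(model: ResTransNet, path: str) -> None:
    """Single-file state container: parameters, BN running stats, config."""
    arrays = {f"param:{name}": p.data for name, p in model.named_parameters()}
    for name, mod in _named_modules(model):
        if isinstance(mod, BatchNorm2d):
            arrays[f"bn_mean:{name}"] = mod.running_mean
            arrays[f"bn_var:{name}"] = mod.running_var
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> ResTransNet:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["config_json"]).decode())
        cfg_dict["channels"] = tuple(cfg_dict["channels"])
        model = ResTransNet(ModelConfig(**cfg_dict))
        params = dict(model.named_parameters())
        for key in data.files:
            if key.startswith("param:"):
                params[key[6:]].data = data[key]
            elif key.startswith("bn_mean:"):
                _get_module(model, key[8:]).running_mean = data[key].copy()
            elif key.startswith("bn_var:"):
                _get_module(model, key[7:]).running_var = data[key].copy()
    return model


def _named_modules(module: Module, prefix: str = ""):
    yield prefix.rstrip("."), module
    for name, child in module._modules.items():
        yield from _named_modules(child, prefix + name + ".")


def _get_module(model: Module, dotted: str) -> Module:
    mod = model
    for part in dotted.split("."):
        if part:
            mod = mod._modules[part]
    return mod
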