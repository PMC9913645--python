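"""Model introspection: feature maps from named layers and a class-activation
heatmap from the class-token attention of the last transformer block."""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize

from .model import ResTransNet
from .preprocess import PATCH_SIZE

# The original report indexes convolution layers by a flat numbering it never
# defines; these aliases are approximate structural equivalents.
LAYER_ALIASES = {
    "conv_6": "backbone.block2.conv1",
    "conv_27": "backbone.block3.conv2",
    "transformer_last": "transformer.last",
}


def feature_maps(model: ResTransNet, image: np.ndarray,
                 selectors: list[str], first_k: int = 4) -> dict[str, np.ndarray]:
    """Activations of the requested layers for one image (eval mode).

    Selectors are structural paths ('backbone.block2.conv1',
    'transformer.block11') or the documented aliases.  Convolutional
    activations are returned as (first_k, h, w) filter grids; transformer
    activations as the raw (n+1, d) token sequence.
    """
    was_training = model.training
    model.eval()
    x = np.asarray(image, dtype=np.float32).reshape(1, 1, PATCH_SIZE, PATCH_SIZE)
    model.forward(x, capture=True)
    if was_training:
        model.train()
    acts = model.activations
    last = len(model.blocks) - 1
    out = {}
    for sel in selectors:
        key = LAYER_ALIASES.get(sel, sel)
        if key == "transformer.last":
            key = f"transformer.block{last}"
        if key not in acts:
            raise KeyError(f"unknown layer selector {sel!r}; "
                           f"available: {sorted(acts)}")
        a = acts[key][0]
        if a.ndim == 3:  # channels-last conv activation -> (first_k, h, w)
            out[sel] = np.moveaxis(a, -1, 0)[:first_k].copy()
        else:            # transformer token sequence (n+1, d)
            out[sel] = a.copy()
    return out


def _normalize_unit(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    return (a - lo) / (hi - lo) if hi > lo else a - lo


def attention_to_heatmap(class_to_patch: np.ndarray, grid: int,
                         size: int = PATCH_SIZE) -> np.ndarray:
    """Reshape class-token-to-patch attention weights (n,) to the patch grid
    and bilinearly upsample to the input resolution, min-max normalised.
    A constant attention pattern yields a constant (all-zero range) map."""
    w = np.asarray(class_to_patch, dtype=float).reshape(grid, grid)
    up = _sk_resize(w, (size, size), order=1, anti_aliasing=False,
                    preserve_range=True)
    return _normalize_unit(up)


def class_activation_map(model: ResTransNet, image: np.ndarray,
                         rollout: bool = False) -> np.ndarray:
    """128x128 class-activation heatmap in [0, 1].

    Default: the last block's class-token attention row, averaged over heads.
    With ``rollout=True`` attention is propagated through all blocks via
    attention rollout (0.5 I + 0.5 A, row-normalised, multiplied front to
    back) before the class row is read.
    """
    was_training = model.training
    model.eval()
    x = np.asarray(image, dtype=np.float32).reshape(1, 1, PATCH_SIZE, PATCH_SIZE)
    model.forward(x)
    if was_training:
        model.train()
    attns = [blk.msa.last_attn[0].mean(axis=0) for blk in model.blocks]  # (N, N)
    if rollout:
        n = attns[0].shape[0]
        acc = np.eye(n)
        for a in attns:
            mixed = 0.5 * np.eye(n) + 0.5 * a
            mixed = mixed / mixed.sum(axis=-1, keepdims=True)
            acc = mixed @ acc
        class_row = acc[0, 1:]
    else:
        class_row = attns[-1][0, 1:]
    return attention_to_heatmap(class_row, model.config.patch_grid)
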