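"""Image -> spatial feature tokens.

Two backbone kinds share one interface:

* ``tiny`` — three stride-2 3x3 conv blocks (3->8->16->32 channels, ReLU),
  randomly initialized and trainable; a 224x224 input yields a 28x28 grid of
  32-channel tokens (224 / 2**3), a 96x96 input a 12x12 grid.  Self-contained
  and fast on CPU.
* ``resnet50`` — the pretrained deep residual trunk with the classifier head
  removed (7x7 grid of 2048-channel tokens for 224x224 input).  Requires the
  optional ``torch``/``torchvision`` dependency and a weight download, so it
  is loaded lazily and is never needed by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from ppgbp.config import BackboneConfig
from ppgbp.nn import ops

TINY_CHANNELS = (8, 16, 32)
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


@dataclass
class TokenGrid:
    """S x C spatial tokens from one image."""

    tokens: np.ndarray
    grid_shape: Tuple[int, int]
    source_modality: str = ""

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens, dtype=float)
        if self.tokens.ndim != 2 or self.tokens.shape[0] < 1:
            raise ValueError("tokens must be a non-empty S x C matrix")
        if self.grid_shape[0] * self.grid_shape[1] != self.tokens.shape[0]:
            raise ValueError("grid_shape inconsistent with token count")
        if not np.all(np.isfinite(self.tokens)):
            raise ValueError("tokens must be finite")


def init_tiny_params(rng: np.random.Generator, prefix: str = "") -> Dict[str, np.ndarray]:
    """He-normal weights for the three conv blocks (variance-preserving
    through the ReLU cascade)."""
    params: Dict[str, np.ndarray] = {}
    c_in = 3
    for i, c_out in enumerate(TINY_CHANNELS, start=1):
        fan_in = 3 * 3 * c_in
        params[f"{prefix}conv{i}.W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(3, 3, c_in, c_out)
        )
        params[f"{prefix}conv{i}.b"] = np.zeros(c_out)
        c_in = c_out
    return params


def tiny_forward(images: np.ndarray, params: Dict[str, np.ndarray], prefix: str = ""):
    """Batch of uint8 NHWC images -> (tokens (B, S, 32), grid_shape, cache).

    Images are mapped to an ink-positive encoding (trace = 1, background =
    0) so activations are driven by the trace rather than by the constant
    background.
    """
    dtype = params[f"{prefix}conv1.W"].dtype
    x = (1.0 - np.asarray(images, dtype=dtype) / dtype.type(255.0)).astype(dtype)
    caches = []
    for i in range(1, len(TINY_CHANNELS) + 1):
        x, conv_cache = ops.conv2d_forward(
            x, params[f"{prefix}conv{i}.W"], params[f"{prefix}conv{i}.b"], stride=2, pad=1
        )
        x, relu_mask = ops.relu_forward(x)
        caches.append((conv_cache, relu_mask))
    b, gh, gw, c = x.shape
    tokens = x.reshape(b, gh * gw, c)
    return tokens, (gh, gw), caches


def tiny_backward(dtokens: np.ndarray, grid_shape, caches, prefix: str = "") -> Dict[str, np.ndarray]:
    """Gradients w.r.t. the conv parameters (input gradient discarded)."""
    b, s, c = dtokens.shape
    dx = dtokens.reshape(b, grid_shape[0], grid_shape[1], c)
    grads: Dict[str, np.ndarray] = {}
    for i in range(len(TINY_CHANNELS), 0, -1):
        conv_cache, relu_mask = caches[i - 1]
        dx = ops.relu_backward(dx, relu_mask)
        dx, dw, db = ops.conv2d_backward(dx, conv_cache)
        grads[f"{prefix}conv{i}.W"] = dw
        grads[f"{prefix}conv{i}.b"] = db
    return grads


_RESNET = {}


def _resnet50_trunk(pretrained: bool):
    try:
        import torch
        import torchvision
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise RuntimeError(
            "backbone kind 'resnet50' needs the optional torch/torchvision "
            "dependency (pip install ppgbp[resnet]); use kind='tiny' for a "
            "self-contained CPU backbone"
        ) from exc
    key = pretrained
    if key not in _RESNET:
        weights = torchvision.models.ResNet50_Weights.IMAGENET1K_V1 if pretrained else None
        net = torchvision.models.resnet50(weights=weights)
        net.eval()
        _RESNET[key] = (torch, torch.nn.Sequential(*list(net.children())[:-2]))
    return _RESNET[key]


def resnet50_tokens(images: np.ndarray, pretrained: bool = True) -> np.ndarray:
    """Final conv-stage tokens of the residual trunk (no grad, eval mode)."""
    torch, trunk = _resnet50_trunk(pretrained)
    x = np.asarray(images, dtype=np.float32) / 255.0
    if pretrained:
        x = (x - IMAGENET_MEAN) / IMAGENET_STD
    with torch.no_grad():
        feats = trunk(torch.from_numpy(x.transpose(0, 3, 1, 2)).float())
    f = feats.numpy()  # (B, 2048, 7, 7)
    b, c, gh, gw = f.shape
    return f.transpose(0, 2, 3, 1).reshape(b, gh * gw, c)


def extract_tokens(
    images: np.ndarray,
    config: BackboneConfig,
    params: Dict[str, np.ndarray] | None = None,
    modality: str = "",
) -> List[TokenGrid]:
    """Map a batch of images to per-image token grids."""
    config.validate()
    imgs = np.asarray(images)
    if imgs.ndim == 3:
        imgs = imgs[None]
    if imgs.ndim != 4 or imgs.shape[3] != 3:
        raise ValueError(f"expected NHWC images with 3 channels, got {imgs.shape}")
    if config.kind == "tiny":
        if params is None:
            params = init_tiny_params(np.random.default_rng(config.seed))
        tokens, grid, _ = tiny_forward(imgs, params)
    else:
        tokens = resnet50_tokens(imgs, pretrained=config.pretrained)
        side = int(np.sqrt(tokens.shape[1]))
        grid = (side, side)
    return [TokenGrid(tokens=t, grid_shape=grid, source_modality=modality) for t in tokens]


def pool_embedding(tokens: TokenGrid) -> np.ndarray:
    """Global average pooling: mean over spatial positions per channel."""
    return tokens.tokens.mean(axis=0)


__all__ = [
    "TokenGrid",
    "TINY_CHANNELS",
    "init_tiny_params",
    "tiny_forward",
    "tiny_backward",
    "resnet50_tokens",
    "extract_tokens",
    "pool_embedding",
]
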