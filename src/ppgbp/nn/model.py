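"""End-to-end model: image triplet -> tokens -> cross-attention -> (SBP, DBP).

The network predicts z-scored pressures internally (the output layer starts
near zero, and the optimizer moves parameters by at most ~lr per step, so
raw mmHg targets with a ~100 mmHg offset would dominate the first thousands
of steps); the stored target mean/scale de-standardizes predictions back to
mmHg.  Before training the scale is identity, so the functional equations
hold exactly in unit tests.
"""

from __future__ import annotations

import json
import os
from typing import Dict, List, Optional

import numpy as np

from ppgbp.config import BackboneConfig, MHCAConfig, RenderSpec, derive_seed
from ppgbp.imaging import ModalityImageTriplet, render_triplet
from ppgbp.nn import attention, backbone as bb, ops
from ppgbp.nn.attention import BPEstimate
from ppgbp.preprocess import SegmentWindow

MODALITIES = ("ppg", "vppg", "appg")


class CrossAttentionRegressor:
    """Trainable cross-attention blood-pressure regressor.

    Holds a flat parameter dict; ``forward_batch``/``backward_batch`` give
    the differentiable path used by training, and ``predict_window`` the
    user-facing path from a segment window to a BP estimate.
    """

    def __init__(
        self,
        backbone_config: Optional[BackboneConfig] = None,
        mhca_config: Optional[MHCAConfig] = None,
        render_spec: Optional[RenderSpec] = None,
        seed: int = 0,
        dtype=np.float64,
    ):
        self.backbone_config = (backbone_config or BackboneConfig()).validate()
        self.mhca_config = (mhca_config or MHCAConfig()).validate()
        self.render_spec = (render_spec or RenderSpec()).validate()
        self.seed = seed
        self.dtype = np.dtype(dtype)
        self.y_mean = np.zeros(2)
        self.y_scale = np.ones(2)
        rng = np.random.default_rng(derive_seed(seed, 11))
        self.params: Dict[str, np.ndarray] = {}
        if self.backbone_config.kind == "tiny":
            for mod in MODALITIES:
                self.params.update(bb.init_tiny_params(rng, prefix=f"{mod}."))
        self.params.update(
            attention.init_mhca_params(
                rng, self._attention_channels(), self.mhca_config
            )
        )
        if self.dtype != np.float64:
            self.params = {k: v.astype(self.dtype) for k, v in self.params.items()}

    def _attention_channels(self) -> int:
        return self.backbone_config.token_channels

    # ------------------------------------------------------------ forward

    def _backbone_tokens(self, images: Dict[str, np.ndarray]):
        """Per-modality (B, S, C) tokens plus caches for the backward pass.

        Tokens are standardized per position over channels (layer norm,
        no affine) before entering the fusion block: it removes the long
        symmetry-breaking plateau of attention training.
        """
        tokens, caches, ln_caches, grid = {}, {}, {}, None
        for mod in MODALITIES:
            if self.backbone_config.kind == "tiny":
                tok, grid, cache = bb.tiny_forward(images[mod], self.params, prefix=f"{mod}.")
            else:
                tok = bb.resnet50_tokens(images[mod], pretrained=self.backbone_config.pretrained)
                side = int(np.sqrt(tok.shape[1]))
                grid, cache = (side, side), None
            tok, ln_cache = ops.layernorm_forward(tok)
            if self.mhca_config.attend_over == "vector":
                tok = tok.mean(axis=1, keepdims=True)
            tokens[mod] = tok
            caches[mod] = cache
            ln_caches[mod] = ln_cache
        return tokens, caches, ln_caches, grid

    def forward_batch(self, images: Dict[str, np.ndarray], need_grad: bool = True):
        """images[mod]: (B, H, W, 3) uint8 -> standardized predictions (B, 2)."""
        tokens, bb_caches, ln_caches, grid = self._backbone_tokens(images)
        x_fusion, attn, _, mhca_cache = attention.mhca_forward(
            tokens["ppg"], tokens["vppg"], tokens["appg"], self.params, self.mhca_config
        )
        preds, head_cache = ops.linear_forward(
            x_fusion, self.params["head.W"], self.params["head.b"]
        )
        cache = (bb_caches, ln_caches, grid, mhca_cache, head_cache) if need_grad else None
        return preds, attn, cache

    def backward_batch(self, dpreds: np.ndarray, cache, train_backbone: bool = True):
        bb_caches, ln_caches, grid, mhca_cache, head_cache = cache
        grads: Dict[str, np.ndarray] = {}
        dxf, grads["head.W"], grads["head.b"] = ops.linear_backward(dpreds, head_cache)
        mhca_grads, dtq, dtk, dtv = attention.mhca_backward(dxf, mhca_cache, self.mhca_config)
        grads.update(mhca_grads)
        if (
            train_backbone
            and self.backbone_config.kind == "tiny"
            and not self.backbone_config.freeze
        ):
            if self.mhca_config.attend_over == "vector":
                s = grid[0] * grid[1]
                dtq, dtk, dtv = (
                    np.broadcast_to(d / s, (d.shape[0], s, d.shape[2])) for d in (dtq, dtk, dtv)
                )
            for mod, dt in zip(MODALITIES, (dtq, dtk, dtv)):
                dt = ops.layernorm_backward(np.ascontiguousarray(dt), ln_caches[mod])
                grads.update(
                    bb.tiny_backward(np.ascontiguousarray(dt), grid, bb_caches[mod], prefix=f"{mod}.")
                )
        return grads

    # ------------------------------------------------------------ predict

    def destandardize(self, preds: np.ndarray) -> np.ndarray:
        return preds * self.y_scale + self.y_mean

    def images_from_window(self, window: SegmentWindow) -> Dict[str, np.ndarray]:
        trip = render_triplet(window, self.render_spec)
        return {mod: img[None] for mod, img in zip(MODALITIES, trip.images)}

    def images_from_triplet(self, trip: ModalityImageTriplet) -> Dict[str, np.ndarray]:
        return {mod: img[None] for mod, img in zip(MODALITIES, trip.images)}

    def predict_window(self, window: SegmentWindow) -> BPEstimate:
        preds, _, _ = self.forward_batch(self.images_from_window(window), need_grad=False)
        sbp, dbp = self.destandardize(preds)[0]
        return BPEstimate(sbp_hat=float(sbp), dbp_hat=float(dbp), window_id=window.window_id)

    def predict_triplets(self, triplets: List[ModalityImageTriplet], batch_size: int = 32) -> np.ndarray:
        out = []
        for i in range(0, len(triplets), batch_size):
            chunk = triplets[i : i + batch_size]
            images = {
                mod: np.stack([t.images[j] for t in chunk])
                for j, mod in enumerate(MODALITIES)
            }
            preds, _, _ = self.forward_batch(images, need_grad=False)
            out.append(self.destandardize(preds))
        return np.concatenate(out, axis=0)

    # --------------------------------------------------------- parameters

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def trainable_names(self) -> List[str]:
        names = [n for n in self.params if not n.split(".")[0] in MODALITIES or ".adapter." in n]
        if (
            self.backbone_config.kind == "tiny"
            and not self.backbone_config.freeze
        ):
            names += [n for n in self.params if ".conv" in n]
        return sorted(set(names))

    def copy_params(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_params(self, params: Dict[str, np.ndarray]) -> None:
        for k, v in params.items():
            self.params[k] = np.asarray(v, dtype=self.dtype).copy()

    # --------------------------------------------------------- checkpoint

    def save(self, path: str) -> None:
        """Single-file archive with parameters, scaling and config."""
        meta = {
            "backbone": self.backbone_config.__dict__,
            "fusion": self.mhca_config.__dict__,
            "render": self.render_spec.__dict__,
            "seed": self.seed,
        }
        os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
        np.savez(
            path,
            __meta__=json.dumps(meta),
            __y_mean__=self.y_mean,
            __y_scale__=self.y_scale,
            **self.params,
        )

    @classmethod
    def load(cls, path: str) -> "CrossAttentionRegressor":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            model = cls(
                backbone_config=BackboneConfig(**meta["backbone"]),
                mhca_config=MHCAConfig(**meta["fusion"]),
                render_spec=RenderSpec(**meta["render"]),
                seed=meta["seed"],
            )
            model.y_mean = data["__y_mean__"]
            model.y_scale = data["__y_scale__"]
            for key in data.files:
                if not key.startswith("__"):
                    model.params[key] = data[key]
        return model


__all__ = ["CrossAttentionRegressor", "MODALITIES"]
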