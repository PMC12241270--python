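"""Multi-head cross-attention fusion of the three PPG modalities.

PPG tokens form the queries, vPPG tokens the keys, and aPPG tokens the
values:

    Q_i = X_PPG W_i^Q,  K_i = X_vPPG W_i^K,  V_i = X_aPPG W_i^V
    head_i = softmax(Q_i K_i^T / sqrt(d_k)) V_i
    MHCA = Concat(head_1 ... head_h) W^O

Each modality first passes through a ReLU adapter mapping the backbone's
token channels to ``d_model``; the per-head projections are stored stacked,
so column block i of ``attn.Wq`` is W_i^Q.  The fused vector is the mean of
the per-query fused tokens (``fusion_mode='concat'``); the alternative
``'head_mean'`` averages the h head outputs instead of concatenating them.
A fully connected head maps the fused vector to (SBP, DBP).

Attention runs over the backbone's spatial token sequence: with a single
pooled vector per modality the softmax has one key, every weight is 1, and
the output simply passes the value modality through.  That degenerate
reading remains available via ``attend_over='vector'``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple, Union

import numpy as np

from ppgbp.config import MHCAConfig
from ppgbp.nn import ops
from ppgbp.nn.backbone import TokenGrid

ArrayLike = Union[np.ndarray, TokenGrid]


@dataclass
class FusedRepresentation:
    """Fused d_model vector plus the attention maps that produced it."""

    x_fusion: np.ndarray
    attention_weights: np.ndarray  # (h, S_q, S_k), rows sum to 1
    fused_tokens: np.ndarray  # (S_q, d_out)


@dataclass
class BPEstimate:
    sbp_hat: float
    dbp_hat: float
    window_id: str = ""


def _tokens(x: ArrayLike) -> np.ndarray:
    arr = x.tokens if isinstance(x, TokenGrid) else np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected an S x C token matrix")
    return arr


def init_mhca_params(
    rng: np.random.Generator, token_channels: int, cfg: MHCAConfig
) -> Dict[str, np.ndarray]:
    """Fan-in-uniform adapters, Q/K/V/O projections and regression head."""
    cfg.validate()
    d = cfg.d_model
    params: Dict[str, np.ndarray] = {}
    for mod in ("ppg", "vppg", "appg"):
        params[f"{mod}.adapter.W"] = ops.fan_in_uniform(rng, (token_channels, d), token_channels)
        params[f"{mod}.adapter.b"] = np.zeros(d)
    for name in ("Wq", "Wk", "Wv"):
        params[f"attn.{name}"] = ops.fan_in_uniform(rng, (d, d), d)
    params["attn.Wo"] = ops.fan_in_uniform(rng, (d, d), d)
    d_out = d if cfg.fusion_mode == "concat" else cfg.d_k
    params["head.W"] = ops.fan_in_uniform(rng, (d_out, 2), d_out)
    params["head.b"] = np.zeros(2)
    return params


def scaled_dot_attention(
    q: np.ndarray, k: np.ndarray, v: np.ndarray, return_weights: bool = False
):
    """softmax(QK^T / sqrt(d_k)) V — output rows are convex combinations of V rows."""
    q, k, v = (np.asarray(a, dtype=float) for a in (q, k, v))
    if k.shape[0] == 0:
        raise ValueError("attention requires at least one key")
    out, weights, _ = ops.attention_forward(q, k, v)
    return (out, weights) if return_weights else out


def _split_heads(x: np.ndarray, h: int) -> np.ndarray:
    """(..., S, h*d_k) -> (..., h, S, d_k)"""
    *lead, s, d = x.shape
    return x.reshape(*lead, s, h, d // h).swapaxes(-2, -3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    """(..., h, S, d_k) -> (..., S, h*d_k)"""
    *lead, h, s, dk = x.shape
    return x.swapaxes(-2, -3).reshape(*lead, s, h * dk)


def apply_adapter(tokens: np.ndarray, params: Dict[str, np.ndarray], mod: str):
    y, lin_cache = ops.linear_forward(
        tokens, params[f"{mod}.adapter.W"], params[f"{mod}.adapter.b"]
    )
    y, mask = ops.relu_forward(y)
    return y, (lin_cache, mask)


def project_qkv(
    ppg_tokens: ArrayLike,
    vppg_tokens: ArrayLike,
    appg_tokens: ArrayLike,
    params: Dict[str, np.ndarray],
    cfg: MHCAConfig,
) -> List[Tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-head (Q_i, K_i, V_i); row counts follow the source modalities."""
    xq, _ = apply_adapter(_tokens(ppg_tokens), params, "ppg")
    xk, _ = apply_adapter(_tokens(vppg_tokens), params, "vppg")
    xv, _ = apply_adapter(_tokens(appg_tokens), params, "appg")
    q = xq @ params["attn.Wq"]
    k = xk @ params["attn.Wk"]
    v = xv @ params["attn.Wv"]
    dk = cfg.d_k
    return [
        (q[:, i * dk : (i + 1) * dk], k[:, i * dk : (i + 1) * dk], v[:, i * dk : (i + 1) * dk])
        for i in range(cfg.n_heads)
    ]


def mhca_forward(
    tok_q: np.ndarray,
    tok_k: np.ndarray,
    tok_v: np.ndarray,
    params: Dict[str, np.ndarray],
    cfg: MHCAConfig,
):
    """Batched fusion: (B, S, C) token triplet -> (B, d_out) fused vectors."""
    xq, cq = apply_adapter(tok_q, params, "ppg")
    xk, ck = apply_adapter(tok_k, params, "vppg")
    xv, cv = apply_adapter(tok_v, params, "appg")
    q, cache_q = ops.linear_forward(xq, params["attn.Wq"], None)
    k, cache_k = ops.linear_forward(xk, params["attn.Wk"], None)
    v, cache_v = ops.linear_forward(xv, params["attn.Wv"], None)
    h = cfg.n_heads
    qh, kh, vh = _split_heads(q, h), _split_heads(k, h), _split_heads(v, h)
    heads, attn, att_cache = ops.attention_forward(qh, kh, vh)
    if cfg.fusion_mode == "concat":
        cat = _merge_heads(heads)  # (B, Sq, d_model)
        fused, cache_o = ops.linear_forward(cat, params["attn.Wo"], None)
    else:  # head_mean: average the h head outputs
        fused, cache_o = heads.mean(axis=-3), None
    x_fusion = fused.mean(axis=-2)
    cache = (cq, ck, cv, cache_q, cache_k, cache_v, att_cache, cache_o, fused.shape, h)
    return x_fusion, attn, fused, cache


def mhca_backward(dxf: np.ndarray, cache, cfg: MHCAConfig):
    """Gradients of the fused vector w.r.t. params and input tokens."""
    cq, ck, cv, cache_q, cache_k, cache_v, att_cache, cache_o, fused_shape, h = cache
    grads: Dict[str, np.ndarray] = {}
    s_q = fused_shape[-2]
    dfused = np.broadcast_to(dxf[..., None, :] / s_q, fused_shape)
    if cfg.fusion_mode == "concat":
        dcat, grads["attn.Wo"], _ = ops.linear_backward(dfused, cache_o)
        dheads = _split_heads(dcat, h)
    else:
        dheads = np.broadcast_to(np.expand_dims(dfused / h, -3), att_cache[3].shape[:-1] + (dfused.shape[-1],))
    dqh, dkh, dvh = ops.attention_backward(np.ascontiguousarray(dheads), att_cache)
    dq, dk, dv = _merge_heads(dqh), _merge_heads(dkh), _merge_heads(dvh)
    dxq, grads["attn.Wq"], _ = ops.linear_backward(dq, cache_q)
    dxk, grads["attn.Wk"], _ = ops.linear_backward(dk, cache_k)
    dxv, grads["attn.Wv"], _ = ops.linear_backward(dv, cache_v)
    dtok = []
    for mod, dx, (lin_cache, mask) in (("ppg", dxq, cq), ("vppg", dxk, ck), ("appg", dxv, cv)):
        dx = ops.relu_backward(dx, mask)
        dt, grads[f"{mod}.adapter.W"], grads[f"{mod}.adapter.b"] = ops.linear_backward(dx, lin_cache)
        dtok.append(dt)
    return grads, dtok[0], dtok[1], dtok[2]


def multi_head_cross_attention(
    ppg_tokens: ArrayLike,
    vppg_tokens: ArrayLike,
    appg_tokens: ArrayLike,
    params: Dict[str, np.ndarray],
    cfg: MHCAConfig,
) -> FusedRepresentation:
    """Single-instance fusion with attention maps exposed for inspection."""
    cfg.validate()
    tq = _tokens(ppg_tokens)[None]
    tk = _tokens(vppg_tokens)[None]
    tv = _tokens(appg_tokens)[None]
    x_fusion, attn, fused, _ = mhca_forward(tq, tk, tv, params, cfg)
    return FusedRepresentation(
        x_fusion=x_fusion[0], attention_weights=attn[0], fused_tokens=fused[0]
    )


def regress_bp(
    fused: Union[FusedRepresentation, np.ndarray],
    params: Dict[str, np.ndarray],
    window_id: str = "",
) -> BPEstimate:
    """Fully connected map from the fused vector to (SBP, DBP) in mmHg."""
    x = fused.x_fusion if isinstance(fused, FusedRepresentation) else np.asarray(fused, float)
    y = x @ params["head.W"] + params["head.b"]
    return BPEstimate(sbp_hat=float(y[0]), dbp_hat=float(y[1]), window_id=window_id)


__all__ = [
    "FusedRepresentation",
    "BPEstimate",
    "init_mhca_params",
    "scaled_dot_attention",
    "project_qkv",
    "apply_adapter",
    "mhca_forward",
    "mhca_backward",
    "multi_head_cross_attention",
    "regress_bp",
]
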