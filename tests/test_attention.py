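"""Cross-attention fusion against brute-force oracles and its invariants."""

import math

import numpy as np
import pytest

from ppgbp.config import MHCAConfig
from ppgbp.nn.attention import (
    init_mhca_params,
    multi_head_cross_attention,
    project_qkv,
    regress_bp,
    scaled_dot_attention,
)


def brute_force_attention(q, k, v):
    """Straight-line scaled dot-product attention with explicit loops."""
    s_q, d_k = q.shape
    s_k = k.shape[0]
    out = np.zeros((s_q, v.shape[1]))
    for i in range(s_q):
        logits = [sum(q[i][c] * k[j][c] for c in range(d_k)) / math.sqrt(d_k) for j in range(s_k)]
        mx = max(logits)
        ex = [math.exp(l - mx) for l in logits]
        z = sum(ex)
        weights = [e / z for e in ex]
        for col in range(v.shape[1]):
            out[i, col] = sum(weights[j] * v[j][col] for j in range(s_k))
    return out


def brute_force_mhca(tok_q, tok_k, tok_v, params, cfg):
    """Loop re-implementation: adapters -> per-head attention -> concat W^O -> mean."""

    def adapter(tokens, mod):
        y = tokens @ params[f"{mod}.adapter.W"] + params[f"{mod}.adapter.b"]
        return np.maximum(y, 0.0)

    xq, xk, xv = adapter(tok_q, "ppg"), adapter(tok_k, "vppg"), adapter(tok_v, "appg")
    dk = cfg.d_k
    heads = []
    for i in range(cfg.n_heads):
        wq = params["attn.Wq"][:, i * dk : (i + 1) * dk]
        wk = params["attn.Wk"][:, i * dk : (i + 1) * dk]
        wv = params["attn.Wv"][:, i * dk : (i + 1) * dk]
        heads.append(brute_force_attention(xq @ wq, xk @ wk, xv @ wv))
    cat = np.concatenate(heads, axis=1)
    fused = cat @ params["attn.Wo"]
    return fused.mean(axis=0)


class TestScaledDotAttention:
    def test_single_key_passes_value_through(self, rng):
        q = rng.normal(size=(3, 4))
        k = rng.normal(size=(1, 4))
        v = rng.normal(size=(1, 5))
        out, w = scaled_dot_attention(q, k, v, return_weights=True)
        assert out == pytest.approx(np.tile(v, (3, 1)))
        assert w == pytest.approx(np.ones((3, 1)))

    def test_equal_logits_give_column_mean(self, rng):
        k = rng.normal(size=(4, 3))
        q = np.zeros((2, 3))  # orthogonal to everything
        v = rng.normal(size=(4, 6))
        out = scaled_dot_attention(q, k, v)
        assert out == pytest.approx(np.tile(v.mean(axis=0), (2, 1)))

    def test_hand_softmax_example(self):
        q = np.array([[1.0, 0.0]])
        k = np.array([[1.0, 0.0], [0.0, 1.0]])
        v = np.array([[1.0, 0.0], [0.0, 1.0]])
        out, w = scaled_dot_attention(q, k, v, return_weights=True)
        assert w[0] == pytest.approx([0.6698, 0.3302], abs=5e-5)
        assert out[0] == pytest.approx([0.6698, 0.3302], abs=5e-5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        s_q, s_k, d_k, d_v = r.integers(1, 5, size=4)
        q = r.normal(size=(s_q, d_k))
        k = r.normal(size=(s_k, d_k))
        v = r.normal(size=(s_k, d_v))
        assert scaled_dot_attention(q, k, v) == pytest.approx(
            brute_force_attention(q, k, v), abs=1e-10
        )

    def test_rows_sum_to_one_and_convex_hull(self, rng):
        for _ in range(20):
            q = rng.normal(size=(3, 4)) * rng.uniform(0.1, 5)
            k = rng.normal(size=(5, 4))
            v = rng.normal(size=(5, 2))
            out, w = scaled_dot_attention(q, k, v, return_weights=True)
            assert w.sum(axis=1) == pytest.approx(np.ones(3), abs=1e-5)
            assert np.all(w >= 0)
            assert np.all(out >= v.min(axis=0) - 1e-12)
            assert np.all(out <= v.max(axis=0) + 1e-12)

    def test_empty_keys_rejected(self, rng):
        with pytest.raises(ValueError):
            scaled_dot_attention(rng.normal(size=(2, 3)), np.zeros((0, 3)), np.zeros((0, 3)))


class TestProjectQKV:
    def test_identity_projections_preserve_tokens(self):
        cfg = MHCAConfig(d_model=4, n_heads=1)
        tokens = np.abs(np.random.default_rng(0).normal(size=(3, 4)))
        params = init_mhca_params(np.random.default_rng(1), 4, cfg)
        for mod in ("ppg", "vppg", "appg"):
            params[f"{mod}.adapter.W"] = np.eye(4)
            params[f"{mod}.adapter.b"] = np.zeros(4)
        params["attn.Wq"] = np.eye(4)
        (q, k, v), = project_qkv(tokens, tokens, tokens, params, cfg)
        assert q == pytest.approx(tokens)

    def test_zero_tokens_give_zero_qkv(self):
        cfg = MHCAConfig(d_model=4, n_heads=2)
        params = init_mhca_params(np.random.default_rng(1), 3, cfg)
        for mod in ("ppg", "vppg", "appg"):
            params[f"{mod}.adapter.b"] = np.zeros(4)
        zeros = np.zeros((2, 3))
        for q, k, v in project_qkv(zeros, zeros, zeros, params, cfg):
            assert np.allclose(q, 0) and np.allclose(k, 0) and np.allclose(v, 0)

    def test_matches_explicit_matmul(self, rng):
        cfg = MHCAConfig(d_model=4, n_heads=2)
        params = init_mhca_params(rng, 4, cfg)
        tokens = np.abs(rng.normal(size=(3, 4)))
        heads = project_qkv(tokens, tokens, tokens, params, cfg)
        x = np.maximum(tokens @ params["ppg.adapter.W"] + params["ppg.adapter.b"], 0)
        expected_q = np.zeros((3, 2))
        for i in range(3):
            for j in range(2):
                expected_q[i, j] = sum(x[i, c] * params["attn.Wq"][c, j] for c in range(4))
        assert heads[0][0] == pytest.approx(expected_q)
        assert heads[0][0].shape == (3, cfg.d_k)


class TestMultiHeadCrossAttention:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_reimplementation(self, seed):
        r = np.random.default_rng(seed)
        s = int(r.integers(1, 5))
        c = int(r.integers(1, 5))
        h = int(r.integers(1, 3))
        cfg = MHCAConfig(d_model=4, n_heads=h if 4 % h == 0 else 1)
        params = init_mhca_params(r, c, cfg)
        tq, tk, tv = (r.normal(size=(s, c)) for _ in range(3))
        fused = multi_head_cross_attention(tq, tk, tv, params, cfg)
        expected = brute_force_mhca(tq, tk, tv, params, cfg)
        assert np.max(np.abs(fused.x_fusion - expected)) < 1e-5

    def test_single_head_identity_wo_reduces_to_attention(self, rng):
        cfg = MHCAConfig(d_model=4, n_heads=1)
        params = init_mhca_params(rng, 4, cfg)
        params["attn.Wo"] = np.eye(4)
        tq, tk, tv = (rng.normal(size=(3, 4)) for _ in range(3))
        fused = multi_head_cross_attention(tq, tk, tv, params, cfg)
        heads = project_qkv(tq, tk, tv, params, cfg)
        q, k, v = heads[0]
        assert fused.fused_tokens == pytest.approx(scaled_dot_attention(q, k, v))

    def test_identical_value_tokens_dominate_output(self, rng):
        # every attention row is a convex combination; if all value rows are
        # equal the fused tokens cannot depend on the query/key content
        cfg = MHCAConfig(d_model=4, n_heads=2)
        params = init_mhca_params(rng, 4, cfg)
        tv = np.tile(rng.normal(size=(1, 4)), (3, 1))
        f1 = multi_head_cross_attention(rng.normal(size=(3, 4)), rng.normal(size=(3, 4)), tv, params, cfg)
        f2 = multi_head_cross_attention(rng.normal(size=(3, 4)), rng.normal(size=(3, 4)), tv, params, cfg)
        assert f1.x_fusion == pytest.approx(f2.x_fusion, abs=1e-10)

    def test_attention_rows_sum_to_one(self, rng):
        cfg = MHCAConfig(d_model=8, n_heads=4)
        params = init_mhca_params(rng, 5, cfg)
        fused = multi_head_cross_attention(
            rng.normal(size=(4, 5)), rng.normal(size=(6, 5)), rng.normal(size=(6, 5)), params, cfg
        )
        assert fused.attention_weights.shape == (4, 4, 6)
        assert fused.attention_weights.sum(axis=-1) == pytest.approx(
            np.ones((4, 4)), abs=1e-5
        )

    def test_key_value_permutation_invariance(self, rng):
        cfg = MHCAConfig(d_model=4, n_heads=2)
        params = init_mhca_params(rng, 4, cfg)
        tq = rng.normal(size=(3, 4))
        tk = rng.normal(size=(5, 4))
        tv = rng.normal(size=(5, 4))
        perm = rng.permutation(5)
        a = multi_head_cross_attention(tq, tk, tv, params, cfg)
        b = multi_head_cross_attention(tq, tk[perm], tv[perm], params, cfg)
        assert a.x_fusion == pytest.approx(b.x_fusion, abs=1e-10)


class TestRegressBP:
    def test_zero_weight_returns_bias(self, rng):
        cfg = MHCAConfig(d_model=4, n_heads=2)
        params = init_mhca_params(rng, 4, cfg)
        params["head.W"] = np.zeros((4, 2))
        params["head.b"] = np.array([120.0, 80.0])
        est = regress_bp(rng.normal(size=4), params)
        assert (est.sbp_hat, est.dbp_hat) == (120.0, 80.0)

    def test_zero_fusion_returns_bias(self, rng):
        cfg = MHCAConfig(d_model=4, n_heads=2)
        params = init_mhca_params(rng, 4, cfg)
        params["head.b"] = np.array([1.0, -1.0])
        est = regress_bp(np.zeros(4), params)
        assert (est.sbp_hat, est.dbp_hat) == (1.0, -1.0)

    def test_matches_explicit_dot_products(self, rng):
        cfg = MHCAConfig(d_model=4, n_heads=2)
        params = init_mhca_params(rng, 4, cfg)
        x = rng.normal(size=4)
        est = regress_bp(x, params)
        expected = [
            sum(x[c] * params["head.W"][c, j] for c in range(4)) + params["head.b"][j]
            for j in range(2)
        ]
        assert est.sbp_hat == pytest.approx(expected[0])
        assert est.dbp_hat == pytest.approx(expected[1])
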