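"""Network components against independent dense-loop oracles, plus
shape/identity/determinism contracts of the full model."""
import numpy as np
import pytest
from scipy.special import erf

from conftest import randomize
from tractformer3d import build_network, threshold_probabilities, tiny_config
from tractformer3d.model import CFFN, MCCA, NetworkConfig, TransformerBlock
from tractformer3d.nn import Tensor


# --- dense-loop reference implementations (independent of the nn engine) ----

def conv_loop(x, w, stride=1, pad=0):
    """x (H,W,D,Cin), w (k,k,k,Cin,Cout): explicit-loop convolution."""
    k = w.shape[0]
    H, W, D, ci = x.shape
    xp = np.zeros((H + 2 * pad, W + 2 * pad, D + 2 * pad, ci))
    xp[pad:pad + H, pad:pad + W, pad:pad + D] = x
    Ho = (H + 2 * pad - k) // stride + 1
    out = np.zeros((Ho, Ho, Ho, w.shape[4]))
    for i in range(Ho):
        for j in range(Ho):
            for l in range(Ho):
                patch = xp[i * stride:i * stride + k,
                           j * stride:j * stride + k,
                           l * stride:l * stride + k, :]
                for co in range(w.shape[4]):
                    out[i, j, l, co] = np.sum(patch * w[..., co])
    return out


def dwconv_loop(x, w, pad=1):
    """Depthwise convolution by loops; w (k,k,k,C)."""
    k = w.shape[0]
    H, W, D, c = x.shape
    xp = np.zeros((H + 2 * pad, W + 2 * pad, D + 2 * pad, c))
    xp[pad:pad + H, pad:pad + W, pad:pad + D] = x
    out = np.zeros_like(x, dtype=np.float64)
    for i in range(H):
        for j in range(W):
            for l in range(D):
                for ch in range(c):
                    out[i, j, l, ch] = np.sum(
                        xp[i:i + k, j:j + k, l:l + k, ch] * w[..., ch])
    return out


def sep_conv_loop(x, module):
    dw = dwconv_loop(x, module.depthwise.weight.data.astype(np.float64))
    return dw @ module.pointwise.data.astype(np.float64)


def maxpool_loop(x, r):
    H, W, D, c = x.shape
    out = np.zeros((H // r, W // r, D // r, c))
    for i in range(H // r):
        for j in range(W // r):
            for l in range(D // r):
                out[i, j, l] = x[i * r:(i + 1) * r, j * r:(j + 1) * r,
                                 l * r:(l + 1) * r].max(axis=(0, 1, 2))
    return out


def gelu_ref(x):
    return 0.5 * x * (1 + erf(x / np.sqrt(2)))


def mcca_oracle(x, module):
    """Materialize Q', K', V' explicitly and evaluate
    Softmax(Q'K'^T * alpha) V' with dense loops."""
    c, h, r = module.c, module.heads, module.r
    H, W, D, _ = x.shape
    q = maxpool_loop(sep_conv_loop(x, module.ds_q), r)
    k = maxpool_loop(sep_conv_loop(x, module.ds_k), r)
    v = sep_conv_loop(x, module.ds_v)
    ck = c // h
    n, np_ = H * W * D, (H // r) * (W // r) * (D // r)
    qf = q.reshape(np_, c).T  # (C, Np) channel-as-token layout
    kf = k.reshape(np_, c).T
    vf = v.reshape(n, c).T
    out = np.zeros((c, n))
    for head in range(h):
        Q = qf[head * ck:(head + 1) * ck]
        K = kf[head * ck:(head + 1) * ck]
        V = vf[head * ck:(head + 1) * ck]
        logits = np.zeros((ck, ck))
        for a in range(ck):
            for b in range(ck):
                alpha = float(module.alpha.data[head, 0, 0])
                logits[a, b] = alpha * np.dot(Q[a], K[b])
        attn = np.exp(logits - logits.max(axis=1, keepdims=True))
        attn /= attn.sum(axis=1, keepdims=True)
        out[head * ck:(head + 1) * ck] = attn @ V
    out_vol = out.T.reshape(H, W, D, c)
    refined = out_vol @ module.refine.weight.data.reshape(c, c).astype(np.float64)
    return refined + x


def cffn_oracle(x, module):
    a = sep_conv_loop(x, module.ds_a)
    b = sep_conv_loop(x, module.ds_b)
    hid = module.project.weight.shape[3]
    proj = module.project.weight.data.reshape(hid, -1).astype(np.float64)
    return (a * gelu_ref(b)) @ proj + x


def _no_norm_cfg(**kw):
    base = dict(level_channels=(8, 8, 8, 8), heads_per_level=(2, 2, 2, 2),
                blocks_per_level=(1, 1, 1, 1), out_channels=3,
                use_norm=False, ffn_expansion=1.5, nominal_patch=16)
    base.update(kw)
    return NetworkConfig(in_channels=9, **base)


# --- oracle equivalence ------------------------------------------------------

def test_mcca_matches_dense_loop_oracle(rng):
    cfg = _no_norm_cfg()
    m = MCCA(8, 2, cfg, np.random.default_rng(0), level=0)
    randomize(m, rng)
    m.alpha.data = np.abs(m.alpha.data) + 0.5
    x = rng.normal(size=(4, 4, 4, 8)).astype(np.float32)
    got = m(Tensor(x[None])).data[0].astype(np.float64)
    want = mcca_oracle(x.astype(np.float64), m)
    np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-5)


def test_cffn_matches_dense_loop_oracle(rng):
    cfg = _no_norm_cfg()
    m = CFFN(8, cfg, np.random.default_rng(0))
    randomize(m, rng)
    x = rng.normal(size=(4, 4, 4, 8)).astype(np.float32)
    got = m(Tensor(x[None])).data[0].astype(np.float64)
    want = cffn_oracle(x.astype(np.float64), m)
    np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-5)


def test_block_composes_cffn_after_mcca(rng):
    cfg = _no_norm_cfg()
    blk = TransformerBlock(8, 2, cfg, np.random.default_rng(3), level=0)
    randomize(blk, rng)
    blk.mcca.alpha.data = np.abs(blk.mcca.alpha.data) + 0.5
    x = Tensor(rng.normal(size=(1, 4, 4, 4, 8)).astype(np.float32))
    got = blk(x).data
    want = blk.cffn(blk.mcca(x)).data
    np.testing.assert_array_equal(got, want)


# --- shape contracts ---------------------------------------------------------

def test_mcca_shapes_single_head_36_channels():
    """8x8x8x36 input, one head, r=2: pooled tokens 4^3=64, value tokens 512,
    attention map 36x36, output shape preserved."""
    cfg = NetworkConfig(level_channels=(36, 36, 36, 36),
                        heads_per_level=(1, 1, 1, 1),
                        blocks_per_level=(1, 1, 1, 1), out_channels=3,
                        use_norm=False, nominal_patch=16)
    m = MCCA(36, 1, cfg, np.random.default_rng(0), level=0)
    randomize(m, np.random.default_rng(1), scale=0.1)
    x = np.random.default_rng(2).normal(size=(1, 8, 8, 8, 36)).astype(np.float32)
    out, attn = m(Tensor(x), return_attention=True)
    assert attn.shape == (1, 1, 36, 36)
    assert out.shape == (1, 8, 8, 8, 36)


def test_attention_rows_sum_to_one(rng):
    cfg = _no_norm_cfg()
    m = MCCA(8, 2, cfg, np.random.default_rng(0), level=0)
    randomize(m, rng, scale=1.0)
    x = rng.normal(size=(2, 4, 4, 4, 8)).astype(np.float32) * 10
    _, attn = m(Tensor(x), return_attention=True)
    np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)


def test_indivisible_spatial_dims_raise(rng):
    cfg = _no_norm_cfg()
    m = MCCA(8, 2, cfg, np.random.default_rng(0), level=0)
    with pytest.raises(ValueError, match="divisible"):
        m(Tensor(rng.normal(size=(1, 3, 4, 4, 8)).astype(np.float32)))


def test_published_config_has_36_channels_per_head():
    cfg = NetworkConfig()
    per_head = [c // h for c, h in zip(cfg.level_channels, cfg.heads_per_level)]
    assert per_head == [36, 36, 36, 36]


# --- zero-weight identities --------------------------------------------------

def test_zero_weight_mcca_is_identity(rng):
    cfg = _no_norm_cfg()
    m = MCCA(8, 2, cfg, np.random.default_rng(0), level=0)
    for _, p in m.named_parameters():
        p.data[...] = 0.0
    x = rng.normal(size=(1, 4, 4, 4, 8)).astype(np.float32)
    np.testing.assert_array_equal(m(Tensor(x)).data, x)


def test_zero_weight_block_stack_is_identity(rng):
    cfg = _no_norm_cfg()
    blocks = [TransformerBlock(8, 2, cfg, np.random.default_rng(i), level=0)
              for i in range(3)]
    for blk in blocks:
        for _, p in blk.named_parameters():
            p.data[...] = 0.0
    x = rng.normal(size=(1, 4, 4, 4, 8)).astype(np.float32)
    y = Tensor(x)
    for blk in blocks:
        y = blk(y)
    np.testing.assert_array_equal(y.data, x)


def test_zero_weight_network_outputs_half_everywhere(micro_net, rng):
    for _, p in micro_net.named_parameters():
        p.data[...] = 0.0
    x = rng.normal(size=(16, 16, 16, 9)).astype(np.float32)
    prob = micro_net.predict_proba(x)
    assert np.all(prob == 0.5)
    randomize(micro_net, np.random.default_rng(7), scale=0.1)  # restore


# --- full network ------------------------------------------------------------

def test_build_is_deterministic():
    cfg = tiny_config()
    a = build_network(cfg, 5).state_dict()
    b = build_network(cfg, 5).state_dict()
    assert a.keys() == b.keys()
    for k in a:
        np.testing.assert_array_equal(a[k], b[k])


def test_forward_shapes_and_range(micro_net, rng):
    x = rng.normal(size=(16, 16, 16, 9)).astype(np.float32)
    prob = micro_net.predict_proba(x)
    assert prob.shape == (16, 16, 16, micro_net.cfg.out_channels)
    assert prob.min() > 0.0 and prob.max() < 1.0


def test_forward_pads_odd_sizes(micro_net, rng):
    x = rng.normal(size=(20, 18, 22, 9)).astype(np.float32)
    prob = micro_net.predict_proba(x)
    assert prob.shape == (20, 18, 22, micro_net.cfg.out_channels)


def test_forward_is_deterministic(micro_net, rng):
    x = rng.normal(size=(16, 16, 16, 9)).astype(np.float32)
    a = micro_net.predict_proba(x)
    b = micro_net.predict_proba(x)
    np.testing.assert_array_equal(a, b)


def test_wrong_channel_count_raises(micro_net, rng):
    with pytest.raises(ValueError, match="9"):
        micro_net.predict_proba(rng.normal(size=(16, 16, 16, 6)))


def test_save_load_roundtrip(tmp_path, micro_net, rng):
    from tractformer3d import load_network, save_network
    save_network(micro_net, tmp_path / "ckpt")
    back = load_network(tmp_path / "ckpt")
    x = rng.normal(size=(16, 16, 16, 9)).astype(np.float32)
    np.testing.assert_array_equal(back.predict_proba(x),
                                  micro_net.predict_proba(x))


# --- thresholding ------------------------------------------------------------

def test_threshold_is_strict_at_boundary():
    prob = np.full((4, 4, 4, 2), 0.5)
    assert not threshold_probabilities(prob, 0.5).any()


def test_threshold_sets_only_exceeding_channel():
    prob = np.full((2, 2, 2, 5), 0.2)
    prob[..., 3] = 0.51
    lab = threshold_probabilities(prob, 0.5)
    assert lab[..., 3].all()
    assert not lab[..., [0, 1, 2, 4]].any()


def test_threshold_matches_elementwise_loop(rng):
    prob = rng.uniform(size=(5, 4, 3, 6))
    lab = threshold_probabilities(prob, 0.5)
    for idx in np.ndindex(prob.shape):
        assert lab[idx] == (1 if prob[idx] > 0.5 else 0)


def test_threshold_validates_tau():
    with pytest.raises(ValueError):
        threshold_probabilities(np.zeros((2, 2, 2, 1)), 1.0)


def test_config_invariant_validation():
    with pytest.raises(ValueError, match="divisible"):
        NetworkConfig(level_channels=(10, 20, 40, 80),
                      heads_per_level=(3, 2, 4, 8))
    with pytest.raises(ValueError):
        NetworkConfig(threshold=0.0)
    with pytest.raises(ValueError):
        NetworkConfig(blocks_per_level=(1, 2, 4))
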