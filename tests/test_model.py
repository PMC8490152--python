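"""Architecture checks: basis functions, relative attention, shape chain."""

import numpy as np
import pytest
from scipy import stats as st

from regformer.autodiff import Tensor, no_grad
from regformer.model import (
    ModelConfig,
    RelativeMHA,
    SeqToTracksModel,
    basis_central_mask,
    basis_exponential,
    basis_gamma,
    central_mask_thresholds,
    conv_channel_schedule,
    crop_output,
    exponential_half_lives,
    gamma_means_sigma,
    positional_features,
    toy_config,
)

# ---------------------------------------------------------------------------
# basis functions


def test_exponential_basis_half_life_values():
    hl = np.array([4.0, 16.0, 64.0])
    np.testing.assert_allclose(basis_exponential(np.array([0.0]), hl)[0], 1.0)
    for i, h in enumerate(hl):
        np.testing.assert_allclose(basis_exponential(np.array([h]), hl)[0, i], 0.5)
        np.testing.assert_allclose(basis_exponential(np.array([2 * h]), hl)[0, i], 0.25)


def test_exponential_half_lives_log_spaced():
    hl = exponential_half_lives(5, 1000)
    assert hl[0] == pytest.approx(3.0)
    assert hl[-1] == pytest.approx(1000.0)
    np.testing.assert_allclose(np.diff(np.log(hl)), np.diff(np.log(hl))[0])


def test_central_mask_boundaries():
    th = central_mask_thresholds(4)  # 2, 4, 8, 16
    np.testing.assert_array_equal(th, [2, 4, 8, 16])
    assert basis_central_mask(np.array([8.0]), th)[0, 2] == 1.0
    assert basis_central_mask(np.array([9.0]), th)[0, 2] == 0.0
    np.testing.assert_array_equal(basis_central_mask(np.array([0.0]), th)[0], 1.0)
    # monotone non-increasing in r, feature-wise
    grid = basis_central_mask(np.arange(0, 40, dtype=float), th)
    assert (np.diff(grid, axis=0) <= 0).all()


def test_gamma_basis_matches_pdf_oracle():
    means, sigma = gamma_means_sigma(4, 256)
    r = np.linspace(0, 256, 200)
    feats = basis_gamma(r, means, sigma, normalize=False)
    assert (feats >= 0).all()
    shape = (means / sigma) ** 2
    rate = means / sigma**2
    for i in range(4):
        np.testing.assert_allclose(feats[:, i], st.gamma.pdf(r, a=shape[i], scale=1 / rate[i]), rtol=1e-10)
        # peak of the normalized feature sits near the distribution mode
        mode = (shape[i] - 1) / rate[i]
        peak_r = r[np.argmax(feats[:, i])]
        assert abs(peak_r - mode) < 256 / 199 * 2


def test_gamma_basis_normalized_peak_is_one():
    means, sigma = gamma_means_sigma(3, 512)
    r = np.linspace(0, 512, 2000)
    feats = basis_gamma(r, means, sigma, normalize=True)
    np.testing.assert_allclose(feats.max(axis=0), 1.0, atol=5e-3)


def test_positional_features_allocation_and_parity():
    # full-scale budget: 192 features over 3 classes = 64 per class, 32 + 32
    r = np.linspace(-800, 800, 41)
    feats = positional_features(r, 192, 1536)
    assert feats.shape == (41, 192)
    sym, asym = feats[:, :96], feats[:, 96:]
    assert sym.shape[1] == 3 * 32 and asym.shape[1] == 3 * 32
    # symmetric block is even, asymmetric block is odd
    np.testing.assert_allclose(sym, sym[::-1], atol=1e-12)
    np.testing.assert_allclose(asym, -asym[::-1], atol=1e-12)
    # r = 0 kills the asymmetric block
    feats0 = positional_features(np.array([0.0]), 192, 1536)
    np.testing.assert_array_equal(feats0[0, 96:], 0.0)


def test_positional_features_budget_must_divide():
    with pytest.raises(ValueError):
        positional_features(np.array([1.0]), 10, 64)


# ---------------------------------------------------------------------------
# relative multi-head attention


def _mha_cfg(**kw):
    base = dict(
        channels=6,
        conv_blocks=1,
        transformer_blocks=1,
        heads=2,
        key_size=3,
        value_size=3,
        positional_features=6,
        input_length=64,
        crop_bins=0,
        head_widths={"human": 1},
        dtype="float64",
        dropout_positional=0.0,
        dropout_attention=0.0,
    )
    base.update(kw)
    return ModelConfig(**base).validate()


def test_attention_rows_sum_to_one():
    mha = RelativeMHA(_mha_cfg(), np.random.default_rng(0))
    x = Tensor(np.random.default_rng(1).standard_normal((2, 12, 6)))
    _, maps = mha(x, return_attention=True)
    assert maps.shape == (2, 2, 12, 12)
    np.testing.assert_allclose(maps.sum(axis=-1), 1.0, atol=1e-5)
    assert (maps >= 0).all()


def test_attention_single_position():
    mha = RelativeMHA(_mha_cfg(), np.random.default_rng(0))
    x = Tensor(np.random.default_rng(2).standard_normal((1, 1, 6)))
    y, maps = mha(x, return_attention=True)
    np.testing.assert_allclose(maps, 1.0)
    # output = out-projection of the value projection of x
    v = x.data @ mha.wv.w.data
    expect = v @ mha.out.w.data + mha.out.b.data
    np.testing.assert_allclose(y.data, expect, atol=1e-12)


def test_attention_matches_hand_computed_softmax():
    """Single head, positional terms zeroed: a = softmax(q k^T / sqrt(K))."""
    cfg = _mha_cfg(heads=1, channels=2, key_size=2, value_size=2)
    mha = RelativeMHA(cfg, np.random.default_rng(0))
    mha.wr.w.data[:] = 0.0
    mha.u.data[:] = 0.0
    mha.v.data[:] = 0.0
    mha.wq.w.data = np.array([[1.0, 0.0], [0.0, 1.0]])
    mha.wk.w.data = np.array([[0.0, 1.0], [1.0, 0.0]])
    mha.wv.w.data = np.array([[1.0, 2.0], [3.0, 4.0]])
    mha.out.w.data = np.eye(2)
    mha.out.b.data[:] = 0.0
    x0 = np.array([[0.5, -1.0], [2.0, 0.25]])
    q, k, v = x0, x0 @ mha.wk.w.data, x0 @ mha.wv.w.data
    logits = q @ k.T / np.sqrt(2)
    a = np.exp(logits - logits.max(1, keepdims=True))
    a /= a.sum(1, keepdims=True)
    y, maps = mha(Tensor(x0[None]), return_attention=True)
    np.testing.assert_allclose(maps[0, 0], a, atol=1e-12)
    np.testing.assert_allclose(y.data[0], a @ v, atol=1e-12)


def test_relative_bias_matches_direct_construction():
    """The shift-trick R_ij terms equal the direct O(L^2) evaluation, L <= 32."""
    cfg = _mha_cfg()
    mha = RelativeMHA(cfg, np.random.default_rng(3))
    L = 32
    x0 = np.random.default_rng(4).standard_normal((1, L, 6))
    _, maps = mha(Tensor(x0), return_attention=True)

    # direct construction
    H, K = cfg.heads, cfg.key_size
    q = (x0 @ mha.wq.w.data).reshape(L, H, K).transpose(1, 0, 2)
    k = (x0 @ mha.wk.w.data).reshape(L, H, K).transpose(1, 0, 2)
    logits = np.einsum("hik,hjk->hij", q, k) / np.sqrt(K)
    for i in range(L):
        for j in range(L):
            f = positional_features(np.array([float(i - j)]), cfg.positional_features, L)[0]
            r = (f @ mha.wr.w.data).reshape(H, K)
            for h in range(H):
                logits[h, i, j] += q[h, i] @ r[h] + mha.u.data[h, 0] @ k[h, j] + mha.v.data[h, 0] @ r[h]
    expect = np.exp(logits - logits.max(-1, keepdims=True))
    expect /= expect.sum(-1, keepdims=True)
    np.testing.assert_allclose(maps[0], expect, atol=1e-10)


# ---------------------------------------------------------------------------
# full model


@pytest.mark.parametrize(
    "cfg",
    [
        toy_config(),
        toy_config(input_length=16384, conv_blocks=6, crop_bins=16, channels=24, value_size=6, heads=4, key_size=4),
        toy_config(input_length=4096, conv_blocks=4, crop_bins=8, channels=16, transformer_blocks=1, heads=2, value_size=8, key_size=4),
    ],
    ids=["toy8k", "toy16k", "toy4k"],
)
def test_shape_chain(cfg):
    expect_bins = cfg.input_length // 2**cfg.conv_blocks - 2 * cfg.crop_bins
    assert cfg.output_bins == expect_bins
    model = SeqToTracksModel(cfg)
    x = np.eye(4, dtype="float32")[np.random.default_rng(0).integers(0, 4, cfg.input_length)]
    y = model.predict(x, "human")
    assert y.shape == (expect_bins, cfg.head_widths["human"])
    assert (y >= 0).all()


def test_paper_scale_config_arithmetic():
    cfg = ModelConfig()
    assert cfg.pooled_length == 1536
    assert cfg.bin_width == 128
    assert cfg.output_bins == 896
    assert cfg.output_span_bp == 114_688
    sched = conv_channel_schedule(cfg)
    assert sched[0] == 768 and sched[-1] == 1536 and len(sched) == 7


def test_forward_deterministic_and_rejects_wrong_length(tiny_model, tiny_onehot):
    y1 = tiny_model.predict(tiny_onehot, "human")
    y2 = tiny_model.predict(tiny_onehot, "human")
    np.testing.assert_array_equal(y1, y2)
    with pytest.raises(ValueError):
        tiny_model.predict(tiny_onehot[:-1], "human")


def test_organism_heads_have_configured_widths(tiny_model, tiny_onehot):
    assert tiny_model.predict(tiny_onehot, "human").shape[1] == 3
    assert tiny_model.predict(tiny_onehot, "mouse").shape[1] == 2


def test_attention_maps_stochastic(tiny_model, tiny_onehot):
    maps = tiny_model.attention_maps(tiny_onehot)
    n_layers, n_heads = tiny_model.cfg.transformer_blocks, tiny_model.cfg.heads
    L = tiny_model.cfg.pooled_length
    assert maps.shape == (n_layers, n_heads, L, L)
    np.testing.assert_allclose(maps.sum(axis=-1), 1.0, atol=1e-5)


def test_crop_output():
    x = np.arange(30.0).reshape(3, 10)
    np.testing.assert_array_equal(crop_output(x, 0), x)
    np.testing.assert_array_equal(crop_output(x, 3), x[:, 3:7])


def test_checkpoint_round_trip(tmp_path, tiny_model, tiny_onehot):
    path = tmp_path / "model.ckpt"
    tiny_model.save(path)
    clone = SeqToTracksModel.load(path)
    np.testing.assert_array_equal(clone.predict(tiny_onehot, "human"), tiny_model.predict(tiny_onehot, "human"))


def test_config_yaml_round_trip(tmp_path):
    cfg = toy_config(channels=24, value_size=6)
    p = tmp_path / "cfg.yaml"
    cfg.to_yaml(p)
    assert ModelConfig.from_yaml(p) == cfg


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        toy_config(input_length=1000).validate()  # not divisible by 2^5
    with pytest.raises(ValueError):
        toy_config(crop_bins=10_000).validate()
    with pytest.raises(ValueError):
        toy_config(positional_features=10).validate()
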