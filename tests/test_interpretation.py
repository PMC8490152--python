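"""Contribution scores: gradient correctness, attention profiles, ISM."""

import numpy as np
import pytest

from regformer.interpretation import (
    ContributionTrack,
    attention_profile,
    grad_input,
    ism_region,
    ism_saturation,
    tss_prediction,
    window_score,
)
from regformer.model import SeqToTracksModel, toy_config


@pytest.fixture(scope="module")
def grad_model():
    """Small float64 model for finite-difference comparisons."""
    cfg = toy_config(
        channels=8,
        conv_blocks=3,
        transformer_blocks=1,
        heads=2,
        key_size=4,
        value_size=4,
        positional_features=6,
        input_length=256,
        crop_bins=2,
        head_widths={"human": 2},
        dtype="float64",
        seed=5,
    )
    return SeqToTracksModel(cfg)


@pytest.fixture(scope="module")
def grad_seq(grad_model):
    rng = np.random.default_rng(8)
    return np.eye(4)[rng.integers(0, 4, grad_model.cfg.input_length)]


def test_grad_input_matches_finite_differences(grad_model, grad_seq):
    track = grad_input(grad_model, grad_seq, "human", tss_bin=10, track_indices=[0])
    # central differences on the one-hot channel actually set, 10 positions
    eps = 1e-5
    positions = np.linspace(5, len(grad_seq) - 5, 10, dtype=int)
    for pos in positions:
        ch = int(grad_seq[pos].argmax())
        up, down = grad_seq.copy(), grad_seq.copy()
        up[pos, ch] += eps
        down[pos, ch] -= eps
        fd = (
            tss_prediction(grad_model, up, "human", 10, [0])
            - tss_prediction(grad_model, down, "human", 10, [0])
        ) / (2 * eps)
        assert track.scores[pos] == pytest.approx(abs(fd), rel=1e-3, abs=1e-9)


def test_grad_input_zero_cases(grad_model, grad_seq):
    zeroed = SeqToTracksModel(grad_model.cfg)
    zeroed.load_state_dict(grad_model.state_dict())
    head = zeroed.heads["human"]
    head.w.data = np.zeros_like(head.w.data)
    head.b.data = np.zeros_like(head.b.data)
    track = zeroed(np.asarray(grad_seq), "human")  # forward works; now gradients:
    scores = grad_input(zeroed, grad_seq, "human", 10, [0]).scores
    np.testing.assert_array_equal(scores, 0.0)
    # all-N input: gradient x input is zero because the input factor is zero
    scores_n = grad_input(grad_model, np.zeros_like(grad_seq), "human", 10, [0]).scores
    np.testing.assert_array_equal(scores_n, 0.0)


def test_grad_input_rejects_edge_tss(grad_model, grad_seq):
    with pytest.raises(ValueError):
        grad_input(grad_model, grad_seq, "human", 0, [0])


def test_attention_profile_properties(grad_model, grad_seq):
    profile = attention_profile(grad_model, grad_seq, query_bin=12)
    assert profile.resolution_bp == grad_model.cfg.bin_width
    assert len(profile.scores) == grad_model.cfg.pooled_length
    assert (profile.scores >= 0).all()
    assert profile.scores.sum() == pytest.approx(1.0, abs=1e-5)
    # equals direct aggregation of the retained per-layer maps, any order
    maps = grad_model.attention_maps(grad_seq)
    rows = maps[:, :, 12, :].reshape(-1, maps.shape[-1])
    np.testing.assert_allclose(profile.scores, rows.mean(axis=0), rtol=1e-6)
    np.testing.assert_allclose(profile.scores, rows[::-1].mean(axis=0), rtol=1e-6)


def test_ism_region_identity_replacement_is_zero(grad_model, grad_seq):
    region = (100, 140)
    score = ism_region(
        grad_model, grad_seq, "human", region, 10, [0], replacements=[grad_seq[100:140].copy()]
    )
    assert score == 0.0


def test_ism_region_stability_across_replicates(grad_model, grad_seq):
    a = ism_region(grad_model, grad_seq, "human", (100, 140), 10, [0], replicates=5, seed=0)
    b = ism_region(grad_model, grad_seq, "human", (100, 140), 10, [0], replicates=5, seed=0)
    assert a == b  # fixed seed reproducible
    assert a >= 0


def test_ism_beyond_receptive_field_is_zero():
    """A conv-only model cannot see a region outside its receptive field."""
    cfg = toy_config(
        channels=8,
        conv_blocks=4,
        transformer_blocks=0,
        heads=2,
        key_size=4,
        value_size=4,
        positional_features=6,
        input_length=4096,
        crop_bins=2,
        head_widths={"human": 1},
        seed=2,
    )
    model = SeqToTracksModel(cfg)
    rng = np.random.default_rng(3)
    seq = np.eye(4, dtype="float32")[rng.integers(0, 4, cfg.input_length)]
    tss_bin = 120  # near the right edge; region at the far left, > 3 kb away
    score = ism_region(model, seq, "human", (0, 100), tss_bin, [0], replicates=2, seed=0)
    assert score == 0.0
    grad = grad_input(model, seq, "human", tss_bin, [0]).scores
    assert np.array_equal(grad[:1000], np.zeros(1000))


def test_ism_saturation(grad_model, grad_seq):
    window = (120, 126)
    sat = ism_saturation(grad_model, grad_seq, "human", window, 10, [0])
    assert sat.effects.shape == (6, 4)
    for i in range(6):
        ref = int(grad_seq[window[0] + i].argmax())
        assert sat.effects[i, ref] == 0.0
    # definition: each entry equals a one-at-a-time forward difference
    pos, alt = 2, 0
    if int(grad_seq[122].argmax()) == 0:
        alt = 1
    mod = grad_seq.copy()
    mod[122] = np.eye(4)[alt]
    expect = tss_prediction(grad_model, mod, "human", 10, [0]) - tss_prediction(grad_model, grad_seq, "human", 10, [0])
    assert sat.effects[pos, alt] == pytest.approx(expect, rel=1e-10)
    frame = sat.to_frame()
    assert set(frame.columns) == {"pos", "ref", "alt", "effect"}
    assert len(frame) == 24


def test_window_score_properties():
    track = ContributionTrack(np.zeros(5000), "grad_input")
    assert window_score(track, 2500) == 0.0
    scores = np.ones(5000)
    track = ContributionTrack(scores, "grad_input")
    assert window_score(track, 2500, 2000) == pytest.approx(2000)
    # clipped at the sequence edge sums the available positions
    assert window_score(track, 100, 2000) == pytest.approx(1100)
    # additive over disjoint sub-windows
    left = window_score(track, 2000, 1000)
    right = window_score(track, 3000, 1000)
    assert left + right == pytest.approx(window_score(track, 2500, 2000))
    # attention-resolution tracks are windowed in bp via their bin width
    att = ContributionTrack(np.ones(40), "attention", resolution_bp=128)
    assert window_score(att, 2560, 2560) == pytest.approx(20)


def test_contribution_track_rejects_nonfinite():
    with pytest.raises(ValueError):
        ContributionTrack(np.array([1.0, np.nan]), "grad_input")
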