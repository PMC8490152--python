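"""Pair prioritization: auPRC, bootstrap, strata, ABC*, TAD contrast."""

import numpy as np
import pytest

from regformer.enhancer_benchmark import (
    EnhancerGenePair,
    abc_star,
    auprc,
    bootstrap_auprc,
    stratify_distance,
    tad_attention_contrast,
    tad_region_masks,
)
from regformer.sequence_io import GenomicInterval


def brute_force_auprc(labels, scores):
    """Oracle: walk the ranking, summing precision at each positive."""
    order = sorted(range(len(labels)), key=lambda i: (-scores[i], i))
    tp = fp = 0
    total = 0.0
    n_pos = sum(labels)
    for i in order:
        if labels[i]:
            tp += 1
            total += tp / (tp + fp)
        else:
            fp += 1
    return total / n_pos


def test_auprc_perfect_ranking():
    assert auprc([True, True, False, False], [4, 3, 2, 1]) == 1.0


def test_auprc_matches_brute_force_on_all_small_rankings():
    rng = np.random.default_rng(0)
    for n in range(2, 11):
        for _ in range(30):
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid to exercise ties
            mine = auprc(labels, scores)
            assert mine == pytest.approx(brute_force_auprc(list(labels), list(scores)), rel=1e-12)


def test_auprc_matches_sklearn_without_ties():
    from sklearn.metrics import average_precision_score

    rng = np.random.default_rng(1)
    labels = rng.random(50) < 0.3
    scores = rng.standard_normal(50)
    assert auprc(labels, scores) == pytest.approx(average_precision_score(labels, scores), rel=1e-10)


def test_auprc_all_tied_averages_to_prevalence():
    """Expectation over input orders of a fully tied ranking ~ prevalence.

    A random ranking's average precision is prevalence plus a known
    finite-sample bonus; the Monte-Carlo oracle here is the brute-force AP
    over random label orders."""
    rng = np.random.default_rng(2)
    labels = np.array([True] * 6 + [False] * 14)
    oracle = np.mean(
        [brute_force_auprc(list(rng.permutation(labels)), [0.0] * 20) for _ in range(800)]
    )
    vals = [auprc(rng.permutation(labels), np.zeros(20)) for _ in range(800)]
    assert np.mean(vals) == pytest.approx(oracle, abs=0.02)
    # the expectation tracks prevalence up to the finite-sample bonus
    assert 6 / 20 <= np.mean(vals) <= 6 / 20 + 0.15


def test_auprc_degenerate_returns_nan():
    assert np.isnan(auprc([True, True], [1.0, 2.0]))
    assert np.isnan(auprc([False, False], [1.0, 2.0]))


def test_bootstrap_auprc_reproducible_and_ordered():
    rng = np.random.default_rng(3)
    labels = rng.random(60) < 0.3
    scores = labels * 1.0 + rng.standard_normal(60) * 0.6
    r1 = bootstrap_auprc(labels, scores, seed=7)
    r2 = bootstrap_auprc(labels, scores, seed=7)
    assert (r1.auprc_median, r1.auprc_q25, r1.auprc_q75) == (r2.auprc_median, r2.auprc_q25, r2.auprc_q75)
    assert r1.auprc_q25 <= r1.auprc_median <= r1.auprc_q75
    # quartiles bracket the full-data value on a well-behaved fixture
    full = auprc(labels, scores)
    assert r1.auprc_q25 - 0.1 <= full <= r1.auprc_q75 + 0.1


def test_bootstrap_skips_single_class_subsamples():
    labels = np.array([True] * 9 + [False])
    scores = np.arange(10.0)
    res = bootstrap_auprc(labels, scores, frac=0.5, reps=50, seed=0)
    assert res.n_skipped_reps > 0


def _pair(dist, label=True, score=1.0):
    enh = GenomicInterval("c", 10_000 + dist - 50, 10_000 + dist + 50)
    return EnhancerGenePair(enh, "g", 10_000, label, score)


def test_stratify_distance_partition():
    rng = np.random.default_rng(4)
    pairs = [_pair(int(d)) for d in rng.integers(100, 99_000, 60)]
    edges = [0, 10_000, 40_000, 100_000]
    strata = stratify_distance(pairs, edges)
    assert sum(len(v) for v in strata.values()) == len(pairs)
    # half-open assignment agrees with a naive filter
    for (lo, hi), key in zip([(0, 10_000), (10_000, 40_000), (40_000, 100_000)], strata):
        naive = [p for p in pairs if lo <= p.distance < hi]
        assert strata[key] == naive
    # boundary value goes to the upper stratum
    exact = _pair(10_000)
    assert exact in stratify_distance([exact], edges)["[10000,40000)"]


def test_abc_star():
    activity = np.zeros(30_000)
    enh = GenomicInterval("c", 19_000, 21_000)
    assert abc_star(activity, enh, tss=10_000) == 0.0
    activity[19_000:21_000] = 1.0  # 2000 signal in the window
    s1 = abc_star(activity, enh, tss=10_000)
    assert s1 == pytest.approx(2000 / 10_000)
    # doubling the distance halves the score; doubling activity doubles it
    assert abc_star(activity, enh, tss=0) == pytest.approx(s1 / 2)
    assert abc_star(2 * activity, enh, tss=10_000) == pytest.approx(2 * s1)


def test_abc_star_geometric_mean():
    two = np.zeros((2, 30_000))
    enh = GenomicInterval("c", 19_000, 21_000)
    two[0, 19_000:21_000] = 4 / 2000
    two[1, 19_000:21_000] = 9 / 2000
    s = abc_star(two, enh, tss=5_000, geometric_mean=True)
    assert s == pytest.approx(6 / 15_000, rel=1e-6)
    with pytest.raises(ValueError):
        abc_star(np.zeros((3, 100)), GenomicInterval("c", 10, 20), tss=50, geometric_mean=True)


def test_abc_star_zero_distance_rejected():
    with pytest.raises(ValueError):
        abc_star(np.ones(1000), GenomicInterval("c", 400, 600), tss=500)


def test_tad_region_masks_partition():
    masks = tad_region_masks(32, key_halfwidth=2)
    total = np.zeros((32, 32), dtype=int)
    for m in masks.values():
        total += m.astype(int)
    np.testing.assert_array_equal(total, 1)  # disjoint and exhaustive


class _FakeAttentionModel:
    """Duck-typed stand-in exposing attention_maps; synthetic maps let the
    contrast statistic be tested without training an insulator model."""

    def __init__(self, blocked: bool, rng):
        self.blocked = blocked
        self.rng = rng

    def attention_maps(self, seq):
        L = 32
        logits = self.rng.normal(0, 0.1, (1, 1, L, L))
        if self.blocked:
            b = L // 2
            i = np.arange(L)[:, None]
            j = np.arange(L)[None, :]
            logits[:, :, (i < b) ^ (j < b)] -= 4.0  # suppress cross-boundary attention
        e = np.exp(logits)
        return e / e.sum(-1, keepdims=True)


def test_tad_contrast_identical_groups_null():
    rng = np.random.default_rng(5)
    model = _FakeAttentionModel(False, rng)
    seqs = [np.zeros((64, 4)) for _ in range(12)]
    out = tad_attention_contrast(model, seqs, seqs)
    assert abs(out["difference_matrix"].mean()) < 0.01
    for region in out["regions"].values():
        assert region["p_value"] > 0.05


def test_tad_contrast_detects_insulation():
    blocked = _FakeAttentionModel(True, np.random.default_rng(7))
    control = _FakeAttentionModel(False, np.random.default_rng(8))

    class _Router:
        """Routes boundary-marked sequences to the insulated attention."""

        def attention_maps(self, seq):
            return (blocked if seq[0, 0] > 0 else control).attention_maps(seq)

    mark = np.zeros((64, 4))
    mark[0, 0] = 1.0
    out = tad_attention_contrast(_Router(), [mark] * 15, [np.zeros((64, 4))] * 15)
    across = out["regions"]["across_tad"]
    assert across["difference"] < 0
    assert across["p_value"] < 0.05
    assert out["regions"]["key_at_boundary"]["difference"] > 0
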