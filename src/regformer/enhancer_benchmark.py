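"""Enhancer-gene pair prioritization: auPRC with bootstrap quartiles,
distance stratification, the activity/distance (ABC*) baseline, and the
TAD-boundary attention contrast.

auPRC is computed as average precision over the ranked pairs (rectangular
rule), with ties broken deterministically by stable sort on (score
descending, input order).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _st

from .sequence_io import GenomicInterval


@dataclass
class EnhancerGenePair:
    enhancer: GenomicInterval
    gene_id: str
    tss: int
    label: bool  # True = validated (significant expression change)
    score: float = np.nan

    @property
    def distance(self) -> int:
        return abs(self.enhancer.center - self.tss)


@dataclass
class BenchmarkResult:
    method: str
    stratum: str
    auprc_median: float
    auprc_q25: float
    auprc_q75: float
    n_pairs: int
    n_positive: int
    n_skipped_reps: int = 0

    def __post_init__(self):
        for v in (self.auprc_median, self.auprc_q25, self.auprc_q75):
            if not (0 <= v <= 1 or np.isnan(v)):
                raise ValueError("auPRC values must lie in [0, 1]")


def auprc(labels: Sequence[bool], scores: Sequence[float]) -> float:
    """Average precision: sum over positives of precision at their rank."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be matching 1-D arrays")
    if labels.sum() == 0 or labels.sum() == len(labels):
        return np.nan
    order = np.argsort(-scores, kind="stable")  # score desc, ties by input order
    ranked = labels[order]
    tp = np.cumsum(ranked)
    precision = tp / np.arange(1, len(ranked) + 1)
    return float(precision[ranked].sum() / ranked.sum())


def bootstrap_auprc(
    labels: Sequence[bool],
    scores: Sequence[float],
    frac: float = 0.8,
    reps: int = 100,
    seed: int = 0,
    method: str = "",
    stratum: str = "all",
) -> BenchmarkResult:
    """Median and quartiles of auPRC over subsamples without replacement.

    Replicates whose subsample is single-class (undefined PR curve) are
    skipped and counted.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(labels)
    k = max(1, int(round(frac * n)))
    vals, skipped = [], 0
    for _ in range(reps):
        idx = rng.choice(n, size=k, replace=False)
        v = auprc(labels[idx], scores[idx])
        if np.isnan(v):
            skipped += 1
        else:
            vals.append(v)
    if not vals:
        med = q25 = q75 = np.nan
    else:
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
    return BenchmarkResult(method, stratum, med, q25, q75, n, int(labels.sum()), skipped)


def stratify_distance(pairs: Sequence[EnhancerGenePair], edges: Sequence[int]) -> dict[str, list]:
    """Partition pairs into half-open distance bins [e_i, e_{i+1})."""
    edges = list(edges)
    strata = {f"[{edges[i]},{edges[i + 1]})": [] for i in range(len(edges) - 1)}
    for p in pairs:
        for i in range(len(edges) - 1):
            if edges[i] <= p.distance < edges[i + 1]:
                strata[f"[{edges[i]},{edges[i + 1]})"].append(p)
                break
    return strata


def abc_star(
    activity: np.ndarray,
    enhancer: GenomicInterval,
    tss: int,
    window_start: int = 0,
    window_bp: int = 2000,
    geometric_mean: bool = False,
) -> float:
    """Activity-by-distance score: windowed activity / |enhancer - TSS|.

    ``activity`` is per-base signal (1 track, or 2 tracks combined by
    geometric mean of their windowed sums when ``geometric_mean``).  The
    activity window is ``window_bp`` centered on the enhancer.
    """
    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    center = enhancer.center - window_start
    lo = max(center - window_bp // 2, 0)
    hi = min(center + window_bp // 2, activity.shape[1])
    sums = activity[:, lo:hi].sum(axis=1)
    if geometric_mean:
        if activity.shape[0] != 2:
            raise ValueError("geometric mean combination requires exactly 2 tracks")
        act = float(np.sqrt(sums[0] * sums[1]))
    else:
        act = float(sums[0])
    distance = abs(enhancer.center - tss)
    if distance == 0:
        raise ValueError("enhancer centered on the TSS has undefined distance score")
    return act / distance


# ---------------------------------------------------------------------------
# TAD-boundary attention contrast


def tad_region_masks(n_bins: int, boundary_bin: Optional[int] = None, key_halfwidth: int = 2) -> dict[str, np.ndarray]:
    """Boolean masks over an (L, L) attention matrix around a central boundary.

    ``within_tad``: both query and key on the same side of the boundary;
    ``across_tad``: query and key on opposite sides (off-diagonal quadrants);
    ``key_at_boundary``: key column within ``key_halfwidth`` bins of the
    boundary.  The three masks are pairwise disjoint.
    """
    b = n_bins // 2 if boundary_bin is None else boundary_bin
    i = np.arange(n_bins)[:, None]
    j = np.arange(n_bins)[None, :]
    at_boundary = np.broadcast_to(np.abs(j - b) <= key_halfwidth, (n_bins, n_bins))
    left_q, left_k = i < b, j < b
    within = ((left_q & left_k) | (~left_q & ~left_k)) & ~at_boundary
    across = (left_q ^ left_k) & ~at_boundary
    return {"within_tad": within, "across_tad": across, "key_at_boundary": at_boundary}


def tad_attention_contrast(
    model,
    centered_sequences: Sequence[np.ndarray],
    control_sequences: Sequence[np.ndarray],
    key_halfwidth: int = 2,
) -> dict:
    """Compare attention around TAD-boundary-centered vs control sequences.

    For each sequence the layer/head-averaged attention matrix is reduced to
    mean attention within each region mask; groups are compared per region
    with a two-sided Mann-Whitney U test.  Returns the mean matrices, their
    difference, and per-region statistics.
    """

    def summarize(seqs):
        mats, rows = [], []
        for s in seqs:
            maps = model.attention_maps(np.asarray(s))
            avg = maps.mean(axis=(0, 1))  # (L, L)
            mats.append(avg)
            masks = tad_region_masks(avg.shape[0], key_halfwidth=key_halfwidth)
            rows.append({name: float(avg[m].mean()) for name, m in masks.items()})
        return np.mean(mats, axis=0), rows

    mean_centered, stats_centered = summarize(centered_sequences)
    mean_control, stats_control = summarize(control_sequences)
    regions = {}
    for name in ("within_tad", "across_tad", "key_at_boundary"):
        a = np.array([r[name] for r in stats_centered])
        b = np.array([r[name] for r in stats_control])
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            stat, p = np.nan, 1.0
        else:
            stat, p = _st.mannwhitneyu(a, b, alternative="two-sided")
        regions[name] = {
            "centered_mean": float(a.mean()),
            "control_mean": float(b.mean()),
            "difference": float(a.mean() - b.mean()),
            "u_statistic": float(stat),
            "p_value": float(p),
        }
    return {
        "mean_attention_centered": mean_centered,
        "mean_attention_control": mean_control,
        "difference_matrix": mean_centered - mean_control,
        "regions": regions,
    }


def benchmark_table(results: Sequence[BenchmarkResult]):
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in results])
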