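"""Contribution scores: gradient x input, averaged attention profiles, and
in-silico mutagenesis (ISM), plus their aggregation into per-region scores.

All scalar outputs being attributed are the sum of the chosen tracks over a
TSS bin triple (the bin overlapping the TSS plus one neighbour on each side),
matching gene-focused evaluation.  Because the input is one-hot, the gradient
at the reference channel equals gradient x input; scores are reported as
absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, no_grad
from .sequence_io import OneHotSequence, one_hot_encode


@dataclass
class ContributionTrack:
    scores: np.ndarray  # per-input-position, length = input_length (or pooled for attention)
    method: str  # {"grad_input", "attention", "ism"}
    resolution_bp: int = 1  # 1 for base-level methods, bin width for attention

    def __post_init__(self):
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("contribution scores must be finite")


@dataclass
class SaturationMatrix:
    """L x 4 signed effects (alt - ref prediction); reference entries are 0."""

    effects: np.ndarray
    reference: np.ndarray  # L x 4 one-hot of the scored window
    window_start: int = 0

    def to_frame(self):
        import pandas as pd

        bases = np.array(list("ACGT"))
        rows = []
        ref_idx = self.reference.argmax(axis=1)
        for pos in range(self.effects.shape[0]):
            for alt in range(4):
                rows.append(
                    {
                        "pos": self.window_start + pos,
                        "ref": bases[ref_idx[pos]] if self.reference[pos].sum() else "N",
                        "alt": bases[alt],
                        "effect": self.effects[pos, alt],
                    }
                )
        return pd.DataFrame(rows)


def _tss_triple_scalar(pred: Tensor, tss_bin: int, track_indices) -> Tensor:
    n_bins = pred.shape[-2]
    if not (1 <= tss_bin <= n_bins - 2):
        raise ValueError(f"TSS bin {tss_bin} must lie strictly inside the cropped output (1..{n_bins - 2})")
    window = pred[..., tss_bin - 1 : tss_bin + 2, :]
    sel = window[..., list(track_indices)]
    return sel.sum()


def tss_prediction(model, onehot: np.ndarray, organism: str, tss_bin: int, track_indices) -> float:
    with no_grad():
        pred = model(np.asarray(onehot, dtype=model.cfg.dtype), organism)
        return float(_tss_triple_scalar(pred, tss_bin, track_indices).data)


def grad_input(model, onehot: np.ndarray, organism: str, tss_bin: int, track_indices: Sequence[int]) -> ContributionTrack:
    """|gradient| at the reference channel of each input position.

    The scored quantity is the sum of ``track_indices`` over the TSS bin
    triple.  For one-hot input, the gradient at the nonzero channel equals
    the gradient x input attribution; N positions (all-zero rows) score 0.
    """
    model.eval()
    x = Tensor(np.asarray(onehot, dtype=model.cfg.dtype)[None], requires_grad=True)
    pred = model(x, organism)
    scalar = _tss_triple_scalar(pred, tss_bin, track_indices)
    model.zero_grad()
    scalar.backward()
    g = x.grad[0]  # (L, 4)
    scores = np.abs((g * np.asarray(onehot)).sum(axis=1))
    return ContributionTrack(scores, "grad_input")


def attention_profile(model, onehot: np.ndarray, query_bin: int) -> ContributionTrack:
    """Attention row at the query bin, averaged over all layers and heads.

    The profile lives at pooled (bin) resolution, is non-negative, and sums
    to 1 (an average of row-stochastic rows).
    """
    maps = model.attention_maps(np.asarray(onehot))  # (layers, heads, L, L)
    profile = maps[:, :, query_bin, :].mean(axis=(0, 1))
    return ContributionTrack(profile, "attention", resolution_bp=model.cfg.bin_width)


def random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return np.eye(4, dtype=np.float32)[rng.integers(0, 4, length)]


def ism_region(
    model,
    onehot: np.ndarray,
    organism: str,
    region: tuple[int, int],
    tss_bin: int,
    track_indices: Sequence[int],
    replicates: int = 5,
    seed: int = 0,
    replacements: Optional[list[np.ndarray]] = None,
) -> float:
    """|f(modified) - f(reference)| with the region replaced by random sequence.

    Averaged over ``replicates`` independent random replacements (fixed seed);
    explicit one-hot ``replacements`` may be supplied instead.
    """
    lo, hi = region
    ref = tss_prediction(model, onehot, organism, tss_bin, track_indices)
    if replacements is None:
        rng = np.random.default_rng(seed)
        replacements = [random_sequence(hi - lo, rng) for _ in range(replicates)]
    deltas = []
    for rep in replacements:
        mod = np.array(onehot, dtype=model.cfg.dtype, copy=True)
        mod[lo:hi] = rep
        deltas.append(abs(tss_prediction(model, mod, organism, tss_bin, track_indices) - ref))
    return float(np.mean(deltas))


def ism_saturation(
    model,
    onehot: np.ndarray,
    organism: str,
    window: tuple[int, int],
    tss_bin: int,
    track_indices: Sequence[int],
) -> SaturationMatrix:
    """Score all three substitutions at every position of the window.

    Effects are signed alternative-minus-reference predictions; entries at
    the reference base are zero by construction.
    """
    lo, hi = window
    onehot = np.asarray(onehot, dtype=model.cfg.dtype)
    ref_score = tss_prediction(model, onehot, organism, tss_bin, track_indices)
    effects = np.zeros((hi - lo, 4))
    eye = np.eye(4, dtype=model.cfg.dtype)
    for pos in range(lo, hi):
        ref_col = int(onehot[pos].argmax()) if onehot[pos].sum() else -1
        for alt in range(4):
            if alt == ref_col:
                continue
            mod = np.array(onehot, copy=True)
            mod[pos] = eye[alt]
            effects[pos - lo, alt] = tss_prediction(model, mod, organism, tss_bin, track_indices) - ref_score
    return SaturationMatrix(effects, np.asarray(onehot)[lo:hi].copy(), window_start=lo)


def window_score(track: ContributionTrack, center: int, width: int = 2000) -> float:
    """Sum of scores in a width-bp window centered at ``center`` (bp units);
    windows clipped at the sequence edge sum the available positions."""
    res = track.resolution_bp
    lo_bp, hi_bp = center - width // 2, center + width // 2
    lo = max(lo_bp // res, 0)
    hi = min(-(-hi_bp // res), len(track.scores))
    if hi <= lo:
        return 0.0
    return float(np.sum(track.scores[lo:hi]))
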