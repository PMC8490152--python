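"""Evaluation metrics: per-track bin-level correlation, gene-level CAGE
aggregation, across-genes / across-experiments correlations, and
test-time augmentation.

Gene-level expression is the sum, over a gene's unique TSS locations, of the
128-bp bin overlapping each TSS plus its two neighbours.  Values may then be
log(1+x)-transformed and standardized per experiment across genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .autodiff import no_grad
from .sequence_io import BinnedTracks, OneHotSequence, reverse_complement, shift_sequence


@dataclass
class GeneModel:
    gene_id: str
    tss: list[int]  # genomic coordinates of unique TSS locations
    strand: str = "+"
    biotype: str = "protein_coding"

    def __post_init__(self):
        if not self.tss:
            raise ValueError("a gene needs at least one TSS")
        self.tss = sorted(set(int(t) for t in self.tss))


@dataclass
class GeneExpressionMatrix:
    values: np.ndarray  # genes x experiments
    gene_ids: list[str]
    log1p_applied: bool = False
    standardized: bool = False
    excluded: list[str] = field(default_factory=list)

    def log1p(self) -> "GeneExpressionMatrix":
        return GeneExpressionMatrix(np.log1p(self.values), self.gene_ids, True, self.standardized, self.excluded)

    def standardize(self) -> "GeneExpressionMatrix":
        """Zero mean, unit variance per experiment column across genes."""
        mu = self.values.mean(axis=0, keepdims=True)
        sd = self.values.std(axis=0, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        return GeneExpressionMatrix((self.values - mu) / sd, self.gene_ids, self.log1p_applied, True, self.excluded)


def track_pearson(pred: BinnedTracks, obs: BinnedTracks) -> np.ndarray:
    """Pearson r per track across all bins; NaN for zero-variance tracks."""
    p, o = np.asarray(pred.values, float), np.asarray(obs.values, float)
    if p.shape != o.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {o.shape}")
    pc = p - p.mean(axis=1, keepdims=True)
    oc = o - o.mean(axis=1, keepdims=True)
    denom = np.sqrt((pc**2).sum(axis=1) * (oc**2).sum(axis=1))
    out = np.full(p.shape[0], np.nan)
    ok = denom > 0
    out[ok] = (pc * oc).sum(axis=1)[ok] / denom[ok]
    return out


def tss_bin_index(tss: int, window_start: int, bin_width: int) -> int:
    return (tss - window_start) // bin_width


def gene_level_cage(
    tracks: BinnedTracks,
    genes: Sequence[GeneModel],
    log1p: bool = False,
    standardize: bool = False,
) -> GeneExpressionMatrix:
    """Aggregate binned signal to per-gene values over TSS bin triples.

    Each TSS contributes bins (b-1, b, b+1) where b is the bin overlapping
    the TSS; contributions from multiple TSSs are summed per TSS location
    even when two TSSs share a bin.  Genes with any TSS outside the window
    (or at its edge, where a neighbour bin is missing) are excluded and
    reported in ``excluded``.
    """
    if tracks.window is None:
        raise ValueError("tracks must carry their genomic window")
    start, bw = tracks.window.start, tracks.bin_width
    n_bins = tracks.n_bins
    values, ids, excluded = [], [], []
    for gene in genes:
        bins = [tss_bin_index(t, start, bw) for t in gene.tss]
        if any(b < 1 or b > n_bins - 2 for b in bins):
            excluded.append(gene.gene_id)
            continue
        total = np.zeros(tracks.n_tracks)
        for b in bins:
            total += tracks.values[:, b - 1 : b + 2].sum(axis=1)
        values.append(total)
        ids.append(gene.gene_id)
    mat = GeneExpressionMatrix(np.array(values, dtype=float).reshape(len(ids), tracks.n_tracks), ids, excluded=excluded)
    if log1p:
        mat = mat.log1p()
    if standardize:
        mat = mat.standardize()
    return mat


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def across_genes_corr(pred: GeneExpressionMatrix, obs: GeneExpressionMatrix) -> np.ndarray:
    """One Pearson r per experiment, computed across genes."""
    if pred.values.shape != obs.values.shape:
        raise ValueError("matrices must align")
    return np.array([_pearson(pred.values[:, j], obs.values[:, j]) for j in range(pred.values.shape[1])])


def across_experiments_corr(
    pred: GeneExpressionMatrix,
    obs: GeneExpressionMatrix,
    n_strata: int = 3,
) -> pd.DataFrame:
    """Per-gene Pearson r across experiments, stratified by observed variance.

    Strata are quantile bins (tertiles by default) of each gene's observed
    expression variance across experiments; every gene lands in exactly one
    stratum.
    """
    if pred.values.shape != obs.values.shape:
        raise ValueError("matrices must align")
    var = obs.values.var(axis=1)
    order = np.argsort(np.argsort(var, kind="stable"), kind="stable")
    strata = np.minimum((order * n_strata) // len(var), n_strata - 1)
    r = np.array([_pearson(pred.values[i], obs.values[i]) for i in range(pred.values.shape[0])])
    return pd.DataFrame({"gene_id": pred.gene_ids, "r": r, "variance": var, "stratum": strata})


def deterministic_augmentations(max_shift: int = 3) -> list[tuple[int, bool]]:
    """The fixed 8-member set used for test-time averaging: shifts
    {-3,-1,+1,+3} crossed with both orientations."""
    shifts = [-max_shift, -1, 1, max_shift] if max_shift > 1 else [0, 0, 0, 0]
    return [(s, rc) for s in shifts for rc in (False, True)]


def predict_tta(model, onehot: np.ndarray, organism: str, augmentations: Optional[list] = None) -> np.ndarray:
    """Average predictions over augmented inputs (test-time augmentation).

    Reverse-orientation predictions are reversed back along the bin axis
    before averaging so all terms live on the forward strand.
    """
    if augmentations is None:
        augmentations = deterministic_augmentations()
    acc = None
    with no_grad():
        for k, rc in augmentations:
            seq = shift_sequence(OneHotSequence(np.asarray(onehot)), k, max_shift=max(abs(k), 1))
            if rc:
                seq, _ = reverse_complement(seq)
            pred = model.predict(seq.matrix, organism)  # (bins, tracks)
            if rc:
                pred = pred[::-1]
            acc = pred if acc is None else acc + pred
    return acc / len(augmentations)
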