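"""Signed variant-effect features and saturation-mutagenesis scoring
pipelines (per-locus lasso with cross-validation, and a training-free
first-principal-component summary).

A variant's feature vector is the per-track difference between reference and
alternative predictions, aggregated either by summing over the whole output
(population-variant mode) or over the 4 bins nearest the variant (512 bp,
local mode, with CAGE tracks log(1+x)-transformed before differencing), and
averaged over orientation and small-shift augmentations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .sequence_io import OneHotSequence, TrackManifest, reverse_complement, shift_sequence

_BASES = "ACGT"


@dataclass(frozen=True)
class Variant:
    """SNV record; position is 0-based in memory (converted from 1-based VCF)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only SNVs are supported")


@dataclass
class VariantFeatureVector:
    values: np.ndarray  # one signed value per track
    mode: str  # {"sum", "local"}
    cage_log1p: bool = False

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("variant features must be finite")


@dataclass
class LocusModel:
    """Per-locus scorer: either a fitted lasso or a PC1 summary definition."""

    locus_id: str
    kind: str  # {"lasso", "pc1"}
    feature_mean: Optional[np.ndarray] = None
    feature_sd: Optional[np.ndarray] = None
    kept_features: Optional[np.ndarray] = None
    coef: Optional[np.ndarray] = None
    intercept: float = 0.0
    alpha: Optional[float] = None
    loading: Optional[np.ndarray] = None
    feature_subset: Optional[np.ndarray] = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if self.kind == "lasso":
            x = (features[:, self.kept_features] - self.feature_mean) / self.feature_sd
            return x @ self.coef + self.intercept
        x = features[:, self.feature_subset] - self.feature_mean
        return x @ self.loading


# ---------------------------------------------------------------------------
# Feature extraction


def default_shifts(max_shift: int = 3) -> list[int]:
    """Small-shift set used for variant scoring (two draws, +/- max shift)."""
    return [-max_shift, max_shift]


def variant_features(
    model,
    context: np.ndarray,
    variant_offset: int,
    ref: str,
    alt: str,
    organism: str = "human",
    mode: str = "sum",
    cage_tracks: Optional[np.ndarray] = None,
    shifts: Optional[list[int]] = None,
    use_reverse_complement: bool = True,
) -> VariantFeatureVector:
    """Signed per-track (reference - alternative) prediction differences.

    ``context`` is the one-hot context window with the variant at
    ``variant_offset``; the base there must match ``ref``.  Predictions for
    each allele are averaged over orientation and shift augmentations before
    differencing.  ``mode="sum"`` sums every output bin per track;
    ``mode="local"`` sums the 4 bins nearest the variant (2 per side), with
    CAGE tracks (boolean mask ``cage_tracks``) log(1+x)-transformed first.
    """
    context = np.asarray(context)
    row = context[variant_offset]
    if row.sum() and _BASES[int(row.argmax())] != ref.upper():
        raise ValueError(
            f"reference mismatch at offset {variant_offset}: genome has {_BASES[int(row.argmax())]}, variant says {ref}"
        )
    shifts = default_shifts() if shifts is None else shifts
    augs = [(k, rc) for k in shifts for rc in ((False, True) if use_reverse_complement else (False,))]

    def allele_pred(base: str) -> np.ndarray:
        x = np.array(context, copy=True)
        x[variant_offset] = np.eye(4, dtype=x.dtype)[_BASES.index(base.upper())]
        acc = None
        for k, rc in augs:
            seq = shift_sequence(OneHotSequence(x), k, max_shift=max(abs(k), 1))
            if rc:
                seq, _ = reverse_complement(seq)
            pred = model.predict(seq.matrix, organism)
            if rc:
                pred = pred[::-1]
            acc = pred if acc is None else acc + pred
        return acc / len(augs)

    pred_ref = allele_pred(ref)
    pred_alt = allele_pred(alt)

    if mode == "sum":
        values = (pred_ref - pred_alt).sum(axis=0)
        log_applied = False
    elif mode == "local":
        bin_w = model.cfg.bin_width
        variant_bin = (variant_offset - model.cfg.crop_bins * bin_w) // bin_w
        lo = max(variant_bin - 2, 0)
        hi = min(variant_bin + 2, pred_ref.shape[0])
        pr, pa = pred_ref.copy(), pred_alt.copy()
        if cage_tracks is not None and np.any(cage_tracks):
            pr[:, cage_tracks] = np.log1p(pr[:, cage_tracks])
            pa[:, cage_tracks] = np.log1p(pa[:, cage_tracks])
        values = (pr[lo:hi] - pa[lo:hi]).sum(axis=0)
        log_applied = cage_tracks is not None and bool(np.any(cage_tracks))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return VariantFeatureVector(values, mode, log_applied)


# ---------------------------------------------------------------------------
# CAGI-style locus models


def fit_locus_lasso(
    train_features: np.ndarray,
    train_effects: np.ndarray,
    locus_id: str = "",
    cv_folds: int = 10,
    seed: int = 0,
) -> LocusModel:
    """Per-locus lasso: scale features to train mean 0 / sd 1, choose the
    regularization strength by k-fold cross-validation over a path.

    Zero-variance features are dropped before fitting.  Fold assignment is
    seeded and stratified by effect quantile for stability.
    """
    from sklearn.linear_model import Lasso, LassoCV

    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_effects, dtype=float)
    sd = X.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    if kept.size == 0 or np.std(y) == 0:
        return LocusModel(
            locus_id,
            "lasso",
            feature_mean=np.zeros(max(kept.size, 1)),
            feature_sd=np.ones(max(kept.size, 1)),
            kept_features=kept if kept.size else np.array([0], dtype=int),
            coef=np.zeros(max(kept.size, 1)),
            intercept=float(np.mean(y)),
            alpha=np.inf,
        )
    Xk = X[:, kept]
    mu, s = Xk.mean(axis=0), Xk.std(axis=0)
    Xs = (Xk - mu) / s

    # effect-quantile-stratified fold assignment, seeded
    n = len(y)
    order = np.argsort(y, kind="stable")
    folds = np.empty(n, dtype=int)
    rng = np.random.default_rng(seed)
    fold_cycle = np.arange(cv_folds)
    for block_start in range(0, n, cv_folds):
        block = order[block_start : block_start + cv_folds]
        folds[block] = rng.permutation(fold_cycle)[: len(block)]
    cv_iter = [(np.flatnonzero(folds != f), np.flatnonzero(folds == f)) for f in range(cv_folds)]

    cv = LassoCV(cv=cv_iter, max_iter=20000, random_state=seed)
    cv.fit(Xs, y)
    return LocusModel(
        locus_id,
        "lasso",
        feature_mean=mu,
        feature_sd=s,
        kept_features=kept,
        coef=cv.coef_,
        intercept=float(cv.intercept_),
        alpha=float(cv.alpha_),
    )


def pc1_summary(features: np.ndarray, subset: Optional[np.ndarray] = None, locus_id: str = "") -> LocusModel:
    """First principal component of the mean-centered selected features,
    with the sign fixed to correlate non-negatively with the feature mean."""
    X = np.asarray(features, dtype=float)
    subset = np.arange(X.shape[1]) if subset is None else np.asarray(subset)
    Xs = X[:, subset]
    mu = Xs.mean(axis=0)
    Xc = Xs - mu
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    loading = vt[0]
    scores = Xc @ loading
    mean_feature = Xc.mean(axis=1)
    if np.std(scores) > 0 and np.std(mean_feature) > 0:
        if np.corrcoef(scores, mean_feature)[0, 1] < 0:
            loading = -loading
    elif loading.sum() < 0:
        loading = -loading
    return LocusModel(locus_id, "pc1", feature_mean=mu, loading=loading, feature_subset=subset)


def select_features(
    manifest: TrackManifest,
    substrings: Optional[Sequence[str]] = None,
    assay_classes: Optional[Sequence[str]] = None,
    case_sensitive: bool = True,
) -> np.ndarray:
    """Indices of tracks whose description contains any substring and whose
    assay class is in ``assay_classes``.  Matching is case-sensitive by
    default; an empty result is allowed (callers should warn)."""
    table = manifest.table
    mask = np.ones(len(table), dtype=bool)
    if assay_classes is not None:
        mask &= table["assay_class"].isin(assay_classes).to_numpy()
    if substrings:
        desc = table["description"].astype(str)
        if not case_sensitive:
            desc = desc.str.lower()
            substrings = [s.lower() for s in substrings]
        sub_mask = np.zeros(len(table), dtype=bool)
        for s in substrings:
            sub_mask |= desc.str.contains(s, regex=False).to_numpy()
        mask &= sub_mask
    return np.flatnonzero(mask)
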