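"""Sequence, interval, coverage, and variant I/O plus augmentation primitives.

Coordinate conventions: 0-based, half-open everywhere in memory (BED-style);
VCF positions are converted from 1-based on ingest.  One-hot encoding maps
A, C, G, T to the four columns in that order and N to an all-zero row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_INDEX_BASE = np.array(list("ACGT"))
ASSAY_CLASSES = ("TF-ChIP", "histone-ChIP", "DNase/ATAC", "CAGE")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


@dataclass
class OneHotSequence:
    """L x 4 one-hot matrix; N rows are all zero."""

    matrix: np.ndarray
    origin: Optional[GenomicInterval] = None

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def decode(self) -> str:
        out = np.full(len(self), "N")
        hit = self.matrix.sum(axis=1) > 0
        out[hit] = _INDEX_BASE[self.matrix[hit].argmax(axis=1)]
        return "".join(out)


@dataclass
class TrackManifest:
    """Per-track metadata: identifier, assay class, organism, description."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"identifier", "assay_class", "organism", "description"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if self.table["identifier"].duplicated().any():
            raise ValueError("track identifiers must be unique")
        bad = set(self.table["assay_class"]) - set(ASSAY_CLASSES)
        if bad:
            raise ValueError(f"unknown assay classes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path) -> "TrackManifest":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class BinnedTracks:
    """T x B matrix of non-negative binned signal with its genomic window."""

    values: np.ndarray
    bin_width: int = 128
    window: Optional[GenomicInterval] = None
    track_ids: Optional[list] = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x B matrix")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("binned values must be finite and non-negative")
        if self.window is not None and len(self.window) != self.values.shape[1] * self.bin_width:
            raise ValueError("window length must equal n_bins * bin_width")

    @property
    def n_tracks(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Encoding and augmentation


def one_hot_encode(seq: str, origin: Optional[GenomicInterval] = None) -> OneHotSequence:
    """Encode A/C/G/T/N (case-insensitive) as an L x 4 {0,1} matrix."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    matrix = np.zeros((len(arr), 4), dtype=np.float32)
    known = np.zeros(len(arr), dtype=bool)
    for base, col in _BASE_INDEX.items():
        hit = arr == base.encode()
        matrix[hit, col] = 1.0
        known |= hit
    known |= arr == b"N"
    if not known.all():
        pos = int(np.flatnonzero(~known)[0])
        raise ValueError(f"unknown character {seq[pos]!r} at position {pos}")
    return OneHotSequence(matrix, origin)


def reverse_complement(x: OneHotSequence, y: Optional[BinnedTracks] = None):
    """Reverse-complement a sequence and (optionally) reverse its targets."""
    rc = x.matrix[::-1, ::-1].copy()  # reverse positions; A<->T, C<->G column swap
    out_x = OneHotSequence(rc, x.origin)
    if y is None:
        return out_x, None
    out_y = BinnedTracks(y.values[:, ::-1].copy(), y.bin_width, y.window, y.track_ids)
    return out_x, out_y


def shift_sequence(x: OneHotSequence, k: int, max_shift: int = 3) -> OneHotSequence:
    """Translate rows by k (positive = rightward); vacated rows become N."""
    if abs(k) > max_shift:
        raise ValueError(f"|shift| = {abs(k)} exceeds maximum {max_shift}")
    out = np.zeros_like(x.matrix)
    if k == 0:
        out[:] = x.matrix
    elif k > 0:
        out[k:] = x.matrix[:-k]
    else:
        out[:k] = x.matrix[-k:]
    return OneHotSequence(out, x.origin)


# ---------------------------------------------------------------------------
# Readers


def read_interval_sequence(fasta_path, interval: GenomicInterval) -> OneHotSequence:
    """Fetch an interval from an indexed FASTA; out-of-bounds bases become N."""
    from pyfaidx import Fasta

    with Fasta(str(fasta_path), one_based_attributes=False) as fa:
        if interval.chrom not in fa:
            raise KeyError(f"contig {interval.chrom!r} not in {fasta_path}")
        contig = fa[interval.chrom]
        clen = len(contig)
        lo = max(interval.start, 0)
        hi = min(interval.end, clen)
        core = str(contig[lo:hi]) if hi > lo else ""
    seq = "N" * (lo - interval.start) + core + "N" * (interval.end - max(hi, interval.start))
    return one_hot_encode(seq, interval)


def read_bin_table(path, track_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read the canonical TSV bin format: chrom, bin_start, one column per track."""
    df = pd.read_csv(path, sep="\t")
    if {"chrom", "bin_start"} - set(df.columns):
        raise ValueError(f"{path}: bin table needs 'chrom' and 'bin_start' columns")
    if track_ids is not None:
        df = df[["chrom", "bin_start", *track_ids]]
    return df


def read_binned_coverage(source, interval: GenomicInterval, bin_width: int = 128) -> BinnedTracks:
    """Aggregate per-base coverage into bins by summation.

    ``source`` may be a TSV bin table (pre-binned at the same width), a
    bedGraph, or a bigWig file; the format is chosen by file extension.
    """
    if len(interval) % bin_width:
        raise ValueError("interval length must be a multiple of bin_width")
    n_bins = len(interval) // bin_width
    path = Path(str(source))
    suffix = path.suffix.lower()
    if suffix in {".bw", ".bigwig"}:
        values, ids = _bins_from_bigwig(path, interval, bin_width, n_bins)
    elif suffix in {".bedgraph", ".bg"}:
        values, ids = _bins_from_bedgraph(path, interval, bin_width, n_bins)
    else:
        values, ids = _bins_from_table(path, interval, bin_width, n_bins)
    return BinnedTracks(values, bin_width, interval, ids)


def _bins_from_table(path, interval, bin_width, n_bins):
    df = read_bin_table(path)
    tracks = [c for c in df.columns if c not in ("chrom", "bin_start")]
    sub = df[df["chrom"] == interval.chrom]
    values = np.zeros((len(tracks), n_bins))
    idx = ((sub["bin_start"] - interval.start) // bin_width).to_numpy()
    keep = (sub["bin_start"] >= interval.start) & (sub["bin_start"] < interval.end)
    if keep.any() and np.any((sub.loc[keep, "bin_start"] - interval.start) % bin_width):
        raise ValueError("bin table is not aligned to the requested bin grid")
    for t, name in enumerate(tracks):
        values[t, idx[keep.to_numpy()]] = sub.loc[keep, name].to_numpy()
    return values, tracks


def _bins_from_bedgraph(path, interval, bin_width, n_bins):
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["chrom", "start", "end", "value"])
    per_base = np.zeros(len(interval))
    for _, row in df[df["chrom"] == interval.chrom].iterrows():
        lo = max(int(row["start"]), interval.start) - interval.start
        hi = min(int(row["end"]), interval.end) - interval.start
        if hi > lo:
            per_base[lo:hi] += row["value"]
    return per_base.reshape(1, n_bins, bin_width).sum(axis=2).reshape(1, n_bins), ["coverage"]


def _bins_from_bigwig(path, interval, bin_width, n_bins):
    import pyBigWig

    bw = pyBigWig.open(str(path))
    try:
        if interval.chrom not in bw.chroms():
            raise KeyError(f"contig {interval.chrom!r} not in {path}")
        clen = bw.chroms()[interval.chrom]
        per_base = np.zeros(len(interval))
        lo = max(interval.start, 0)
        hi = min(interval.end, clen)
        if hi > lo:
            vals = np.nan_to_num(np.asarray(bw.values(interval.chrom, lo, hi), dtype=float))
            per_base[lo - interval.start : hi - interval.start] = vals
    finally:
        bw.close()
    return per_base.reshape(1, n_bins, bin_width).sum(axis=2).reshape(1, n_bins), ["coverage"]


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path, names: Optional[Sequence[str]] = None):
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_variants(path) -> list:
    """Read SNV records from a VCF (coordinates and alleles only; INFO ignored)."""
    import pysam

    from .variant_effects import Variant

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alts = rec.alts or ()
            for alt in alts:
                out.append(Variant(rec.chrom, rec.pos - 1, rec.ref, alt))
    return out


def write_bedgraph(values: np.ndarray, interval: GenomicInterval, step: int, path):
    """Export a per-position score vector as bedGraph at the given step size."""
    with open(path, "w") as fh:
        for i, v in enumerate(np.asarray(values)):
            s = interval.start + i * step
            fh.write(f"{interval.chrom}\t{s}\t{min(s + step, interval.end)}\t{float(v):.6g}\n")
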