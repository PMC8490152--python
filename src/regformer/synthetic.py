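"""Synthetic regulatory-genome generator.

Generates loci with a planted regulatory grammar — a central promoter/TSS,
distal enhancers whose strength is encoded in the number of motif copies,
and optional insulator elements — together with matching multi-track binned
count targets:

* a CAGE-like track: point signal at the TSS whose rate is
  ``lambda0 * prod_e (1 + s_e * g(d_e))`` over enhancers e at distance d_e,
  with ``g(d) = 2^(-d / half_distance)`` and the factor dropped for
  enhancers separated from the TSS by an insulator;
* a DNase-like track: peaks at promoter, enhancers, and insulators;
* an H3K27ac-like track: peaks at enhancers (strength-scaled) and promoter.

Counts are drawn Poisson per 128-bp bin from the deterministic rates, which
are exactly reproducible from the element annotations.  The generator is a
controllable ground truth for testing long-range attribution, not a claim
about chromatin biology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .sequence_io import GenomicInterval

TRACKS = ("CAGE", "DNASE", "H3K27AC")
_BASES = np.array(list("ACGT"))


def consensus_pwm(consensus: str, p: float = 0.88) -> np.ndarray:
    """PWM with probability p on the consensus base, rest uniform."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    pwm = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        pwm[i, idx[b]] = p
    return pwm


@dataclass
class RegulatoryGrammar:
    """Parameters of the planted grammar (rates are counts per 128-bp bin)."""

    promoter_motif: np.ndarray = field(default_factory=lambda: consensus_pwm("TATAAAGGCC"))
    enhancer_motif: np.ndarray = field(default_factory=lambda: consensus_pwm("GGACGTCATC"))
    insulator_motif: np.ndarray = field(default_factory=lambda: consensus_pwm("CCACCAGGGGGC"))
    bin_width: int = 128
    gc_content: float = 0.5
    # element geometry
    promoter_halfwidth: int = 128  # bp on each side of the TSS
    enhancer_width: int = 2000
    insulator_width: int = 256
    # placement
    n_enhancers_range: tuple = (0, 3)  # inclusive bounds for generic sampling
    enhancer_distance_range: tuple = (5_000, 90_000)
    insulator_probability: float = 0.3
    # strengths: s_e = strength_per_copy * motif copies
    enhancer_copies_range: tuple = (1, 12)
    strength_per_copy: float = 0.5
    # rates
    lambda0: float = 8.0  # basal CAGE rate at the TSS bin
    half_distance: float = 30_000.0  # exponential distance-decay half-distance
    cage_background: float = 0.05
    dnase_background: float = 0.2
    k27ac_background: float = 0.2
    promoter_dnase: float = 12.0
    promoter_k27ac: float = 4.0
    enhancer_dnase_per_copy: float = 1.0
    enhancer_k27ac_per_copy: float = 1.5
    insulator_dnase: float = 8.0

    def decay(self, distance) -> np.ndarray:
        """g(d) = 2^(-d / half_distance); non-increasing, g(0) = 1."""
        return np.exp2(-np.abs(np.asarray(distance, dtype=float)) / self.half_distance)

    def validate(self):
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if self.strength_per_copy < 0:
            raise ValueError("enhancer strengths must be non-negative")
        return self


@dataclass(frozen=True)
class Element:
    kind: str  # {"promoter", "enhancer", "insulator"}
    start: int
    end: int
    copies: int = 0  # motif copies (enhancers)

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class SyntheticLocus:
    seq_indices: np.ndarray  # L, uint8 in 0..3
    tss: int
    elements: list[Element]
    rates: np.ndarray  # 3 x B deterministic Poisson rates
    counts: np.ndarray  # 3 x B sampled counts
    bin_width: int
    locus_id: str = "locus"

    @property
    def length(self) -> int:
        return len(self.seq_indices)

    @property
    def sequence(self) -> str:
        return "".join(_BASES[self.seq_indices])

    def onehot(self, dtype="float32") -> np.ndarray:
        return np.eye(4, dtype=dtype)[self.seq_indices]

    @property
    def enhancers(self) -> list[Element]:
        return [e for e in self.elements if e.kind == "enhancer"]

    @property
    def insulators(self) -> list[Element]:
        return [e for e in self.elements if e.kind == "insulator"]

    def pairs(self) -> list[dict]:
        """Ground-truth enhancer-gene records (all planted => validated)."""
        return [
            {
                "locus_id": self.locus_id,
                "enhancer_start": e.start,
                "enhancer_end": e.end,
                "tss": self.tss,
                "distance": abs(e.center - self.tss),
                "copies": e.copies,
                "label": True,
            }
            for e in self.enhancers
        ]


# ---------------------------------------------------------------------------
# Rates


def _blocked(enhancer: Element, tss: int, insulators: list[Element]) -> bool:
    lo, hi = sorted((enhancer.center, tss))
    return any(lo < ins.center < hi for ins in insulators)


def tss_rate(grammar: RegulatoryGrammar, elements: list[Element], tss: int) -> float:
    """lambda0 * prod over unblocked enhancers of (1 + s_e g(d_e))."""
    enhancers = [e for e in elements if e.kind == "enhancer"]
    insulators = [e for e in elements if e.kind == "insulator"]
    rate = grammar.lambda0
    for e in enhancers:
        if _blocked(e, tss, insulators):
            continue
        s_e = grammar.strength_per_copy * e.copies
        rate *= 1.0 + s_e * float(grammar.decay(e.center - tss))
    return rate


def rates_from_annotations(
    grammar: RegulatoryGrammar, elements: list[Element], tss: int, length: int
) -> np.ndarray:
    """Deterministic 3 x B rate matrix implied by the annotations."""
    bw = grammar.bin_width
    if length % bw:
        raise ValueError("locus length must be a multiple of bin_width")
    B = length // bw
    rates = np.zeros((3, B))
    rates[0] = grammar.cage_background
    rates[1] = grammar.dnase_background
    rates[2] = grammar.k27ac_background

    def bins_of(start, end):
        return slice(max(start // bw, 0), min(-(-end // bw), B))

    lam = tss_rate(grammar, elements, tss)
    b = tss // bw
    # CAGE point signal: full rate at the TSS bin, half in each neighbour
    rates[0, b] += lam
    if b - 1 >= 0:
        rates[0, b - 1] += 0.5 * lam
    if b + 1 < B:
        rates[0, b + 1] += 0.5 * lam

    for e in elements:
        sl = bins_of(e.start, e.end)
        if e.kind == "promoter":
            rates[1, sl] += grammar.promoter_dnase
            rates[2, sl] += grammar.promoter_k27ac
        elif e.kind == "enhancer":
            rates[1, sl] += grammar.enhancer_dnase_per_copy * e.copies
            rates[2, sl] += grammar.enhancer_k27ac_per_copy * e.copies
        elif e.kind == "insulator":
            rates[1, sl] += grammar.insulator_dnase
    return rates


# ---------------------------------------------------------------------------
# Sequence synthesis


def _background_indices(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _sample_motif(rng: np.random.Generator, pwm: np.ndarray) -> np.ndarray:
    return np.array([rng.choice(4, p=row) for row in pwm], dtype=np.uint8)


def _plant_motifs(seq, rng, pwm, start, end, copies):
    """Write ``copies`` motif instances evenly spaced across [start, end)."""
    w = pwm.shape[0]
    positions = np.linspace(start, end - w, copies).astype(int)
    for p in positions:
        seq[p : p + w] = _sample_motif(rng, pwm)


def sample_locus(
    grammar: RegulatoryGrammar,
    length: int,
    seed: int,
    n_enhancers: Optional[int] = None,
    enhancer_distance_range: Optional[tuple] = None,
    enhancer_copies: Optional[int] = None,
    allow_insulators: bool = True,
    locus_id: Optional[str] = None,
) -> SyntheticLocus:
    """Generate one locus: sequence, annotations, rates, and Poisson counts.

    Optional arguments pin placement choices (used by designed experiments);
    by default counts and positions are drawn from the grammar's ranges.
    """
    grammar.validate()
    rng = np.random.default_rng(seed)
    bw = grammar.bin_width
    if length % bw:
        raise ValueError("locus length must be a multiple of bin_width")
    tss = length // 2
    lo_d, hi_d = enhancer_distance_range or grammar.enhancer_distance_range
    max_n = n_enhancers if n_enhancers is not None else grammar.n_enhancers_range[1]
    if max_n > 0 and tss - lo_d - grammar.enhancer_width // 2 < 0:
        raise ValueError(f"locus length {length} too short for enhancer distances >= {lo_d}")
    seq = _background_indices(rng, length, grammar.gc_content)

    elements: list[Element] = []
    promoter = Element("promoter", tss - grammar.promoter_halfwidth, tss + grammar.promoter_halfwidth)
    _plant_motifs(seq, rng, grammar.promoter_motif, promoter.start, promoter.end, 3)
    elements.append(promoter)

    if n_enhancers is None:
        n_enhancers = int(rng.integers(grammar.n_enhancers_range[0], grammar.n_enhancers_range[1] + 1))
    occupied = [(promoter.start, promoter.end)]
    for _ in range(n_enhancers):
        for _attempt in range(50):
            d = int(rng.integers(lo_d, hi_d + 1))
            side = 1 if rng.random() < 0.5 else -1
            center = tss + side * d
            start, end = center - grammar.enhancer_width // 2, center + grammar.enhancer_width // 2
            if start < 0 or end > length:
                continue
            if all(end <= s or start >= e for s, e in occupied):
                break
        else:
            continue
        copies = (
            enhancer_copies
            if enhancer_copies is not None
            else int(rng.integers(grammar.enhancer_copies_range[0], grammar.enhancer_copies_range[1] + 1))
        )
        enh = Element("enhancer", start, end, copies=copies)
        _plant_motifs(seq, rng, grammar.enhancer_motif, start, end, copies)
        elements.append(enh)
        occupied.append((start, end))

    if allow_insulators and elements[-1].kind == "enhancer" and rng.random() < grammar.insulator_probability:
        # place an insulator between the TSS and the most recent enhancer
        enh = elements[-1]
        mid = (enh.center + tss) // 2
        start, end = mid - grammar.insulator_width // 2, mid + grammar.insulator_width // 2
        if all(end <= s or start >= e for s, e in occupied):
            ins = Element("insulator", start, end)
            _plant_motifs(seq, rng, grammar.insulator_motif, start, end, 4)
            elements.append(ins)

    rates = rates_from_annotations(grammar, elements, tss, length)
    counts = rng.poisson(rates).astype(np.float64)
    return SyntheticLocus(seq, tss, elements, rates, counts, bw, locus_id or f"locus_{seed}")


# ---------------------------------------------------------------------------
# Datasets


@dataclass
class SyntheticDataset:
    loci: list[SyntheticLocus]
    grammar: RegulatoryGrammar

    def __len__(self):
        return len(self.loci)

    def sampler(self, crop_bins: int, batch_size: int, use_rates: bool = False):
        """Batch sampler for the training loop: rng -> (x, y).

        y is the count (or rate) matrix cropped to the model's output bins,
        shaped (B, bins, tracks).
        """
        loci = self.loci

        def sample(rng: np.random.Generator):
            idx = rng.integers(0, len(loci), size=batch_size)
            xs, ys = [], []
            for i in idx:
                loc = loci[i]
                target = loc.rates if use_rates else loc.counts
                n_bins = target.shape[1]
                y = target[:, crop_bins : n_bins - crop_bins].T
                xs.append(loc.onehot())
                ys.append(y)
            return np.stack(xs), np.stack(ys)

        return sample


def make_dataset(
    grammar: RegulatoryGrammar,
    n_loci: int,
    length: int,
    split_fractions: dict = None,
    seed: int = 0,
    out_dir=None,
    **locus_kwargs,
) -> dict[str, SyntheticDataset]:
    """Generate loci with disjoint per-locus seeds and partition into splits.

    With ``out_dir`` the splits are also written as FASTA + TSV bin tables +
    a TSV element/pair manifest.
    """
    split_fractions = split_fractions or {"train": 0.8, "validation": 0.1, "test": 0.1}
    if abs(sum(split_fractions.values()) - 1) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    counts = {s: int(round(f * n_loci)) for s, f in split_fractions.items()}
    drift = n_loci - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift

    datasets, offset = {}, 0
    for split in split_fractions:
        loci = [
            sample_locus(grammar, length, seed=seed + offset + i, locus_id=f"{split}_{i}", **locus_kwargs)
            for i in range(counts[split])
        ]
        offset += counts[split]
        datasets[split] = SyntheticDataset(loci, grammar)

    if out_dir is not None:
        write_dataset(datasets, Path(out_dir))
    return datasets


def write_dataset(datasets: dict[str, SyntheticDataset], out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    for split, ds in datasets.items():
        with open(out_dir / f"{split}.fasta", "w") as fh:
            for loc in ds.loci:
                fh.write(f">{loc.locus_id}\n")
                seq = loc.sequence
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        rows = []
        for loc in ds.loci:
            for b in range(loc.counts.shape[1]):
                rows.append(
                    {
                        "chrom": loc.locus_id,
                        "bin_start": b * loc.bin_width,
                        **{t: loc.counts[k, b] for k, t in enumerate(TRACKS)},
                    }
                )
        pd.DataFrame(rows).to_csv(out_dir / f"{split}.bins.tsv", sep="\t", index=False)
        manifest = []
        for loc in ds.loci:
            for e in loc.elements:
                manifest.append(
                    {"locus_id": loc.locus_id, "kind": e.kind, "start": e.start, "end": e.end, "copies": e.copies, "tss": loc.tss}
                )
        pd.DataFrame(manifest).to_csv(out_dir / f"{split}.elements.tsv", sep="\t", index=False)
        pairs = [p for loc in ds.loci for p in loc.pairs()]
        pd.DataFrame(pairs, columns=["locus_id", "enhancer_start", "enhancer_end", "tss", "distance", "copies", "label"]).to_csv(
            out_dir / f"{split}.pairs.tsv", sep="\t", index=False
        )


def load_dataset(data_dir, split: str, grammar: Optional[RegulatoryGrammar] = None) -> SyntheticDataset:
    """Read a split written by :func:`write_dataset` back into memory.

    Rates are reconstructed from the element annotations (the rate model is
    deterministic given the grammar), so a round-tripped dataset is fully
    equivalent to the in-memory original.
    """
    data_dir = Path(data_dir)
    grammar = grammar or RegulatoryGrammar()
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    seqs: dict[str, str] = {}
    name = None
    with open(data_dir / f"{split}.fasta") as fh:
        chunks: list[str] = []
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            else:
                chunks.append(line)
        if name is not None:
            seqs[name] = "".join(chunks)
    bins = pd.read_csv(data_dir / f"{split}.bins.tsv", sep="\t")
    elements = pd.read_csv(data_dir / f"{split}.elements.tsv", sep="\t")
    loci = []
    for locus_id, seq in seqs.items():
        sub = bins[bins["chrom"] == locus_id].sort_values("bin_start")
        counts = sub[list(TRACKS)].to_numpy().T.astype(float)
        esub = elements[elements["locus_id"] == locus_id]
        tss = int(esub["tss"].iloc[0])
        elems = [Element(r.kind, int(r.start), int(r.end), copies=int(r.copies)) for r in esub.itertuples()]
        rates = rates_from_annotations(grammar, elems, tss, len(seq))
        indices = np.fromiter((idx[b] for b in seq), dtype=np.uint8, count=len(seq))
        loci.append(SyntheticLocus(indices, tss, elems, rates, counts, grammar.bin_width, locus_id))
    return SyntheticDataset(loci, grammar)


def track_manifest() -> "pd.DataFrame":
    """Manifest for the three synthetic tracks, matching the real-track schema."""
    from .sequence_io import TrackManifest

    return TrackManifest(
        pd.DataFrame(
            {
                "identifier": list(TRACKS),
                "assay_class": ["CAGE", "DNase/ATAC", "histone-ChIP"],
                "organism": ["human"] * 3,
                "description": ["CAGE synthetic TSS signal", "DNase synthetic accessibility", "H3K27ac synthetic enhancer mark"],
            }
        )
    )
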