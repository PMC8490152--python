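"""Homology-aware train/validation/test partitioning.

Both genomes are tiled into fixed-size regions (1 Mb by default); tiles from
the two organisms are joined by an edge whenever their summed aligned
sequence exceeds a threshold (100 kb), and connected components of the
resulting bipartite graph are assigned atomically to splits so no homologous
pair straddles a split boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_io import GenomicInterval

SPLITS = ("train", "validation", "test")


@dataclass(frozen=True)
class RegionTile:
    organism: str
    interval: GenomicInterval

    def __len__(self):
        return len(self.interval)


@dataclass(frozen=True)
class HomologyEdge:
    tile_a: RegionTile
    tile_b: RegionTile
    aligned_bp: int

    def __post_init__(self):
        if self.aligned_bp < 0:
            raise ValueError("aligned_bp must be non-negative")
        if self.aligned_bp > min(len(self.tile_a), len(self.tile_b)):
            raise ValueError("aligned_bp cannot exceed the shorter tile")


@dataclass
class SplitAssignment:
    assignment: dict[RegionTile, str]
    seed: int
    fractions: dict[str, float]

    def tiles(self, split: str) -> list[RegionTile]:
        return [t for t, s in self.assignment.items() if s == split]


def tile_genome(chrom_sizes: dict[str, int], tile_bp: int = 1_000_000, organism: str = "genome") -> list[RegionTile]:
    """Disjoint fixed-size tiles covering each chromosome; last tile shorter."""
    tiles = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, tile_bp):
            tiles.append(RegionTile(organism, GenomicInterval(chrom, start, min(start + tile_bp, size))))
    return tiles


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def _tile_of(tiles_by_chrom: dict, chrom: str, pos: int, tile_bp: int):
    return tiles_by_chrom.get((chrom, pos // tile_bp))


def build_edges(
    alignment_blocks: pd.DataFrame,
    tiles_a: Sequence[RegionTile],
    tiles_b: Sequence[RegionTile],
    threshold_bp: int = 100_000,
    tile_bp: int = 1_000_000,
) -> list[HomologyEdge]:
    """Aggregate aligned bp per tile pair; keep pairs strictly above threshold.

    ``alignment_blocks`` columns: chrom_a, start_a, end_a, chrom_b, start_b,
    end_b.  A block is credited to the tile containing its start in each
    genome (blocks are assumed short relative to tiles, as in net files).
    """
    index_a = {(t.interval.chrom, t.interval.start // tile_bp): t for t in tiles_a}
    index_b = {(t.interval.chrom, t.interval.start // tile_bp): t for t in tiles_b}
    acc: dict[tuple, int] = {}
    for row in alignment_blocks.itertuples(index=False):
        ta = _tile_of(index_a, row.chrom_a, int(row.start_a), tile_bp)
        tb = _tile_of(index_b, row.chrom_b, int(row.start_b), tile_bp)
        if ta is None or tb is None:
            continue
        span = min(int(row.end_a) - int(row.start_a), int(row.end_b) - int(row.start_b))
        acc[(ta, tb)] = acc.get((ta, tb), 0) + span
    return [HomologyEdge(a, b, bp) for (a, b), bp in acc.items() if bp > threshold_bp]


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}
        self.rank = {x: 0 for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1


def connected_components(tiles: Sequence[RegionTile], edges: Sequence[HomologyEdge]) -> list[list[RegionTile]]:
    uf = UnionFind(tiles)
    for e in edges:
        uf.union(e.tile_a, e.tile_b)
    groups: dict[RegionTile, list] = {}
    for t in tiles:
        groups.setdefault(uf.find(t), []).append(t)
    return list(groups.values())


def assign_splits(
    tiles: Sequence[RegionTile],
    edges: Sequence[HomologyEdge],
    fractions: dict[str, float] = None,
    seed: int = 0,
) -> SplitAssignment:
    """Assign connected components atomically to splits.

    Components are shuffled in seeded order and greedily routed to whichever
    split is furthest below its target tile-mass fraction, so realized
    fractions track the targets while every component stays intact.
    """
    fractions = fractions or {"train": 0.8, "validation": 0.1, "test": 0.1}
    if abs(sum(fractions.values()) - 1) > 1e-9:
        raise ValueError("fractions must sum to 1")
    comps = connected_components(tiles, edges)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(comps))
    total_mass = sum(len(t) for t in tiles)
    filled = {s: 0.0 for s in fractions}
    assignment: dict[RegionTile, str] = {}
    for ci in order:
        comp = comps[ci]
        mass = sum(len(t) for t in comp)
        # deficit relative to target fraction
        split = max(fractions, key=lambda s: fractions[s] - filled[s] / total_mass)
        for t in comp:
            assignment[t] = split
        filled[split] += mass
    return SplitAssignment(assignment, seed, fractions)


def read_alignment_blocks(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"}
    if need - set(df.columns):
        raise ValueError(f"alignment table needs columns {sorted(need)}")
    return df


def write_split_beds(assignment: SplitAssignment, out_dir):
    from pathlib import Path

    from .sequence_io import write_bed

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for split in SPLITS:
        tiles = assignment.tiles(split)
        by_org: dict[str, list] = {}
        for t in tiles:
            by_org.setdefault(t.organism, []).append(t.interval)
        for org, ivs in by_org.items():
            write_bed(sorted(ivs, key=lambda iv: (iv.chrom, iv.start)), out / f"{org}.{split}.bed")
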