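"""Deterministic genome-pair simulator with planted conserved segments.

The generator emulates the structure of a pair of annotated bacterial gene
orders: a pool of homology families shared by both genomes, genes whose
family is unique to one genome (and therefore disappears when the orders are
restricted to the common family universe), and operon-like *planted
segments* — short runs of genes whose families appear, close together, in
both genomes.  Each planted segment uses dedicated families that occur
exactly once per genome, so the segment is the unique locus of those
families; background genes draw their families uniformly (with replacement)
from the shared pool.

Planted segments are kept apart by a minimum stretch of filler genes so that
distinct segments cannot fall inside one window at the window lengths the
segments themselves require; within a segment, consecutive members are
placed 1..max_intra_gap positions apart, the gaps filled with background
genes.  Positions are the 1-based indices of genes in the complete genome.

Everything is driven by a single seeded generator, so a configuration plus
a seed reproduces the pair byte for byte.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from typing import Sequence

from .genome_model import Gene, GeneOrder, Operon

__all__ = ["SimulationConfig", "generate_pair", "truth_as_operons"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated genome pair.

    n_families : size of the shared background family pool.
    genome_length : total genes per genome (background + planted + noise).
    n_planted : number of planted conserved segments.
    planted_size_range : inclusive (min, max) genes per planted segment;
        at least 2.
    max_intra_gap : maximum positional spacing between consecutive segment
        members (1 = contiguous).
    noise_insertions : genes per genome whose family is unique to that
        genome; they vanish under family restriction but still occupy
        positions, exercising the index-vs-distance semantics.
    shuffle_within_segment : permute each segment's family order in genome B.
    seed : base seed; all randomness flows from it.
    """

    n_families: int = 40
    genome_length: int = 120
    n_planted: int = 3
    planted_size_range: tuple[int, int] = (4, 6)
    max_intra_gap: int = 1
    noise_insertions: int = 10
    shuffle_within_segment: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.planted_size_range
        if lo < 2 or hi < lo:
            raise ValueError("planted segment sizes must satisfy 2 <= min <= max")
        if self.max_intra_gap < 1:
            raise ValueError("max_intra_gap must be >= 1")
        if min(self.n_families, self.genome_length, self.n_planted, self.noise_insertions) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_families == 0 and self.genome_length > 0:
            raise ValueError("need a non-empty family pool for background genes")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _min_separation(cfg: SimulationConfig) -> int:
    # enough filler between segments that no window at the r needed for
    # contiguous segments can bridge two of them
    return max(6, cfg.max_intra_gap + 2)


def _build_genome(
    name: str,
    segments: Sequence[Sequence[str]],
    cfg: SimulationConfig,
    rng: random.Random,
) -> tuple[GeneOrder, dict[str, list[str]]]:
    """Assemble one genome; returns the order and gene ids per segment family."""
    planted_total = sum(len(s) for s in segments)
    n_background = cfg.genome_length - planted_total - cfg.noise_insertions
    if n_background < 0:
        raise ValueError(
            f"infeasible packing: {planted_total} planted + {cfg.noise_insertions} "
            f"noise genes exceed genome_length={cfg.genome_length}"
        )
    fillers = [rng.choice(range(cfg.n_families)) for _ in range(n_background)]
    filler_fams = [f"F{f:04d}" for f in fillers]
    filler_fams += [f"U{name}{k:04d}" for k in range(cfg.noise_insertions)]
    rng.shuffle(filler_fams)

    # intra-segment gaps (gap d => d-1 fillers between consecutive members)
    gaps: list[list[int]] = [
        [rng.randint(1, cfg.max_intra_gap) for _ in range(len(seg) - 1)]
        for seg in segments
    ]
    intra_need = sum(d - 1 for seg in gaps for d in seg)

    sep = _min_separation(cfg)
    n_inner_chunks = max(len(segments) - 1, 0)
    if intra_need + n_inner_chunks * sep > len(filler_fams):
        raise ValueError(
            "infeasible packing: not enough filler genes for intra-segment gaps "
            "and inter-segment separation; increase genome_length"
        )
    filler_iter = iter(filler_fams)
    intra_fillers = [next(filler_iter) for _ in range(intra_need)]
    rest = list(filler_iter)

    # split remaining fillers into chunks around the segments; interior
    # chunks get at least `sep` genes
    chunks: list[list[str]] = []
    free = len(rest) - n_inner_chunks * sep
    bounds = sorted(rng.randint(0, free) for _ in range(len(segments)))
    sizes = [bounds[0]] if segments else [len(rest)]
    for a, b in zip(bounds, bounds[1:]):
        sizes.append(sep + (b - a))
    if segments:
        sizes.append(free - bounds[-1])
    pos = 0
    for size in sizes:
        chunks.append(rest[pos : pos + size])
        pos += size

    # interleave: chunk0 seg0 chunk1 seg1 ... chunkN
    families: list[str | None] = []
    intra_iter = iter(intra_fillers)
    families.extend(chunks[0])
    for seg, seg_gaps, chunk in zip(segments, gaps, chunks[1:]):
        for k, fam in enumerate(seg):
            families.append(fam)
            if k < len(seg_gaps):
                for _ in range(seg_gaps[k] - 1):
                    families.append(next(intra_iter))
        families.extend(chunk)

    genes = tuple(
        Gene(fam, pos + 1, f"{name}.{pos + 1:05d}") for pos, fam in enumerate(families)
    )
    order = GeneOrder(genes, name=name)
    ids_by_family: dict[str, list[str]] = {}
    for g in genes:
        ids_by_family.setdefault(g.family, []).append(g.gene_id)
    return order, ids_by_family


def generate_pair(
    config: SimulationConfig,
) -> tuple[GeneOrder, GeneOrder, list[frozenset[str]]]:
    """Simulate a genome pair with planted conserved segments.

    Returns genome A, genome B, and the truth: one set of genome-A gene ids
    per planted segment, in segment order.  Both genomes contain every
    segment's families within ``max_intra_gap`` spacing; genome B sees the
    segments in an independently shuffled order (and internally shuffled if
    ``shuffle_within_segment``).
    """
    rng = random.Random(config.seed)
    sizes = [
        rng.randint(*config.planted_size_range) for _ in range(config.n_planted)
    ]
    segments_a = [
        [f"S{idx:02d}G{k:02d}" for k in range(size)] for idx, size in enumerate(sizes)
    ]

    order_a, ids_a = _build_genome("A", segments_a, config, rng)

    segments_b = [list(seg) for seg in segments_a]
    rng.shuffle(segments_b)
    if config.shuffle_within_segment:
        for seg in segments_b:
            rng.shuffle(seg)
    order_b, _ = _build_genome("B", segments_b, config, rng)

    truth = [
        frozenset(gid for fam in seg for gid in ids_a[fam]) for seg in segments_a
    ]
    return order_a, order_b, truth


def truth_as_operons(truth: Sequence[frozenset[str]]) -> list[Operon]:
    """Planted segments as operons on genome A, for end-to-end evaluation."""
    return [
        Operon(f"segment_{idx:02d}", members) for idx, members in enumerate(truth)
    ]
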