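"""Bidirectional best hit r-window gene clusters.

The model: an r-window is a contiguous stretch of a gene order whose
first-to-last positional span is at most r.  The similarity between two
windows is the *shared gene count* — the number of genes in one window whose
family occurs in the other.  The best hit of a query window is the
counterpart window with the highest shared gene count, ties broken by the
shortest window (and, as a residual deterministic tie-break, the smallest
start position).  A pair of windows that are each other's best hits, maximal
under simultaneous substring inclusion and containing more than a single
pair of genes, is a BBH r-window gene cluster.

The fast path enumerates query windows by sliding: from each start gene the
window is grown gene by gene while its span stays within r, the counterpart
genes of each newly covered family are fed into a :class:`WindowIndex`, and
the current best hit is read off the index after every extension.  Best hits
in both directions are intersected with a hash map and pruned to maximal,
non-trivial pairs.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Sequence

from .genome_model import (
    Gene,
    GeneOrder,
    Window,
    distance,
    restrict_to_common_families,
    shared_gene_count,
)
from .window_index import WindowIndex

__all__ = ["BestHit", "ClusterPair", "best_hit_windows", "canonical_trim", "bbh_filter", "maximality_filter", "find_clusters"]


@dataclass(frozen=True)
class BestHit:
    """A query window together with its best hit in the counterpart genome.

    Both windows are canonically trimmed: the hit begins and ends at genes
    whose family occurs in the query, and the query is trimmed to genes whose
    family occurs in the hit, so that window identities are comparable across
    the two directions of the search.
    """

    query: Window
    hit: Window
    count: int  # shared gene count of `hit` with respect to `query`

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("a best hit requires at least one shared gene")


@dataclass(frozen=True)
class ClusterPair:
    """A bidirectional best hit pair of r-windows.

    ``count_h`` is the shared gene count of the H-window with respect to the
    G-window and ``count_g`` the reverse.  ``trivial`` flags pairs consisting
    of a single gene on each side.
    """

    g_window: Window
    h_window: Window
    count_h: int
    count_g: int

    @property
    def trivial(self) -> bool:
        return self.g_window.n_genes == 1 and self.h_window.n_genes == 1

    @property
    def identity(self) -> tuple[tuple[str, float, float], tuple[str, float, float]]:
        return (self.g_window.identity, self.h_window.identity)

    def contains(self, other: "ClusterPair") -> bool:
        """Substring containment of *both* windows of ``other`` in ``self``."""
        return (
            self.g_window.start_pos <= other.g_window.start_pos
            and other.g_window.end_pos <= self.g_window.end_pos
            and self.h_window.start_pos <= other.h_window.start_pos
            and other.h_window.end_pos <= self.h_window.end_pos
        )


# ---------------------------------------------------------------------------
# canonical trimming
# ---------------------------------------------------------------------------

def canonical_trim(
    hit_start: float,
    query_families: frozenset[str] | set[str],
    H: GeneOrder,
    r: float,
) -> Window:
    """Trim the r-window of ``H`` anchored at ``hit_start`` to canonical form.

    The window runs from the anchor gene to the *last* gene within distance r
    whose family occurs in the query; this is the shortest window anchored at
    ``hit_start`` that realises its shared gene count.  The anchor itself must
    be a shared gene.
    """
    positions = [g.position for g in H.genes]
    i = bisect_left(positions, hit_start)
    if i >= len(positions) or positions[i] != hit_start:
        raise ValueError(f"no gene of {H.name} at position {hit_start!r}")
    if H.genes[i].family not in query_families:
        raise ValueError(
            f"anchor gene {H.genes[i].gene_id} does not share a family with the query"
        )
    j = bisect_right(positions, hit_start + r) - 1
    while H.genes[j].family not in query_families:
        j -= 1
    return Window(H, i + 1, j + 1)


def _trim_to_families(order: GeneOrder, i: int, j: int, families: frozenset[str]) -> Window:
    """Trim window ``order[i..j]`` (1-based) to first/last gene with family in ``families``."""
    genes = order.genes
    while genes[i - 1].family not in families:
        i += 1
    while genes[j - 1].family not in families:
        j -= 1
    return Window(order, i, j)


# ---------------------------------------------------------------------------
# the sliding-window enumeration (Algorithm "BestHitWindows")
# ---------------------------------------------------------------------------

def best_hit_windows(G: GeneOrder, H: GeneOrder, r: float) -> list[BestHit]:
    """Best hit in ``H`` for every r-window of ``G`` with a non-zero count.

    Expects gene orders already restricted to their common family universe
    (:func:`find_clusters` does this).  Query windows are enumerated from
    every start gene by extension; for each extension the genes of ``H``
    belonging to the newly covered family are inserted into a fresh
    :class:`WindowIndex` and the best window is queried.  Results are
    canonically trimmed and deduplicated.
    """
    if r < 0:
        raise ValueError(f"maximum window length r must be >= 0, got {r}")
    n = len(G)
    if n == 0 or len(H) == 0:
        return []

    # per-family gene positions in H (the `gs` table)
    gs: dict[str, list[float]] = {}
    for h in H.genes:
        gs.setdefault(h.family, []).append(h.position)

    h_positions = [h.position for h in H.genes]

    seen: dict[tuple, BestHit] = {}
    for i in range(1, n + 1):
        g_i = G.genes[i - 1]
        T = WindowIndex(r)
        covered: set[str] = set()
        e = i - 1  # 0-based index of the last gene currently in the window
        while e < n and distance(g_i, G.genes[e]) <= r:
            gene = G.genes[e]
            if gene.family not in covered:
                covered.add(gene.family)
                for pos in gs.get(gene.family, ()):
                    T.insert(pos)
            e += 1
            if not T:
                continue
            keys, smax = T.best_window()
            # Definition 2 tie-break: shortest trimmed window, then smallest
            # start position.
            best_key = None
            best_len = None
            best_end = None
            for k in keys:
                end = T.last_key_at_most(k + r)
                if best_len is None or (end - k, k) < (best_len, best_key):
                    best_key, best_len, best_end = k, end - k, end
            hi = bisect_left(h_positions, best_key) + 1
            hj = bisect_left(h_positions, best_end) + 1
            hit = Window(H, hi, hj)
            # trim the query to genes shared with the hit so both directions
            # agree on window identity
            shared_fams = frozenset(hit.families) & frozenset(covered)
            query = _trim_to_families(G, i, e, shared_fams)
            bh = BestHit(query=query, hit=hit, count=smax)
            seen.setdefault((query.identity, hit.identity), bh)
    return sorted(
        seen.values(),
        key=lambda b: (b.query.start_pos, b.query.end_pos, b.hit.start_pos, b.hit.end_pos),
    )


# ---------------------------------------------------------------------------
# bidirectional intersection and pruning (Algorithm "BBHWindows")
# ---------------------------------------------------------------------------

def _better_hit(a: BestHit, b: BestHit) -> BestHit:
    """Pick the stronger of two hits recorded for the same query identity."""
    ka = (-a.count, a.hit.length, a.hit.start_pos)
    kb = (-b.count, b.hit.length, b.hit.start_pos)
    return a if ka <= kb else b


def bbh_filter(bh_gh: Sequence[BestHit], bh_hg: Sequence[BestHit]) -> list[ClusterPair]:
    """Keep pairs that are best hits in both directions.

    The H-to-G hits are indexed by query identity in a hash map; a G-to-H
    record (w_G, w_H) survives iff the map sends w_H back to w_G.
    """
    M: dict[tuple, BestHit] = {}
    for bh in bh_hg:
        key = bh.query.identity
        M[key] = _better_hit(M[key], bh) if key in M else bh
    out: dict[tuple, ClusterPair] = {}
    for bh in bh_gh:
        rec = M.get(bh.hit.identity)
        if rec is not None and rec.hit.identity == bh.query.identity:
            pair = ClusterPair(
                g_window=bh.query,
                h_window=bh.hit,
                count_h=bh.count,
                count_g=rec.count,
            )
            out.setdefault(pair.identity, pair)
    return sorted(out.values(), key=lambda p: p.identity)


def maximality_filter(pairs: Sequence[ClusterPair]) -> list[ClusterPair]:
    """Drop pairs contained (on both sides) in another pair.

    Quadratic pairwise containment; cluster counts are small in practice.
    """
    pairs = list(pairs)
    kept = []
    for a in pairs:
        dominated = any(
            b is not a and b.contains(a) and not a.contains(b) for b in pairs
        )
        if not dominated:
            kept.append(a)
    return kept


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------

def _map_to_order(w: Window, order: GeneOrder) -> Window:
    """Re-express a window as the positional interval on another gene order.

    Used to report clusters on the complete gene orders: interior genes whose
    family is unique to one genome re-enter the window, exactly as in the
    reported cluster content.
    """
    return order.window_by_positions(w.start_pos, w.end_pos)


def run_pipeline(
    G: GeneOrder,
    H: GeneOrder,
    r: float,
    best_hits_fn,
    *,
    keep_trivial: bool = False,
) -> list[ClusterPair]:
    """Full clustering pipeline around a directional best-hit routine.

    Restrict to common families, compute best hits both ways, intersect,
    prune to maximal non-trivial pairs, and map windows back onto the
    complete input orders.  Both the sliding-window engine and the naive
    oracle engine share this skeleton so their outputs are directly
    comparable.
    """
    if r < 0:
        raise ValueError(f"maximum window length r must be >= 0, got {r}")
    Gr, Hr = restrict_to_common_families(G, H)
    bh_gh = best_hits_fn(Gr, Hr, r)
    bh_hg = best_hits_fn(Hr, Gr, r)
    pairs = bbh_filter(bh_gh, bh_hg)
    pairs = maximality_filter(pairs)
    if not keep_trivial:
        pairs = [p for p in pairs if not p.trivial]
    mapped = [
        ClusterPair(
            g_window=_map_to_order(p.g_window, G),
            h_window=_map_to_order(p.h_window, H),
            count_h=p.count_h,
            count_g=p.count_g,
        )
        for p in pairs
    ]
    return sorted(mapped, key=lambda p: p.identity)


def find_clusters(
    G: GeneOrder,
    H: GeneOrder,
    r: float,
    *,
    keep_trivial: bool = False,
) -> list[ClusterPair]:
    """All maximal, non-trivial BBH r-window gene clusters of G and H.

    The computation restricts both orders to their common family universe
    (original positions retained), finds directional best hits with the
    sliding-window algorithm, intersects them into bidirectional best hits,
    prunes non-maximal and trivial pairs, and reports windows as positional
    intervals on the *complete* input orders.  Output is sorted by G-window
    start and deterministic for a fixed input.
    """
    return run_pipeline(G, H, r, best_hit_windows, keep_trivial=keep_trivial)
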