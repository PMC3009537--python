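"""Exhaustive reference implementation of the clustering model.

Generates every r-window of both gene orders explicitly and finds each
query's best hit by scanning all counterpart windows.  Quartic-ish cost —
O(n·m·r^3) window comparisons — so only suitable for small instances, which
is exactly its job: it is the correctness oracle the sliding-window engine
is validated against.  Selection and trimming conventions match the fast
path precisely; an oracle with different conventions would test nothing.
"""

from __future__ import annotations

from .clustering import BestHit, ClusterPair, _trim_to_families, run_pipeline
from .genome_model import GeneOrder, Window, restrict_to_common_families

__all__ = ["naive_best_hits", "naive_find_clusters", "BudgetExceededError"]


class BudgetExceededError(RuntimeError):
    """The instance is too large for the exhaustive algorithm."""


def _all_windows(order: GeneOrder, r: float) -> list[Window]:
    """Every window (i, j) with positional span at most r."""
    out = []
    genes = order.genes
    n = len(genes)
    for i in range(n):
        for j in range(i, n):
            if genes[j].position - genes[i].position > r:
                break
            out.append(Window(order, i + 1, j + 1))
    return out


def naive_best_hits(G: GeneOrder, H: GeneOrder, r: float) -> list[BestHit]:
    """Best hit in H for every r-window of G, by brute-force scanning.

    For each query window every counterpart window is scored by shared gene
    count; the winner has the highest count, then the shortest span, then
    the smallest start position.  The winning window is necessarily in
    canonical (trimmed) form; the query is then trimmed to genes shared with
    the hit and duplicate (query, hit) records are merged, exactly as in the
    sliding-window engine.
    """
    if r < 0:
        raise ValueError(f"maximum window length r must be >= 0, got {r}")
    h_windows = [
        (w, w.families, tuple(g.family for g in w.genes)) for w in _all_windows(H, r)
    ]
    seen: dict[tuple, BestHit] = {}
    for q in _all_windows(G, r):
        qfams = q.families
        best = None  # (neg count, length, start, window)
        for w, wfams, wfam_list in h_windows:
            if qfams.isdisjoint(wfams):
                continue
            count = sum(1 for f in wfam_list if f in qfams)
            key = (-count, w.length, w.start_pos)
            if best is None or key < best[0]:
                best = (key, w, count)
        if best is None:
            continue
        _, hit, count = best
        shared = hit.families & qfams
        query = _trim_to_families(G, q.i, q.j, shared)
        bh = BestHit(query=query, hit=hit, count=count)
        seen.setdefault((query.identity, hit.identity), bh)
    return sorted(
        seen.values(),
        key=lambda b: (b.query.start_pos, b.query.end_pos, b.hit.start_pos, b.hit.end_pos),
    )


def naive_find_clusters(
    G: GeneOrder,
    H: GeneOrder,
    r: float,
    *,
    keep_trivial: bool = False,
    max_work: float = 5e7,
) -> list[ClusterPair]:
    """Maximal non-trivial BBH r-window clusters via the exhaustive algorithm.

    Refuses instances whose n·m·r^3 window-comparison estimate exceeds
    ``max_work`` — the point of this engine is correctness, not speed.
    """
    work = max(len(G), 1) * max(len(H), 1) * max(r, 1) ** 3
    if work > max_work:
        raise BudgetExceededError(
            f"instance too large for the exhaustive engine: n*m*r^3 = {work:g} "
            f"exceeds the budget of {max_work:g}; use find_clusters instead"
        )
    return run_pipeline(G, H, r, naive_best_hits, keep_trivial=keep_trivial)
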