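"""Scoring gene clusters against known operons.

An operon and a cluster are each represented by a set of gene ids on the
operon-bearing genome; their agreement is the Jaccard coefficient
|o ∩ c| / |o ∪ c|.  An operon's *Jaccard score* against a cluster set is its
best coefficient over the clusters, and it counts as *identified* when that
score reaches a threshold (2/3 by default, as a closed comparison so a score
of exactly 2/3 qualifies).  Given an external ranking of the clusters
(smaller score = better, e.g. a significance estimate), precision/recall
points are computed per ranking cutoff: the top-p clusters each contribute
at most one matched operon (their best, if above threshold), precision is
the number of distinct matched operons over p, and recall is that number
over the count of identifiable operons.

A cluster's gene set is taken from the cluster's window on the
operon-bearing genome, including interior genes whose family is unique to
that genome — such genes count against the Jaccard union, so a cluster that
sprawls beyond an operon is penalised.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .genome_model import ClusterRecord, Operon

__all__ = [
    "jaccard",
    "cluster_gene_ids",
    "jaccard_score",
    "identifiable_operons",
    "identified_operons",
    "rank_clusters",
    "precision_recall",
    "evaluate",
    "EvaluationReport",
]

DEFAULT_THRESHOLD = 2.0 / 3.0


def jaccard(o: Iterable[str], c: Iterable[str]) -> float:
    """Jaccard coefficient |o ∩ c| / |o ∪ c| of two gene-id sets.

    Equals 1 exactly for a perfect match and 0 for disjoint sets; undefined
    (raises) when both sets are empty.
    """
    o, c = set(o), set(c)
    union = o | c
    if not union:
        raise ValueError("Jaccard coefficient is undefined for two empty sets")
    return len(o & c) / len(union)


def cluster_gene_ids(cluster) -> frozenset[str]:
    """Gene ids of a cluster on the operon-bearing genome (genome A / G).

    Accepts in-memory :class:`~bbhwin.clustering.ClusterPair` objects and
    :class:`~bbhwin.genome_model.ClusterRecord` rows read from file.
    """
    if isinstance(cluster, ClusterRecord):
        return frozenset(cluster.g_gene_ids)
    return frozenset(cluster.g_window.gene_ids)


def jaccard_score(operon: Operon, clusters: Sequence) -> float:
    """Highest Jaccard coefficient between the operon and any cluster."""
    best = 0.0
    for c in clusters:
        ids = cluster_gene_ids(c)
        if not ids:
            continue
        best = max(best, jaccard(operon.members, ids))
    return best


def identifiable_operons(operons: Iterable[Operon]) -> list[Operon]:
    """Operons that can in principle be identified: at least two members."""
    return [o for o in operons if len(o.members) >= 2]


def identified_operons(
    operons: Iterable[Operon],
    clusters: Sequence,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[Operon]:
    """Identifiable operons whose Jaccard score reaches the threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    out = []
    for o in identifiable_operons(operons):
        s = jaccard_score(o, clusters)
        # a match always requires overlap, so threshold 0 means "any overlap"
        if s > 0 and s >= threshold:
            out.append(o)
    return out


def rank_clusters(clusters: Sequence, scores: Sequence[float] | None = None) -> list:
    """Order clusters for precision/recall, best first.

    With explicit ``scores`` (one per cluster, smaller = better, e.g. a log
    significance value) clusters are sorted ascending by score.  Without
    scores a proxy ranking is used: descending total shared gene count, then
    ascending combined window length — bigger and tighter ranks higher.
    """
    clusters = list(clusters)
    if scores is not None:
        if len(scores) != len(clusters):
            raise ValueError("need exactly one ranking score per cluster")
        return [c for _, _, c in sorted(zip(scores, range(len(clusters)), clusters))]

    def proxy(c):
        if isinstance(c, ClusterRecord):
            return (-(c.count_h + c.count_g), c.g_length + c.h_length, c.g_start_pos)
        return (
            -(c.count_h + c.count_g),
            c.g_window.length + c.h_window.length,
            c.g_window.start_pos,
        )

    return sorted(clusters, key=proxy)


def _best_matched_operon(cluster, operons: Sequence[Operon], threshold: float):
    """The operon best matched by this cluster, if the match reaches threshold."""
    ids = cluster_gene_ids(cluster)
    if not ids:
        return None
    best = None
    best_j = 0.0
    for o in operons:
        j = jaccard(o.members, ids)
        if j > best_j:
            best, best_j = o, j
    return best if best_j > 0 and best_j >= threshold else None


def precision_recall(
    ranked_clusters: Sequence,
    operons: Iterable[Operon],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[tuple[float, float]]:
    """Precision/recall at every cutoff of a ranked cluster list.

    At cutoff p, the top-p clusters each contribute their best-matching
    operon (when the Jaccard coefficient reaches the threshold); precision
    is the number of distinct matched operons over p and recall the same
    number over the count of identifiable operons.  Recall is non-decreasing
    in p.  An empty ranking yields an empty list.
    """
    ops = identifiable_operons(operons)
    matched: set[str] = set()
    points: list[tuple[float, float]] = []
    for p, cluster in enumerate(ranked_clusters, start=1):
        o = _best_matched_operon(cluster, ops, threshold)
        if o is not None:
            matched.add(o.name)
        precision = len(matched) / p
        recall = len(matched) / len(ops) if ops else 0.0
        points.append((precision, recall))
    return points


class EvaluationReport:
    """Bundle of the evaluation outputs for one cluster set.

    Attributes
    ----------
    scores : dict mapping operon name to its Jaccard score.
    identified : names of operons identified at the threshold.
    n_identifiable : number of operons with >= 2 members.
    n_matched_clusters / n_unmatched_clusters : clusters that do / do not
        match some identifiable operon at the threshold.
    pr_points : precision/recall per ranking cutoff.
    """

    def __init__(
        self,
        operons: Sequence[Operon],
        clusters: Sequence,
        threshold: float = DEFAULT_THRESHOLD,
        scores: Sequence[float] | None = None,
    ) -> None:
        ops = identifiable_operons(operons)
        self.threshold = threshold
        self.n_identifiable = len(ops)
        self.scores = {o.name: jaccard_score(o, clusters) for o in ops}
        self.identified = sorted(
            name for name, s in self.scores.items() if s > 0 and s >= threshold
        )
        ranked = rank_clusters(clusters, scores)
        self.n_matched_clusters = sum(
            1 for c in ranked if _best_matched_operon(c, ops, threshold) is not None
        )
        self.n_unmatched_clusters = len(ranked) - self.n_matched_clusters
        self.pr_points = precision_recall(ranked, ops, threshold)

    @property
    def recall(self) -> float:
        return len(self.identified) / self.n_identifiable if self.n_identifiable else 0.0


def evaluate(
    operons: Sequence[Operon],
    clusters: Sequence,
    threshold: float = DEFAULT_THRESHOLD,
    scores: Sequence[float] | None = None,
) -> EvaluationReport:
    """Convenience wrapper building an :class:`EvaluationReport`."""
    return EvaluationReport(operons, clusters, threshold, scores)
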