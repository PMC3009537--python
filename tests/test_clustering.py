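"""The sliding-window engine: best hits, trimming, BBH and maximality."""

import random

import pytest

from bbhwin import (
    Gene,
    GeneOrder,
    bbh_filter,
    best_hit_windows,
    canonical_trim,
    find_clusters,
    maximality_filter,
    naive_find_clusters,
    restrict_to_common_families,
    shared_gene_count,
)
from bbhwin.clustering import BestHit, ClusterPair

from conftest import random_instance


def order(*pairs, name="X"):
    return GeneOrder([Gene(f, p) for f, p in pairs], name=name)


class TestBestHitWindows:
    def test_example_query_finds_spanning_hit(self, example_G, example_H):
        G, H = restrict_to_common_families(example_G, example_H)
        hits = best_hit_windows(G, H, 3)
        by_query = {bh.query.identity: bh for bh in hits}
        bh = by_query[("G", 5, 6)]  # query ⟨c^5, d^6⟩
        assert (bh.hit.start_pos, bh.hit.end_pos, bh.count) == (1, 4, 2)

    def test_empty_counterpart_gives_no_hits(self, example_G):
        assert best_hit_windows(example_G, GeneOrder((), name="H"), 3) == []

    def test_negative_r_rejected(self, example_G, example_H):
        with pytest.raises(ValueError):
            best_hit_windows(example_G, example_H, -1)

    def test_hit_endpoints_share_family_with_query(self):
        rng = random.Random(7)
        for seed in range(20):
            G, H, r = random_instance(3000 + seed, max_n=40)
            Gr, Hr = restrict_to_common_families(G, H)
            for bh in best_hit_windows(Gr, Hr, r):
                qf = bh.query.families
                assert bh.hit.genes[0].family in qf
                assert bh.hit.genes[-1].family in qf
                assert bh.hit.length <= r and bh.query.length <= r
                assert bh.count == shared_gene_count(bh.hit, bh.query)


class TestCanonicalTrim:
    def test_trims_to_last_shared_gene_within_r(self, example_H):
        w = canonical_trim(1, {"c", "d"}, example_H, 3)
        assert (w.start_pos, w.end_pos) == (1, 4)  # ⟨c^1, a^3, d^4⟩

    def test_second_example_window(self, example_H):
        w = canonical_trim(6, {"e", "c", "b"}, example_H, 3)
        assert (w.start_pos, w.end_pos) == (6, 9)  # ⟨b^6, e^7, b^8, c^9⟩

    def test_no_further_shared_gene_gives_single_gene_window(self, example_H):
        w = canonical_trim(1, {"c"}, example_H, 3)
        assert w.n_genes == 1 and w.length == 0

    def test_anchor_must_share_a_family(self, example_H):
        with pytest.raises(ValueError):
            canonical_trim(3, {"c", "d"}, example_H, 3)  # a^3 not shared


class TestBbhFilter:
    def _bh(self, q, h, count):
        return BestHit(query=q, hit=h, count=count)

    def test_mutual_pair_survives(self):
        A = order(("x", 1), ("y", 2), name="A")
        B = order(("x", 1), ("y", 2), name="B")
        ab = self._bh(A.window(1, 2), B.window(1, 2), 2)
        ba = self._bh(B.window(1, 2), A.window(1, 2), 2)
        out = bbh_filter([ab], [ba])
        assert len(out) == 1 and out[0].count_h == out[0].count_g == 2

    def test_one_sided_hit_discarded(self):
        A = order(("x", 1), ("y", 2), name="A")
        B = order(("x", 1), ("y", 2), ("x", 5), name="B")
        ab = self._bh(A.window(1, 2), B.window(1, 2), 2)
        ba = self._bh(B.window(1, 2), A.window(1, 1), 1)  # maps back elsewhere
        assert bbh_filter([ab], [ba]) == []


class TestMaximalityFilter:
    def _pair(self, A, B, gi, gj, hi, hj):
        return ClusterPair(A.window(gi, gj), B.window(hi, hj), 1, 1)

    def test_contained_pair_removed(self):
        A = order(("a", 1), ("b", 2), ("c", 3), ("d", 4), name="A")
        B = order(("a", 4), ("b", 5), ("c", 6), ("d", 7), name="B")
        small = self._pair(A, B, 2, 3, 2, 3)
        big = self._pair(A, B, 1, 4, 1, 4)
        assert maximality_filter([small, big]) == [big]

    def test_incomparable_pairs_kept(self):
        A = order(("a", 1), ("b", 2), ("c", 3), name="A")
        B = order(("a", 1), ("b", 2), ("c", 3), name="B")
        p1 = self._pair(A, B, 1, 2, 1, 2)
        p2 = self._pair(A, B, 2, 3, 2, 3)
        assert maximality_filter([p1, p2]) == [p1, p2]

    def test_one_sided_containment_keeps_both(self):
        A = order(("a", 1), ("b", 2), ("c", 3), name="A")
        B = order(("a", 1), ("b", 2), ("c", 3), name="B")
        p1 = self._pair(A, B, 1, 2, 1, 3)
        p2 = self._pair(A, B, 1, 3, 2, 3)
        assert maximality_filter([p1, p2]) == [p1, p2]


class TestFindClusters:
    def test_worked_example(self, example_G, example_H):
        out = find_clusters(example_G, example_H, 3)
        got = {
            (tuple((g.family, g.position) for g in p.g_window.genes),
             tuple((g.family, g.position) for g in p.h_window.genes))
            for p in out
        }
        assert got == {
            ((("c", 5), ("d", 6)), (("c", 1), ("a", 3), ("d", 4))),
            ((("e", 9), ("c", 10), ("b", 11)),
             (("b", 6), ("e", 7), ("b", 8), ("c", 9))),
        }

    def test_reported_windows_live_on_complete_orders(self, example_G, example_H):
        # a^3 is unique to H yet sits inside the reported cluster window
        out = find_clusters(example_G, example_H, 3)
        h_families = {g.family for p in out for g in p.h_window.genes}
        assert "a" in h_families

    def test_disjoint_families_give_no_clusters(self):
        G = order(("a", 1), ("b", 2), name="G")
        H = order(("x", 1), ("y", 2), name="H")
        assert find_clusters(G, H, 3) == []

    def test_self_comparison_with_unique_families(self):
        G = order(*[(f"f{i}", i + 1) for i in range(8)], name="G")
        H = order(*[(f"f{i}", i + 1) for i in range(8)], name="H")
        for r in (1, 3, 5):
            fast = find_clusters(G, H, r)
            naive = naive_find_clusters(G, H, r)
            assert [p.identity for p in fast] == [p.identity for p in naive]
            assert fast  # identical orders always share clusters

    def test_trivial_pairs_dropped_by_default(self):
        G = order(("a", 1), name="G")
        H = order(("a", 1), name="H")
        assert find_clusters(G, H, 3) == []
        kept = find_clusters(G, H, 3, keep_trivial=True)
        assert len(kept) == 1 and kept[0].trivial

    def test_swap_symmetry_on_random_instances(self):
        for seed in range(15):
            G, H, r = random_instance(4000 + seed, max_n=50)
            fwd = find_clusters(G, H, r)
            rev = find_clusters(H, G, r)
            assert {(p.g_window.identity, p.h_window.identity) for p in fwd} == \
                   {(p.h_window.identity, p.g_window.identity) for p in rev}

    def test_deterministic_output(self):
        G, H, r = random_instance(777, max_n=60)
        assert find_clusters(G, H, r) == find_clusters(G, H, r)
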