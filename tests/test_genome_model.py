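"""Core data types, elementary operations and file round-trips."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbhwin import (
    Gene,
    GeneOrder,
    GeneOrderFormatError,
    Window,
    concat_chromosomes,
    distance,
    read_gene_order,
    read_operons,
    restrict_to_common_families,
    shared_gene_count,
    window_length,
    write_gene_order,
    write_operons,
    Operon,
)

from conftest import random_gene_order


def order(*pairs, name="X"):
    return GeneOrder([Gene(f, p) for f, p in pairs], name=name)


class TestGeneAndOrderInvariants:
    def test_gene_rejects_empty_family_and_nonfinite_position(self):
        with pytest.raises(ValueError):
            Gene("", 1)
        with pytest.raises(ValueError):
            Gene("a", math.inf)
        with pytest.raises(ValueError):
            Gene("a", math.nan)

    def test_gene_order_rejects_non_increasing_positions(self):
        with pytest.raises(ValueError):
            order(("a", 2), ("b", 1))
        with pytest.raises(ValueError):
            order(("a", 2), ("b", 2))

    def test_window_indices_are_one_based_inclusive(self):
        G = order(("a", 1), ("b", 2), ("c", 3))
        w = G.window(1, 3)
        assert [g.family for g in w.genes] == ["a", "b", "c"]
        with pytest.raises(ValueError):
            G.window(0, 2)
        with pytest.raises(ValueError):
            G.window(2, 4)

    def test_window_identity_ignores_backing_order_object(self):
        G = order(("a", 1), ("b", 2), ("c", 3), name="G")
        G2 = order(("a", 1), ("c", 3), name="G")  # restricted variant
        assert G.window(1, 3) == G2.window(1, 2)
        assert hash(G.window(1, 3)) == hash(G2.window(1, 2))


class TestDistance:
    @pytest.mark.parametrize(
        "g, h, expect",
        [
            (Gene("c", 5), Gene("d", 6), 1),
            (Gene("g", 4), Gene("g", 4), 0),
            (Gene("a", 3), Gene("c", 9), 6),
        ],
    )
    def test_examples(self, g, h, expect):
        assert distance(g, h) == expect

    @given(p=st.integers(-1000, 1000), q=st.integers(-1000, 1000))
    @settings(derandomize=True)
    def test_symmetric_and_zero_iff_equal(self, p, q):
        g, h = Gene("a", p), Gene("b", q)
        assert distance(g, h) == distance(h, g) == abs(p - q)
        assert (distance(g, h) == 0) == (p == q)


class TestWindowLength:
    def test_examples(self, example_G, example_H):
        assert window_length(example_H.window(1, 3)) == 3  # ⟨c^1,a^3,d^4⟩
        assert window_length(example_H.window(4, 7)) == 3  # ⟨b^6,e^7,b^8,c^9⟩
        assert window_length(example_G.window(2, 2)) == 0  # single gene


class TestSharedGeneCount:
    def test_examples(self, example_G, example_H):
        # ⟨c^1,a^3,d^4⟩ wrt ⟨c^5,d^6⟩: c and d shared, a not
        assert shared_gene_count(example_H.window(1, 3), example_G.window(1, 2)) == 2
        # ⟨b^6,e^7,b^8,c^9⟩ wrt ⟨e^9,c^10,b^11⟩: all four genes shared
        assert shared_gene_count(example_H.window(4, 7), example_G.window(3, 5)) == 4

    def test_zero_when_families_disjoint(self):
        A = order(("a", 1), ("b", 2))
        B = order(("x", 1), ("y", 2))
        assert shared_gene_count(A.window(1, 2), B.window(1, 2)) == 0

    def test_asymmetric_with_duplicated_families(self):
        A = order(("a", 1), ("a", 2), ("a", 3))
        B = order(("a", 1), ("b", 2))
        assert shared_gene_count(A.window(1, 3), B.window(1, 2)) == 3
        assert shared_gene_count(B.window(1, 2), A.window(1, 3)) == 1

    def test_bounded_by_target_size(self, example_G, example_H):
        w = example_H.window(1, 5)
        assert shared_gene_count(w, example_G.window(1, 5)) <= w.n_genes


class TestRestrictToCommonFamilies:
    def test_keeps_shared_families_with_original_positions(self):
        G = order(("a", 1), ("b", 5), name="G")
        H = order(("b", 2), ("c", 3), name="H")
        G2, H2 = restrict_to_common_families(G, H)
        assert [(g.family, g.position) for g in G2] == [("b", 5)]
        assert [(h.family, h.position) for h in H2] == [("b", 2)]

    def test_identity_when_universes_equal(self, example_G):
        G2, _ = restrict_to_common_families(example_G, example_G)
        assert G2.genes == example_G.genes

    def test_disjoint_universes_give_empty_orders(self):
        G2, H2 = restrict_to_common_families(
            order(("a", 1)), order(("z", 1))
        )
        assert len(G2) == 0 and len(H2) == 0

    def test_idempotent(self, example_G, example_H):
        G1, H1 = restrict_to_common_families(example_G, example_H)
        G2, H2 = restrict_to_common_families(G1, H1)
        assert G1.genes == G2.genes and H1.genes == H2.genes


class TestConcatChromosomes:
    def test_offset_arithmetic(self):
        c1 = order(("x", 1), ("y", 2))
        c2 = order(("z", 1))
        out = concat_chromosomes([c1, c2], gap=7)
        assert [g.position for g in out] == [1, 2, 9]

    def test_single_chromosome_unchanged(self, example_G):
        assert concat_chromosomes([example_G], gap=10).genes == example_G.genes

    def test_two_single_gene_chromosomes(self):
        out = concat_chromosomes([order(("a", 1)), order(("b", 1))], gap=10)
        assert [g.position for g in out] == [1, 11]

    @pytest.mark.parametrize("gap", [0, -1])
    def test_non_positive_gap_rejected(self, gap):
        with pytest.raises(ValueError):
            concat_chromosomes([order(("a", 1))], gap=gap)


class TestGeneOrderIO:
    def test_three_line_fixture(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(
            "gene_id\tfamily\tchromosome\tposition\n"
            "# a comment\n"
            "g1\tfamA\tchr1\t1\n"
            "g2\tfamB\tchr1\t4\n"
            "g3\tfamA\tchr1\t2\n"
        )
        G = read_gene_order(p)
        # rows sorted by position within the chromosome
        assert [(g.gene_id, g.position) for g in G] == [("g1", 1), ("g3", 2), ("g2", 4)]

    def test_header_only_file_is_empty_order(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("gene_id\tfamily\tchromosome\tposition\n")
        assert len(read_gene_order(p)) == 0

    @pytest.mark.parametrize(
        "body, fragment",
        [
            ("g1\tfamA\tchr1\t1\ng2\tfamB\tchr1\t1\n", "duplicate position"),
            ("g1\tfamA\tchr1\n", "columns"),
            ("g1\tfamA\tchr1\tNOPE\n", "non-numeric"),
        ],
    )
    def test_format_errors_name_offending_line(self, tmp_path, body, fragment):
        p = tmp_path / "bad.tsv"
        p.write_text("gene_id\tfamily\tchromosome\tposition\n" + body)
        with pytest.raises(GeneOrderFormatError, match=fragment):
            read_gene_order(p)

    def test_multi_chromosome_concatenation_requires_gap(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(
            "gene_id\tfamily\tchromosome\tposition\n"
            "g1\ta\tchr1\t1\n"
            "g2\tb\tchr1\t2\n"
            "g3\tc\tchr2\t1\n"
        )
        with pytest.raises(GeneOrderFormatError, match="gap"):
            read_gene_order(p)
        G = read_gene_order(p, gap=4)  # r=3 convention: gap = r+1
        assert [g.position for g in G] == [1, 2, 6]

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_write_read_round_trip(self, seed, tmp_path_factory):
        import random

        rng = random.Random(seed)
        G = random_gene_order(rng, "rt", rng.randint(0, 40), 7, gapped=True)
        p = tmp_path_factory.mktemp("io") / "g.tsv"
        write_gene_order(G, p)
        back = read_gene_order(p, name="rt")
        assert back.genes == G.genes and back.name == G.name

    def test_operon_round_trip(self, tmp_path):
        ops = [Operon("op1", frozenset({"g1", "g2"})), Operon("op2", frozenset({"g9"}))]
        p = tmp_path / "ops.tsv"
        write_operons(ops, p)
        assert read_operons(p) == ops
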