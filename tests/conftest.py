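import random

import pytest

from bbhwin import Gene, GeneOrder


@pytest.fixture(scope="session")
def example_G():
    """G = ⟨c^5, d^6, e^9, c^10, b^11⟩ — the worked two-genome example."""
    return GeneOrder(
        [Gene("c", 5, "g1"), Gene("d", 6, "g2"), Gene("e", 9, "g3"),
         Gene("c", 10, "g4"), Gene("b", 11, "g5")],
        name="G",
    )


@pytest.fixture(scope="session")
def example_H():
    """H = ⟨c^1, a^3, d^4, b^6, e^7, b^8, c^9⟩ (family a unique to H)."""
    return GeneOrder(
        [Gene("c", 1, "h1"), Gene("a", 3, "h2"), Gene("d", 4, "h3"),
         Gene("b", 6, "h4"), Gene("e", 7, "h5"), Gene("b", 8, "h6"),
         Gene("c", 9, "h7")],
        name="H",
    )


def random_gene_order(rng: random.Random, name: str, n: int, sigma: int,
                      gapped: bool = False) -> GeneOrder:
    """A random gene order: n genes over `sigma` families.

    With ``gapped`` the positions are a sorted sample from 1..2n (as if genes
    unique to the other genome had been removed); otherwise 1..n.
    """
    if gapped:
        positions = sorted(rng.sample(range(1, 2 * n + 1), n))
    else:
        positions = list(range(1, n + 1))
    return GeneOrder(
        [Gene(f"f{rng.randrange(sigma)}", p, f"{name}{i}")
         for i, p in enumerate(positions)],
        name=name,
    )


def random_instance(seed: int, max_n: int = 120):
    """One seeded clustering instance (G, H, r) for oracle comparisons."""
    rng = random.Random(seed)
    sigma = rng.choice([5, 20, 60])
    r = rng.randint(1, 8)
    n, m = rng.randint(4, max_n), rng.randint(4, max_n)
    G = random_gene_order(rng, "G", n, sigma, rng.random() < 0.3)
    H = random_gene_order(rng, "H", m, sigma, rng.random() < 0.3)
    return G, H, r
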