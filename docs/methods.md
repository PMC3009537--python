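# Methods

## The cluster model

`bbhwin` detects conserved gene clusters between two genomes abstracted as
*gene orders*: sequences of genes sorted by position, each gene labelled with
a homology family from an alphabet Σ. Only families with at least one gene
in each genome take part in the comparison; genes from genome-unique
families are removed before clustering, but **positions are kept**, so the
distance Δ(g, h) = |p − q| between two genes still counts the removed genes
lying between them. In the default convention positions are the 1-based
indices of genes in the complete genome.

An *r-window* G[i, j] is a contiguous substring whose span
Δ(g_i, g_j) does not exceed the single model parameter r, the maximum window
length. The similarity of two windows is the **shared gene count**: the
number of genes in one window whose family occurs in the other (asymmetric —
each gene counts once, so duplicated families contribute once per gene
copy). The **best hit** of a query window is the counterpart window with the
highest shared gene count; ties go to the shortest window, and a residual
tie (same count and span) goes to the smallest start position — the paper-
silent residual rule, chosen for determinism. A pair of windows that are
each other's best hits, is maximal under simultaneous substring inclusion,
and contains more than a single pair of genes is a **BBH r-window gene
cluster**. The bidirectional-best-hit constraint replaces the minimum
shared-gene-count parameter that a plain r-window model would need.

### Canonical window identity

The mutual-best-hit test compares a window recorded as a *hit* in one
direction with a window recorded as a *query* in the other, so both must be
reduced to a canonical form. A hit is trimmed to start and end at genes
whose family occurs in the query (trimming never changes the count and
yields the shortest window with that count, satisfying the tie-break); the
query is symmetrically trimmed to genes whose family occurs in the hit.
Identity is the triple (genome name, start position, end position). Whether
the original formulation trims query windows is not spelled out; trimmed
identity is the choice consistent with the worked example's printed output,
and the exhaustive reference engine applies the identical convention.

Clusters are reported as positional intervals mapped back onto the
*complete* gene orders, so genes from genome-unique families reappear in the
interior of reported windows (the worked example's ⟨c¹, a³, d⁴⟩ window
contains the unshared gene a³). Counts are unaffected: such genes belong to
families absent from the partner genome.

## Algorithms

**Exhaustive reference.** Enumerate every r-window of both genomes and scan
all counterpart windows per query — O(n·m·r³) window comparisons. It exists
as the correctness oracle: selection and trimming conventions match the fast
path exactly, and `naive_find_clusters` refuses instances beyond a
configurable work estimate (default 5·10⁷).

**Sliding-window engine.** For each start gene of the query genome the
window grows gene by gene while its span stays ≤ r. The counterpart genes of
each newly covered family (precomputed per-family lists) are inserted into a
fresh `WindowIndex`; after every extension the index reports the best
candidate start. Both directions are computed, intersected through a hash
map keyed by canonical identity, then pruned: containment on *both* sides
removes a pair (O(K²) pairwise checks — clusters are few), and pairs that
are a single gene on each side are dropped as trivial. Following the
published pseudocode the index is rebuilt per start gene rather than
maintained by deletions while sliding; `delete` exists and is exercised by
tests, and would support that optimisation.

**The window index.** Candidate H-window starts are exactly the genes of H
sharing a family with the current query (any maximal-count window can be
shifted to start at its first shared gene without losing count, so this
candidate set suffices). The index keeps them in a treap keyed by position;
the window anchored at key k is [k, k + r] and its count s(k) is the number
of stored keys inside. Insertion initialises the new node's count by
range-counting (size augmentation) and range-adds +1 over keys in
[p − r, p); deletion reverses this. Range updates touch the roots of the
O(lg|T|) subtrees canonically decomposing the interval and are resolved
lazily (pending Δ_s per subtree), as in segment trees. Each node also
carries the subtree maximum count and subtree key bounds, so the best
window — all argmax keys — is reported by descending only subtrees whose
maximum equals the global one. Split/merge operations recompute the
augmented attributes in constant time per touched node.

*Balancing*: a treap with a fixed-seed priority stream. Expected height is
c·lg n with c ≈ 4.31 almost surely; tests assert height ≤ 4.4·lg₂(n+1) + 6
under the default seed, including adversarial (sorted) insertion orders.
When one family is very frequent the index can hold more than r keys for a
single query window; the structure stays correct, the complexity of the
enumeration then being output-sensitive.

## Degenerate inputs and numerical choices

- r = 0 is legal: every window is a single gene and the non-trivial filter
  empties the output.
- Positions are reals in the data model (ints in practice); duplicate
  positions are rejected, as tie positions are undefined in the model.
- Family identifiers compare as exact, case-sensitive strings.
- Multi-chromosome inputs are concatenated in input order with a gap
  supplied by the caller; r + 1 is the minimal gap that stops windows from
  spanning chromosomes and is the CLI default.
- Queries with zero shared genes produce no best-hit record.

## Evaluation protocol

An operon o and a cluster c are compared as gene-id sets on the
operon-bearing genome by the Jaccard coefficient |o ∩ c| / |o ∪ c|
(undefined for two empty sets). The cluster's gene set is **every** gene of
the complete genome inside its window there — interior genes from unshared
families count against the union, penalising sprawling clusters; whether the
original analysis included them is unstated, and this is the package's
flagged choice. An operon's *Jaccard score* is its best coefficient over the
cluster set; it is *identified* when the score reaches the threshold
(default 2/3, closed comparison so exactly 2/3 qualifies, and always
requiring positive overlap). Operons with fewer than two genes are never
identifiable and are excluded from denominators.

Precision/recall: clusters are ranked externally (any per-cluster real
score, ascending = better — e.g. a significance estimate computed outside
this package) or by the built-in proxy (descending total shared gene count,
then ascending combined span: bigger and tighter first). At cutoff p each of
the top-p clusters contributes at most its single best-matching operon;
precision = distinct matched operons / p, recall = distinct matched operons
/ identifiable operons. Recall is non-decreasing in p by construction.

## Synthetic data

The simulator emulates the structure of a pair of annotated bacterial
genomes: a shared background family pool (default 40 families, drawn
uniformly with replacement), per-genome unique-family genes (default 10;
they vanish under family restriction but occupy positions), and operon-like
planted segments (default 3 segments of 4–6 genes) whose dedicated families
occur exactly once per genome. Genome B sees the segments in shuffled order,
optionally internally shuffled. Consecutive segment members sit 1 to
`max_intra_gap` positions apart (background genes fill wider gaps); distinct
segments are separated by at least max(6, max_intra_gap + 2) filler genes so
that windows at the r values implied by contiguous segments cannot bridge
segments. Default genome length is 120 genes — large enough for realistic
background around three segments, small enough that ensembles of dozens of
simulations run in seconds. One seeded generator drives everything; a
configuration plus seed reproduces the pair byte for byte.

These choices make contiguous-segment recovery provable rather than merely
likely: with gaps of 1 and r equal to the largest planted span, the exact
segment pair is always a mutual best hit (its dedicated families occur
nowhere else), and any containing cluster that replaces it under maximality
can exceed the segment by at most r − span(segment) ≤ 2 genes on the
operon-bearing side, keeping the Jaccard score at ≥ s/(s+2) ≥ 2/3 for
segments of ≥ 4 genes. Once intra-segment gaps push a segment's span past r
no single window covers it and its score collapses, which is the degradation
the gap-sweep tests measure.

What the simulator does **not** model: inversions and transpositions within
segments (segment order between genomes is shuffled, member order is not
rearranged unless `shuffle_within_segment`), gene loss inside segments,
paralog expansions of planted families, and realistic family-size
distributions for the background. Passing the recovery tests therefore
shows the pipeline is correct under the model's own assumptions, not that
real operons are recovered at these rates; on real genome pairs the
achievable recall is bounded by how many operons survive in both genomes at
all.

## Problem sizes used in the checks

The engine-equivalence ensemble uses 200 seeded instances with up to 120
genes per genome, family alphabets of 5/20/60 and r from 1 to 8 — the
largest sizes at which the exhaustive reference is comfortable; the index
recount checks use ~30-operation random sequences over a 0–60 key space;
recovery ensembles use 50 seeds at 120–220 genes. These sizes exercise
every code path (window rebuilds, lazy pushes, ties, multi-occurrence
families) while keeping the full suite fast.

## Known limitations

- Orientation-blind: strand information is ignored by the model.
- Pairwise only: no quorum/multi-genome extension, and the max-gap "gene
  teams" model is out of scope (the evaluation protocol accepts any
  externally produced cluster ranking for comparison purposes).
- No statistical significance estimation; the default ranking proxy is not
  a p-value.
- The maximality filter is quadratic in the number of BBH pairs.
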