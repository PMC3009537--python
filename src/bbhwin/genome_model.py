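"""Core data types for gene-order comparison.

A genome is abstracted as a *gene order*: a sequence of genes sorted by
position, where each gene carries a homology-family label (a symbol from the
family alphabet) and a real-valued position.  In the default convention the
position of a gene is its 1-based index in the complete genome, so the
distance between two genes counts the genes lying between them (including
genes later removed because their family occurs in only one of the two
genomes under comparison).

This module also provides the TSV readers/writers for gene orders, operon
annotations and cluster output.
"""

from __future__ import annotations

import csv
import json
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Gene",
    "GeneOrder",
    "Window",
    "Operon",
    "ClusterRecord",
    "GeneOrderFormatError",
    "distance",
    "window_length",
    "shared_gene_count",
    "restrict_to_common_families",
    "concat_chromosomes",
    "read_gene_order",
    "write_gene_order",
    "read_operons",
    "write_operons",
    "clusters_to_text",
    "write_clusters",
    "read_clusters",
]


class GeneOrderFormatError(ValueError):
    """Raised when an input file violates the gene-order / operon TSV format."""


@dataclass(frozen=True, order=True)
class Gene:
    """A single gene: a homology family plus a position on the genome.

    ``family`` is a symbol from the family alphabet; ``position`` is a finite
    real number (an integer index in the default convention); ``gene_id`` is
    an opaque label used for evaluation and reporting only — it takes no part
    in the clustering model itself.
    """

    family: str
    position: float
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("gene family must be non-empty")
        if not math.isfinite(self.position):
            raise ValueError(f"gene position must be finite, got {self.position!r}")
        if not self.gene_id:
            object.__setattr__(self, "gene_id", f"{self.family}^{self.position:g}")


@dataclass(frozen=True)
class GeneOrder:
    """A genome as a position-sorted sequence of genes.

    Positions must be strictly increasing: two genes never share a position.
    """

    genes: tuple[Gene, ...]
    name: str = "genome"

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        for a, b in zip(self.genes, self.genes[1:]):
            if not (a.position < b.position):
                raise ValueError(
                    f"gene positions must be strictly increasing: "
                    f"{a.gene_id}@{a.position} before {b.gene_id}@{b.position}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __getitem__(self, idx: int) -> Gene:
        return self.genes[idx]

    @property
    def positions(self) -> tuple[float, ...]:
        return tuple(g.position for g in self.genes)

    @property
    def families(self) -> frozenset[str]:
        return frozenset(g.family for g in self.genes)

    def window(self, i: int, j: int) -> "Window":
        """The window from the i-th to the j-th gene (1-based, inclusive)."""
        return Window(self, i, j)

    def window_by_positions(self, lo: float, hi: float) -> "Window":
        """Smallest window covering all genes with position in [lo, hi].

        Raises ValueError when no gene falls inside the interval.
        """
        pos = [g.position for g in self.genes]
        i = bisect_left(pos, lo)
        j = bisect_right(pos, hi) - 1
        if i > j:
            raise ValueError(f"no gene of {self.name} in position range [{lo}, {hi}]")
        return Window(self, i + 1, j + 1)


@dataclass(frozen=True)
class Window:
    """A contiguous substring ``order[i..j]`` of a gene order.

    ``i`` and ``j`` are 1-based gene indices, inclusive on both ends.  Two
    windows are equal when they denote the same positional interval on a
    genome of the same name (the canonical window identity); the underlying
    gene-order object does not enter the comparison, so a window on a
    family-restricted order equals the corresponding window on the complete
    order.
    """

    order: GeneOrder = field(compare=False)
    i: int
    j: int

    def __post_init__(self) -> None:
        if not (1 <= self.i <= self.j <= len(self.order)):
            raise ValueError(
                f"window indices out of range: 1 <= {self.i} <= {self.j} "
                f"<= {len(self.order)} violated"
            )

    # canonical identity -----------------------------------------------------
    @property
    def identity(self) -> tuple[str, float, float]:
        return (self.order.name, self.start_pos, self.end_pos)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Window):
            return NotImplemented
        return self.identity == other.identity

    def __hash__(self) -> int:
        return hash(self.identity)

    # accessors --------------------------------------------------------------
    @property
    def genes(self) -> tuple[Gene, ...]:
        return self.order.genes[self.i - 1 : self.j]

    @property
    def start_pos(self) -> float:
        return self.order.genes[self.i - 1].position

    @property
    def end_pos(self) -> float:
        return self.order.genes[self.j - 1].position

    @property
    def length(self) -> float:
        """Positional span; a single-gene window has length 0."""
        return self.end_pos - self.start_pos

    @property
    def n_genes(self) -> int:
        return self.j - self.i + 1

    @property
    def families(self) -> frozenset[str]:
        return frozenset(g.family for g in self.genes)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        inner = ", ".join(f"{g.family}^{g.position:g}" for g in self.genes)
        return f"{self.order.name}[{self.i},{self.j}]=⟨{inner}⟩"


@dataclass(frozen=True)
class Operon:
    """A named set of co-transcribed genes, identified by gene ids."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"operon {self.name!r} has no members")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def distance(g: Gene, h: Gene) -> float:
    """Absolute positional difference |p - q| between two genes.

    With index positions this is the number of elements between the two genes
    of interest (endpoints spanning k intervening genes are k+1 apart).
    """
    return abs(g.position - h.position)


def window_length(w: Window) -> float:
    """Span of a window: distance between its first and last genes."""
    return distance(w.genes[0], w.genes[-1])


def shared_gene_count(w_target: Window, w_reference: Window) -> int:
    """Number of genes of ``w_target`` from a family present in ``w_reference``.

    Asymmetric: each gene of the target window counts once, so a family with
    several gene copies in the target contributes once per copy.
    """
    ref_families = w_reference.families
    return sum(1 for g in w_target.genes if g.family in ref_families)


def restrict_to_common_families(G: GeneOrder, H: GeneOrder) -> tuple[GeneOrder, GeneOrder]:
    """Keep only genes whose family occurs in both genomes.

    Positions are left untouched, so distances measured on the restricted
    orders still count removed (genome-unique) intervening genes.  Idempotent.
    """
    common = G.families & H.families
    g2 = GeneOrder(tuple(g for g in G.genes if g.family in common), name=G.name)
    h2 = GeneOrder(tuple(h for h in H.genes if h.family in common), name=H.name)
    return g2, h2


def concat_chromosomes(chroms: Sequence[GeneOrder], gap: float, name: str | None = None) -> GeneOrder:
    """Concatenate chromosomes into one gene order.

    Each chromosome after the first is shifted so that its first gene lies
    exactly ``gap`` beyond the last gene of the previous chromosome.  A gap
    larger than the window length r guarantees that no window spans two
    chromosomes.
    """
    if gap <= 0:
        raise ValueError(f"chromosome gap must be positive, got {gap}")
    if not chroms:
        return GeneOrder((), name=name or "genome")
    if len(chroms) == 1:
        c = chroms[0]
        return c if name is None else GeneOrder(c.genes, name=name)
    genes: list[Gene] = list(chroms[0].genes)
    for chrom in chroms[1:]:
        if not chrom.genes:
            continue
        if genes:
            offset = genes[-1].position + gap - chrom.genes[0].position
        else:
            offset = 0.0
        for g in chrom.genes:
            genes.append(Gene(g.family, g.position + offset, g.gene_id))
    return GeneOrder(tuple(genes), name=name or chroms[0].name)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

_GENE_ORDER_COLUMNS = ("gene_id", "family", "chromosome", "position")


def _parse_position(text: str, path: str, lineno: int) -> float:
    try:
        value = float(text)
    except ValueError:
        raise GeneOrderFormatError(
            f"{path}:{lineno}: non-numeric position {text!r}"
        ) from None
    if value == int(value):
        return int(value)
    return value


def _data_rows(path: Path) -> Iterator[tuple[int, list[str]]]:
    with path.open(encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_gene_order(
    path: str | Path,
    *,
    name: str | None = None,
    gap: float | None = None,
) -> GeneOrder:
    """Read a gene-order TSV (``gene_id  family  chromosome  position``).

    Rows are grouped by chromosome (in order of first appearance) and sorted
    by position within each chromosome.  Multi-chromosome files are
    concatenated with :func:`concat_chromosomes`; the caller must then supply
    ``gap`` (use r+1 for a window length r).  ``#`` comment lines are skipped.
    """
    path = Path(path)
    rows = _data_rows(path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise GeneOrderFormatError(f"{path}:1: empty file, expected header") from None
    if tuple(header) != _GENE_ORDER_COLUMNS:
        raise GeneOrderFormatError(
            f"{path}:{header_lineno}: expected header "
            f"{' / '.join(_GENE_ORDER_COLUMNS)}, got {' / '.join(header)}"
        )
    by_chrom: dict[str, list[tuple[float, Gene]]] = {}
    for lineno, fields in rows:
        if len(fields) != 4:
            raise GeneOrderFormatError(
                f"{path}:{lineno}: expected 4 tab-separated columns, got {len(fields)}"
            )
        gene_id, family, chrom, pos_text = fields
        if not family:
            raise GeneOrderFormatError(f"{path}:{lineno}: empty family")
        pos = _parse_position(pos_text, str(path), lineno)
        entry = by_chrom.setdefault(chrom, [])
        if any(p == pos for p, _ in entry):
            raise GeneOrderFormatError(
                f"{path}:{lineno}: duplicate position {pos_text} on chromosome {chrom!r}"
            )
        entry.append((pos, Gene(family, pos, gene_id)))
    order_name = name if name is not None else path.stem
    chroms = [
        GeneOrder(tuple(g for _, g in sorted(entry)), name=order_name)
        for entry in by_chrom.values()
    ]
    if not chroms:
        return GeneOrder((), name=order_name)
    if len(chroms) > 1:
        if gap is None:
            raise GeneOrderFormatError(
                f"{path}: {len(chroms)} chromosomes found; a concatenation gap "
                f"is required (use r+1)"
            )
        return concat_chromosomes(chroms, gap, name=order_name)
    return chroms[0]


def write_gene_order(order: GeneOrder, path: str | Path, *, chromosome: str = "chr1") -> None:
    """Write a (single-chromosome) gene order as gene-order TSV."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_GENE_ORDER_COLUMNS) + "\n")
        for g in order.genes:
            fh.write(f"{g.gene_id}\t{g.family}\t{chromosome}\t{g.position:g}\n")


def read_operons(path: str | Path) -> list[Operon]:
    """Read an operon TSV (``operon  gene_ids`` with comma-separated ids)."""
    path = Path(path)
    rows = _data_rows(path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise GeneOrderFormatError(f"{path}:1: empty file, expected header") from None
    if tuple(header) != ("operon", "gene_ids"):
        raise GeneOrderFormatError(
            f"{path}:{header_lineno}: expected header operon / gene_ids"
        )
    operons = []
    for lineno, fields in rows:
        if len(fields) != 2:
            raise GeneOrderFormatError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
            )
        name, ids = fields
        members = frozenset(x for x in ids.split(",") if x)
        if not members:
            raise GeneOrderFormatError(f"{path}:{lineno}: operon {name!r} has no members")
        operons.append(Operon(name, members))
    return operons


def write_operons(operons: Iterable[Operon], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("operon\tgene_ids\n")
        for op in operons:
            fh.write(f"{op.name}\t{','.join(sorted(op.members))}\n")


# --- cluster output ---------------------------------------------------------

_CLUSTER_COLUMNS = (
    "cluster_id",
    "g_start_pos",
    "g_end_pos",
    "g_genes",
    "h_start_pos",
    "h_end_pos",
    "h_genes",
    "count_h_wrt_g",
    "count_g_wrt_h",
    "g_length",
    "h_length",
)


@dataclass(frozen=True)
class ClusterRecord:
    """A cluster as read back from a cluster TSV/JSON file.

    Mirrors the on-disk schema; ``extras`` holds any additional columns (for
    instance an externally computed significance score used for ranking).
    """

    cluster_id: str
    g_start_pos: float
    g_end_pos: float
    g_gene_ids: tuple[str, ...]
    h_start_pos: float
    h_end_pos: float
    h_gene_ids: tuple[str, ...]
    count_h: int
    count_g: int
    g_length: float
    h_length: float
    extras: Mapping[str, str] = field(default_factory=dict)


def _cluster_row(idx: int, pair) -> dict[str, str]:
    gw, hw = pair.g_window, pair.h_window
    return {
        "cluster_id": f"c{idx}",
        "g_start_pos": f"{gw.start_pos:g}",
        "g_end_pos": f"{gw.end_pos:g}",
        "g_genes": ",".join(gw.gene_ids),
        "h_start_pos": f"{hw.start_pos:g}",
        "h_end_pos": f"{hw.end_pos:g}",
        "h_genes": ",".join(hw.gene_ids),
        "count_h_wrt_g": str(pair.count_h),
        "count_g_wrt_h": str(pair.count_g),
        "g_length": f"{gw.length:g}",
        "h_length": f"{hw.length:g}",
    }


def clusters_to_text(
    clusters: Sequence,
    *,
    format: str = "tsv",
    parameters: Mapping[str, object] | None = None,
) -> str:
    """Render cluster pairs as TSV (default) or a JSON mirror.

    A ``#`` header records the tool version and the full parameter set so the
    output documents how it was produced.
    """
    import io

    from . import __version__

    params = dict(parameters or {})
    rows = [_cluster_row(i + 1, p) for i, p in enumerate(clusters)]
    if format == "json":
        payload = {
            "tool": f"bbhwin {__version__}",
            "parameters": params,
            "clusters": rows,
        }
        return json.dumps(payload, indent=2) + "\n"
    if format != "tsv":
        raise ValueError(f"unknown cluster output format {format!r}")
    buf = io.StringIO()
    buf.write(f"# bbhwin {__version__}\n")
    if params:
        rendered = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
        buf.write(f"# parameters: {rendered}\n")
    writer = csv.DictWriter(buf, fieldnames=_CLUSTER_COLUMNS, delimiter="\t", lineterminator="\n")
    writer.writeheader()
    writer.writerows(rows)
    return buf.getvalue()


def write_clusters(
    clusters: Sequence,
    path: str | Path,
    *,
    format: str = "tsv",
    parameters: Mapping[str, object] | None = None,
) -> None:
    """Write cluster pairs to a file; see :func:`clusters_to_text`."""
    Path(path).write_text(
        clusters_to_text(clusters, format=format, parameters=parameters),
        encoding="utf-8",
    )


def read_clusters(path: str | Path) -> list[ClusterRecord]:
    """Read a cluster TSV back into :class:`ClusterRecord` objects.

    Extra columns beyond the canonical schema are preserved in ``extras``.
    """
    path = Path(path)
    rows = _data_rows(path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise GeneOrderFormatError(f"{path}:1: empty file, expected header") from None
    missing = [c for c in _CLUSTER_COLUMNS if c not in header]
    if missing:
        raise GeneOrderFormatError(
            f"{path}:{header_lineno}: missing cluster columns: {', '.join(missing)}"
        )
    out = []
    for lineno, fields in rows:
        if len(fields) != len(header):
            raise GeneOrderFormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
            )
        row = dict(zip(header, fields))
        extras = {k: v for k, v in row.items() if k not in _CLUSTER_COLUMNS}
        out.append(
            ClusterRecord(
                cluster_id=row["cluster_id"],
                g_start_pos=_parse_position(row["g_start_pos"], str(path), lineno),
                g_end_pos=_parse_position(row["g_end_pos"], str(path), lineno),
                g_gene_ids=tuple(x for x in row["g_genes"].split(",") if x),
                h_start_pos=_parse_position(row["h_start_pos"], str(path), lineno),
                h_end_pos=_parse_position(row["h_end_pos"], str(path), lineno),
                h_gene_ids=tuple(x for x in row["h_genes"].split(",") if x),
                count_h=int(row["count_h_wrt_g"]),
                count_g=int(row["count_g_wrt_h"]),
                g_length=_parse_position(row["g_length"], str(path), lineno),
                h_length=_parse_position(row["h_length"], str(path), lineno),
                extras=extras,
            )
        )
    return out
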