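"""Circular gene-order comparison: breakpoint distances and synteny blocks.

A circular gene order over n unique labels defines n directed adjacencies
(g, next(g)). Because all genes in these mitogenomes lie on a single strand,
adjacencies are *directed ordered pairs*: a full reversal of the order breaks
every adjacency. The breakpoint distance BD between two orders over the same
label set is the number of adjacencies of one order absent from the other
(symmetric by a counting argument), and the normalized distance BDn = BD / n
(n = 13 for the shared ctenophore gene set); BDn near 1 indicates
rearrangement close to random.

A synteny block is a maximal run of >= 2 genes appearing consecutively and in
the same relative order in both circular orders; the blocks partition exactly
the conserved adjacencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .io import AnnotationSet

__all__ = [
    "GeneOrder",
    "BreakpointResult",
    "SyntenyBlock",
    "gene_order_from_annotation",
    "restrict_to_shared",
    "breakpoint_distance",
    "synteny_blocks",
    "distance_matrix",
    "render_distance_table",
    "round_display",
]


def round_display(x: float, ndigits: int = 2) -> float:
    """Round-half-up display rounding (9/13 -> 0.69, 12/13 -> 0.92)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GeneOrder:
    """A circular sequence of oriented gene labels (all '+': single-strand coding)."""

    genome_id: str
    order: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "order", tuple(self.order))
        if len(self.order) < 2:
            raise ValueError(f"{self.genome_id}: a gene order needs >= 2 labels")
        if len(set(self.order)) != len(self.order):
            raise ValueError(f"{self.genome_id}: duplicate labels in gene order")

    @property
    def n_genes(self) -> int:
        return len(self.order)

    def canonical(self) -> tuple[str, ...]:
        """Rotation starting at the lexicographically smallest label."""
        i = self.order.index(min(self.order))
        return self.order[i:] + self.order[:i]

    def rotated(self, k: int) -> "GeneOrder":
        k %= len(self.order)
        return GeneOrder(self.genome_id, self.order[k:] + self.order[:k])

    def adjacencies(self) -> set[tuple[str, str]]:
        n = len(self.order)
        return {(self.order[i], self.order[(i + 1) % n]) for i in range(n)}

    def __eq__(self, other: object) -> bool:  # rotations compare equal
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())


@dataclass(frozen=True)
class BreakpointResult:
    bd: int
    n_shared: int

    @property
    def bdn(self) -> float:
        return self.bd / self.n_shared

    @property
    def bdn_display(self) -> float:
        return round_display(self.bdn, 2)


@dataclass(frozen=True)
class SyntenyBlock:
    """genes appear consecutively, co-ordered, in both circular inputs."""

    genes: tuple[str, ...]
    circular: bool = False  # True only when the whole circle is one conserved block

    @property
    def length(self) -> int:
        return len(self.genes)

    @property
    def n_adjacencies(self) -> int:
        return self.length if self.circular else self.length - 1


def gene_order_from_annotation(ann: AnnotationSet, include_urfs: bool = False) -> GeneOrder:
    """Circular gene order by start coordinate; URFs excluded unless requested."""
    labels = [
        f.label
        for f in ann
        if include_urfs or f.kind != "URF"
    ]
    if len(labels) != len(set(labels)):
        dup = next(l for l in labels if labels.count(l) > 1)
        raise ValueError(f"{ann.genome_id}: duplicate label {dup!r} in annotation")
    if len(labels) < 2:
        raise ValueError(f"{ann.genome_id}: fewer than 2 features")
    return GeneOrder(ann.genome_id, tuple(labels))


def restrict_to_shared(a: GeneOrder, b: GeneOrder) -> tuple[GeneOrder, GeneOrder]:
    shared = set(a.order) & set(b.order)
    if len(shared) < 2:
        raise ValueError(
            f"{a.genome_id} vs {b.genome_id}: fewer than 2 shared labels"
        )
    return (
        GeneOrder(a.genome_id, tuple(g for g in a.order if g in shared)),
        GeneOrder(b.genome_id, tuple(g for g in b.order if g in shared)),
    )


def _require_same_labels(a: GeneOrder, b: GeneOrder) -> None:
    if set(a.order) != set(b.order):
        raise ValueError(
            f"{a.genome_id} vs {b.genome_id}: label sets differ; "
            "apply restrict_to_shared first"
        )


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> BreakpointResult:
    """Number of directed adjacencies of ``a`` absent from ``b`` (symmetric)."""
    _require_same_labels(a, b)
    bd = len(a.adjacencies() - b.adjacencies())
    return BreakpointResult(bd=bd, n_shared=a.n_genes)


def synteny_blocks(a: GeneOrder, b: GeneOrder) -> list[SyntenyBlock]:
    """Maximal conserved runs of >= 2 genes, reported in ``a``'s order.

    The reporting scan starts at the lexicographically smallest label of ``a``
    so output is deterministic; blocks themselves are circular objects and may
    cross that anchor.
    """
    _require_same_labels(a, b)
    conserved = a.adjacencies() & b.adjacencies()
    order = a.canonical()
    n = len(order)
    kept = [((order[i], order[(i + 1) % n]) in conserved) for i in range(n)]
    if all(kept):
        return [SyntenyBlock(order, circular=True)]
    if not any(kept):
        return []
    # break the circle at a non-conserved adjacency, then scan linear runs
    start = next(i for i in range(n) if not kept[i])
    blocks: list[SyntenyBlock] = []
    run: list[str] = []
    for off in range(1, n + 1):
        i = (start + off) % n
        prev = (start + off - 1) % n
        # adjacency prev->i conserved means gene order[prev]..order[i] chained
        if kept[prev] if off > 1 else False:
            run.append(order[i])
        else:
            if len(run) >= 2:
                blocks.append(SyntenyBlock(tuple(run)))
            run = [order[i]]
    if len(run) >= 2:
        blocks.append(SyntenyBlock(tuple(run)))
    return blocks


def distance_matrix(orders: Sequence[GeneOrder]) -> pd.DataFrame:
    """Symmetric matrix of :class:`BreakpointResult` (None on the diagonal).

    Pairs are restricted to their shared label set before comparison.
    """
    if len(orders) < 2:
        raise ValueError("need >= 2 gene orders")
    ids = [o.genome_id for o in orders]
    mat = pd.DataFrame(index=ids, columns=ids, dtype=object)
    for i, oa in enumerate(orders):
        for j, ob in enumerate(orders):
            if i == j:
                mat.iloc[i, j] = None
            elif i < j:
                ra, rb = restrict_to_shared(oa, ob)
                res = breakpoint_distance(ra, rb)
                mat.iloc[i, j] = res
                mat.iloc[j, i] = res
    return mat


def render_distance_table(mat: pd.DataFrame) -> str:
    """Text rendering with BD above and BDn (2 decimals) below the diagonal."""
    ids = list(mat.index)
    rows = []
    header = [""] + ids
    rows.append(header)
    for i, ri in enumerate(ids):
        row = [ri]
        for j in range(len(ids)):
            if i == j:
                row.append("-")
            elif j > i:
                row.append(str(mat.iloc[i, j].bd))
            else:
                row.append(f"{mat.iloc[i, j].bdn_display:.2f}")
        rows.append(row)
    widths = [max(len(r[c]) for r in rows) for c in range(len(header))]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip() for r in rows
    )
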