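"""Iterative read-mapping contig extension and circularization.

A contig end is extended by reads whose prefix exactly matches the contig
suffix (or whose suffix matches the contig prefix) over at least ``min_overlap``
bases; the extension appended each round is the column-wise majority consensus
of the overhanging bases. With 100 bp reads and a 25 bp minimum overlap a
productive round extends an end by at least 75 bp whenever a fully overhanging
read exists. Circularity is recognised when a contig suffix exactly equals its
prefix over at least ``min_end_overlap`` bases; trimming the duplicated copy
yields the circular genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import MitoGenome, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "Contig",
    "CoverageSummary",
    "extend_contig",
    "detect_circularity",
    "coverage_stats",
    "find_seed",
    "elongate_and_circularize",
]


@dataclass(frozen=True)
class Contig:
    sequence: str
    rounds_applied: int = 0
    left_extended_bp: int = 0
    right_extended_bp: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)


def _consensus(columns: list[list[str]]) -> str:
    """Majority consensus per column; stops at the first column where no base
    reaches 50% of the reads covering it."""
    out = []
    for col in columns:
        if not col:
            break
        counts: dict[str, int] = {}
        for b in col:
            counts[b] = counts.get(b, 0) + 1
        base, n = max(counts.items(), key=lambda kv: kv[1])
        if 2 * n < len(col):
            logger.info("consensus conflict at extension column %d", len(out))
            break
        out.append(base)
    return "".join(out)


def _overhangs_right(seq: str, reads: Sequence[str], min_overlap: int) -> list[str]:
    probe = seq[-min_overlap:]
    out = []
    for read in reads:
        for r in (read, reverse_complement(read)):
            i = r.find(probe)
            while i != -1:
                k = i + min_overlap
                if k < len(r) and k <= len(seq) and r[:k] == seq[-k:]:
                    out.append(r[k:])
                i = r.find(probe, i + 1)
    return out


def extend_contig(
    contig: Contig,
    reads: Sequence[str],
    min_overlap: int = 25,
    max_rounds: int = 100,
) -> Contig:
    """Extend both contig ends round by round until no read extends either end
    or ``max_rounds`` is reached. Matching is exact; reads are used in both
    orientations."""
    if min_overlap < 15:
        raise ValueError("min_overlap must be >= 15")
    usable = [r for r in reads if len(r) >= min_overlap + 1]
    seq = contig.sequence
    left = contig.left_extended_bp
    right = contig.right_extended_bp
    rounds = contig.rounds_applied
    for _ in range(max_rounds):
        grew = False
        # right end
        over = _overhangs_right(seq, usable, min_overlap)
        if over:
            width = max(len(o) for o in over)
            cols = [[o[i] for o in over if i < len(o)] for i in range(width)]
            ext = _consensus(cols)
            if ext:
                seq = seq + ext
                right += len(ext)
                grew = True
        # left end: mirror through reversal
        rseq = seq[::-1]
        over = _overhangs_right(rseq, [r[::-1] for r in usable], min_overlap)
        if over:
            width = max(len(o) for o in over)
            cols = [[o[i] for o in over if i < len(o)] for i in range(width)]
            ext = _consensus(cols)
            if ext:
                seq = ext[::-1] + seq
                left += len(ext)
                grew = True
        rounds += 1
        if not grew:
            break
    return Contig(seq, rounds, left, right)


def _longest_border(s: str) -> int:
    """Longest proper prefix of ``s`` that is also a suffix (KMP failure link)."""
    pi = [0] * len(s)
    for i in range(1, len(s)):
        k = pi[i - 1]
        while k and s[i] != s[k]:
            k = pi[k - 1]
        if s[i] == s[k]:
            k += 1
        pi[i] = k
    return pi[-1] if s else 0


def detect_circularity(
    contig: Contig | str, min_end_overlap: int = 25, genome_id: str = "contig"
) -> tuple[bool, MitoGenome | None]:
    """If a suffix of length >= ``min_end_overlap`` exactly equals a prefix, the
    duplicated copy is trimmed and a circular genome returned. Among multiple
    qualifying end-overlaps the longest is taken (with a warning)."""
    seq = contig.sequence if isinstance(contig, Contig) else contig
    if len(seq) <= 2 * min_end_overlap:
        raise ValueError("contig shorter than twice the end overlap")
    borders = []
    k = _longest_border(seq)
    while k >= min_end_overlap:
        borders.append(k)
        k = _longest_border(seq[:k])
    if not borders:
        return False, None
    if len(borders) > 1:
        logger.warning(
            "%s: %d distinct end-overlaps >= %d; taking the longest (%d bp)",
            genome_id, len(borders), min_end_overlap, borders[0],
        )
    k = borders[0]
    return True, MitoGenome(genome_id, seq[: len(seq) - k], is_circular=True)


@dataclass(frozen=True)
class CoverageSummary:
    mean: float
    sd: float  # population SD
    min: int
    max: int
    depths: tuple[int, ...]
    unplaced_reads: int = 0

    @property
    def total_depth(self) -> int:
        return int(sum(self.depths))


def coverage_stats(
    genome: MitoGenome, reads: Sequence[str], min_overlap: int = 25
) -> CoverageSummary:
    """Per-base depth on the circle from exact full-length read placements.

    Each read is placed at every exact match of its full sequence (either
    orientation) on the doubled genome; reads with no placement are counted
    but not fatal.
    """
    L = genome.length
    D = genome.sequence + genome.sequence if genome.is_circular else genome.sequence
    depth = np.zeros(L, dtype=np.int64)
    unplaced = 0
    for read in reads:
        placed = False
        seen: set[int] = set()
        for r in {read, reverse_complement(read)}:
            i = D.find(r)
            while i != -1:
                if i < L and i not in seen:
                    seen.add(i)
                    placed = True
                    e = i + len(r)
                    if e <= L:
                        depth[i:e] += 1
                    else:
                        depth[i:L] += 1
                        depth[: e - L] += 1
                i = D.find(r, i + 1)
        if not placed:
            unplaced += 1
    return CoverageSummary(
        mean=float(depth.mean()),
        sd=float(depth.std()),
        min=int(depth.min()),
        max=int(depth.max()),
        depths=tuple(int(d) for d in depth),
        unplaced_reads=unplaced,
    )


def find_seed(reads: Sequence[str], bait: str, k: int = 21) -> Contig:
    """Pick the read sharing the most exact k-mers with a bait sequence
    (e.g. a published cox1) as the seed contig."""
    bait = bait.upper()
    kmers = {bait[i : i + k] for i in range(len(bait) - k + 1)}
    if not kmers:
        raise ValueError(f"bait shorter than k={k}")
    best_read, best_n = None, 0
    for read in reads:
        for r in (read, reverse_complement(read)):
            n = sum(1 for i in range(len(r) - k + 1) if r[i : i + k] in kmers)
            if n > best_n:
                best_read, best_n = r, n
    if best_read is None:
        raise ValueError("no read shares a k-mer with the bait")
    return Contig(best_read)


def elongate_and_circularize(
    seed: Contig | str,
    reads: Sequence[str],
    min_overlap: int = 25,
    min_end_overlap: int = 25,
    max_rounds: int = 200,
    genome_id: str = "assembly",
) -> tuple[MitoGenome | None, Contig]:
    """Extend a seed contig until its ends meet around the circle.

    Returns (circular genome or None, final contig).
    """
    contig = Contig(seed) if isinstance(seed, str) else seed
    for _ in range(max_rounds):
        if contig.length > 2 * min_end_overlap:
            ok, genome = detect_circularity(contig, min_end_overlap, genome_id)
            if ok:
                return genome, contig
        grown = extend_contig(contig, reads, min_overlap, max_rounds=1)
        if grown.length == contig.length:
            contig = grown
            break
        contig = grown
    if contig.length > 2 * min_end_overlap:
        ok, genome = detect_circularity(contig, min_end_overlap, genome_id)
        if ok:
            return genome, contig
    return None, contig
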