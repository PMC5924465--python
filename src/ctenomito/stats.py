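"""Per-genome statistics: base composition, codon usage, non-coding accounting,
the genome-size ~ NC-length correlation, and perfect-repeat finding.

Non-coding (NC) length is the circular complement of the union of annotated
features, computed twice: once with URFs treated as coding (NC *without* URFs)
and once with URFs treated as non-coding (NC *with* URFs). A gap spanning the
origin counts once.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .codes import CodeTable
from .io import AnnotationSet, GeneFeature, MitoGenome, extract_feature_sequence
from .rearrange import round_display

__all__ = [
    "CompositionProfile",
    "CodonUsageTable",
    "NCProfile",
    "RepeatHit",
    "composition",
    "codon_usage",
    "summarize_noncoding",
    "nc_percent",
    "format_percent",
    "size_nc_correlation",
    "find_perfect_repeats",
    "dinucleotide_entropy",
]


# ---------------------------------------------------------------------------
# Base composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionProfile:
    counts: dict[str, int]
    length: int

    @property
    def percent(self) -> dict[str, float]:
        return {b: 100.0 * c / self.length for b, c in self.counts.items()}

    @property
    def at_percent(self) -> float:
        return 100.0 * (self.counts.get("A", 0) + self.counts.get("T", 0)) / self.length


def composition(genome: MitoGenome) -> CompositionProfile:
    counts = Counter(genome.sequence)
    return CompositionProfile(counts=dict(counts), length=genome.length)


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageTable:
    """Codon tallies over the protein-coding features of one genome.

    Start codons and stop codons (complete TAA/TAG plus incomplete T/TA) are
    tallied separately from internal codons; percentages are over internal
    codons only.
    """

    genome_id: str
    codon_counts: Counter = field(default_factory=Counter)
    start_counts: Counter = field(default_factory=Counter)
    stop_counts: Counter = field(default_factory=Counter)
    aa_counts: Counter = field(default_factory=Counter)

    @property
    def total_internal(self) -> int:
        return sum(self.codon_counts.values())

    @property
    def total_codons(self) -> int:
        """All complete codons tallied (start + internal + complete stops)."""
        complete_stops = sum(v for k, v in self.stop_counts.items() if len(k) == 3)
        return sum(self.start_counts.values()) + self.total_internal + complete_stops

    def percent(self, codon: str) -> float:
        if self.total_internal == 0:
            return 0.0
        return 100.0 * self.codon_counts[codon] / self.total_internal

    def percentages(self) -> dict[str, float]:
        return {c: self.percent(c) for c in sorted(self.codon_counts)}


def codon_usage(
    ann: AnnotationSet,
    genome: MitoGenome,
    code: CodeTable,
    include_urfs: bool = False,
) -> CodonUsageTable:
    import warnings

    table = CodonUsageTable(genome_id=genome.id)
    for f in ann:
        if f.kind == "rRNA" or (f.kind == "URF" and not include_urfs):
            continue
        seq = extract_feature_sequence(genome, f)
        if len(seq) < 6:
            raise ValueError(f"{f.label}: protein feature shorter than 6 bp")
        trailing = len(seq) % 3
        if trailing and not f.has_incomplete_stop:
            warnings.warn(
                f"{genome.id}/{f.label}: length not a multiple of 3; trailing "
                f"{trailing} base(s) dropped"
            )
        codons = [seq[i : i + 3] for i in range(0, len(seq) - trailing, 3)]
        table.start_counts[codons[0]] += 1
        body = codons[1:]
        if f.has_incomplete_stop:
            table.stop_counts[seq[len(seq) - trailing :] if trailing else codons[-1]] += 1
            if not trailing:
                body = codons[1:-1]
        elif body and code.is_stop(body[-1]):
            table.stop_counts[body[-1]] += 1
            body = body[:-1]
        for c in body:
            table.codon_counts[c] += 1
            table.aa_counts[code.codon_map[c]] += 1
    return table


# ---------------------------------------------------------------------------
# Non-coding accounting (the Table-2 row)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NCProfile:
    genome_id: str
    genome_length: int
    nc_with_urfs: int  # URFs counted as non-coding
    nc_without_urfs: int  # URFs counted as coding
    n_nc_gt20_with: int
    n_nc_gt20_without: int
    longest_nc_with: tuple[int, tuple[str, str]]
    longest_nc_without: tuple[int, tuple[str, str]]


def _feature_intervals(features: Iterable[GeneFeature], L: int) -> list[tuple[int, int]]:
    iv: list[tuple[int, int]] = []
    for f in features:
        if f.end > L:  # origin-spanning: split
            iv.append((f.start, L))
            iv.append((0, f.end - L))
        else:
            iv.append((f.start, f.end))
    return sorted(iv)


def _nc_tracts(
    features: list[GeneFeature], L: int
) -> list[tuple[int, int, tuple[str, str]]]:
    """Circular complement of the feature union: (start, length, flank labels)."""
    if not features:
        return [(0, L, ("", ""))]
    iv = _feature_intervals(features, L)
    merged: list[list[int]] = []
    for s, e in iv:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    # wrap-merge: gap between last end and first start (mod L)
    tracts: list[tuple[int, int]] = []
    for i, (s, e) in enumerate(merged):
        nxt_s = merged[(i + 1) % len(merged)][0]
        gap_start = e % L
        gap_len = (nxt_s - e) % L if len(merged) > 1 else (L - (e - s))
        if len(merged) == 1:
            gap_start = e % L
        if gap_len > 0:
            tracts.append((gap_start, gap_len))
    if sum(e - s for s, e in merged) >= L:
        return []

    def flank_labels(gs: int, gl: int) -> tuple[str, str]:
        ge = (gs + gl) % L
        left = right = ""
        for f in features:
            if f.end % L == gs or (f.end == L and gs == 0) or f.end == gs:
                left = f.label
            if f.start == ge:
                right = f.label
        return (left, right)

    return [(gs, gl, flank_labels(gs, gl)) for gs, gl in tracts]


def summarize_noncoding(ann: AnnotationSet, genome: MitoGenome) -> NCProfile:
    L = genome.length

    def account(features: list[GeneFeature]):
        tracts = _nc_tracts(features, L)
        total = sum(t[1] for t in tracts)
        n_gt20 = sum(1 for t in tracts if t[1] > 20)
        if tracts:
            longest = max(tracts, key=lambda t: t[1])
            longest_out = (longest[1], longest[2])
        else:
            longest_out = (0, ("", ""))
        return total, n_gt20, longest_out

    all_features = list(ann)
    non_urf = [f for f in all_features if f.kind != "URF"]
    nc_without, n_without, longest_without = account(all_features)
    nc_with, n_with, longest_with = account(non_urf)
    return NCProfile(
        genome_id=genome.id,
        genome_length=L,
        nc_with_urfs=nc_with,
        nc_without_urfs=nc_without,
        n_nc_gt20_with=n_with,
        n_nc_gt20_without=n_without,
        longest_nc_with=longest_with,
        longest_nc_without=longest_without,
    )


def nc_percent(nc_len: int, genome_len: int) -> float:
    """Non-coding proportion as a percentage, display-rounded to one decimal."""
    if genome_len <= 0:
        raise ValueError("genome length must be positive")
    if not 0 <= nc_len <= genome_len:
        raise ValueError("NC length outside [0, genome length]")
    return round_display(100.0 * nc_len / genome_len, 1)


def format_percent(p: float) -> str:
    """'8.0' -> '8', '7.9' -> '7.9' (the convention used in prose)."""
    s = f"{p:.1f}"
    return s[:-2] if s.endswith(".0") else s


def size_nc_correlation(rows: Sequence[tuple[float, float]]) -> float:
    """Sample Pearson correlation between genome length and NC length."""
    if len(rows) < 3:
        raise ValueError("need >= 3 genomes for a correlation")
    x = np.asarray([r[0] for r in rows], dtype=float)
    y = np.asarray([r[1] for r in rows], dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined for a constant column")
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Perfect repeats
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatHit:
    """A maximal exact repeat: identical unit occurring at >= 2 positions."""

    unit: str
    positions: tuple[int, ...]
    low_complexity: bool

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def separations(self) -> tuple[int, ...]:
        return tuple(
            self.positions[i + 1] - self.positions[i]
            for i in range(len(self.positions) - 1)
        )


def dinucleotide_entropy(unit: str) -> float:
    """Shannon entropy (bits) of the overlapping-dinucleotide composition."""
    if len(unit) < 2:
        return 0.0
    counts = Counter(unit[i : i + 2] for i in range(len(unit) - 1))
    n = sum(counts.values())
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


LOW_COMPLEXITY_ENTROPY = 1.5  # bits; poly-T tracts score far below this


def find_perfect_repeats(
    genome: MitoGenome,
    min_unit: int = 21,
    filter_low_complexity: bool = False,
) -> list[RepeatHit]:
    """All maximal exact repeats of length >= ``min_unit`` on the (circular) sequence.

    Maximality: extending the matched pair one base left or right breaks it.
    On circular genomes the scan runs on the doubled string and hits are
    de-duplicated modulo the genome length. Hits whose unit dinucleotide
    entropy falls below :data:`LOW_COMPLEXITY_ENTROPY` are flagged, and
    suppressed when ``filter_low_complexity`` is set.
    """
    seq = genome.sequence
    L = len(seq)
    if min_unit < 2:
        raise ValueError("min_unit must be >= 2")
    if min_unit > L:
        return []
    circular = genome.is_circular
    # seeds sit in the middle copy of a tripled string so extension can cross
    # the origin in both directions without index gymnastics
    S = seq * 3 if circular else seq
    base = L if circular else 0
    k = min_unit
    kmers: dict[str, list[int]] = {}
    limit = L if circular else L - k + 1
    for p in range(limit):
        kmers.setdefault(S[base + p : base + p + k], []).append(base + p)

    # memo of maximal matches already found, per offset d = (q - p) mod L
    covered: dict[int, list[tuple[int, int]]] = {}

    def already(d: int, p: int) -> bool:
        return any(s <= p and p + k <= s + ln for s, ln in covered.get(d, ()))

    def extend(p: int, q: int) -> tuple[int, int, int]:
        # maximal common extension of S[p:], S[q:] around the seed of length k
        left = 0
        max_left = min(p, q, L - k) if not circular else min(p, q, L - k)
        while left < max_left and S[p - left - 1] == S[q - left - 1]:
            left += 1
        right = 0
        n = len(S)
        while (
            p + k + right < n
            and q + k + right < n
            and k + left + right < L
            and S[p + k + right] == S[q + k + right]
        ):
            right += 1
        return p - left, q - left, k + left + right

    matches: dict[tuple[int, int, int], None] = {}
    for positions in kmers.values():
        if len(positions) < 2:
            continue
        for i in range(len(positions)):
            for j in range(i + 1, len(positions)):
                p, q = positions[i], positions[j]
                d = (q - p) % L if circular else q - p
                if d == 0:
                    continue
                if already(d, p):
                    continue
                s1, s2, ln = extend(p, q)
                covered.setdefault(d, []).append((s1, ln))
                key = (s1 % L, s2 % L, ln) if circular else (s1, s2, ln)
                matches[key] = None

    # group maximal matches by unit string, union of occurrence positions
    by_unit: dict[str, set[int]] = {}
    for s1, s2, ln in matches:
        if circular:
            unit = (seq * 3)[(s1 % L) + L : (s1 % L) + L + ln]
            occ = (s1 % L, s2 % L)
        else:
            unit = S[s1 : s1 + ln]
            occ = (s1, s2)
        by_unit.setdefault(unit, set()).update(occ)

    hits = []
    for unit, pos in by_unit.items():
        if len(unit) < min_unit or len(unit) >= L:
            continue
        low = dinucleotide_entropy(unit) < LOW_COMPLEXITY_ENTROPY
        if filter_low_complexity and low:
            continue
        hits.append(RepeatHit(unit=unit, positions=tuple(sorted(pos)), low_complexity=low))
    hits.sort(key=lambda h: (-h.unit_length, h.positions))
    return hits
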