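"""Homology-guided annotation of tiny AT-rich circular mitochondrial genomes.

The pipeline scans all reading frames of the coding strand for maximal ORFs
(these genomes encode everything on one strand), labels ORFs by global
protein alignment against reference proteins, then refines each gene's start
and stop by two lexicographic criteria: (1) minimization of overlap with
neighbouring genes, (2) maximization of similarity to the reference.
Unassigned ORFs longer than 100 bp that contain at least one predicted
transmembrane segment are annotated as URFs. The module also provides a
conserved-column codon-usage test for genetic-code reassignment and a
read-backed homopolymer frameshift repair.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .codes import STOP, CodeTable
from .io import (
    AnnotationSet,
    GeneFeature,
    MitoGenome,
    TopologyError,
    reverse_complement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OrfCandidate",
    "HomologyHit",
    "ReassignmentReport",
    "TrnaCandidate",
    "translate",
    "find_orfs",
    "homology_scan",
    "pairwise_similarity",
    "select_boundaries",
    "enumerate_start_variants",
    "predict_tm",
    "annotate_urfs",
    "filter_trna_candidates",
    "detect_reassignment",
    "repair_frameshift",
    "annotate_genome",
    "KYTE_DOOLITTLE",
]


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def translate(seq: str, code: CodeTable) -> str:
    """Translate a nucleotide string; stops render as '*', a trailing 1-2 base
    incomplete codon renders as 'X'."""
    seq = seq.upper()
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if any(b not in "ACGT" for b in codon):
            pos = i + next(j for j, b in enumerate(codon) if b not in "ACGT")
            raise ValueError(f"ambiguous base {seq[pos]!r} at position {pos}")
        out.append(code.codon_map[codon])
    if len(seq) % 3:
        out.append("X")
    return "".join(out)


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrfCandidate:
    """A maximal open reading frame. ``end`` includes the stop codon (or the
    1-2 incomplete stop bases); coordinates are unwrapped on circular genomes."""

    start: int
    end: int
    frame: int
    strand: str
    protein: str
    stop_kind: str  # TAA | TAG | incomplete_T | incomplete_TA

    def __post_init__(self) -> None:
        rem = (self.end - self.start) % 3
        expected = {"TAA": 0, "TAG": 0, "incomplete_T": 1, "incomplete_TA": 2}[self.stop_kind]
        if rem != expected:
            raise ValueError(
                f"ORF at {self.start}: length {self.end - self.start} inconsistent "
                f"with stop kind {self.stop_kind}"
            )
        if STOP in self.protein:
            raise ValueError(f"ORF at {self.start}: internal stop in protein")

    @property
    def length(self) -> int:
        return self.end - self.start


def _scan_strand(seq: str, L: int, circular: bool, code: CodeTable, min_len: int,
                 strand: str) -> list[OrfCandidate]:
    """Scan one strand. ``seq`` is the strand sequence (already revcomped for '-')."""
    S = seq * 3 if circular else seq
    lo = L if circular else 0  # maximal ORF starts reported from the middle copy
    found: dict[tuple[int, int], OrfCandidate] = {}
    for frame in range(3):
        stops = [
            p for p in range(frame, len(S) - 2, 3) if code.is_stop(S[p : p + 3])
        ]
        segments: list[tuple[int, int | None]] = []
        prev = frame
        for sp in stops:
            segments.append((prev, sp))
            prev = sp + 3
        segments.append((prev, None))  # tail without stop
        for seg_start, stop_pos in segments:
            if stop_pos is None:
                if circular:
                    continue  # a frame with no closing stop before string end
                # linear: ORF truncated at the sequence end
                limit = len(S) - (len(S) - seg_start) % 3
                start = _first_start(S, seg_start, limit, code)
                if start is None:
                    continue
                trailing = len(S) - limit
                tail = S[limit:]
                if trailing == 1 and tail == "T":
                    kind, end = "incomplete_T", len(S)
                elif trailing == 2 and tail == "TA":
                    kind, end = "incomplete_TA", len(S)
                else:
                    warnings.warn(
                        f"ORF at {start} truncated at linear sequence end; dropped"
                    )
                    continue
                if end - start < min_len:
                    continue
                prot = translate(S[start:limit], code)
                found.setdefault((start, end), OrfCandidate(
                    start, end, frame, strand, prot, kind))
                continue
            start = _first_start(S, seg_start, stop_pos, code)
            if start is None:
                continue
            end = stop_pos + 3
            if end - start < min_len or end - start > L:
                continue
            if not (lo <= start < lo + L):
                continue
            s0, e0 = start - lo, end - lo
            prot = translate(S[start:stop_pos], code)
            stop = S[stop_pos : stop_pos + 3]
            found.setdefault((s0, e0), OrfCandidate(s0, e0, frame, strand, prot, stop))
    return sorted(found.values(), key=lambda o: (o.start, o.end))


def _first_start(S: str, lo: int, hi: int, code: CodeTable) -> int | None:
    for p in range(lo, hi, 3):
        if code.is_start(S[p : p + 3]):
            return p
    return None


def find_orfs(
    genome: MitoGenome,
    code: CodeTable,
    min_len: int = 100,
    scan_minus: bool = False,
) -> list[OrfCandidate]:
    """All maximal ORFs on the coding (+) strand, in all three frames, wrapping
    the origin on circular genomes.

    An ORF begins at the first allowed start codon after the previous in-frame
    stop and ends at (and includes) a stop codon. The minus strand is scanned
    only when ``scan_minus`` is set, since these genomes are single-strand
    coders.
    """
    if min_len < 3:
        raise ValueError("min_len must be >= 3")
    if "N" in genome.sequence:
        raise ValueError(f"genome {genome.id!r} contains N bases; resolve before scanning")
    L = genome.length
    orfs = _scan_strand(genome.sequence, L, genome.is_circular, code, min_len, "+")
    if scan_minus:
        orfs += _scan_strand(
            reverse_complement(genome.sequence), L, genome.is_circular, code, min_len, "-"
        )
    return orfs


# ---------------------------------------------------------------------------
# Homology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomologyHit:
    query_label: str
    score: float  # normalized to [0, 1] by reference self-score
    query_span: tuple[int, int]
    target_span: tuple[int, int]


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _protein_aligner()


def _self_score(protein: str) -> float:
    m = _ALIGNER.substitution_matrix
    return float(sum(m[a, a] for a in protein))


def pairwise_similarity(query: str, reference: str) -> float:
    """Global alignment score normalized by the reference self-score."""
    if not query or not reference:
        return 0.0
    q = query.replace(STOP, "X")
    return float(_ALIGNER.score(reference, q)) / _self_score(reference)


def homology_scan(
    orfs: Sequence[OrfCandidate],
    references: Mapping[str, str],
    floor: float = 0.3,
) -> list[HomologyHit | None]:
    """Best reference label per ORF; hits scoring below ``floor`` are dropped.

    Ties are broken by longer aligned span, then lexicographic label.
    """
    if not references:
        raise ValueError("reference set is empty")
    out: list[HomologyHit | None] = []
    for orf in orfs:
        best: HomologyHit | None = None
        for label in sorted(references):
            ref = references[label]
            score = pairwise_similarity(orf.protein, ref)
            if score < floor:
                continue
            span = min(len(orf.protein), len(ref))
            hit = HomologyHit(label, score, (0, len(orf.protein)), (0, span))
            if (
                best is None
                or score > best.score
                or (
                    score == best.score
                    and (hit.target_span[1] - hit.target_span[0])
                    > (best.target_span[1] - best.target_span[0])
                )
            ):
                best = hit
        out.append(best)
    return out


# ---------------------------------------------------------------------------
# Boundary selection
# ---------------------------------------------------------------------------

def _circ_overlap(a: tuple[int, int], b: tuple[int, int], L: int) -> int:
    """Overlap in bp of two possibly origin-spanning intervals on a circle."""

    def split(iv: tuple[int, int]) -> list[tuple[int, int]]:
        s, e = iv
        s %= L
        e = s + (iv[1] - iv[0])
        if e <= L:
            return [(s, e)]
        return [(s, L), (0, e - L)]

    total = 0
    for s1, e1 in split(a):
        for s2, e2 in split(b):
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def select_boundaries(
    candidate_starts: Sequence[int],
    candidate_stops: Sequence[tuple[int, str]],
    neighbors: Sequence[GeneFeature],
    genome: MitoGenome,
    code: CodeTable,
    reference: str,
) -> tuple[int, int, str]:
    """Choose a gene's (start, end, stop_kind) lexicographically by
    (1) minimal total overlap with neighbouring features, (2) maximal
    similarity of the implied protein to the reference, (3) longest ORF.

    ``candidate_stops`` are (end, stop_kind) pairs; incomplete stops should
    only be offered when no in-frame complete stop precedes the next feature.
    """
    if not candidate_starts:
        raise ValueError("no candidate start")
    L = genome.length
    D = genome.sequence * 2 if genome.is_circular else genome.sequence
    scored = []
    for s in candidate_starts:
        for e, kind in candidate_stops:
            if e <= s or (e - s) % 3 != {"TAA": 0, "TAG": 0,
                                         "incomplete_T": 1, "incomplete_TA": 2}[kind]:
                continue
            prot = translate(D[s : s + ((e - s) // 3) * 3], code)
            if kind in {"TAA", "TAG"}:
                prot = prot[:-1]  # drop the stop residue
            if STOP in prot:
                continue
            overlap = sum(_circ_overlap((s, e), (n.start, n.end), L) for n in neighbors)
            sim = pairwise_similarity(prot, reference)
            scored.append(((overlap, -sim, -(e - s)), (s, e, kind)))
    if not scored:
        raise ValueError("no valid start/stop combination")
    scored.sort(key=lambda t: t[0])
    return scored[0][1]


def enumerate_start_variants(
    orf: OrfCandidate, genome: MitoGenome, code: CodeTable, max_variants: int = 48
) -> list[int]:
    """In-frame allowed start codons inside a maximal ORF, 5' to 3'."""
    D = genome.sequence * 2 if genome.is_circular else genome.sequence
    stops = {"TAA": 3, "TAG": 3, "incomplete_T": 1, "incomplete_TA": 2}[orf.stop_kind]
    starts = [
        p
        for p in range(orf.start, orf.end - stops, 3)
        if code.is_start(D[p : p + 3])
    ]
    return starts[:max_variants]


# ---------------------------------------------------------------------------
# Transmembrane segments (Kyte-Doolittle sliding window)
# ---------------------------------------------------------------------------

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

TM_WINDOW = 19
TM_CUTOFF = 1.6


def predict_tm(protein: str, window: int = TM_WINDOW, cutoff: float = TM_CUTOFF) -> int:
    """Count non-overlapping windows of mean Kyte-Doolittle hydropathy > cutoff,
    scanning left to right greedily. Unknown residues score 0 with a warning."""
    if not protein:
        raise ValueError("empty protein")
    vals = []
    for a in protein:
        if a not in KYTE_DOOLITTLE:
            warnings.warn(f"unknown residue {a!r}: hydropathy treated as 0")
            vals.append(0.0)
        else:
            vals.append(KYTE_DOOLITTLE[a])
    count = 0
    i = 0
    while i + window <= len(vals):
        if sum(vals[i : i + window]) / window > cutoff:
            count += 1
            i += window
        else:
            i += 1
    return count


def annotate_urfs(
    orfs: Sequence[OrfCandidate], min_len: int = 100
) -> list[GeneFeature]:
    """URFs: unassigned ORFs longer than ``min_len`` bp with >= 1 predicted
    transmembrane segment, labelled urf1..urfN in genomic order."""
    kept = [
        o
        for o in sorted(orfs, key=lambda o: o.start)
        if o.length > min_len and predict_tm(o.protein) >= 1
    ]
    return [
        GeneFeature(
            f"urf{i + 1}",
            o.start,
            o.end,
            o.strand,
            "URF",
            has_incomplete_stop=o.stop_kind.startswith("incomplete"),
        )
        for i, o in enumerate(kept)
    ]


# ---------------------------------------------------------------------------
# tRNA false-positive filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrnaCandidate:
    start: int
    end: int
    canonical_structure: bool
    name: str = "trna"


def filter_trna_candidates(
    candidates: Sequence[TrnaCandidate],
    ann: AnnotationSet,
    genome_length: int | None = None,
) -> tuple[list[tuple[TrnaCandidate, bool]], list[TrnaCandidate]]:
    """Partition tRNA-like hits: rejected iff they overlap an annotated
    protein/rRNA feature AND lack the canonical cloverleaf; everything else is
    kept with a review flag marking in-feature location."""
    L = genome_length or max((f.end for f in ann), default=0)
    kept: list[tuple[TrnaCandidate, bool]] = []
    rejected: list[TrnaCandidate] = []
    coding = [f for f in ann if f.kind in {"protein", "rRNA"}]
    for c in candidates:
        overlaps = any(
            _circ_overlap((c.start, c.end), (f.start, f.end), max(L, c.end, f.end)) > 0
            for f in coding
        )
        if overlaps and not c.canonical_structure:
            rejected.append(c)
        else:
            kept.append((c, overlaps))
    return kept, rejected


# ---------------------------------------------------------------------------
# Genetic-code reassignment detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonEvidence:
    codon: str
    expected: str
    inferred: str | None
    n_columns: int
    profile: dict[str, float]
    flagged: bool


@dataclass
class ReassignmentReport:
    target_species: str
    evidence: dict[str, CodonEvidence]

    @property
    def flagged_codons(self) -> list[str]:
        return [c for c, e in self.evidence.items() if e.flagged]


def detect_reassignment(
    coding_alignments: Mapping[str, Mapping[str, str]],
    target_species: str,
    expected: CodeTable,
    conservation_threshold: float = 0.7,
    min_columns: int = 5,
    modal_threshold: float = 0.5,
) -> ReassignmentReport:
    """Infer codon meanings for the target species from conserved alignment columns.

    For each codon-aware alignment column where at least ``conservation_threshold``
    of the non-target species agree on one amino acid, the target's codon at
    that column is credited with the consensus amino acid. A codon is flagged
    as reassigned when its modal consensus differs from the expected table's
    meaning, rests on >= ``min_columns`` columns, and reaches modal frequency
    >= ``modal_threshold``.
    """
    tallies: dict[str, Counter] = {}
    n_others = 0
    for gene, rows in coding_alignments.items():
        lengths = {len(r) for r in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"{gene}: alignment rows of unequal length")
        (width,) = lengths
        if width % 3:
            raise ValueError(f"{gene}: alignment width {width} not a multiple of 3")
        if target_species not in rows:
            continue
        others = {sp: r for sp, r in rows.items() if sp != target_species}
        n_others = max(n_others, len(others))
        target_row = rows[target_species]
        for col in range(0, width, 3):
            aas = []
            for r in others.values():
                codon = r[col : col + 3]
                if "-" in codon:
                    continue
                aas.append(expected.codon_map[codon])
            if not aas:
                continue
            cnt = Counter(aas)
            aa, n = cnt.most_common(1)[0]
            if aa == STOP or n / len(aas) < conservation_threshold:
                continue
            tcodon = target_row[col : col + 3]
            if "-" in tcodon:
                continue
            tallies.setdefault(tcodon, Counter())[aa] += 1
    if n_others < 3:
        raise ValueError("need >= 3 non-target species in the alignments")
    evidence: dict[str, CodonEvidence] = {}
    for codon, cnt in sorted(tallies.items()):
        total = sum(cnt.values())
        profile = {aa: n / total for aa, n in sorted(cnt.items())}
        inferred, n_modal = cnt.most_common(1)[0]
        exp = expected.codon_map[codon]
        flagged = (
            inferred != exp
            and total >= min_columns
            and n_modal / total >= modal_threshold
        )
        evidence[codon] = CodonEvidence(codon, exp, inferred, total, profile, flagged)
    return ReassignmentReport(target_species=target_species, evidence=evidence)


# ---------------------------------------------------------------------------
# Homopolymer frameshift repair
# ---------------------------------------------------------------------------

def repair_frameshift(
    genome: MitoGenome,
    reads: Sequence[str],
    region: tuple[int, int],
    min_run: int = 3,
    flank: int = 8,
) -> tuple[MitoGenome, list[dict]]:
    """Re-estimate homopolymer run lengths in ``region`` from reads that span
    them; apply a single-base insertion/deletion where the majority of spanning
    reads disagrees with the reference. Ties and uncovered runs leave the
    genome unchanged and are logged.
    """
    s0, e0 = region
    if e0 - s0 > 500:
        raise ValueError("region larger than 500 bp")
    seq = genome.sequence
    log: list[dict] = []
    # homopolymer runs within the region
    runs: list[tuple[int, int, str]] = []
    i = s0
    while i < min(e0, len(seq)):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j, seq[i]))
        i = j
    edits: list[tuple[int, int, int, str]] = []
    for rs, re_, base in runs:
        left = seq[max(0, rs - flank) : rs]
        right = seq[re_ : re_ + flank]
        ref_len = re_ - rs
        observed = Counter()
        for read in reads:
            for r in (read, reverse_complement(read)):
                idx = r.find(left)
                while idx != -1:
                    p = idx + len(left)
                    q = p
                    while q < len(r) and r[q] == base:
                        q += 1
                    if r[q : q + len(right)] == right and len(right) == flank:
                        observed[q - p] += 1
                    idx = r.find(left, idx + 1)
        entry = {
            "position": rs,
            "base": base,
            "ref_run_length": ref_len,
            "support": dict(observed),
        }
        if not observed:
            entry["status"] = "uncorrectable"
            log.append(entry)
            continue
        top = observed.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            entry["status"] = "ambiguous"
            log.append(entry)
            continue
        new_len = top[0][0]
        if new_len == ref_len:
            entry["status"] = "confirmed"
            log.append(entry)
            continue
        entry["status"] = "edited"
        entry["new_run_length"] = new_len
        entry["supporting_reads"] = top[0][1]
        log.append(entry)
        edits.append((rs, ref_len, new_len, base))
    for rs, ref_len, new_len, base in sorted(edits, reverse=True):
        seq = seq[:rs] + base * new_len + seq[rs + ref_len :]
    new = MitoGenome(genome.id, seq, genome.is_circular) if edits else genome
    return new, log


# ---------------------------------------------------------------------------
# Whole-genome annotation
# ---------------------------------------------------------------------------

def _locate_rrna(genome: MitoGenome, ref: str) -> tuple[int, int] | None:
    """Locate an rRNA by exact match first, nucleotide local alignment as fallback."""
    D = genome.sequence * 2 if genome.is_circular else genome.sequence
    L = genome.length
    i = D.find(ref)
    if i != -1 and i < L:
        return i, i + len(ref)
    if i != -1:
        return i - L, i - L + len(ref)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    try:
        aln = aligner.align(D, ref)[0]
    except (IndexError, ValueError):
        return None
    if aln.score < 0.5 * len(ref):
        return None
    s, e = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
    if s >= L:
        s, e = s - L, e - L
    return s, e


def annotate_genome(
    genome: MitoGenome,
    protein_refs: Mapping[str, str],
    rrna_refs: Mapping[str, str] | None = None,
    code: CodeTable | None = None,
    min_orf_len: int = 100,
    min_urf_len: int = 100,
    homology_floor: float = 0.3,
) -> AnnotationSet:
    """Annotate a circular genome: label ORFs by homology, refine boundaries,
    place rRNAs, and annotate URFs."""
    from .codes import MOLD

    code = code or MOLD
    orfs = find_orfs(genome, code, min_len=min_orf_len)
    hits = homology_scan(orfs, protein_refs, floor=homology_floor)

    # best ORF per label
    best: dict[str, tuple[OrfCandidate, HomologyHit]] = {}
    for orf, hit in zip(orfs, hits):
        if hit is None:
            continue
        if hit.query_label not in best or hit.score > best[hit.query_label][1].score:
            best[hit.query_label] = (orf, hit)

    features: list[GeneFeature] = []
    rrna_feats: list[GeneFeature] = []
    if rrna_refs:
        for label, ref in rrna_refs.items():
            span = _locate_rrna(genome, ref)
            if span is None:
                logger.warning("%s: rRNA %s not located", genome.id, label)
                continue
            rrna_feats.append(GeneFeature(label, span[0], span[1], "+", "rRNA"))

    # pass 1: refine starts against the reference alone (maximal ORF spans are
    # inflated and would mislead the overlap criterion); pass 2 re-selects with
    # the refined spans of all other genes as neighbours.
    L = genome.length

    def normalized(s: int, e: int) -> tuple[int, int]:
        length = e - s
        s %= L
        return s, s + length

    provisional: dict[str, tuple[int, int]] = {}
    for label, (orf, hit) in best.items():
        starts = enumerate_start_variants(orf, genome, code)
        stops = [(orf.end, orf.stop_kind)]
        s, e, _ = select_boundaries(starts, stops, [], genome, code, protein_refs[label])
        provisional[label] = normalized(s, e)
    for label, (orf, hit) in sorted(best.items(), key=lambda kv: kv[1][0].start):
        neighbors = [
            GeneFeature(l, s, e, "+", "protein")
            for l, (s, e) in provisional.items()
            if l != label
        ] + rrna_feats
        starts = enumerate_start_variants(orf, genome, code)
        stops = [(orf.end, orf.stop_kind)]
        s, e, kind = select_boundaries(
            starts, stops, neighbors, genome, code, protein_refs[label]
        )
        s, e = normalized(s, e)
        provisional[label] = (s, e)
        features.append(
            GeneFeature(
                label, s, e, orf.strand, "protein",
                has_incomplete_stop=kind.startswith("incomplete"),
            )
        )

    assigned_spans = [(f.start, f.end) for f in features] + [
        (f.start, f.end) for f in rrna_feats
    ]
    L = genome.length
    unassigned = [
        o
        for o, h in zip(orfs, hits)
        if h is None
        and all(
            _circ_overlap((o.start, o.end), span, L) < 0.5 * o.length
            for span in assigned_spans
        )
    ]
    urfs = annotate_urfs(unassigned, min_len=min_urf_len)
    return AnnotationSet(genome.id, features + rrna_feats + urfs)
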