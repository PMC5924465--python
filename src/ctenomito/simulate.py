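"""Synthetic mitogenome generator with a truth ledger.

Emulates the statistical structure of ctenophore mitochondrial genomes:
~84% AT with T around 60% of all nucleotides, 13 single-strand genes
(11 proteins + 2 rRNAs) on a circle, URFs longer than 100 bp carrying a
hydrophobic stretch, short non-coding tracts with poly-T runs, optional
planted perfect repeats, rearranged gene orders with known move counts,
error-free reads at a target depth, and codon-aware alignments with an
optional planted codon reassignment. Every planted property is recorded in a
JSON-serialisable ledger so downstream outputs can be verified without
re-derivation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .codes import MOLD, CodeTable, get_code
from .io import AnnotationSet, GeneFeature, MitoGenome, reverse_complement
from .rearrange import GeneOrder
from .stats import dinucleotide_entropy, LOW_COMPLEXITY_ENTROPY

__all__ = [
    "GenomeSpec",
    "TruthLedger",
    "generate_genome",
    "rearrange_order",
    "simulate_reads",
    "simulate_code_alignment",
    "DEFAULT_GENE_MODELS",
    "SMALL_GENE_MODELS",
]

#: Realistic protein lengths (aa) for the 11 mt proteins plus rRNA lengths (nt),
#: sized so the default genome lands in the observed 10.0-11.6 kb range.
DEFAULT_GENE_MODELS: tuple[tuple[str, int], ...] = (
    ("cox1", 480), ("cox2", 220), ("nad4", 430),
    ("nad4L", 90), ("nad1", 290), ("nad2", 300),
    ("nad5", 470), ("nad6", 160), ("cob", 360),
    ("cox3", 245), ("nad3", 110),
    ("rnl", 840), ("rns", 410),  # rRNAs: value is nucleotides, not aa
)

#: Scaled-down models for simulation studies at desk scale.
SMALL_GENE_MODELS: tuple[tuple[str, int], ...] = (
    ("cox1", 70), ("cox2", 48), ("nad4", 66),
    ("nad4L", 40), ("nad1", 55), ("nad2", 58),
    ("nad5", 72), ("nad6", 44), ("cob", 62),
    ("cox3", 52), ("nad3", 42),
    ("rnl", 150), ("rns", 110),
)

_RRNA_LABELS = {"rnl", "rns"}


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one synthetic genome.

    ``at_fraction``/``t_fraction`` are genome-wide targets (defaults follow the
    observed 84% AT with T at ~60%); gene models give protein lengths in amino
    acids (rRNA entries in nucleotides); NC tract lengths are cycled between
    consecutive genes.
    """

    gene_models: tuple[tuple[str, int], ...] = DEFAULT_GENE_MODELS
    at_fraction: float = 0.84
    t_fraction: float = 0.60
    n_urfs: int = 2
    urf_aa_range: tuple[int, int] = (35, 100)
    nc_tract_lengths: tuple[int, ...] = (15, 90, 25, 12, 18, 30, 10, 22, 35, 14, 16, 95, 20, 12, 18)
    planted_repeat: Optional[tuple[int, int]] = None  # (unit bp, separation bp)
    code_name: str = "mold"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.t_fraction <= self.at_fraction < 1):
            raise ValueError("need 0 < t_fraction <= at_fraction < 1")
        if self.n_urfs < 0:
            raise ValueError("n_urfs must be >= 0")
        if self.planted_repeat is not None:
            unit, sep = self.planted_repeat
            if unit < 2 or sep < unit:
                raise ValueError("planted repeat needs unit >= 2 and separation >= unit")

    @property
    def code(self) -> CodeTable:
        return get_code(self.code_name)


@dataclass
class TruthLedger:
    """Everything planted into a synthetic object, enough to verify outputs."""

    genome_id: str = ""
    features: list[dict] = field(default_factory=list)
    gene_order: list[str] = field(default_factory=list)
    nc_tracts: list[dict] = field(default_factory=list)
    repeat: Optional[dict] = None
    rearrangement_moves: list[dict] = field(default_factory=list)
    reassignment: Optional[dict] = None
    read_params: Optional[dict] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthLedger":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# Nucleotide / codon sampling
# ---------------------------------------------------------------------------

def _base_probs(spec: GenomeSpec) -> np.ndarray:
    pT = spec.t_fraction
    pA = spec.at_fraction - spec.t_fraction
    pC = pG = (1.0 - spec.at_fraction) / 2.0
    return np.array([pA, pC, pG, pT])


_BASES = np.array(list("ACGT"))


def _sample_bases(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=probs)])


def _sample_codon(rng: np.random.Generator, probs: np.ndarray, code: CodeTable) -> str:
    while True:
        c = _sample_bases(rng, 3, probs)
        if not code.is_stop(c):
            return c


_START_CODONS = ("ATT", "ATG", "ATA", "TTA")
_START_WEIGHTS = (0.40, 0.38, 0.17, 0.05)
_STOP_CODONS = ("TAA", "TAG")
_STOP_WEIGHTS = (0.9, 0.1)

#: AT-rich codons for strongly hydrophobic residues, used to plant a
#: transmembrane stretch inside URFs.
_HYDROPHOBIC_CODONS = ("TTA", "ATT", "TTT", "GTT", "ATA", "CTT")


def _sample_cds(rng: np.random.Generator, n_aa: int, probs: np.ndarray,
                code: CodeTable, tm_stretch: bool = False) -> str:
    start = rng.choice(_START_CODONS, p=_START_WEIGHTS)
    body = [_sample_codon(rng, probs, code) for _ in range(n_aa - 1)]
    if tm_stretch and n_aa >= 24:
        at = int(rng.integers(1, n_aa - 22))
        for i in range(21):
            body[at + i - 1] = str(rng.choice(_HYDROPHOBIC_CODONS))
    stop = rng.choice(_STOP_CODONS, p=_STOP_WEIGHTS)
    return start + "".join(body) + stop


def _sample_nc(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    tract = list(_sample_bases(rng, n, probs))
    run = int(rng.integers(5, 13))
    if n > run + 2:
        at = int(rng.integers(1, n - run))
        tract[at : at + run] = "T" * run
    return "".join(tract)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_genome(spec: GenomeSpec) -> tuple[MitoGenome, AnnotationSet, TruthLedger]:
    """Build a circular genome: 13 canonical genes on one strand with NC tracts
    (poly-T runs) between them, URFs with a planted hydrophobic stretch, and an
    optional planted perfect repeat. Deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    probs = _base_probs(spec)
    code = spec.code

    # decide URF insertion slots (after which gene index)
    n_genes = len(spec.gene_models)
    urf_slots = sorted(rng.choice(n_genes, size=spec.n_urfs, replace=False)) if spec.n_urfs else []

    elements: list[tuple[str, str, str]] = []  # (label, kind, sequence)
    urf_i = 0
    for gi, (label, size) in enumerate(spec.gene_models):
        if label in _RRNA_LABELS:
            elements.append((label, "rRNA", _sample_bases(rng, size, probs)))
        else:
            elements.append((label, "protein", _sample_cds(rng, size, probs, code)))
        if gi in urf_slots:
            for _ in range(list(urf_slots).count(gi)):
                urf_i += 1
                n_aa = int(rng.integers(*spec.urf_aa_range))
                elements.append(
                    (f"urf{urf_i}", "URF", _sample_cds(rng, n_aa, probs, code, tm_stretch=True))
                )

    # interleave NC tracts, remembering which are wide enough for repeat planting
    nc_lengths = [spec.nc_tract_lengths[i % len(spec.nc_tract_lengths)] for i in range(len(elements))]
    parts: list[str] = []
    features: list[dict] = []
    nc_records: list[dict] = []
    pos = 0
    for (label, kind, seq), nc_len in zip(elements, nc_lengths):
        nc = _sample_nc(rng, nc_len, probs)
        nc_records.append({"start": pos, "length": nc_len})
        parts.append(nc)
        pos += nc_len
        features.append({"label": label, "kind": kind, "start": pos, "end": pos + len(seq)})
        parts.append(seq)
        pos += len(seq)
    sequence = "".join(parts)
    L = len(sequence)

    repeat_record = None
    if spec.planted_repeat is not None:
        unit_len, separation = spec.planted_repeat
        while True:
            unit = _sample_bases(rng, unit_len, probs)
            if dinucleotide_entropy(unit) >= LOW_COMPLEXITY_ENTROPY:
                break
        wide = [t for t in nc_records if t["length"] >= unit_len + 4]
        if len(wide) < 2:
            raise ValueError("spec NC tracts too small to plant the requested repeat")
        best = None
        for i in range(len(wide)):
            for j in range(i + 1, len(wide)):
                d = abs((wide[j]["start"] - wide[i]["start"]) - separation)
                circ_d = abs(L - (wide[j]["start"] - wide[i]["start"]) - separation)
                d = min(d, circ_d)
                if best is None or d < best[0]:
                    best = (d, wide[i], wide[j])
        _, t1, t2 = best
        p1 = t1["start"] + 2
        p2 = t2["start"] + 2
        s = list(sequence)
        s[p1 : p1 + unit_len] = unit
        s[p2 : p2 + unit_len] = unit
        # enforce maximality: distinct flanking bases on both sides
        for left, right in ((p1, p2),):
            if s[left - 1] == s[right - 1]:
                s[right - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[right - 1]]
            if s[left + unit_len] == s[right + unit_len]:
                s[right + unit_len] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[right + unit_len]]
        sequence = "".join(s)
        repeat_record = {
            "unit_length": unit_len,
            "positions": [p1, p2],
            "separation": p2 - p1,
            "requested_separation": separation,
        }

    genome = MitoGenome(f"syn{spec.seed}", sequence, is_circular=True)
    ann = AnnotationSet(
        genome.id,
        [
            GeneFeature(f["label"], f["start"], f["end"], "+", f["kind"])
            for f in features
        ],
    )
    ledger = TruthLedger(
        genome_id=genome.id,
        features=features,
        gene_order=[f["label"] for f in features if f["kind"] != "URF"],
        nc_tracts=nc_records,
        repeat=repeat_record,
    )
    return genome, ann, ledger


# ---------------------------------------------------------------------------
# Gene-order rearrangement
# ---------------------------------------------------------------------------

def rearrange_order(
    order: GeneOrder, k_moves: int, seed: int
) -> tuple[GeneOrder, TruthLedger]:
    """Apply ``k_moves`` random single-gene transpositions. Each transposition
    alters at most 3 adjacencies, so BD(input, output) <= 3 * k_moves."""
    if k_moves < 0:
        raise ValueError("k_moves must be >= 0")
    rng = np.random.default_rng(seed)
    labels = list(order.order)
    ledger = TruthLedger(genome_id=order.genome_id)

    def adjacency_set(ls: list[str]) -> set[tuple[str, str]]:
        return {(ls[i], ls[(i + 1) % len(ls)]) for i in range(len(ls))}

    for _ in range(k_moves):
        before = adjacency_set(labels)
        while True:  # redraw until the move changes the circular order
            i = int(rng.integers(len(labels)))
            trial = list(labels)
            gene = trial.pop(i)
            j = int(rng.integers(len(trial) + 1))
            trial.insert(j, gene)
            if adjacency_set(trial) != before:
                break
        labels = trial
        ledger.rearrangement_moves.append({"gene": gene, "from": i, "to": j})
    ledger.gene_order = labels
    return GeneOrder(order.genome_id + "_rearr", tuple(labels)), ledger


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: MitoGenome,
    depth: float,
    read_len: int = 100,
    paired: bool = False,
    insert: int = 300,
    seed: int = 0,
) -> tuple[list[str], TruthLedger]:
    """Error-free reads sampled uniformly on the circle at the expected depth
    (Poisson count), in random orientation; paired mode emits both mates of
    fragments of the given insert size."""
    if read_len >= genome.length:
        raise ValueError("read length must be below genome length")
    rng = np.random.default_rng(seed)
    L = genome.length
    D = genome.sequence + genome.sequence
    reads: list[str] = []
    if depth > 0:
        if paired:
            n_frag = int(rng.poisson(depth * L / (2 * read_len)))
            for _ in range(n_frag):
                s = int(rng.integers(L))
                frag = (genome.sequence * 3)[s : s + insert]
                reads.append(frag[:read_len])
                reads.append(reverse_complement(frag[-read_len:]))
        else:
            n = int(rng.poisson(depth * L / read_len))
            starts = rng.integers(0, L, size=n)
            flips = rng.random(n) < 0.5
            for s, flip in zip(starts, flips):
                r = D[int(s) : int(s) + read_len]
                reads.append(reverse_complement(r) if flip else r)
    ledger = TruthLedger(
        genome_id=genome.id,
        read_params={
            "depth": depth,
            "read_len": read_len,
            "paired": paired,
            "insert": insert,
            "n_reads": len(reads),
            "seed": seed,
        },
    )
    return reads, ledger


# ---------------------------------------------------------------------------
# Codon-aware alignments for reassignment detection
# ---------------------------------------------------------------------------

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _synonyms(code: CodeTable) -> dict[str, list[str]]:
    syn: dict[str, list[str]] = {}
    for codon, aa in sorted(code.codon_map.items()):
        syn.setdefault(aa, []).append(codon)
    return syn


def simulate_code_alignment(
    n_species: int = 8,
    n_columns: int = 100,
    reassigned: Optional[tuple[str, str]] = None,
    seed: int = 0,
    conservation: float = 0.9,
    reassigned_fraction: float = 0.25,
) -> tuple[dict[str, dict[str, str]], TruthLedger]:
    """One codon-aware alignment (gene "gene1") of ``n_species`` background
    species plus a species named "target".

    Columns are conserved with probability ``conservation``; when a codon
    reassignment (codon, new_aa) is planted, a ``reassigned_fraction`` of the
    columns have the new amino acid as consensus and the target writes the
    reassigned codon there.
    """
    if n_species < 4:
        raise ValueError("need >= 4 species")
    rng = np.random.default_rng(seed)
    syn = _synonyms(MOLD)
    target_code = (
        MOLD.with_reassignment(reassigned[0], reassigned[1], "target")
        if reassigned is not None
        else MOLD
    )
    syn_target = _synonyms(target_code)
    rows: dict[str, list[str]] = {f"sp{i}": [] for i in range(n_species - 1)}
    rows["target"] = []
    truth_cols = 0
    for col in range(n_columns):
        planted = reassigned is not None and rng.random() < reassigned_fraction
        if planted:
            consensus = reassigned[1]
        else:
            consensus = str(rng.choice(list(_AA_ALPHABET)))
        for sp in rows:
            if sp == "target":
                continue
            if rng.random() < conservation:
                aa = consensus
            else:
                aa = str(rng.choice([a for a in _AA_ALPHABET if a != consensus]))
            rows[sp].append(str(rng.choice(syn[aa])))
        if planted:
            rows["target"].append(reassigned[0])
            truth_cols += 1
        else:
            rows["target"].append(str(rng.choice(syn_target[consensus])))
    alignment = {"gene1": {sp: "".join(cs) for sp, cs in rows.items()}}
    ledger = TruthLedger(
        genome_id="alignment",
        reassignment=(
            None
            if reassigned is None
            else {"codon": reassigned[0], "amino_acid": reassigned[1], "n_columns": truth_cols}
        ),
    )
    return alignment, ledger
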