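"""Reading and writing of mitogenome files with explicit circular-coordinate semantics.

Internal coordinates are 0-based, half-open. A feature that spans the origin of
a circular genome is stored *unwrapped*: its ``end`` exceeds the genome length
and satisfies ``end - length < start``, so ``end - start`` is always the true
feature length. GenBank 1-based inclusive locations (including
``join(x..len,1..y)`` origin spans) are converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MitoFormatError",
    "TopologyError",
    "MitoGenome",
    "GeneFeature",
    "AnnotationSet",
    "CANONICAL_LABELS",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "write_genbank",
    "read_fastq",
    "write_fastq",
    "extract_feature_sequence",
    "reverse_complement",
]

#: The 13 single-strand genes shared by ctenophore mitochondrial genomes:
#: 11 proteins (atp6/atp8 and all tRNAs are absent in this lineage) plus 2 rRNAs.
CANONICAL_LABELS = (
    "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "rns", "rnl",
)

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MitoFormatError(ValueError):
    """A file did not conform to the expected format."""


class TopologyError(ValueError):
    """An operation required circular topology on a linear sequence."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MitoGenome:
    """A (possibly circular) mitochondrial nucleotide sequence."""

    id: str
    sequence: str
    is_circular: bool = False

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise MitoFormatError(f"genome {self.id!r}: empty sequence")
        bad = set(seq) - _ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise MitoFormatError(
                f"genome {self.id!r}: illegal character {seq[pos]!r} at position {pos}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A located, stranded, typed feature on the circular coordinate system.

    ``kind`` is one of ``protein``, ``rRNA``, ``URF``. ``has_incomplete_stop``
    marks genes ending on T/TA completed to TAA by polyadenylation.
    """

    label: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "protein"
    has_incomplete_stop: bool = False

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.label}: negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"{self.label}: end {self.end} <= start {self.start}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.label}: strand must be '+' or '-'")
        if self.kind not in {"protein", "rRNA", "URF"}:
            raise ValueError(f"{self.label}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def spans_origin(self, genome_length: int) -> bool:
        return self.end > genome_length

    def validate(self, genome_length: int) -> None:
        if self.start >= genome_length:
            raise ValueError(
                f"{self.label}: start {self.start} beyond genome length {genome_length}"
            )
        if self.end > genome_length and self.end - genome_length > self.start:
            raise ValueError(
                f"{self.label}: wrapped end {self.end} overruns its own start"
            )


@dataclass
class AnnotationSet:
    """Features of one genome, kept sorted by start coordinate.

    Every canonical label appears at most once.
    """

    genome_id: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.label))
        seen: set[str] = set()
        for f in self.features:
            if f.label in CANONICAL_LABELS:
                if f.label in seen:
                    raise ValueError(
                        f"{self.genome_id}: duplicate canonical label {f.label!r}"
                    )
                seen.add(f.label)

    def add(self, feature: GeneFeature) -> None:
        self.features.append(feature)
        self.__post_init__()

    def by_label(self, label: str) -> GeneFeature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(label)

    def labels(self) -> list[str]:
        return [f.label for f in self.features]

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[MitoGenome]:
    """Read a multi-FASTA file into genomes.

    Topology defaults to linear; a whitespace-separated ``circular`` token in
    the header marks the record circular. Lowercase is accepted and uppercased.
    """
    genomes: list[MitoGenome] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        circular = "circular" in rec.description.lower().split()
        try:
            genomes.append(MitoGenome(rec.id, str(rec.seq), is_circular=circular))
        except MitoFormatError as exc:
            raise MitoFormatError(f"{path}: record {rec.id!r}: {exc}") from exc
    return genomes


def write_fasta(genomes: Iterable[MitoGenome], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            topo = " circular" if g.is_circular else ""
            fh.write(f">{g.id}{topo}\n")
            for i in range(0, g.length, width):
                fh.write(g.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (plain text; reads are returned as bare sequences)
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Sequence[str], path: str | Path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@{prefix}{i}\n{r}\n+\n{'I' * len(r)}\n")


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_KIND_TO_GB = {"protein": "CDS", "URF": "CDS", "rRNA": "rRNA"}


def _feature_from_gb(feat: SeqFeature, genome_length: int, genome_id: str) -> GeneFeature:
    quals = feat.qualifiers
    label = (quals.get("gene") or quals.get("product") or ["?"])[0]
    loc = feat.location
    if loc is None:
        raise MitoFormatError(f"{genome_id}: feature {label!r}: unresolvable location")
    strand = "-" if loc.strand == -1 else "+"
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        tail, head = parts[-1], parts[0]
        if int(tail.end) != genome_length or int(head.start) != 0:
            raise MitoFormatError(
                f"{genome_id}: feature {label!r}: join() is not an origin span"
            )
        start, end = int(tail.start), genome_length + int(head.end)
    else:
        start, end = int(loc.start), int(loc.end)
    if feat.type == "rRNA":
        kind = "rRNA"
    elif label.lower().startswith("urf"):
        kind = "URF"
    else:
        kind = "protein"
    incomplete = "transl_except" in quals or quals.get("note", [""])[0].startswith(
        "incomplete stop"
    )
    return GeneFeature(label, start, end, strand, kind, has_incomplete_stop=incomplete)


def read_genbank(path: str | Path) -> tuple[MitoGenome, AnnotationSet]:
    """Parse a GenBank flatfile into a genome plus its annotation.

    1-based inclusive locations become 0-based half-open; ``join(x..len,1..y)``
    becomes one unwrapped origin-spanning feature; topology comes from LOCUS.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise MitoFormatError(f"{path}: {exc}") from exc
    try:
        seq = str(rec.seq)
    except Exception as exc:  # undefined sequence => missing ORIGIN
        raise MitoFormatError(f"{path}: missing ORIGIN sequence") from exc
    if not seq:
        raise MitoFormatError(f"{path}: missing ORIGIN sequence")
    circular = rec.annotations.get("topology", "linear") == "circular"
    genome = MitoGenome(rec.id if rec.id != "<unknown id>" else rec.name, seq, circular)
    feats = [
        _feature_from_gb(f, genome.length, genome.id)
        for f in rec.features
        if f.type in {"CDS", "rRNA", "gene"}
    ]
    # gene + CDS pairs describe the same interval; keep one per (label, span)
    uniq: dict[tuple, GeneFeature] = {}
    for f in feats:
        key = (f.label, f.start, f.end)
        if key not in uniq or uniq[key].kind == "protein":
            uniq.setdefault(key, f)
    return genome, AnnotationSet(genome.id, list(uniq.values()))


def write_genbank(genome: MitoGenome, ann: AnnotationSet, path: str | Path) -> None:
    """Write a GenBank flatfile that round-trips exactly through :func:`read_genbank`."""
    L = genome.length
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.is_circular else "linear"
    for f in ann:
        f.validate(L)
        if f.end > L and not genome.is_circular:
            raise ValueError(f"{f.label}: origin-spanning feature on a linear genome")
        strand = -1 if f.strand == "-" else 1
        if f.end > L:
            loc = CompoundLocation(
                [SimpleLocation(f.start, L, strand), SimpleLocation(0, f.end - L, strand)]
            )
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        quals = {"gene": [f.label]}
        if f.has_incomplete_stop:
            quals["note"] = ["incomplete stop codon completed by polyadenylation"]
        feat = SeqFeature(loc, type=_KIND_TO_GB[f.kind], qualifiers=quals)
        rec.features.append(feat)
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------

def extract_feature_sequence(genome: MitoGenome, f: GeneFeature) -> str:
    """Nucleotide sequence of a feature, wrapping the origin and honouring strand."""
    f.validate(genome.length)
    if f.end > genome.length:
        if not genome.is_circular:
            raise TopologyError(
                f"{f.label}: feature wraps the origin but genome {genome.id!r} is linear"
            )
        sub = (genome.sequence + genome.sequence)[f.start : f.end]
    else:
        sub = genome.sequence[f.start : f.end]
    return reverse_complement(sub) if f.strand == "-" else sub


def rotate_genome(
    genome: MitoGenome, ann: AnnotationSet, shift: int
) -> tuple[MitoGenome, AnnotationSet]:
    """Rotate a circular genome so old position ``shift`` becomes position 0.

    Features crossing the new origin become origin-spanning (unwrapped ends).
    """
    if not genome.is_circular:
        raise TopologyError(f"cannot rotate linear genome {genome.id!r}")
    L = genome.length
    shift %= L
    seq = genome.sequence[shift:] + genome.sequence[:shift]
    rotated = MitoGenome(genome.id, seq, True)
    feats = []
    for f in ann:
        s = (f.start - shift) % L
        feats.append(replace(f, start=s, end=s + f.length))
    return rotated, AnnotationSet(ann.genome_id, feats)
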