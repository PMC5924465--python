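"""Mitochondrial genetic-code tables.

The ctenophore mt genomes analysed here use the "Mold, Protozoan and
Coelenterate" mitochondrial code (NCBI translation table 4), in which TGA
encodes tryptophan. *Pleurobrachia bachei* carries a lineage-specific
reassignment of TGA from tryptophan to serine; its table is identical to the
mold table at every other codon.

Start codons are restricted to the four observed in Coeloplanidae mt genes:
ATA, ATG, ATT and TTA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from Bio.Data import CodonTable as _BioCodonTable

__all__ = ["CodeTable", "MOLD", "PBACHEI", "get_code", "STOP"]

STOP = "*"

_BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


@dataclass(frozen=True)
class CodeTable:
    """A 64-entry codon -> amino-acid map with explicit start and stop sets."""

    name: str
    codon_map: Mapping[str, str]  # stops mapped to "*"
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    def __post_init__(self) -> None:
        if set(self.codon_map) != set(ALL_CODONS):
            missing = set(ALL_CODONS) - set(self.codon_map)
            raise ValueError(f"code {self.name!r}: incomplete codon map ({len(missing)} missing)")
        if not self.start_codons <= set(ALL_CODONS):
            raise ValueError(f"code {self.name!r}: start codons outside the 64")
        if not self.stop_codons <= set(ALL_CODONS):
            raise ValueError(f"code {self.name!r}: stop codons outside the 64")
        for c in self.stop_codons:
            if self.codon_map[c] != STOP:
                raise ValueError(f"code {self.name!r}: stop codon {c} not mapped to '*'")

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def is_start(self, codon: str) -> bool:
        return codon in self.start_codons

    def with_reassignment(self, codon: str, amino_acid: str, name: str) -> "CodeTable":
        cmap = dict(self.codon_map)
        cmap[codon] = amino_acid
        stops = frozenset(c for c in self.stop_codons if c != codon)
        return CodeTable(name, cmap, self.start_codons, stops)


def _mold_table() -> CodeTable:
    t4 = _BioCodonTable.unambiguous_dna_by_id[4]
    cmap = dict(t4.forward_table)
    for c in t4.stop_codons:
        cmap[c] = STOP
    return CodeTable(
        name="mold",
        codon_map=cmap,
        start_codons=frozenset({"ATA", "ATG", "ATT", "TTA"}),
        stop_codons=frozenset(t4.stop_codons),
    )


#: NCBI table 4 (TGA -> Trp) with the Coeloplanidae start-codon set.
MOLD = _mold_table()

#: The *P. bachei* variant: TGA reassigned from tryptophan to serine.
PBACHEI = MOLD.with_reassignment("TGA", "S", "pbachei")

_CODES = {"mold": MOLD, "pbachei": PBACHEI}


def get_code(name: str) -> CodeTable:
    try:
        return _CODES[name]
    except KeyError:
        raise KeyError(f"unknown code table {name!r}; available: {sorted(_CODES)}") from None
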