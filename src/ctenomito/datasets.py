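"""Published summary tables for the five sequenced ctenophore mitogenomes.

Two small delimited fixtures ship with the package:

* ``ctenophore_nc_table.tsv`` — per-genome non-coding statistics (genome
  length; NC length with URFs counted as non-coding and with URFs counted as
  coding; counts of NC tracts > 20 bp; longest tract and its flanking genes).
* ``ctenophore_bd_table.tsv`` — pairwise breakpoint distances over the 13
  shared genes, with the published two-decimal normalized distances. Note the
  *V. multiformis* / *P. bachei* pair prints BD 12 but BDn 0.77 in the source
  table; the published values are carried verbatim and the inconsistency is
  left to the caller (12/13 rounds to 0.92).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_nc_table", "load_breakpoint_table", "N_SHARED_GENES"]

#: Number of genes shared by all five ctenophore mitogenomes (11 proteins + 2 rRNAs).
N_SHARED_GENES = 13


def _read(name: str) -> pd.DataFrame:
    with resources.files("ctenomito.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_nc_table() -> pd.DataFrame:
    """Non-coding statistics per genome (one row per species)."""
    return _read("ctenophore_nc_table.tsv")


def load_breakpoint_table() -> pd.DataFrame:
    """Pairwise breakpoint distances; ``same_order`` marks pairs within the
    same taxonomic order (the three Platyctenida)."""
    return _read("ctenophore_bd_table.tsv")
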