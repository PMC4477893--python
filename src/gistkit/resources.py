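"""Packaged reference tables from the studied GIST case.

Three small fixtures ship with the package:

* ``founder_candidates`` — the candidate founding mutations of the
  sequenced tumour with their published mutant-read fractions;
* ``znf407_screen_panel`` — the ZNF407 prevalence screen over 52 GIST
  samples: dbSNP id, 1000 Genomes minor allele frequency (``?`` where
  unknown) and carrier counts;
* ``znf407_zf_motifs`` — the two published C2H2 finger motif strings of
  ZNF407 (anchor residues upper-case, spacers lower-case).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
from Bio import SeqIO

from .screen import ScreenSite, sites_from_frame

__all__ = [
    "load_founder_candidates",
    "load_screen_panel",
    "load_screen_sites",
    "load_zf_motifs",
]

_DATA = resources.files("gistkit") / "data"


def load_founder_candidates() -> pd.DataFrame:
    """Candidate founding mutations: gene, class, alt_count, coverage."""
    with resources.as_file(_DATA / "founder_candidates.tsv") as path:
        return pd.read_csv(path, sep="\t")


def load_screen_panel() -> pd.DataFrame:
    """ZNF407 screen panel table (MAF as string, ``?`` where unknown)."""
    with resources.as_file(_DATA / "znf407_screen_panel.tsv") as path:
        return pd.read_csv(path, sep="\t", dtype={"maf": str})


def load_screen_sites() -> list[ScreenSite]:
    """The screen panel as :class:`~gistkit.screen.ScreenSite` objects."""
    return sites_from_frame(load_screen_panel())


def load_zf_motifs() -> dict[str, str]:
    """Published ZNF407 C2H2 motif strings keyed by record id."""
    with resources.as_file(_DATA / "znf407_zf_motifs.fasta") as path:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
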