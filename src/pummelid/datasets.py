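"""Bundled reference datasets from the published pummelo survey.

Three small tables ship with the package:

* ``snp_panel`` — the 25-SNP identification panel with its published
  per-locus summary statistics (Ho, He, PIC, f) over the full
  260-accession collection.
* ``sequenced_accessions`` — haplotype-pair profiles of 24 sequenced
  accessions across 12 genomic segments (``h1/h2`` per cell, ``-`` =
  not sequenced).  Groups: wendan, shatianyou, other (together the 20
  true-to-type pummelos) and hybrid_or_unassigned.
* ``segment_summary`` — the published per-segment diversity summary
  (available sequences, length, S, haplotype count, Hd, pi) over the 20
  true-to-type pummelos.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genotype_data import LocusMeta
from .segment_analysis import HaplotypeTable

__all__ = [
    "snp_panel",
    "snp_panel_loci",
    "sequenced_accessions",
    "sequenced_accession_table",
    "true_to_type_accessions",
    "segment_summary",
    "SUPER_LOCUS_GROUPS",
]

#: The three published groups of linked panel SNPs merged as super loci.
SUPER_LOCUS_GROUPS = (
    ("chr2_30594899T/C", "chr2_30595627T/C"),
    ("chr5_12963514T/C", "chr5_13684450T/C", "chr5_15275826A/G"),
    ("chrUn_5023005A/G", "chrUn_19904498A/G"),
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("pummelid.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype=str, keep_default_na=False)


def snp_panel() -> pd.DataFrame:
    """25-SNP panel with published Ho/He/PIC/f (floats)."""
    df = _read("snp_panel.csv")
    for c in ("ho", "he", "pic", "f"):
        df[c] = df[c].astype(float)
    df["amplicon_bp"] = df["amplicon_bp"].astype(int)
    return df


def snp_panel_loci() -> list:
    """The panel as parsed :class:`~pummelid.genotype_data.LocusMeta`."""
    return [LocusMeta.from_name(n) for n in snp_panel()["name"]]


def sequenced_accessions() -> pd.DataFrame:
    """Raw 24 x 12 haplotype-pair profile table."""
    return _read("sequenced_accessions.csv")


def sequenced_accession_table() -> HaplotypeTable:
    """The 24 x 12 profile as a :class:`HaplotypeTable`."""
    return HaplotypeTable.from_dataframe(sequenced_accessions())


def true_to_type_accessions() -> list:
    """The 20 true-to-type pummelos (groups wendan/shatianyou/other)."""
    df = sequenced_accessions()
    keep = df["group"].isin(["wendan", "shatianyou", "other"])
    return df.loc[keep, "accession"].tolist()


def segment_summary() -> pd.DataFrame:
    """Published per-segment diversity summary (floats/ints)."""
    df = _read("segment_summary.csv")
    for c in ("available_sequences", "length_bp", "n_snps", "n_haplotypes"):
        df[c] = df[c].astype(int)
    for c in ("hd", "pi"):
        df[c] = df[c].astype(float)
    return df
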