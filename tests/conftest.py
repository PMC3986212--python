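"""Shared fixtures: bundled reference tables and small genotype builders."""

from __future__ import annotations

import numpy as np
import pytest

from pummelid import datasets
from pummelid.genotype_data import (
    Accession,
    GenotypeMatrix,
    LocusMeta,
    genotype,
    parse_genotype,
)


@pytest.fixture(scope="session")
def table2():
    """Haplotype-pair profiles of the 24 sequenced accessions (12 segments)."""
    return datasets.sequenced_accession_table()


@pytest.fixture(scope="session")
def true20():
    """The 20 true-to-type pummelo accessions."""
    return datasets.true_to_type_accessions()


@pytest.fixture(scope="session")
def panel_df():
    """Published 25-SNP panel summary (Ho/He/PIC/f)."""
    return datasets.snp_panel()


@pytest.fixture(scope="session")
def segment_summary_df():
    return datasets.segment_summary()


def build_matrix(cell_rows, alleles=None, groups=None, locus_ids=None):
    """Small-matrix builder: rows of 'A/G'-style strings ('-' = missing)."""
    n_loci = len(cell_rows[0])
    if alleles is None:
        alleles = [("A", "G")] * n_loci
    if locus_ids is None:
        locus_ids = [f"L{j + 1}" for j in range(n_loci)]
    loci = [
        LocusMeta(locus_id=locus_ids[j], chromosome="1",
                  position=1000 * (j + 1), alleles=alleles[j])
        for j in range(n_loci)
    ]
    accessions = [
        Accession(f"acc{i + 1}", group=(groups[i] if groups else ""))
        for i in range(len(cell_rows))
    ]
    cells = [[parse_genotype(c) for c in row] for row in cell_rows]
    return GenotypeMatrix(accessions=accessions, loci=loci, cells=cells)


def random_matrix(rng, n_acc, n_loci, missing_rate=0.0, maf=0.4):
    """Random HWE matrix for property tests (independent loci)."""
    rows = []
    for i in range(n_acc):
        row = []
        for j in range(n_loci):
            if rng.random() < missing_rate:
                row.append("-")
            else:
                d = rng.binomial(2, maf)
                row.append("/".join(["A"] * d + ["G"] * (2 - d)))
        rows.append(row)
    return build_matrix(rows)
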