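"""Data model and I/O for diploid SNP genotype panels.

The central container is :class:`GenotypeMatrix`: accessions (cultivar
samples) by loci, each cell an unordered diploid allele pair or missing.
Heterozygotes are canonicalized (``A/G`` and ``G/A`` are the same cell),
missing data is a single sentinel (``None``, rendered ``-`` in CSV and
``./.`` in VCF).

Coordinates are 1-based inclusive; SNP names follow the
``chr<tag>_<position><ref>/<alt>`` convention (e.g. ``chr1_7539019A/G``:
an A/G SNP at reference position 7,539,019 on pseudo-chromosome 1).
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "MISSING",
    "Genotype",
    "LocusMeta",
    "DerivedLocus",
    "Accession",
    "GenotypeMatrix",
    "GroupPartition",
    "genotype",
    "format_genotype",
    "parse_genotype",
    "read_genotype_csv",
    "write_genotype_csv",
    "export_barcode",
    "write_vcf",
    "read_vcf",
]

#: Sentinel for a missing (untyped) genotype cell.
MISSING = None

#: A genotype cell: canonically sorted allele pair, or ``MISSING``.
Genotype = Optional[tuple]

_NUCLEOTIDES = frozenset("ACGT")
_NAME_RE = re.compile(r"^chr(.+?)_(\d+)([ACGT])/([ACGT])$")


class GenotypeFormatError(ValueError):
    """Malformed genotype table or cell."""


class GenotypeValidationError(ValueError):
    """A genotype cell carries an allele not defined for its locus."""


def genotype(a: str, b: str) -> tuple:
    """Build a canonical (alphabetically sorted) unordered allele pair."""
    return (a, b) if a <= b else (b, a)


def parse_genotype(cell: str) -> Genotype:
    """Parse an ``X/Y`` cell; ``-`` (or empty) means missing."""
    cell = cell.strip()
    if cell in ("-", "", "./."):
        return MISSING
    parts = cell.split("/")
    if len(parts) != 2 or not all(parts):
        raise GenotypeFormatError(f"malformed genotype cell {cell!r}")
    return genotype(parts[0], parts[1])


def format_genotype(g: Genotype) -> str:
    return "-" if g is MISSING else f"{g[0]}/{g[1]}"


@dataclass(frozen=True)
class LocusMeta:
    """A bi-allelic SNP locus anchored on the reference genome.

    ``name`` round-trips through :meth:`from_name` / :attr:`name`.
    """

    locus_id: str
    chromosome: str
    position: int
    alleles: tuple

    def __post_init__(self):
        if len(self.alleles) != 2 or len(set(self.alleles)) != 2:
            raise ValueError(f"{self.locus_id}: alleles must be a distinct pair")
        if not set(self.alleles) <= _NUCLEOTIDES:
            raise ValueError(f"{self.locus_id}: alleles must be nucleotides (ACGT)")
        if self.position < 1:
            raise ValueError(f"{self.locus_id}: position must be >= 1 (1-based)")

    @property
    def name(self) -> str:
        a, b = self.alleles
        return f"chr{self.chromosome}_{self.position}{a}/{b}"

    @classmethod
    def from_name(cls, name: str, locus_id: str | None = None) -> "LocusMeta":
        m = _NAME_RE.match(name)
        if not m:
            raise ValueError(f"cannot parse SNP name {name!r}")
        chrom, pos, a, b = m.groups()
        return cls(locus_id=locus_id or name, chromosome=chrom,
                   position=int(pos), alleles=(a, b))


@dataclass(frozen=True)
class DerivedLocus:
    """A multi-allelic locus derived from other data (super locus, segment).

    Alleles are arbitrary symbols (haplotype labels); no reference anchor.
    """

    locus_id: str
    alleles: tuple

    def __post_init__(self):
        if len(set(self.alleles)) != len(self.alleles) or not self.alleles:
            raise ValueError(f"{self.locus_id}: alleles must be distinct and non-empty")


@dataclass(frozen=True)
class Accession:
    accession_id: str
    name: str = ""
    group: str = ""

    def __post_init__(self):
        if not self.name:
            object.__setattr__(self, "name", self.accession_id)


#: accession_id -> group label.  Every accession appears in at most one group.
GroupPartition = Mapping[str, str]


@dataclass
class GenotypeMatrix:
    """Rectangular accessions x loci table of diploid genotypes."""

    accessions: list
    loci: list
    cells: list  # list (per accession) of lists (per locus) of Genotype

    def __post_init__(self):
        ids = [a.accession_id for a in self.accessions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate accession ids")
        lids = [l.locus_id for l in self.loci]
        if len(set(lids)) != len(lids):
            raise ValueError("duplicate locus ids")
        for row in self.cells:
            if len(row) != len(self.loci):
                raise GenotypeFormatError("ragged genotype rows")
        if len(self.cells) != len(self.accessions):
            raise GenotypeFormatError("cell row count != accession count")
        self._validate_alleles()

    def _validate_alleles(self):
        for acc, row in zip(self.accessions, self.cells):
            for locus, g in zip(self.loci, row):
                if g is MISSING:
                    continue
                bad = set(g) - set(locus.alleles)
                if bad:
                    raise GenotypeValidationError(
                        f"accession {acc.accession_id!r}, locus "
                        f"{locus.locus_id!r}: allele(s) {sorted(bad)} not in "
                        f"locus alleles {list(locus.alleles)}"
                    )

    # -- access helpers -------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def accession_ids(self) -> list:
        return [a.accession_id for a in self.accessions]

    @property
    def locus_ids(self) -> list:
        return [l.locus_id for l in self.loci]

    def locus_index(self, locus_id: str) -> int:
        return self.locus_ids.index(locus_id)

    def column(self, locus_id: str) -> list:
        j = self.locus_index(locus_id)
        return [row[j] for row in self.cells]

    def row(self, accession_id: str) -> list:
        i = self.accession_ids.index(accession_id)
        return list(self.cells[i])

    def groups(self) -> dict:
        """Group partition read off the accession records (empty labels dropped)."""
        return {a.accession_id: a.group for a in self.accessions if a.group}

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.locus_index(l) for l in locus_ids]
        return GenotypeMatrix(
            accessions=list(self.accessions),
            loci=[self.loci[j] for j in idx],
            cells=[[row[j] for j in idx] for row in self.cells],
        )

    def subset_accessions(self, accession_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.accession_ids.index(a) for a in accession_ids]
        return GenotypeMatrix(
            accessions=[self.accessions[i] for i in idx],
            loci=list(self.loci),
            cells=[list(self.cells[i]) for i in idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[format_genotype(g) for g in row] for row in self.cells],
            index=pd.Index(self.accession_ids, name="accession"),
            columns=self.locus_ids,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accessions == other.accessions
            and self.loci == other.loci
            and self.cells == other.cells
        )


# -- CSV dialect --------------------------------------------------------
# Comma-separated, UTF-8; first column "accession", optional "group"
# column, then one column per locus named by locus_id; "-" = missing.

def read_genotype_csv(text, loci: Sequence) -> GenotypeMatrix:
    """Read the genotype CSV dialect, validating cells against ``loci``.

    ``text`` may be a string or an open text stream.  Header must name
    every locus in ``loci`` (order taken from the header).
    """
    if isinstance(text, str):
        text = io.StringIO(text)
    import csv
    rows = list(csv.reader(text))
    if not rows:
        raise GenotypeFormatError("empty genotype table")
    width = len(rows[0])
    for k, r in enumerate(rows):
        if len(r) != width:
            raise GenotypeFormatError(f"ragged row {k + 1}: "
                                      f"{len(r)} fields, expected {width}")
    df = pd.DataFrame(rows[1:], columns=rows[0], dtype=str)
    if "accession" not in df.columns:
        raise GenotypeFormatError("missing 'accession' column")
    by_id = {l.locus_id: l for l in loci}
    locus_cols = [c for c in df.columns if c not in ("accession", "group")]
    unknown = [c for c in locus_cols if c not in by_id]
    if unknown:
        raise GenotypeFormatError(f"header names unknown loci: {unknown}")
    missing_cols = [l.locus_id for l in loci if l.locus_id not in locus_cols]
    if missing_cols:
        raise GenotypeFormatError(f"header lacks loci: {missing_cols}")
    ordered = [by_id[c] for c in locus_cols]
    accessions, cells = [], []
    for _, rec in df.iterrows():
        group = rec["group"] if "group" in df.columns else ""
        accessions.append(Accession(rec["accession"], group=group))
        cells.append([parse_genotype(rec[c]) for c in locus_cols])
    return GenotypeMatrix(accessions=accessions, loci=ordered, cells=cells)


def write_genotype_csv(matrix: GenotypeMatrix) -> str:
    cols = ["accession"]
    has_groups = any(a.group for a in matrix.accessions)
    if has_groups:
        cols.append("group")
    cols += matrix.locus_ids
    lines = [",".join(cols)]
    for acc, row in zip(matrix.accessions, matrix.cells):
        rec = [acc.accession_id] + ([acc.group] if has_groups else [])
        rec += [format_genotype(g) for g in row]
        lines.append(",".join(rec))
    return "\n".join(lines) + "\n"


# -- barcodes -----------------------------------------------------------

def export_barcode(matrix: GenotypeMatrix,
                   locus_order: Sequence | None = None) -> dict:
    """Canonical per-accession barcode strings.

    Homozygote ``AA``, heterozygote alphabetical ``AG``, missing ``--``;
    fields joined by ``|``.  Identical multilocus genotypes map to
    identical strings (and conversely, absent missing data).
    """
    if locus_order is None:
        locus_order = matrix.loci
    ids = [l.locus_id for l in locus_order]
    unknown = set(ids) - set(matrix.locus_ids)
    if unknown:
        raise ValueError(f"locus_order not a subset of matrix loci: {sorted(unknown)}")
    sub = matrix.subset_loci(ids)
    out = {}
    for acc, row in zip(sub.accessions, sub.cells):
        fields = ["--" if g is MISSING else f"{g[0]}{g[1]}" for g in row]
        out[acc.accession_id] = "|".join(fields)
    return out


# -- VCF 4.2 ------------------------------------------------------------

def write_vcf(matrix: GenotypeMatrix) -> str:
    """Emit unphased diploid VCF 4.2 text (one record per locus)."""
    for l in matrix.loci:
        if not isinstance(l, LocusMeta):
            raise ValueError("VCF export requires reference-anchored loci")
    lines = ["##fileformat=VCFv4.2", "##source=pummelid"]
    groups = matrix.groups()
    if groups:
        lines.append("##pummelid_groups=" + json.dumps(groups, sort_keys=True))
    seen = []
    for l in matrix.loci:
        if l.chromosome not in seen:
            seen.append(l.chromosome)
    for chrom in seen:
        lines.append(f"##contig=<ID={chrom}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
              "FORMAT"] + matrix.accession_ids
    lines.append("\t".join(header))
    for j, l in enumerate(matrix.loci):
        ref, alt = l.alleles
        gts = []
        for row in matrix.cells:
            g = row[j]
            if g is MISSING:
                gts.append("./.")
            else:
                idx = sorted(0 if a == ref else 1 for a in g)
                gts.append(f"{idx[0]}/{idx[1]}")
        rec = [l.chromosome, str(l.position), l.locus_id, ref, alt,
               ".", ".", ".", "GT"] + gts
        lines.append("\t".join(rec))
    return "\n".join(lines) + "\n"


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a (plain-text) VCF produced by :func:`write_vcf` back into a matrix."""
    import pysam

    groups: dict = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##pummelid_groups="):
                groups = json.loads(line.split("=", 1)[1])
            if not line.startswith("#"):
                break
    loci, columns = [], []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alleles = (rec.ref,) + tuple(rec.alts or ())
            loci.append(LocusMeta(
                locus_id=rec.id or f"{rec.chrom}_{rec.pos}",
                chromosome=rec.chrom, position=rec.pos,
                alleles=tuple(alleles[:2]),
            ))
            col = []
            for s in samples:
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    col.append(MISSING)
                else:
                    col.append(genotype(alleles[gt[0]], alleles[gt[1]]))
            columns.append(col)
    accessions = [Accession(s, group=groups.get(s, "")) for s in samples]
    cells = [[columns[j][i] for j in range(len(loci))]
             for i in range(len(samples))]
    return GenotypeMatrix(accessions=accessions, loci=loci, cells=cells)
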