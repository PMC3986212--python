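"""Sequence-segment "genetic barcode" analysis.

Works on short aligned genomic segments (a few hundred bp, sequenced as
two haploid copies — or several clones — per accession).  Provides SNP
calling under the clone-support rule (an allele must be seen in at least
two independent clones), diversity statistics (segregating sites S,
per-site nucleotide diversity pi, haplotype diversity Hd), EM phasing of
unphased segment genotypes, and segment-based duplicate matching via the
identity machinery (each segment = one multi-allelic locus whose alleles
are haplotypes).

Hd uses Nei's unbiased form n(1 - sum p_i^2)/(n - 1).  The n/(n-1)
correction is deliberate here and absent from the SNP-level He — the
published per-segment summaries require the corrected form.
"""

from __future__ import annotations

import io
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genotype_data import Accession, DerivedLocus, GenotypeMatrix, MISSING
from .identity import MatchReport, cumulative_pi, match_genotypes, pi_random, pi_sibs
from .linkage import em_from_genotype_rows
from .marker_stats import UndefinedStatisticError

__all__ = [
    "SegmentAlignment",
    "SegmentVariants",
    "HaplotypeTable",
    "SegmentStats",
    "read_segment_fasta",
    "call_segment_snps",
    "haplotype_census",
    "haplotype_diversity",
    "segregating_sites",
    "nucleotide_diversity",
    "nucleotide_diversity_from_haplotypes",
    "phase_segment",
    "segment_match",
    "segment_ld_r2",
    "segment_pi_stats",
]

_VALID = frozenset("ACGT")


@dataclass
class SegmentAlignment:
    """Equal-length aligned sequences for one segment.

    ``records`` are (accession_id, copy_label, sequence); alphabet
    {A,C,G,T,N,-}.
    """

    segment_id: str
    records: list
    genomic_location: str = ""

    def __post_init__(self):
        lengths = {len(seq) for _, _, seq in self.records}
        if len(lengths) > 1:
            raise ValueError(f"{self.segment_id}: unequal sequence lengths")
        for _, _, seq in self.records:
            bad = set(seq) - set("ACGTN-")
            if bad:
                raise ValueError(f"{self.segment_id}: invalid symbols {bad}")

    @property
    def length(self) -> int:
        return len(self.records[0][2]) if self.records else 0

    @property
    def sequences(self) -> list:
        return [seq for _, _, seq in self.records]

    def by_accession(self) -> dict:
        out: dict = {}
        for acc, copy, seq in self.records:
            out.setdefault(acc, []).append((copy, seq))
        return out


def read_segment_fasta(handle, segment_id: str) -> SegmentAlignment:
    """Read one segment's FASTA; sequence ids ``<accession>__<copy>``."""
    if isinstance(handle, str):
        handle = io.StringIO(handle)
    records = []
    for rec in SeqIO.parse(handle, "fasta"):
        if "__" in rec.id:
            acc, copy = rec.id.rsplit("__", 1)
        else:
            acc, copy = rec.id, "1"
        records.append((acc, copy, str(rec.seq).upper()))
    return SegmentAlignment(segment_id=segment_id, records=records)


@dataclass
class SegmentVariants:
    """Called SNP sites and per-accession unphased site genotypes."""

    segment_id: str
    sites: list            # (column index, alleles tuple)
    genotypes: dict        # accession -> tuple of sorted allele pairs / None


def call_segment_snps(aln: SegmentAlignment,
                      min_clone_support: int = 2) -> SegmentVariants:
    """Call SNPs under the clone rule.

    A column is a SNP when, after dropping alleles supported by fewer
    than ``min_clone_support`` sequences, at least two alleles remain.
    Columns containing N or gaps are excluded outright.  Per-accession
    genotypes are read from its first two sequence copies; an accession
    carrying an unsupported allele at a site is missing at that site.
    """
    if len(aln.records) < 4:
        raise ValueError("SNP calling needs at least 4 sequences")
    seqs = aln.sequences
    sites = []
    for col in range(aln.length):
        chars = [s[col] for s in seqs]
        if any(c not in _VALID for c in chars):
            continue
        counts: dict = {}
        for c in chars:
            counts[c] = counts.get(c, 0) + 1
        supported = tuple(sorted(a for a, n in counts.items()
                                 if n >= min_clone_support))
        if len(supported) >= 2:
            sites.append((col, supported))

    genotypes: dict = {}
    for acc, copies in aln.by_accession().items():
        copies = sorted(copies)
        row = []
        for col, alleles in sites:
            obs = [seq[col] for _, seq in copies[:2]]
            if len(obs) == 1:
                obs = obs * 2
            if any(c not in alleles for c in obs):
                row.append(None)
            else:
                row.append(tuple(sorted(obs)))
        genotypes[acc] = tuple(row)
    return SegmentVariants(segment_id=aln.segment_id, sites=sites,
                           genotypes=genotypes)


@dataclass
class HaplotypeTable:
    """Per accession x segment unordered haplotype-id pairs.

    Haplotype ids are dense positive integers, namespaced per segment;
    cells are sorted (h1, h2) tuples or MISSING.  ``haplotypes`` may map
    (segment, id) -> sequence when sequences are known.
    """

    accessions: list       # accession ids, input order
    segments: list         # segment ids
    cells: dict            # (accession, segment) -> (h1, h2) or MISSING
    groups: dict = field(default_factory=dict)   # accession -> group label
    haplotypes: dict = field(default_factory=dict)  # (segment, id) -> sequence

    def pair(self, accession: str, segment: str):
        return self.cells.get((accession, segment), MISSING)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "HaplotypeTable":
        """Build from a table shaped like the published 24 x 12 profile
        (columns ``accession``, optional ``group``, then segments;
        cells ``h1/h2`` or ``-``)."""
        segs = [c for c in df.columns if c not in ("accession", "group")]
        accs, cells, groups = [], {}, {}
        for _, rec in df.iterrows():
            acc = rec["accession"]
            accs.append(acc)
            if "group" in df.columns:
                groups[acc] = rec["group"]
            for s in segs:
                raw = str(rec[s]).strip()
                if raw in ("-", "", "nan"):
                    cells[(acc, s)] = MISSING
                else:
                    a, b = raw.split("/")
                    cells[(acc, s)] = tuple(sorted((int(a), int(b))))
        return cls(accessions=accs, segments=segs, cells=cells, groups=groups)

    def to_genotype_matrix(self) -> GenotypeMatrix:
        """One multi-allelic locus per segment; alleles are haplotype ids."""
        loci = []
        for s in self.segments:
            alleles = sorted({str(h) for a in self.accessions
                              for pair in [self.pair(a, s)] if pair
                              for h in pair})
            loci.append(DerivedLocus(locus_id=s, alleles=tuple(alleles)))
        cells = []
        for a in self.accessions:
            row = []
            for s in self.segments:
                pair = self.pair(a, s)
                row.append(MISSING if pair is MISSING
                           else tuple(sorted((str(pair[0]), str(pair[1])))))
            cells.append(row)
        accessions = [Accession(a, group=self.groups.get(a, ""))
                      for a in self.accessions]
        return GenotypeMatrix(accessions=accessions, loci=loci, cells=cells)


@dataclass(frozen=True)
class SegmentStats:
    segment_id: str
    n_sequences: int
    s: int
    n_haplotypes: int
    hd: float
    pi: float


# -- diversity statistics ----------------------------------------------

def haplotype_census(table: HaplotypeTable, segment: str,
                     accessions: Sequence[str] | None = None) -> tuple:
    """(n_sequences, n_haplotypes, counts) over non-missing pairs.

    ``n_sequences`` is twice the number of typed accessions in the
    subset.
    """
    subset = list(accessions) if accessions is not None else table.accessions
    if not subset:
        raise ValueError("empty accession subset")
    counts: dict = {}
    for a in subset:
        pair = table.pair(a, segment)
        if pair is MISSING:
            continue
        for h in pair:
            counts[h] = counts.get(h, 0) + 1
    n = sum(counts.values())
    return n, len(counts), dict(sorted(counts.items()))


def haplotype_diversity(counts: Mapping | Sequence[int], n: int | None = None) -> float:
    """Nei's unbiased haplotype diversity Hd = n(1 - sum p_i^2)/(n - 1)."""
    vals = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    total = sum(vals)
    if n is None:
        n = total
    if n < 2 or total != n:
        raise UndefinedStatisticError("Hd needs n >= 2 matching counts")
    p = np.asarray(vals, float) / n
    return float(n * (1.0 - np.sum(p ** 2)) / (n - 1))


def segregating_sites(aln: SegmentAlignment) -> int:
    """Count polymorphic columns (N/gap characters ignored per column)."""
    s = 0
    for col in range(aln.length):
        chars = {seq[col] for seq in aln.sequences} & _VALID
        if len(chars) >= 2:
            s += 1
    return s


def nucleotide_diversity(aln: SegmentAlignment) -> float:
    """Per-site nucleotide diversity pi.

    Average over all sequence pairs of (differences / comparable
    columns), columns with N/gap in either sequence excluded pairwise.
    The all-pairs mean over C(n,2) pairs is the unbiased (n/(n-1)-
    corrected) estimator.
    """
    seqs = aln.sequences
    if len(seqs) < 2:
        raise ValueError("pi needs at least 2 sequences")
    total = 0.0
    n_pairs = 0
    for sa, sb in itertools.combinations(seqs, 2):
        diffs = comparable = 0
        for ca, cb in zip(sa, sb):
            if ca in _VALID and cb in _VALID:
                comparable += 1
                if ca != cb:
                    diffs += 1
        if comparable:
            total += diffs / comparable
        n_pairs += 1
    return total / n_pairs


def nucleotide_diversity_from_haplotypes(haplotypes: Mapping[object, str],
                                         counts: Mapping[object, int]) -> float:
    """pi from haplotype sequences and counts:
    n/(n-1) * sum_{i<j} 2 p_i p_j d_ij / L."""
    ids = sorted(counts)
    n = sum(counts.values())
    if n < 2:
        raise ValueError("pi needs at least 2 sequences")
    length = len(next(iter(haplotypes.values())))
    acc = 0.0
    for i, j in itertools.combinations(ids, 2):
        d = sum(1 for a, b in zip(haplotypes[i], haplotypes[j]) if a != b)
        acc += 2 * (counts[i] / n) * (counts[j] / n) * d
    return (n / (n - 1)) * acc / length


def segment_stats(aln: SegmentAlignment,
                  table: HaplotypeTable | None = None,
                  accessions: Sequence[str] | None = None) -> SegmentStats:
    """Summary statistics for one aligned segment (table optional for Hd)."""
    s = segregating_sites(aln)
    pi = nucleotide_diversity(aln)
    if table is not None:
        n, k, counts = haplotype_census(table, aln.segment_id, accessions)
        hd = haplotype_diversity(counts) if n >= 2 else float("nan")
    else:
        counts: dict = {}
        for seq in aln.sequences:
            counts[seq] = counts.get(seq, 0) + 1
        n, k = sum(counts.values()), len(counts)
        hd = haplotype_diversity(counts)
    return SegmentStats(segment_id=aln.segment_id, n_sequences=n, s=s,
                        n_haplotypes=k, hd=hd, pi=pi)


# -- phasing ------------------------------------------------------------

def phase_segment(variants: SegmentVariants,
                  posterior_min: float = 0.0) -> tuple:
    """EM phasing of unphased segment genotypes.

    Returns ``(table, posteriors, hapfreqs)``: a one-segment
    :class:`HaplotypeTable` with ids assigned by first occurrence order,
    the per-accession posterior of the assigned pair, and the EM
    haplotype frequencies.  Accessions missing at any site, or whose
    best phase posterior falls below ``posterior_min``, are MISSING.
    """
    if len(variants.sites) > 12:
        raise ValueError("phasing enumerates haplotypes; max 12 sites")
    typed = {a: g for a, g in variants.genotypes.items()
             if g and all(c is not None for c in g)}
    if not typed:
        raise UndefinedStatisticError("no fully typed accession to phase")
    hf = em_from_genotype_rows(list(typed.values()),
                               tuple(str(c) for c, _ in variants.sites))
    if not hf.converged:
        warnings.warn(f"{variants.segment_id}: phasing EM did not converge; "
                      "best-likelihood result returned")

    ids: dict = {}   # haplotype allele-tuple -> integer id

    def hap_id(h: tuple) -> int:
        if h not in ids:
            ids[h] = len(ids) + 1
        return ids[h]

    accs = list(variants.genotypes)
    cells: dict = {}
    posteriors: dict = {}
    for a in accs:
        g = variants.genotypes.get(a)
        if a not in typed:
            cells[(a, variants.segment_id)] = MISSING
            posteriors[a] = None
            continue
        post = hf.pair_posteriors(typed[a])
        (h1, h2), p = max(post.items(), key=lambda kv: (kv[1], kv[0]))
        posteriors[a] = p
        if p < posterior_min:
            cells[(a, variants.segment_id)] = MISSING
        else:
            cells[(a, variants.segment_id)] = tuple(sorted((hap_id(h1),
                                                            hap_id(h2))))
    haplotypes = {(variants.segment_id, i): "".join(h)
                  for h, i in ids.items()}
    table = HaplotypeTable(accessions=accs, segments=[variants.segment_id],
                           cells=cells, haplotypes=haplotypes)
    return table, posteriors, hf


# -- matching and identity over segments --------------------------------

def segment_match(table: HaplotypeTable,
                  max_mismatch: int = 0,
                  min_shared_loci: int = 6) -> MatchReport:
    """Duplicate matching treating each segment as one multi-allelic locus."""
    return match_genotypes(table.to_genotype_matrix(),
                           max_mismatch=max_mismatch,
                           min_shared_loci=min_shared_loci)


def segment_ld_r2(table: HaplotypeTable, seg_a: str, seg_b: str,
                  tol: float = 1e-8, max_iter: int = 1000) -> float:
    """Multi-allelic r^2 analog between two segments.

    Hedrick-style: sum_ab D_ab^2 / (p_a p_b), normalized by
    min(k_A - 1, k_B - 1); joint haplotype frequencies by EM over the
    unphased two-segment genotypes.
    """
    rows = []
    for a in table.accessions:
        pa = table.pair(a, seg_a)
        pb = table.pair(a, seg_b)
        if pa is MISSING or pb is MISSING:
            continue
        rows.append((tuple(str(h) for h in pa), tuple(str(h) for h in pb)))
    if len(rows) < 2:
        raise UndefinedStatisticError("too few co-typed accessions")
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # loose-tolerance EM may stop early
        hf = em_from_genotype_rows(rows, (seg_a, seg_b), tol=tol,
                                   max_iter=max_iter)
    pa_m: dict = {}
    pb_m: dict = {}
    for (ha, hb), f in hf.freqs.items():
        pa_m[ha] = pa_m.get(ha, 0.0) + f
        pb_m[hb] = pb_m.get(hb, 0.0) + f
    ka = sum(1 for v in pa_m.values() if v > 1e-12)
    kb = sum(1 for v in pb_m.values() if v > 1e-12)
    if ka < 2 or kb < 2:
        raise UndefinedStatisticError("monomorphic segment")
    w2 = 0.0
    for ha, fa in pa_m.items():
        for hb, fb in pb_m.items():
            if fa > 1e-12 and fb > 1e-12:
                d = hf.freqs.get((ha, hb), 0.0) - fa * fb
                w2 += d * d / (fa * fb)
    return w2 / min(ka - 1, kb - 1)


def segment_ld_significance(table: HaplotypeTable, seg_a: str, seg_b: str,
                            n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation p-value for the multi-allelic segment LD statistic."""
    obs = segment_ld_r2(table, seg_a, seg_b)
    rng = np.random.default_rng(seed)
    accs = table.accessions
    col_b = [table.pair(a, seg_b) for a in accs]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(accs))
        shuffled = HaplotypeTable(
            accessions=accs, segments=[seg_a, seg_b],
            cells={**{(a, seg_a): table.pair(a, seg_a) for a in accs},
                   **{(a, seg_b): col_b[k] for a, k in zip(accs, perm)}},
        )
        try:
            # permutation statistic needs no tight EM convergence
            stat = segment_ld_r2(shuffled, seg_a, seg_b,
                                 tol=1e-5, max_iter=100)
        except UndefinedStatisticError:
            stat = 0.0
        if stat >= obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def segment_pi_stats(table: HaplotypeTable,
                     accessions: Sequence[str] | None = None,
                     merge_pairs: Sequence[tuple] | None = None,
                     r2_threshold: float = 0.1,
                     alpha: float = 0.05,
                     n_perm: int = 200,
                     seed: int = 0) -> dict:
    """Multi-segment PI and PIsibs under the product rule.

    Each segment is a multi-allelic locus with haplotype frequencies
    from the census over ``accessions`` (the LD scan runs on the same
    subset — population structure in excluded material would otherwise
    induce spurious cross-segment association).  Significantly linked
    segments are merged into connected components, each contributing
    its joint EM haplotype frequencies once; ``merge_pairs`` overrides
    the LD scan.
    """
    import networkx as nx

    subset = list(accessions) if accessions is not None else table.accessions
    segs = table.segments
    sub_table = HaplotypeTable(
        accessions=subset, segments=segs,
        cells={(a, s): table.pair(a, s) for a in subset for s in segs},
    )
    if merge_pairs is None:
        merge_pairs = []
        for sa, sb in itertools.combinations(segs, 2):
            try:
                r2 = segment_ld_r2(sub_table, sa, sb)
            except UndefinedStatisticError:
                continue
            if r2 > r2_threshold:
                p = segment_ld_significance(sub_table, sa, sb,
                                            n_perm=n_perm, seed=seed)
                if p < alpha:
                    merge_pairs.append((sa, sb))
    graph = nx.Graph()
    graph.add_edges_from(merge_pairs)
    components = sorted((tuple(sorted(c)) for c in nx.connected_components(graph)
                         if len(c) >= 2), key=lambda c: c[0])
    merged = {s for comp in components for s in comp}

    locus_freqs = []
    effective = []
    for s in segs:
        if s in merged:
            continue
        n, k, counts = haplotype_census(table, s, subset)
        if n == 0:
            continue
        locus_freqs.append([c / n for c in counts.values()])
        effective.append((s,))
    for comp in components:
        rows = []
        for a in subset:
            pairs = [table.pair(a, s) for s in comp]
            if any(pr is MISSING for pr in pairs):
                continue
            rows.append(tuple(tuple(str(h) for h in pr) for pr in pairs))
        hf = em_from_genotype_rows(rows, comp)
        locus_freqs.append(list(hf.freqs.values()))
        effective.append(comp)

    result = cumulative_pi(locus_freqs)
    result["effective_loci"] = effective
    result["n_effective"] = len(effective)
    return result
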