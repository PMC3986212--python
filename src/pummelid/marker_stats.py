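"""Per-locus descriptive and panel-selection statistics.

Allele frequencies, observed/expected heterozygosity, polymorphic
information content (Botstein's PIC), fixation coefficient
f = (He - Ho)/He, the exact conditional Hardy-Weinberg test,
multi-locus Weir-Cockerham Fst, and MAF/PIC/LD-aware greedy panel
selection.

He is the uncorrected gene diversity 1 - sum(p_i^2); the small-sample
n/(n-1) correction is applied only to sequence haplotype diversity in
:mod:`pummelid.segment_analysis`, where the published segment summaries
require it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .genotype_data import MISSING, GenotypeMatrix, GroupPartition

__all__ = [
    "AlleleFreqs",
    "LocusStats",
    "UndefinedStatisticError",
    "allele_frequencies",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "pic",
    "fixation_coefficient",
    "hwe_exact_test",
    "hwe_test",
    "fst_weir_cockerham",
    "locus_stats",
    "panel_stats",
    "select_panel",
    "round_half_up",
]


class UndefinedStatisticError(ValueError):
    """Statistic undefined for the given data (e.g. all-missing locus)."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round-half-up to fixed decimals, as in the published tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AlleleFreqs:
    """Allele proportions at one locus, counted over non-missing gene copies."""

    locus_id: str
    freqs: Mapping[str, float]
    n_copies: int  # non-missing gene copies (2 per typed individual)

    def __post_init__(self):
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.freqs.values()):
            raise ValueError(f"{self.locus_id}: frequencies must be a distribution")

    @property
    def p(self) -> np.ndarray:
        return np.asarray(list(self.freqs.values()), dtype=float)

    @property
    def maf(self) -> float:
        """Frequency of the second most common allele (0 if monomorphic)."""
        if len(self.freqs) < 2:
            return 0.0
        return float(sorted(self.freqs.values())[-2])


@dataclass(frozen=True)
class LocusStats:
    locus_id: str
    ho: float
    he: float
    pic: float
    f: Optional[float]
    hwe_p: float
    maf: float
    n_typed: int


def allele_frequencies(matrix: GenotypeMatrix, locus_id: str) -> AlleleFreqs:
    """Allele proportions over non-missing gene copies at one locus."""
    counts: dict = {}
    for g in matrix.column(locus_id):
        if g is MISSING:
            continue
        for a in g:
            counts[a] = counts.get(a, 0) + 1
    n = sum(counts.values())
    if n == 0:
        raise UndefinedStatisticError(f"{locus_id}: no typed genotypes")
    return AlleleFreqs(locus_id, {a: c / n for a, c in sorted(counts.items())}, n)


def expected_heterozygosity(freqs: AlleleFreqs | Sequence[float]) -> float:
    """Nei gene diversity He = 1 - sum(p_i^2), no sample-size correction."""
    p = freqs.p if isinstance(freqs, AlleleFreqs) else np.asarray(freqs, float)
    return float(1.0 - np.sum(p ** 2))


def observed_heterozygosity(matrix: GenotypeMatrix, locus_id: str) -> float:
    col = [g for g in matrix.column(locus_id) if g is not MISSING]
    if not col:
        raise UndefinedStatisticError(f"{locus_id}: no typed genotypes")
    return sum(1 for g in col if g[0] != g[1]) / len(col)


def pic(freqs: AlleleFreqs | Sequence[float]) -> float:
    """Botstein's polymorphic information content.

    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2; for a bi-allelic
    locus this equals He - 2 (p q)^2.
    """
    p = freqs.p if isinstance(freqs, AlleleFreqs) else np.asarray(freqs, float)
    sq = p ** 2
    cross = (np.sum(sq) ** 2 - np.sum(sq ** 2))  # = sum_{i != j} p_i^2 p_j^2
    return float(1.0 - np.sum(sq) - cross)


def fixation_coefficient(ho: float, he: float) -> float:
    """f = (He - Ho)/He; negative under heterozygote excess."""
    if he <= 0:
        raise UndefinedStatisticError("fixation coefficient undefined at He = 0")
    return (he - ho) / he


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test for bi-allelic counts.

    P-value is the sum of probabilities of heterozygote counts no more
    probable than the observed one, conditional on the allele counts.
    Monomorphic samples return p = 1.
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n == 0:
        raise UndefinedStatisticError("no genotypes")
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    hets = range(rare % 2, rare + 1, 2)  # feasible heterozygote counts

    def logprob(h: int) -> float:
        haa = (n_a - h) // 2
        hbb = (n_b - h) // 2
        # P(h | n_a, n_b) = n! / (haa! h! hbb!) * 2^h * n_a! n_b! / (2n)!
        return (gammaln(n + 1) - gammaln(haa + 1) - gammaln(h + 1)
                - gammaln(hbb + 1) + h * math.log(2)
                + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1))

    lp = {h: logprob(h) for h in hets}
    obs = lp[n_ab]
    return float(min(1.0, sum(math.exp(v) for v in lp.values()
                              if v <= obs + 1e-12)))


def hwe_test(matrix: GenotypeMatrix, locus_id: str) -> float:
    """Exact HWE p-value for one bi-allelic locus of a matrix."""
    locus = matrix.loci[matrix.locus_index(locus_id)]
    a, b = locus.alleles[0], locus.alleles[1]
    col = [g for g in matrix.column(locus_id) if g is not MISSING]
    n_aa = sum(1 for g in col if g == (a, a) or g == tuple(sorted((a, a))))
    n_bb = sum(1 for g in col if g[0] == b and g[1] == b)
    n_ab = len(col) - n_aa - n_bb
    return hwe_exact_test(n_aa, n_ab, n_bb)


def fst_weir_cockerham(matrix: GenotypeMatrix,
                       partition: GroupPartition) -> float:
    """Multi-locus Weir-Cockerham theta (ratio of sums across loci).

    Bi-allelic loci only; groups with fewer than one typed individual at
    a locus are dropped for that locus.
    """
    labels = sorted(set(partition.values()))
    if len(labels) < 2:
        raise UndefinedStatisticError("Fst needs at least two groups")
    num = den = 0.0
    for locus in matrix.loci:
        a_ref = locus.alleles[0]
        col = matrix.column(locus.locus_id)
        ns, ps, hs = [], [], []
        for lab in labels:
            gs = [g for acc_id, g in zip(matrix.accession_ids, col)
                  if partition.get(acc_id) == lab and g is not MISSING]
            if len(gs) < 1:
                continue
            ni = len(gs)
            pi = sum((g[0] == a_ref) + (g[1] == a_ref) for g in gs) / (2 * ni)
            hi = sum(1 for g in gs if g[0] != g[1]) / ni
            ns.append(ni); ps.append(pi); hs.append(hi)
        r = len(ns)
        if r < 2:
            continue
        ns_a = np.asarray(ns, float)
        ps_a = np.asarray(ps, float)
        hs_a = np.asarray(hs, float)
        nbar = ns_a.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - np.sum(ns_a ** 2) / (r * nbar)) / (r - 1)
        pbar = np.sum(ns_a * ps_a) / (r * nbar)
        s2 = np.sum(ns_a * (ps_a - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(ns_a * hs_a) / (r * nbar)
        if nc <= 0:
            continue
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    if den == 0:
        raise UndefinedStatisticError("Fst denominator is zero (no variation)")
    return float(num / den)


def locus_stats(matrix: GenotypeMatrix, locus_id: str) -> LocusStats:
    freqs = allele_frequencies(matrix, locus_id)
    ho = observed_heterozygosity(matrix, locus_id)
    he = expected_heterozygosity(freqs)
    f = fixation_coefficient(ho, he) if he > 0 else None
    return LocusStats(
        locus_id=locus_id, ho=ho, he=he, pic=pic(freqs), f=f,
        hwe_p=hwe_test(matrix, locus_id), maf=freqs.maf,
        n_typed=freqs.n_copies // 2,
    )


def panel_stats(matrix: GenotypeMatrix) -> list:
    """Per-locus stats for the whole panel (one LocusStats per locus)."""
    return [locus_stats(matrix, lid) for lid in matrix.locus_ids]


def select_panel(candidates: Sequence[LocusStats],
                 ld: Mapping[tuple, tuple] | None = None,
                 maf_min: float = 0.10,
                 r2_max: float = 0.10,
                 alpha: float = 0.05,
                 n_target: int | None = None,
                 keep_as_super_locus: frozenset | set = frozenset()) -> list:
    """Greedy MAF/PIC/LD-aware panel selection.

    Candidates with MAF <= ``maf_min`` are dropped (the retained set has
    minor-allele frequency strictly above the threshold).  Remaining
    candidates are ranked by PIC descending (ties by locus_id) and
    accepted greedily, skipping any locus in significant LD
    (r^2 > ``r2_max`` and p < ``alpha``) with an already-accepted locus
    unless it is flagged ``keep_as_super_locus``.

    ``ld`` maps unordered locus-id pairs (as sorted tuples) to
    ``(r2, p)``; missing pairs are treated as unlinked.
    """
    ld = ld or {}
    pool = [c for c in candidates if c.maf > maf_min]
    if not pool:
        import warnings
        warnings.warn("no candidates pass the MAF filter; empty panel")
        return []
    pool.sort(key=lambda c: (-c.pic, c.locus_id))
    accepted: list = []
    for cand in pool:
        if n_target is not None and len(accepted) >= n_target:
            break
        linked = False
        for acc in accepted:
            key = tuple(sorted((cand.locus_id, acc.locus_id)))
            r2, p = ld.get(key, (0.0, 1.0))
            if r2 > r2_max and p < alpha:
                linked = True
                break
        if linked and cand.locus_id not in keep_as_super_locus:
            continue
        accepted.append(cand)
    return accepted
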