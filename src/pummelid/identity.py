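"""Multilocus genotype matching and forensic identity statistics.

Duplicate/synonym detection treats two accessions as the same genotype
when they show zero mismatches over co-typed loci (pairwise-complete
comparison) and share at least ``min_shared_loci`` typed loci; clusters
are transitive closures of that relation, so missing data never
fabricates a difference.

Probability-of-identity statistics follow the forensic standard:

* PI       = 2 (sum p_i^2)^2 - sum p_i^4             (two random individuals)
* PIsibs   = 1/4 + 1/2 sum p_i^2 + 1/2 (sum p_i^2)^2 - 1/4 sum p_i^4
* PIpar-off (population) = sum p_i^2                  (parent vs offspring)

with multi-locus values the product over independent (effective) loci —
super loci must be recoded first so the product rule holds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .genotype_data import MISSING, GenotypeMatrix
from .marker_stats import AlleleFreqs, LocusStats, UndefinedStatisticError

__all__ = [
    "MatchReport",
    "IdentityStats",
    "match_genotypes",
    "min_diff_distribution",
    "accumulation_curve",
    "pi_random",
    "pi_sibs",
    "pi_par_off",
    "genotype_pi",
    "cumulative_pi",
    "discrimination_capacity",
]


@dataclass
class MatchReport:
    """Clusters of accessions carrying identical multilocus genotypes."""

    clusters: list            # list of lists of accession ids (input order)
    unplaceable: list         # accessions typed at too few loci
    min_shared_loci: int

    @property
    def n_distinct(self) -> int:
        return len(self.clusters)

    def cluster_of(self, accession_id: str) -> Optional[list]:
        for c in self.clusters:
            if accession_id in c:
                return c
        return None


def _encode_cells(matrix: GenotypeMatrix) -> np.ndarray:
    """Integer-encode genotype cells per locus (missing = -1)."""
    n, L = matrix.n_accessions, matrix.n_loci
    codes = np.full((n, L), -1, dtype=np.int32)
    for j in range(L):
        seen: dict = {}
        for i in range(n):
            g = matrix.cells[i][j]
            if g is MISSING:
                continue
            if g not in seen:
                seen[g] = len(seen)
            codes[i, j] = seen[g]
    return codes


def _pair_diff(row_a: Sequence, row_b: Sequence) -> tuple:
    """(number of differing co-typed loci, number of co-typed loci)."""
    shared = diffs = 0
    for ga, gb in zip(row_a, row_b):
        if ga is MISSING or gb is MISSING:
            continue
        shared += 1
        if ga != gb:
            diffs += 1
    return diffs, shared


def match_genotypes(matrix: GenotypeMatrix,
                    max_mismatch: int = 0,
                    min_shared_loci: int = 6) -> MatchReport:
    """Group accessions into identical-genotype clusters.

    Two accessions match iff they differ at <= ``max_mismatch`` co-typed
    loci and are co-typed at >= ``min_shared_loci`` loci.  Clusters are
    transitive closures of the match relation.  Accessions typed at
    fewer than ``min_shared_loci`` loci overall are unplaceable and
    excluded from the distinct-genotype count.
    """
    ids = matrix.accession_ids
    codes = _encode_cells(matrix)
    typed_counts = (codes >= 0).sum(axis=1)
    placeable = [i for i, t in enumerate(typed_counts)
                 if t >= min_shared_loci]
    unplaceable = [ids[i] for i, t in enumerate(typed_counts)
                   if t < min_shared_loci]

    # collapse byte-identical rows first: identical rows always co-cluster
    row_key = {i: codes[i].tobytes() for i in placeable}
    reps: dict = {}
    members: dict = {}
    for i in placeable:
        k = row_key[i]
        if k not in reps:
            reps[k] = i
            members[k] = []
        members[k].append(i)
    rep_idx = list(reps.values())

    parent = {i: i for i in rep_idx}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a_pos, i in enumerate(rep_idx):
        a = codes[i]
        for j in rep_idx[a_pos + 1:]:
            b = codes[j]
            shared = (a >= 0) & (b >= 0)
            if int(shared.sum()) < min_shared_loci:
                continue
            if int(((a != b) & shared).sum()) <= max_mismatch:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict = {}
    for k, rep in reps.items():
        groups.setdefault(find(rep), []).extend(members[k])
    clusters = [sorted(groups[r]) for r in sorted(groups)]
    return MatchReport(clusters=[[ids[i] for i in c] for c in clusters],
                       unplaceable=unplaceable,
                       min_shared_loci=min_shared_loci)


def min_diff_distribution(matrix: GenotypeMatrix,
                          report: MatchReport) -> dict:
    """Minimum pairwise locus differences between distinct genotypes.

    Each cluster is represented by its first member (input order); for
    each distinct genotype the minimum over all others of the count of
    differing co-typed loci is reported, with histogram, mean and min.
    """
    if report.n_distinct < 2:
        return {"min_diffs": {}, "histogram": {}, "mean": None, "min": None}
    reps = [c[0] for c in report.clusters]
    rows = {r: matrix.row(r) for r in reps}
    min_diffs = {}
    for a in reps:
        best = None
        for b in reps:
            if a == b:
                continue
            diffs, shared = _pair_diff(rows[a], rows[b])
            if shared == 0:
                continue
            if best is None or diffs < best:
                best = diffs
        min_diffs[a] = best
    values = [v for v in min_diffs.values() if v is not None]
    hist: dict = {}
    for v in values:
        hist[v] = hist.get(v, 0) + 1
    return {
        "min_diffs": min_diffs,
        "histogram": dict(sorted(hist.items())),
        "mean": float(np.mean(values)) if values else None,
        "min": int(min(values)) if values else None,
    }


def accumulation_curve(matrix: GenotypeMatrix,
                       stats: Sequence[LocusStats],
                       max_mismatch: int = 0,
                       min_shared_loci: int = 6) -> list:
    """Distinct-genotype counts as loci are added in PIC-descending order.

    Entry k (1-based) is the number of distinct genotypes using the k
    highest-PIC loci (ties broken by locus_id).  The shared-loci floor is
    capped at k so early points remain defined.
    """
    order = [s.locus_id for s in
             sorted(stats, key=lambda s: (-s.pic, s.locus_id))]
    curve = []
    for k in range(1, len(order) + 1):
        sub = matrix.subset_loci(order[:k])
        rep = match_genotypes(sub, max_mismatch=max_mismatch,
                              min_shared_loci=min(min_shared_loci, k))
        curve.append(rep.n_distinct)
    return curve


# -- probability-of-identity statistics --------------------------------

def _p(freqs) -> np.ndarray:
    arr = freqs.p if isinstance(freqs, AlleleFreqs) else np.asarray(freqs, float)
    if arr.size == 0 or abs(arr.sum() - 1.0) > 1e-6 or np.any(arr < 0):
        raise ValueError("invalid frequency vector")
    return arr


def pi_random(freqs) -> float:
    """Probability two random HWE individuals share a genotype."""
    p = _p(freqs)
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    return 2 * s2 ** 2 - s4


def pi_sibs(freqs) -> float:
    """Probability two full sibs share a genotype (HWE parents)."""
    p = _p(freqs)
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    return 0.25 + 0.5 * s2 + 0.5 * s2 ** 2 - 0.25 * s4


def pi_par_off(freqs) -> float:
    """Probability a parent and its offspring share a genotype.

    Algebraically equal to sum p_i^2 (the offspring must receive the
    parent's other allele from the population).
    """
    p = _p(freqs)
    return float(np.sum(p ** 2))


def genotype_pi(genotype: tuple, freqs) -> tuple:
    """(PI_g, PIsibs_g, PIpar-off_g) for one specific genotype.

    PI_g is the HWE frequency of the genotype; the sib and parent-
    offspring values are the standard forensic conditional forms.
    """
    fmap = dict(freqs.freqs) if isinstance(freqs, AlleleFreqs) else dict(freqs)
    a, b = genotype
    pa = fmap.get(a, 0.0)
    pb = fmap.get(b, 0.0)
    if pa <= 0 or pb <= 0:
        raise ValueError(f"genotype allele with zero frequency: {genotype}")
    if a == b:
        return pa * pa, (1 + pa) ** 2 / 4, pa
    return (2 * pa * pb,
            (1 + pa + pb + 2 * pa * pb) / 4,
            (pa + pb) / 2)


def cumulative_pi(locus_freqs: Sequence) -> dict:
    """Multi-locus identity probabilities under the independence product rule.

    ``locus_freqs`` is one frequency vector (AlleleFreqs or sequence)
    per effective locus — super loci contribute their EM haplotype
    frequencies once, not one entry per member SNP.  Returns the running
    products and the -log10(PI) trajectories.
    """
    pi_t = pis_t = pipo_t = 1.0
    traj_pi, traj_pis, traj_pipo = [], [], []
    for freqs in locus_freqs:
        pi_t *= pi_random(freqs)
        pis_t *= pi_sibs(freqs)
        pipo_t *= pi_par_off(freqs)
        traj_pi.append(-math.log10(pi_t))
        traj_pis.append(-math.log10(pis_t))
        traj_pipo.append(-math.log10(pipo_t))
    return {
        "pi": pi_t, "pi_sibs": pis_t, "pi_par_off": pipo_t,
        "neg_log10_pi": traj_pi,
        "neg_log10_pi_sibs": traj_pis,
        "neg_log10_pi_par_off": traj_pipo,
    }


def discrimination_capacity(pi_total: float,
                            confidence: float = 0.95,
                            mode: str = "pairwise") -> int:
    """Largest collection size identifiable at the given confidence.

    pairwise mode: largest n with (1 - PI)^(n(n-1)/2) >= confidence —
    no false identical pair among all n(n-1)/2 pairs.  query mode:
    largest n with n * PI <= 1 - confidence — a queried genotype has no
    false match in the collection.
    """
    if not (0 < pi_total < 1):
        raise ValueError("PI must lie in (0, 1)")
    if mode == "pairwise":
        m = math.log(confidence) / math.log1p(-pi_total)  # max pair count
        n = int((1 + math.sqrt(1 + 8 * m)) / 2)
        while n * (n - 1) / 2 > m:
            n -= 1
        while (n + 1) * n / 2 <= m:
            n += 1
        return n
    if mode == "query":
        if pi_total > 1 - confidence:
            warnings.warn("PI exceeds the error budget; capacity 0")
            return 0
        return int(math.floor((1 - confidence) / pi_total))
    raise ValueError(f"unknown mode {mode!r}")
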