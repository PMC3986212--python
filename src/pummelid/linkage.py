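"""EM haplotype-frequency estimation, LD r-squared, and super loci.

Markers in significant linkage disequilibrium (r^2 > 0.1 at p < 0.05,
permutation test) are merged into "super loci": connected components of
the significant-LD graph, each treated downstream as one multi-allelic
locus whose alleles are the EM-inferred haplotypes.  This keeps the
product rule for identity probabilities honest, at the price of counting
each merged group once in the effective locus tally.

The EM engine works over unphased multilocus genotypes aggregated into
genotype classes; it is shared with segment phasing
(:mod:`pummelid.segment_analysis`).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .genotype_data import (
    MISSING,
    Accession,
    DerivedLocus,
    GenotypeMatrix,
)
from .marker_stats import UndefinedStatisticError

__all__ = [
    "HaplotypeFreqs",
    "SuperLocus",
    "SuperLocusSet",
    "em_haplotype_frequencies",
    "ld_r2",
    "ld_significance",
    "build_super_loci",
    "effective_locus_count",
]

EM_TOL = 1e-8
EM_MAX_ITER = 1000


@dataclass
class HaplotypeFreqs:
    """EM-estimated haplotype frequencies over a set of member loci."""

    member_loci: tuple
    freqs: dict  # haplotype (allele tuple) -> proportion
    loglik: float
    n_iter: int
    converged: bool = True
    tie_flag: bool = False  # symmetric double-het likelihood tie observed

    def __post_init__(self):
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")

    def pair_posteriors(self, genotype_row: Sequence[tuple]) -> dict:
        """Posterior over unordered haplotype pairs for one unphased genotype."""
        pairs = _compatible_pairs(tuple(genotype_row))
        w = {}
        for h1, h2 in pairs:
            f1 = self.freqs.get(h1, 0.0)
            f2 = self.freqs.get(h2, 0.0)
            w[(h1, h2)] = (1 if h1 == h2 else 2) * f1 * f2
        total = sum(w.values())
        if total <= 0:
            return {p: 1.0 / len(pairs) for p in pairs}
        return {p: v / total for p, v in w.items()}


def _compatible_pairs(genotype_row: tuple) -> list:
    """Unordered haplotype pairs consistent with an unphased genotype.

    Heterozygous loci contribute a binary phase choice; the first
    heterozygous locus is pinned to break the h1/h2 symmetry, so each
    unordered pair appears exactly once.
    """
    het_idx = [i for i, g in enumerate(genotype_row) if g[0] != g[1]]
    base1 = [g[0] for g in genotype_row]
    base2 = [g[1] for g in genotype_row]
    if not het_idx:
        h = tuple(base1)
        return [(h, h)]
    free = het_idx[1:]
    pairs = []
    for flips in itertools.product((False, True), repeat=len(free)):
        h1, h2 = list(base1), list(base2)
        for i, flip in zip(free, flips):
            if flip:
                h1[i], h2[i] = h2[i], h1[i]
        pairs.append(tuple(sorted((tuple(h1), tuple(h2)))))
    return pairs


def em_haplotype_frequencies(matrix: GenotypeMatrix,
                             locus_ids: Sequence[str],
                             tol: float = EM_TOL,
                             max_iter: int = EM_MAX_ITER) -> HaplotypeFreqs:
    """EM over unphased multilocus genotypes at ``locus_ids``.

    Only accessions typed at every member locus contribute.  The
    haplotype space is restricted to haplotypes compatible with at least
    one observed genotype.  Deterministic uniform initialization;
    convergence when max |delta freq| < ``tol``.
    """
    idx = [matrix.locus_index(l) for l in locus_ids]
    rows = []
    for row in matrix.cells:
        g = tuple(row[j] for j in idx)
        if all(c is not MISSING for c in g):
            rows.append(g)
    if len(rows) < 1:
        raise UndefinedStatisticError(
            "no accession fully typed at the member loci")
    return em_from_genotype_rows(rows, tuple(locus_ids), tol=tol,
                                 max_iter=max_iter)


def em_from_genotype_rows(rows: Sequence[tuple],
                          member_loci: tuple,
                          tol: float = EM_TOL,
                          max_iter: int = EM_MAX_ITER) -> HaplotypeFreqs:
    """EM core over pre-extracted, fully-typed genotype rows."""
    classes: dict = {}
    for g in rows:
        classes[g] = classes.get(g, 0) + 1
    class_pairs = {g: _compatible_pairs(g) for g in classes}
    hap_set = sorted({h for pairs in class_pairs.values()
                      for h1, h2 in pairs for h in (h1, h2)})
    hap_index = {h: k for k, h in enumerate(hap_set)}
    H = len(hap_set)
    n = sum(classes.values())

    # flattened pair encoding across classes for vectorized E/M steps
    class_list = list(classes)
    C = len(class_list)
    cnt = np.array([classes[g] for g in class_list], dtype=float)
    ci_l, i_l, j_l, m_l = [], [], [], []
    for c, g in enumerate(class_list):
        for p in class_pairs[g]:
            ci_l.append(c)
            i_l.append(hap_index[p[0]])
            j_l.append(hap_index[p[1]])
            m_l.append(1.0 if p[0] == p[1] else 2.0)
    ci = np.array(ci_l)
    pi_ = np.array(i_l)
    pj = np.array(j_l)
    pm = np.array(m_l)

    f = np.full(H, 1.0 / H)
    loglik = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        w = pm * f[pi_] * f[pj]
        tot = np.bincount(ci, weights=w, minlength=C)
        dead = tot <= 0
        if dead.any():
            w = np.where(dead[ci], 1.0, w)
            tot = np.bincount(ci, weights=w, minlength=C)
        ll = float(np.sum(cnt * np.where(dead, -745.0, np.log(np.maximum(tot, 1e-320)))))
        wn = w / tot[ci] * cnt[ci]
        new = (np.bincount(pi_, weights=wn, minlength=H)
               + np.bincount(pj, weights=wn, minlength=H)) / (2.0 * n)
        if ll < loglik - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        delta = np.max(np.abs(new - f))
        f = new
        loglik = ll
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("haplotype EM did not converge; returning best estimate")

    # tie flag: double-het classes with two equally likely phasings
    tie = False
    for c, g in enumerate(class_list):
        sel = ci == c
        if sel.sum() == 2:
            w = pm[sel] * f[pi_[sel]] * f[pj[sel]]
            if w.sum() > 0 and abs(w[0] - w[1]) / w.sum() < 1e-9:
                tie = True
    freqs = {h: float(f[hap_index[h]]) for h in hap_set}
    # renormalize away accumulated float error
    total = sum(freqs.values())
    freqs = {h: v / total for h, v in freqs.items()}
    return HaplotypeFreqs(member_loci=tuple(member_loci), freqs=freqs,
                          loglik=float(loglik), n_iter=n_iter,
                          converged=converged, tie_flag=tie)


# -- pairwise LD --------------------------------------------------------

def ld_r2(hapfreqs: HaplotypeFreqs) -> tuple:
    """(D, r^2) for a two-locus bi-allelic haplotype frequency estimate.

    D = p_AB - p_A p_B and r^2 = D^2 / (p_A(1-p_A) p_B(1-p_B)), where A
    and B are the lexicographically first allele observed at each locus.
    """
    if len(hapfreqs.member_loci) != 2:
        raise ValueError("ld_r2 requires a two-locus estimate")
    alleles0 = sorted({h[0] for h in hapfreqs.freqs})
    alleles1 = sorted({h[1] for h in hapfreqs.freqs})
    p_a = sum(v for h, v in hapfreqs.freqs.items() if h[0] == alleles0[0])
    p_b = sum(v for h, v in hapfreqs.freqs.items() if h[1] == alleles1[0])
    if len(alleles0) < 2 or len(alleles1) < 2 or min(p_a, 1 - p_a) < 1e-12 \
            or min(p_b, 1 - p_b) < 1e-12:
        raise UndefinedStatisticError("r^2 undefined at a monomorphic locus")
    p_ab = sum(v for h, v in hapfreqs.freqs.items()
               if h[0] == alleles0[0] and h[1] == alleles1[0])
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return float(d), float(r2)


def _pair_r2_from_rows(rows: Sequence[tuple]) -> float:
    """r^2 via EM on two-locus genotype rows; 0 if undefined (monomorphic)."""
    try:
        hf = em_from_genotype_rows(rows, ("L1", "L2"))
        return ld_r2(hf)[1]
    except UndefinedStatisticError:
        return 0.0


def ld_significance(matrix: GenotypeMatrix,
                    pair: tuple,
                    n_perm: int = 10_000,
                    seed: int = 0) -> float:
    """Permutation p-value for LD between two loci.

    One locus's genotype column is permuted across accessions; the
    statistic is r^2 from a re-run EM.  p = (1 + #{perm >= obs}) /
    (n_perm + 1).  Requires >= 10 accessions typed at both loci.
    """
    ja = matrix.locus_index(pair[0])
    jb = matrix.locus_index(pair[1])
    col_a = [row[ja] for row in matrix.cells]
    col_b = [row[jb] for row in matrix.cells]
    shared = [(a, b) for a, b in zip(col_a, col_b)
              if a is not MISSING and b is not MISSING]
    if len(shared) < 10:
        raise UndefinedStatisticError(
            f"loci {pair}: fewer than 10 accessions typed at both")
    obs = _pair_r2_from_rows(shared)
    rng = np.random.default_rng(seed)
    col_b_arr = list(col_b)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(col_b_arr))
        rows = [(a, col_b_arr[k]) for a, k in zip(col_a, perm)
                if a is not MISSING and col_b_arr[k] is not MISSING]
        if len(rows) < 2:
            continue
        if _pair_r2_from_rows(rows) >= obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


# -- super loci ---------------------------------------------------------

@dataclass
class SuperLocus:
    """An LD-merged marker recoded as one multi-allelic locus."""

    super_id: str
    member_loci: tuple
    hapfreqs: HaplotypeFreqs
    #: accession_id -> unordered pair of haplotype labels, or MISSING
    assignments: dict = field(default_factory=dict)
    #: haplotype tuple -> compact allele label ("AG", "TCA", ...)
    labels: dict = field(default_factory=dict)

    @property
    def alleles(self) -> tuple:
        return tuple(self.labels[h] for h in sorted(self.labels))


@dataclass
class SuperLocusSet:
    super_loci: list
    singleton_locus_ids: list
    effective_count: int
    ld_table: dict  # sorted pair -> (r2, p) for evaluated pairs


def effective_locus_count(n_loci: int, component_sizes: Sequence[int]) -> int:
    """Singletons plus one per merged group of >= 2 linked markers."""
    comp = [s for s in component_sizes if s >= 2]
    return n_loci - sum(comp) + len(comp)


def build_super_loci(matrix: GenotypeMatrix,
                     r2_threshold: float = 0.1,
                     alpha: float = 0.05,
                     n_perm: int = 1000,
                     seed: int = 0,
                     posterior_min: float = 0.95) -> SuperLocusSet:
    """Find significant-LD components and recode them as super loci.

    A pair is significant iff r^2 > ``r2_threshold`` AND permutation
    p < ``alpha``; the permutation test is only run for pairs already
    clearing the r^2 threshold (pairs below it cannot be significant).
    Components of size >= 2 of the significant-pair graph become super
    loci.  Each accession typed at all member loci is recoded to its
    most probable haplotype pair; below ``posterior_min`` posterior the
    recoded genotype is MISSING.
    """
    locus_ids = matrix.locus_ids
    graph = nx.Graph()
    graph.add_nodes_from(locus_ids)
    ld_table: dict = {}
    for la, lb in itertools.combinations(locus_ids, 2):
        key = tuple(sorted((la, lb)))
        try:
            hf = em_haplotype_frequencies(matrix, [la, lb])
            _, r2 = ld_r2(hf)
        except UndefinedStatisticError:
            continue
        if r2 <= r2_threshold:
            ld_table[key] = (r2, 1.0)
            continue
        try:
            p = ld_significance(matrix, (la, lb), n_perm=n_perm, seed=seed)
        except UndefinedStatisticError:
            # too few co-typed accessions to test: never significant
            ld_table[key] = (r2, 1.0)
            continue
        ld_table[key] = (r2, p)
        if p < alpha:
            graph.add_edge(la, lb)

    super_loci = []
    merged: set = set()
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph) if len(c) >= 2),
        key=lambda c: c[0],
    )
    for k, members in enumerate(components, start=1):
        hf = em_haplotype_frequencies(matrix, members)
        labels = {h: "".join(h) for h in hf.freqs}
        assignments = {}
        idx = [matrix.locus_index(l) for l in members]
        for acc, row in zip(matrix.accessions, matrix.cells):
            g = tuple(row[j] for j in idx)
            if any(c is MISSING for c in g):
                assignments[acc.accession_id] = MISSING
                continue
            post = hf.pair_posteriors(g)
            best_pair, best_p = max(post.items(), key=lambda kv: kv[1])
            if best_p < posterior_min:
                assignments[acc.accession_id] = MISSING
            else:
                pair = tuple(sorted((labels[best_pair[0]],
                                     labels[best_pair[1]])))
                assignments[acc.accession_id] = pair
        super_loci.append(SuperLocus(
            super_id=f"SL{k}_{members[0]}", member_loci=tuple(members),
            hapfreqs=hf, assignments=assignments, labels=labels,
        ))
        merged.update(members)

    singletons = [l for l in locus_ids if l not in merged]
    eff = effective_locus_count(
        len(locus_ids), [len(s.member_loci) for s in super_loci])
    return SuperLocusSet(super_loci=super_loci,
                         singleton_locus_ids=singletons,
                         effective_count=eff, ld_table=ld_table)


def recode_matrix(matrix: GenotypeMatrix, sls: SuperLocusSet) -> GenotypeMatrix:
    """Matrix with super-locus members replaced by one derived locus each.

    Singleton loci keep their position order; each super locus is placed
    at the position of its first member.
    """
    keep = {l: i for i, l in enumerate(matrix.locus_ids)}
    entries = [(keep[l], ("locus", l)) for l in sls.singleton_locus_ids]
    entries += [(keep[s.member_loci[0]], ("super", s)) for s in sls.super_loci]
    entries.sort(key=lambda e: e[0])

    loci: list = []
    columns: list = []
    for _, (kind, obj) in entries:
        if kind == "locus":
            loci.append(matrix.loci[matrix.locus_index(obj)])
            columns.append(matrix.column(obj))
        else:
            alleles = tuple(sorted(set(obj.labels.values())))
            loci.append(DerivedLocus(locus_id=obj.super_id, alleles=alleles))
            columns.append([obj.assignments[a] for a in matrix.accession_ids])
    cells = [[columns[j][i] for j in range(len(loci))]
             for i in range(matrix.n_accessions)]
    return GenotypeMatrix(accessions=list(matrix.accessions),
                          loci=loci, cells=cells)
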