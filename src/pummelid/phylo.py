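"""Tajima-Nei distances, neighbour joining, and hybrid screening.

Haplotypes inferred from the sequenced segments are placed against
reference sequences of known taxon class (pummelo, mandarin, optional
outgroup).  An accession carrying one or more haplotypes whose nearest
reference is non-pummelo is flagged as a putative interspecific hybrid —
a distance-based reading of the usual visual tree inspection, chosen
because clade-membership tests are brittle on segments of a few hundred
bp.

The distance is the equal-input Tajima-Nei form d = -b ln(1 - p/b) with
p the mismatch proportion and b = 1 - sum q_i^2 over pooled base
frequencies; at uniform composition it reduces to Jukes-Cantor
(b = 0.75).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "SaturationError",
    "tajima_nei_distance",
    "distance_matrix",
    "neighbor_joining",
    "classify_haplotypes",
    "flag_hybrids",
]

_VALID = frozenset("ACGT")


class SaturationError(ValueError):
    """Mismatch proportion at or beyond the model's saturation bound."""


def tajima_nei_distance(seq_a: str, seq_b: str) -> float:
    """Equal-input Tajima-Nei distance between two aligned sequences.

    Sites with N/gap in either sequence are excluded.  Raises
    :class:`SaturationError` when p >= b.
    """
    pairs = [(a, b) for a, b in zip(seq_a.upper(), seq_b.upper())
             if a in _VALID and b in _VALID]
    if not pairs:
        raise ValueError("no comparable sites")
    n = len(pairs)
    mismatches = sum(1 for a, b in pairs if a != b)
    p = mismatches / n
    if p == 0.0:
        return 0.0
    pooled: dict = {}
    for a, b in pairs:
        pooled[a] = pooled.get(a, 0) + 1
        pooled[b] = pooled.get(b, 0) + 1
    total = 2 * n
    b_coef = 1.0 - sum((c / total) ** 2 for c in pooled.values())
    if p >= b_coef:
        raise SaturationError(
            f"mismatch proportion {p:.4f} >= b {b_coef:.4f}; distance undefined")
    return -b_coef * math.log(1.0 - p / b_coef)


@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if (m < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def distance_matrix(sequences: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise Tajima-Nei distance matrix over labeled sequences."""
    labels = list(sequences)
    n = len(labels)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = tajima_nei_distance(sequences[labels[i]], sequences[labels[j]])
        m[i, j] = m[j, i] = d
    return DistanceMatrix(labels=labels, matrix=m)


@dataclass
class _Node:
    label: Optional[str] = None
    children: list = field(default_factory=list)  # (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(f"{c.newick()}:{bl:.10g}"
                         for c, bl in self.children)
        return f"({inner})"


@dataclass
class PhyloTree:
    """Unrooted NJ tree with leaf labels and non-negative branch lengths."""

    root: _Node
    labels: list
    clamped_branches: int = 0  # negative NJ lengths clamped to zero

    def newick(self) -> str:
        return self.root.newick() + ";"

    def as_dendropy(self):
        import dendropy
        return dendropy.Tree.get(data=self.newick(), schema="newick")


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by (label-order) smallest pair.
    Negative branch lengths are clamped to zero and counted.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("NJ needs at least 3 labels")
    nodes = [_Node(label=l) for l in dm.labels]
    d = {frozenset((i, j)): dm.matrix[i, j]
         for i, j in itertools.combinations(range(n), 2)}
    active = dict(enumerate(nodes))
    clamped = 0

    def dist(i, j):
        return d[frozenset((i, j))]

    while len(active) > 2:
        keys = sorted(active)
        r = len(keys)
        sums = {i: sum(dist(i, k) for k in keys if k != i) for i in keys}
        best = None
        for i, j in itertools.combinations(keys, 2):
            q = (r - 2) * dist(i, j) - sums[i] - sums[j]
            cand = (q, i, j)
            if best is None or cand < best:
                best = cand
        _, i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            li, clamped = 0.0, clamped + 1
        if lj < 0:
            lj, clamped = 0.0, clamped + 1
        new = _Node(children=[(active[i], li), (active[j], lj)])
        new_key = max(active) + 1
        for k in keys:
            if k in (i, j):
                continue
            d[frozenset((new_key, k))] = 0.5 * (dist(i, k) + dist(j, k) - dij)
        del active[i], active[j]
        active[new_key] = new

    (ka, na), (kb, nb) = sorted(active.items())
    final = dist(ka, kb)
    if final < 0:
        final, clamped = 0.0, clamped + 1
    # The single remaining edge carries its full length.  Root the
    # serialization at an internal node so a leaf on this edge keeps its
    # pendant branch length.
    if na.children:
        parent, child = na, nb
    else:
        parent, child = nb, na
    root = _Node(children=parent.children + [(child, final)])
    return PhyloTree(root=root, labels=list(dm.labels),
                     clamped_branches=clamped)


# -- hybrid screening ---------------------------------------------------

def classify_haplotypes(haplotypes: Mapping[str, str],
                        references: Mapping[str, tuple]) -> dict:
    """Assign each haplotype the class of its nearest reference.

    ``references`` maps reference label -> (class, sequence).  Exact
    distance ties between different classes yield class ``"ambiguous"``.
    """
    out = {}
    for hap_label, hap_seq in haplotypes.items():
        best_d = None
        best_classes: set = set()
        for _, (cls, ref_seq) in references.items():
            try:
                d = tajima_nei_distance(hap_seq, ref_seq)
            except SaturationError:
                d = math.inf  # beyond the model: never the nearest reference
            if best_d is None or d < best_d - 1e-12:
                best_d, best_classes = d, {cls}
            elif d == best_d or abs(d - best_d) <= 1e-12:
                best_classes.add(cls)
        out[hap_label] = (next(iter(best_classes))
                          if len(best_classes) == 1 else "ambiguous")
    return out


def flag_hybrids(table, references: Mapping[str, Mapping[str, tuple]],
                 pummelo_class: str = "pummelo") -> dict:
    """Count non-pummelo haplotypes per accession across segments.

    ``table`` is a :class:`~pummelid.segment_analysis.HaplotypeTable`
    with haplotype sequences; ``references[segment]`` maps reference
    label -> (class, sequence).  Returns per-accession
    ``{"counts": {segment: n_non_pummelo}, "total", "is_hybrid"}``;
    ambiguous assignments are never counted as evidence.
    """
    per_segment_class: dict = {}
    for seg in table.segments:
        refs = references.get(seg)
        if not refs:
            continue
        haps = {hid: seq for (s, hid), seq in table.haplotypes.items()
                if s == seg}
        classes = classify_haplotypes(
            {str(h): seq for h, seq in haps.items()}, refs)
        per_segment_class[seg] = {int(h): c for h, c in classes.items()}

    result: dict = {}
    for acc in table.accessions:
        counts: dict = {}
        for seg, classes in per_segment_class.items():
            pair = table.pair(acc, seg)
            if pair is None:
                continue
            bad = sum(1 for h in pair
                      if classes.get(h) not in (pummelo_class, "ambiguous", None))
            if bad:
                counts[seg] = bad
        total = sum(counts.values())
        result[acc] = {"counts": counts, "total": total,
                       "is_hybrid": total > 0}
    return result
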