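"""Synthetic data emulating a structured pummelo germplasm collection.

Two generators:

* :func:`simulate_genotypes` — a diploid SNP collection with population
  structure (Balding-Nichols subpopulation allele frequencies at a
  target Fst), clonal groups (a cultivar plus somatic mutants sharing
  its genotype exactly), unique sexually-derived seedlings, and optional
  missing data and genotyping error.
* :func:`simulate_segments` — aligned sequence segments (410-631 bp,
  1-10 SNPs, 2-9 haplotypes) with per-class haplotype pools (pummelo
  vs a diverged mandarin pool) so that interspecific hybrids can be
  planted and recovered.

All randomness flows from a single integer seed; identical seeds give
byte-identical CSV/FASTA output.  Defaults mirror the emulated study
scale: 260 accessions over 25 SNPs (178 distinct genotypes: 123
cultivar genotypes in clonal groups plus 55 unique seedlings), 12
segments, 4 subpopulations at Fst 0.16, minor-allele frequencies above
0.10.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genotype_data import Accession, GenotypeMatrix, LocusMeta, MISSING, genotype

__all__ = [
    "PopulationModel",
    "CollectionDesign",
    "SegmentModel",
    "simulate_genotypes",
    "simulate_segments",
    "default_collection_design",
]

_MAX_LOCUS_TRIES = 1000


@dataclass
class PopulationModel:
    """Balding-Nichols population structure for the SNP generator."""

    k: int = 4
    fst: float = 0.16
    n_loci: int = 25
    maf_range: tuple = (0.10, 0.5)
    admixture_alpha: Optional[float] = None  # None = pure deme membership
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.fst < 1):
            raise ValueError("fst must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")


@dataclass
class CollectionDesign:
    """Composition of the simulated collection.

    ``clone_group_sizes`` lists one entry per cultivar genotype: the
    founder plus its somatic mutants / resampled individuals (size 1 =
    a singleton cultivar).  ``n_seedlings`` adds that many all-unique
    sexually derived genotypes (the Myanmar-like component).
    """

    clone_group_sizes: Sequence[int] = (3, 2, 1, 1, 1)
    n_seedlings: int = 5
    missing_rate: float = 0.0
    genotyping_error_rate: float = 0.0
    error_mode: str = "replacement"  # or "swap" (whole-profile swaps)

    def __post_init__(self):
        if any(s < 1 for s in self.clone_group_sizes):
            raise ValueError("clone group sizes must be >= 1")
        if not (0 <= self.missing_rate < 1 and
                0 <= self.genotyping_error_rate < 1):
            raise ValueError("rates must lie in [0, 1)")

    @property
    def n_accessions(self) -> int:
        return sum(self.clone_group_sizes) + self.n_seedlings

    @property
    def n_genotypes(self) -> int:
        return len(self.clone_group_sizes) + self.n_seedlings


def default_collection_design(missing_rate: float = 0.0,
                              genotyping_error_rate: float = 0.0) -> CollectionDesign:
    """Study-scale default: 260 accessions, 178 genotypes, 55 seedlings."""
    return CollectionDesign(
        clone_group_sizes=tuple([3] * 12 + [2] * 58 + [1] * 53),
        n_seedlings=55,
        missing_rate=missing_rate,
        genotyping_error_rate=genotyping_error_rate,
    )


def _draw_deme_freqs(rng, p_anc: float, fst: float, k: int) -> np.ndarray:
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    return rng.beta(a, b, size=k)


def simulate_genotypes(model: PopulationModel,
                       design: CollectionDesign) -> tuple:
    """Simulate a collection; returns ``(matrix, truth)``.

    Ancestral minor-allele frequencies are uniform in ``maf_range``;
    subpopulation frequencies follow Balding-Nichols
    Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst).  Founders and seedlings are
    HWE draws within their deme (or admixed via a Dirichlet over demes
    when ``admixture_alpha`` is set); clones copy their founder exactly.
    A locus is redrawn if the realized founder-level MAF falls outside
    ``maf_range`` (ascertainment emulation: panels are built from
    markers that survived a frequency screen).  Missing data and
    genotyping error are applied last, clones included.

    ``truth`` records deme labels, the planted clone partition, and the
    per-deme allele frequencies.
    """
    rng = np.random.default_rng(model.seed)
    n_geno = design.n_genotypes
    if n_geno < 1:
        raise ValueError("design yields no genotypes")

    # deme assignment per founder/seedling; seedlings spread across demes
    demes = np.array([i % model.k for i in range(n_geno)])
    if model.admixture_alpha:
        w = rng.dirichlet([model.admixture_alpha] * model.k, size=n_geno)
    else:
        w = np.zeros((n_geno, model.k))
        w[np.arange(n_geno), demes] = 1.0

    lo, hi = model.maf_range
    alleles = ("A", "G")
    founder_geno = np.zeros((n_geno, model.n_loci), dtype=int)  # minor-allele dosage
    deme_freqs = np.zeros((model.k, model.n_loci))
    anc = np.zeros(model.n_loci)
    for j in range(model.n_loci):
        for _ in range(_MAX_LOCUS_TRIES):
            p_anc = rng.uniform(lo, hi)
            pk = _draw_deme_freqs(rng, p_anc, model.fst, model.k)
            p_ind = w @ pk
            dosage = rng.binomial(2, p_ind)
            maf_real = dosage.sum() / (2 * n_geno)
            if lo <= min(maf_real, 1 - maf_real) and maf_real not in (0.0, 1.0):
                break
        else:
            raise RuntimeError("could not realize a locus inside maf_range")
        founder_geno[:, j] = dosage
        deme_freqs[:, j] = pk
        anc[j] = p_anc

    # expand founders into clone groups, then append seedlings
    loci = [
        LocusMeta(locus_id=f"S{j + 1:02d}", chromosome=str(j % 9 + 1),
                  position=10_000 * (j + 1), alleles=alleles)
        for j in range(model.n_loci)
    ]
    accessions: list = []
    rows: list = []
    clone_partition: list = []
    labels: dict = {}
    geno_idx = 0
    for g, size in enumerate(design.clone_group_sizes):
        group_ids = []
        for c in range(size):
            acc_id = f"C{g + 1:03d}" + (f"_m{c}" if c else "")
            accessions.append(Accession(acc_id, group=f"P{demes[geno_idx] + 1}"))
            rows.append(founder_geno[geno_idx].copy())
            group_ids.append(acc_id)
            labels[acc_id] = int(demes[geno_idx])
        clone_partition.append(group_ids)
        geno_idx += 1
    for s in range(design.n_seedlings):
        acc_id = f"M{s + 1:03d}"
        accessions.append(Accession(acc_id, group=f"P{demes[geno_idx] + 1}"))
        rows.append(founder_geno[geno_idx].copy())
        clone_partition.append([acc_id])
        labels[acc_id] = int(demes[geno_idx])
        geno_idx += 1

    dosage = np.vstack(rows)
    n_acc = dosage.shape[0]

    # genotyping error
    if design.genotyping_error_rate > 0:
        if design.error_mode == "replacement":
            mask = rng.random((n_acc, model.n_loci)) < design.genotyping_error_rate
            p_cols = dosage.sum(axis=0) / (2 * n_acc)
            repl = rng.binomial(2, np.broadcast_to(p_cols, dosage.shape))
            dosage = np.where(mask, repl, dosage)
        elif design.error_mode == "swap":
            n_swaps = rng.binomial(n_acc, design.genotyping_error_rate)
            for _ in range(n_swaps):
                i, j = rng.choice(n_acc, size=2, replace=False)
                dosage[[i, j]] = dosage[[j, i]]
        else:
            raise ValueError(f"unknown error_mode {design.error_mode!r}")

    missing_mask = (rng.random((n_acc, model.n_loci)) < design.missing_rate
                    if design.missing_rate > 0 else None)

    minor, major = alleles
    cells = []
    for i in range(n_acc):
        row = []
        for j in range(model.n_loci):
            if missing_mask is not None and missing_mask[i, j]:
                row.append(MISSING)
            else:
                d = dosage[i, j]
                row.append(genotype(*([minor] * d + [major] * (2 - d))))
        cells.append(row)

    matrix = GenotypeMatrix(accessions=accessions, loci=loci, cells=cells)
    truth = {
        "deme_labels": labels,
        "clone_partition": clone_partition,
        "deme_freqs": deme_freqs,
        "ancestral_freqs": anc,
        "minor_allele": minor,
    }
    return matrix, truth


# -- sequence segments --------------------------------------------------

@dataclass
class SegmentModel:
    """Per-segment haplotype-pool model for the sequence generator."""

    n_segments: int = 12
    length_range: tuple = (410, 631)
    n_snps_range: tuple = (1, 10)
    n_haplotypes_range: tuple = (2, 9)
    dirichlet_alpha: float = 1.0
    mandarin_divergence: float = 0.02  # per-site divergence of the mandarin pool
    seed: int = 0

    def __post_init__(self):
        if self.n_haplotypes_range[0] < 2:
            raise ValueError("need at least 2 haplotypes per segment")


def _mutate(rng, seq: list, positions: Sequence[int]) -> list:
    out = list(seq)
    for pos in positions:
        alt = rng.choice([b for b in "ACGT" if b != out[pos]])
        out[pos] = alt
    return out


def simulate_segments(model: SegmentModel,
                      n_accessions: int = 24,
                      hybrid_fraction: float = 0.0,
                      clone_copies: int = 1) -> tuple:
    """Simulate aligned segments; returns ``(alignments, truth)``.

    Per segment, a pummelo haplotype pool is built by planting SNPs on a
    random base sequence (each haplotype a distinct allele combination,
    each SNP polymorphic in the pool); a mandarin pool is the base
    sequence diverged at ``mandarin_divergence`` of its sites, again
    with pool-internal variants.  Diploid accessions draw two pool
    haplotypes from a Dirichlet frequency law; planted hybrids replace
    one haplotype with a mandarin one at a random subset of segments.

    ``truth`` carries the phased haplotype pairs, pool frequencies, the
    hybrid labels, and per-class reference sequences for the screening
    stage.  With ``clone_copies`` > 1, each haploid copy is emitted that
    many times (sequenced clones).
    """
    from .segment_analysis import HaplotypeTable, SegmentAlignment

    rng = np.random.default_rng(model.seed)
    acc_ids = [f"A{i + 1:03d}" for i in range(n_accessions)]
    n_hybrids = int(round(hybrid_fraction * n_accessions))
    hybrid_ids = set(acc_ids[:n_hybrids])  # deterministic planting
    seg_ids = [f"SEG{s + 1:02d}" for s in range(model.n_segments)]
    # each planted hybrid carries mandarin material in >= 1 segment
    planted: dict = {}
    for acc in sorted(hybrid_ids):
        chosen = [s for s in seg_ids if rng.random() < 0.5]
        if not chosen:
            chosen = [seg_ids[int(rng.integers(model.n_segments))]]
        planted[acc] = set(chosen)

    alignments = []
    cells: dict = {}
    hap_seqs: dict = {}
    references: dict = {}
    pool_freqs: dict = {}
    hybrid_segments: dict = {a: [] for a in acc_ids}

    for s in range(model.n_segments):
        seg_id = f"SEG{s + 1:02d}"
        length = int(rng.integers(model.length_range[0],
                                  model.length_range[1] + 1))
        n_snps = int(rng.integers(model.n_snps_range[0],
                                  model.n_snps_range[1] + 1))
        hi_hap = min(model.n_haplotypes_range[1], 2 ** n_snps)
        lo_hap = min(model.n_haplotypes_range[0], hi_hap)
        n_haps = int(rng.integers(lo_hap, hi_hap + 1))
        base = rng.choice(list("ACGT"), size=length).tolist()
        snp_pos = sorted(rng.choice(length, size=n_snps, replace=False).tolist())

        # distinct allele combinations over the SNP sites, every site polymorphic
        combos: set = set()
        while True:
            combos = {tuple(rng.integers(0, 2, size=n_snps).tolist())
                      for _ in range(n_haps * 4)}
            combos = set(itertools.islice(sorted(combos), n_haps))
            if len(combos) == n_haps and all(
                    len({c[k] for c in combos}) == 2 for k in range(n_snps)):
                break
        alt_alleles = [_mutate(rng, [base[p]], [0])[0] for p in snp_pos]
        pool = []
        for combo in sorted(combos):
            seq = list(base)
            for k, bit in enumerate(combo):
                if bit:
                    seq[snp_pos[k]] = alt_alleles[k]
            pool.append("".join(seq))
        freqs = rng.dirichlet([model.dirichlet_alpha] * n_haps)
        pool_freqs[seg_id] = dict(zip(pool, freqs.tolist()))

        # mandarin pool: diverged base + two internal variants
        n_div = max(1, int(round(model.mandarin_divergence * length)))
        div_pos = rng.choice(length, size=n_div, replace=False).tolist()
        mand_base = _mutate(rng, base, div_pos)
        mand_pool = ["".join(mand_base),
                     "".join(_mutate(rng, mand_base,
                                     rng.choice(length, 2, replace=False).tolist()))]
        references[seg_id] = {
            "pummelo_ref": ("pummelo", pool[0]),
            "mandarin_ref": ("mandarin", mand_pool[0]),
        }

        records = []
        for acc in acc_ids:
            pair_idx = rng.choice(n_haps, size=2, p=freqs)
            seqs = [pool[pair_idx[0]], pool[pair_idx[1]]]
            if acc in hybrid_ids and seg_id in planted[acc]:
                seqs[1] = mand_pool[int(rng.integers(len(mand_pool)))]
                hybrid_segments[acc].append(seg_id)
            ids = []
            for copy, seq in enumerate(seqs, start=1):
                if (seg_id, seq) not in hap_seqs:
                    hap_seqs[(seg_id, seq)] = None
                for clone in range(clone_copies):
                    label = f"{copy}" if clone_copies == 1 else f"{copy}c{clone + 1}"
                    records.append((acc, label, seq))
            cells[(acc, seg_id)] = tuple(seqs)
        alignments.append(SegmentAlignment(segment_id=seg_id, records=records))

    # assign dense per-segment haplotype ids by first occurrence
    id_map: dict = {}
    for seg in [a.segment_id for a in alignments]:
        next_id = 1
        for acc in acc_ids:
            for seq in cells[(acc, seg)]:
                if (seg, seq) not in id_map:
                    id_map[(seg, seq)] = next_id
                    next_id += 1
    table_cells = {
        (acc, seg): tuple(sorted(id_map[(seg, s)] for s in cells[(acc, seg)]))
        for (acc, seg) in cells
    }
    haplotypes = {(seg, i): seq for (seg, seq), i in id_map.items()}
    table = HaplotypeTable(
        accessions=acc_ids,
        segments=[a.segment_id for a in alignments],
        cells=table_cells,
        haplotypes=haplotypes,
    )
    truth = {
        "table": table,
        "pool_freqs": pool_freqs,
        "references": references,
        "hybrid_ids": sorted(hybrid_ids),
        "hybrid_segments": {a: segs for a, segs in hybrid_segments.items() if segs},
    }
    return alignments, truth


def write_fasta(aln, handle) -> None:
    """Write one segment alignment as FASTA (ids ``<accession>__<copy>``)."""
    for acc, copy, seq in aln.records:
        handle.write(f">{acc}__{copy}\n{seq}\n")
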