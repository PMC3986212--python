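"""Pipeline orchestration and report writing.

``run_full_pipeline`` chains the stages — per-locus stats, LD and super
loci, identity analysis (matching, mismatch histogram, accumulation
curve, PI statistics, discrimination capacity), optional segment
analysis — and writes a report bundle of TSV/JSON files plus a run log
carrying the package version, the seed, and a hash of the applied
configuration, so every table regenerates identically from the
persisted config.

HWE and LD p-values are reported raw (no multiplicity correction was
applied in the emulated analysis); a Bonferroni-adjusted column is
emitted alongside for transparency.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .genotype_data import GenotypeMatrix, export_barcode
from .identity import (
    accumulation_curve,
    cumulative_pi,
    discrimination_capacity,
    match_genotypes,
    min_diff_distribution,
)
from .linkage import build_super_loci
from .marker_stats import allele_frequencies, panel_stats, round_half_up

__all__ = ["RunConfig", "run_full_pipeline", "write_structure_input"]


@dataclass
class RunConfig:
    """Thresholds and provenance for one pipeline run."""

    maf_min: float = 0.10
    r2_threshold: float = 0.10
    alpha: float = 0.05
    confidence: float = 0.95
    min_shared_loci: int = 6
    posterior_min: float = 0.95
    capacity_mode: str = "pairwise"
    ld_permutations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.confidence < 1 and 0 <= self.maf_min < 0.5
                and 0 < self.alpha < 1 and 0 <= self.r2_threshold <= 1):
            raise ValueError("threshold out of range")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_full_pipeline(matrix: GenotypeMatrix,
                      config: RunConfig = RunConfig(),
                      out_dir: str | Path | None = None) -> dict:
    """Run stats -> LD/super loci -> identity on a genotype matrix.

    Returns the report bundle as a dict; when ``out_dir`` is given the
    bundle is also written as TSV/JSON files plus ``run_log.json``.
    """
    bundle: dict = {"config": dataclasses.asdict(config)}

    stats = panel_stats(matrix)
    n_tests = len(stats)
    bundle["locus_stats"] = [
        {
            "locus_id": s.locus_id,
            "ho": round_half_up(s.ho), "he": round_half_up(s.he),
            "pic": round_half_up(s.pic),
            "f": None if s.f is None else round_half_up(s.f),
            "maf": round_half_up(s.maf, 3),
            "hwe_p": s.hwe_p,
            "hwe_p_bonferroni": min(1.0, s.hwe_p * n_tests),
            "n_typed": s.n_typed,
        }
        for s in stats
    ]

    sls = build_super_loci(matrix, r2_threshold=config.r2_threshold,
                           alpha=config.alpha, n_perm=config.ld_permutations,
                           seed=config.seed,
                           posterior_min=config.posterior_min)
    n_pairs = max(1, len(sls.ld_table))
    bundle["super_loci"] = {
        "groups": [list(s.member_loci) for s in sls.super_loci],
        "effective_locus_count": sls.effective_count,
        "ld_pairs": {
            "|".join(k): {"r2": r2, "p": p,
                          "p_bonferroni": min(1.0, p * n_pairs)}
            for k, (r2, p) in sorted(sls.ld_table.items())
        },
    }

    report = match_genotypes(matrix, min_shared_loci=config.min_shared_loci)
    dist = min_diff_distribution(matrix, report)
    curve = accumulation_curve(matrix, stats,
                               min_shared_loci=config.min_shared_loci)
    bundle["identity"] = {
        "n_distinct": report.n_distinct,
        "clusters": [c for c in report.clusters if len(c) > 1],
        "unplaceable": report.unplaceable,
        "min_diff_histogram": {str(k): v
                               for k, v in dist["histogram"].items()},
        "min_diff_mean": dist["mean"],
        "min_diff_min": dist["min"],
        "accumulation_curve": curve,
    }

    # PI over effective loci: singleton SNP freqs + super-locus haplotype freqs
    locus_freqs = []
    for lid in sls.singleton_locus_ids:
        locus_freqs.append(allele_frequencies(matrix, lid))
    for s in sls.super_loci:
        locus_freqs.append(list(s.hapfreqs.freqs.values()))
    pi_bundle = cumulative_pi(locus_freqs)
    capacity = discrimination_capacity(pi_bundle["pi"],
                                       confidence=config.confidence,
                                       mode=config.capacity_mode)
    bundle["pi"] = {
        "pi": pi_bundle["pi"],
        "pi_sibs": pi_bundle["pi_sibs"],
        "pi_par_off": pi_bundle["pi_par_off"],
        "neg_log10_pi": pi_bundle["neg_log10_pi"],
        "neg_log10_pi_sibs": pi_bundle["neg_log10_pi_sibs"],
        "capacity": capacity,
        "capacity_mode": config.capacity_mode,
        "confidence": config.confidence,
    }
    bundle["fingerprints"] = export_barcode(matrix)

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir), config)
    return bundle


def _write_bundle(bundle: dict, out_dir: Path, config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(
        json.dumps(bundle, indent=2, sort_keys=True, default=str) + "\n")

    rows = bundle["locus_stats"]
    cols = ["locus_id", "ho", "he", "pic", "f", "maf", "hwe_p",
            "hwe_p_bonferroni", "n_typed"]
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append("\t".join(str(r[c]) for c in cols))
    (out_dir / "locus_stats.tsv").write_text("\n".join(lines) + "\n")

    lines = ["k\tn_distinct"]
    for k, v in enumerate(bundle["identity"]["accumulation_curve"], start=1):
        lines.append(f"{k}\t{v}")
    (out_dir / "accumulation.tsv").write_text("\n".join(lines) + "\n")

    lines = ["min_diff\tcount"]
    for k, v in bundle["identity"]["min_diff_histogram"].items():
        lines.append(f"{k}\t{v}")
    (out_dir / "min_diff_histogram.tsv").write_text("\n".join(lines) + "\n")

    lines = ["accession\tbarcode"]
    for acc, code in bundle["fingerprints"].items():
        lines.append(f"{acc}\t{code}")
    (out_dir / "fingerprints.tsv").write_text("\n".join(lines) + "\n")

    log = {
        "package_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "thresholds_applied": {
            "maf_min": config.maf_min,
            "r2_threshold": config.r2_threshold,
            "alpha": config.alpha,
            "confidence": config.confidence,
            "min_shared_loci": config.min_shared_loci,
            "posterior_min": config.posterior_min,
        },
    }
    (out_dir / "run_log.json").write_text(
        json.dumps(log, indent=2, sort_keys=True) + "\n")


def write_structure_input(matrix: GenotypeMatrix) -> str:
    """Genotype matrix in STRUCTURE's two-rows-per-individual format.

    Alleles are coded as integers per locus (missing = -9) so the file
    can be fed to an external Bayesian clustering run; clustering itself
    is out of scope here.
    """
    codes = [{a: i + 1 for i, a in enumerate(l.alleles)} for l in matrix.loci]
    lines = [" ".join(l.locus_id for l in matrix.loci)]
    for acc, row in zip(matrix.accessions, matrix.cells):
        for k in (0, 1):
            fields = [acc.accession_id]
            for j, g in enumerate(row):
                fields.append("-9" if g is None else str(codes[j][g[k]]))
            lines.append(" ".join(fields))
    return "\n".join(lines) + "\n"
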