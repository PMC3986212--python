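"""Duplicate matching, mismatch distributions, PI statistics, capacity."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from pummelid.identity import (
    accumulation_curve,
    cumulative_pi,
    discrimination_capacity,
    genotype_pi,
    match_genotypes,
    min_diff_distribution,
    pi_par_off,
    pi_random,
    pi_sibs,
)
from pummelid.genotype_data import MISSING
from pummelid.marker_stats import panel_stats
from pummelid.segment_analysis import segment_match
from pummelid.synthetic_data import CollectionDesign, PopulationModel, simulate_genotypes

from conftest import build_matrix, random_matrix


# -- enumeration oracles (independent of the closed forms) --------------

def hwe_genotypes(p):
    """[(genotype, HWE frequency)] over allele indices."""
    k = len(p)
    out = []
    for i in range(k):
        for j in range(i, k):
            freq = p[i] ** 2 if i == j else 2 * p[i] * p[j]
            out.append(((i, j), freq))
    return out


def pi_enumeration(p):
    """Sum of squared HWE genotype frequencies."""
    return sum(f ** 2 for _, f in hwe_genotypes(p))


def offspring_distribution(gm, gf, p):
    """Offspring genotype distribution for ordered parents gm x gf."""
    dist = {}
    for am in gm:
        for af in gf:
            g = tuple(sorted((am, af)))
            dist[g] = dist.get(g, 0.0) + 0.25
    return dist


def pi_sibs_enumeration(p):
    """Sum over HWE parent pairs of P(two sibs share a genotype)."""
    total = 0.0
    genos = hwe_genotypes(p)
    for gm, fm in genos:
        for gf, ff in genos:
            dist = offspring_distribution(gm, gf, p)
            total += fm * ff * sum(v ** 2 for v in dist.values())
    return total


def pi_par_off_enumeration(p):
    """P(parent and offspring identical): parent transmits one allele,
    the mate contributes a random population allele."""
    total = 0.0
    for gp, fp in hwe_genotypes(p):
        match = 0.0
        for transmitted in gp:                     # each with prob 1/2
            for a, pa in enumerate(p):             # population allele
                g_off = tuple(sorted((transmitted, a)))
                if g_off == gp:
                    match += 0.5 * pa
        total += fp * match
    return total


def frequency_grid(max_alleles=4, step=0.05):
    """All frequency vectors with <= max_alleles on a coarse grid."""
    steps = int(round(1 / step))
    # compositions of `steps` into k positive parts
    for k in range(1, max_alleles + 1):
        for cuts in itertools.combinations(range(1, steps), k - 1):
            parts = np.diff([0, *cuts, steps]) * step
            yield parts


class TestMatchGenotypes:
    def test_published_profiles(self, table2):
        report = segment_match(table2)
        assert report.n_distinct == 23
        multi = [c for c in report.clusters if len(c) > 1]
        assert multi == [["Hejiangyou", "Lingnanshatianyou"]]

    def test_all_identical_single_cluster(self):
        m = build_matrix([["A/G"] * 6] * 5)
        report = match_genotypes(m)
        assert report.n_distinct == 1
        assert len(report.clusters[0]) == 5

    @pytest.mark.parametrize("seed,missing", [(0, 0.1), (1, 0.2), (2, 0.3)])
    def test_matches_brute_force_with_missing(self, seed, missing):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 50, 12, missing_rate=missing)
        report = match_genotypes(m, min_shared_loci=6)

        # independent O(n^2) oracle via an explicit match graph
        g = nx.Graph()
        typed = {a: [c for c in m.row(a) if c is not MISSING]
                 for a in m.accession_ids}
        nodes = [a for a in m.accession_ids if len(typed[a]) >= 6]
        g.add_nodes_from(nodes)
        for a, b in itertools.combinations(nodes, 2):
            ra, rb = m.row(a), m.row(b)
            shared = [(x, y) for x, y in zip(ra, rb)
                      if x is not MISSING and y is not MISSING]
            if len(shared) >= 6 and all(x == y for x, y in shared):
                g.add_edge(a, b)
        oracle = sorted(tuple(sorted(c)) for c in nx.connected_components(g))
        got = sorted(tuple(sorted(c)) for c in report.clusters)
        assert got == oracle

    def test_undertyped_accession_unplaceable(self):
        m = build_matrix([["A/G"] * 6, ["A/G", "-", "-", "-", "-", "-"]])
        report = match_genotypes(m, min_shared_loci=6)
        assert report.unplaceable == ["acc2"]
        assert report.n_distinct == 1

    def test_clone_groups_recovered(self):
        model = PopulationModel(n_loci=25, seed=17)
        design = CollectionDesign(clone_group_sizes=(3, 2, 2, 1, 1),
                                  n_seedlings=4)
        m, truth = simulate_genotypes(model, design)
        report = match_genotypes(m)
        got = sorted(tuple(sorted(c)) for c in report.clusters)
        want = sorted(tuple(sorted(c)) for c in truth["clone_partition"])
        assert got == want


class TestMinDiffDistribution:
    def test_two_genotypes(self):
        m = build_matrix([["A/A", "A/A", "A/A", "A/G", "G/G", "A/A"],
                          ["A/G", "G/G", "A/A", "A/A", "G/G", "A/A"]])
        report = match_genotypes(m)
        dist = min_diff_distribution(m, report)
        assert dist["histogram"] == {3: 2}
        assert dist["mean"] == 3 and dist["min"] == 3

    def test_three_genotypes_hand_enumeration(self):
        # pairwise diffs: (1,2)=2, (1,3)=5, (2,3)=6 -> min_diffs {2,2,5}
        rows = [
            ["A/A", "A/A", "A/A", "A/A", "A/A", "A/A"],
            ["A/G", "G/G", "A/A", "A/A", "A/A", "A/A"],
            ["A/A", "A/G", "G/G", "G/G", "G/G", "G/G"],
        ]
        m = build_matrix(rows)
        dist = min_diff_distribution(m, match_genotypes(m))
        assert sorted(dist["min_diffs"].values()) == [2, 2, 5]

    def test_identical_pair_excluded_from_histogram(self):
        m = build_matrix([["A/A"] * 6, ["A/A"] * 6,
                          ["G/G", "A/A", "A/A", "A/A", "A/A", "A/A"]])
        report = match_genotypes(m)
        dist = min_diff_distribution(m, report)
        assert report.n_distinct == 2
        assert sum(dist["histogram"].values()) == 2
        assert dist["min"] == 1


class TestAccumulationCurve:
    def test_monomorphic_curve_constant(self):
        m = build_matrix([["A/A"] * 4] * 3)
        stats = panel_stats(m)
        assert accumulation_curve(m, stats) == [1, 1, 1, 1]

    def test_non_decreasing_and_consistent_with_full_match(self):
        rng = np.random.default_rng(6)
        m = random_matrix(rng, 100, 15, missing_rate=0.05)
        stats = panel_stats(m)
        curve = accumulation_curve(m, stats)
        assert all(a <= b for a, b in zip(curve, curve[1:]))
        assert curve[-1] == match_genotypes(m).n_distinct


class TestPiFormulas:
    def test_monomorphic_limits(self):
        assert pi_random([1.0]) == 1.0
        assert pi_sibs([1.0]) == 1.0
        assert pi_par_off([1.0]) == 1.0

    def test_symmetric_biallelic_values(self):
        assert pi_random([0.5, 0.5]) == pytest.approx(0.375, abs=1e-15)
        assert pi_sibs([0.5, 0.5]) == pytest.approx(0.59375, abs=1e-15)
        assert pi_par_off([0.5, 0.5]) == pytest.approx(0.5, abs=1e-15)

    def test_formulas_equal_enumeration_on_grid(self):
        """Closed forms match genotype-pair enumeration to 1e-12
        for every frequency vector with <= 4 alleles on a 0.05 grid."""
        for p in frequency_grid(max_alleles=4, step=0.05):
            assert pi_random(p) == pytest.approx(pi_enumeration(p), abs=1e-12)
            assert pi_par_off(p) == pytest.approx(
                pi_par_off_enumeration(p), abs=1e-12)

    def test_sibs_formula_equals_enumeration_sampled(self):
        # sib enumeration is O(k^6); spot-check a modest random set
        rng = np.random.default_rng(0)
        vectors = [rng.dirichlet([1.0] * k)
                   for k in (2, 3, 4) for _ in range(30)]
        for p in vectors:
            assert pi_sibs(p) == pytest.approx(pi_sibs_enumeration(p),
                                               abs=1e-12)

    def test_ordering_pi_le_paroff_le_sibs(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            k = rng.integers(2, 6)
            p = rng.dirichlet([0.8] * k)
            a, b, c = pi_random(p), pi_par_off(p), pi_sibs(p)
            assert a <= b + 1e-12 <= c + 1e-12
            assert 0 < a <= 1 and c <= 1


class TestGenotypePi:
    def test_fixed_homozygote(self):
        assert genotype_pi(("A", "A"), {"A": 1.0}) == (1.0, 1.0, 1.0)

    def test_het_transmission(self):
        _, _, paroff = genotype_pi(("A", "B"), {"A": 0.5, "B": 0.5})
        assert paroff == 0.5

    def test_population_par_off_identity(self):
        """Sum over HWE genotypes of the genotype-specific parent-offspring
        probability equals sum p_i^2."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            k = rng.integers(2, 5)
            p = rng.dirichlet([1.0] * k)
            alleles = [chr(65 + i) for i in range(k)]
            fmap = dict(zip(alleles, p))
            total = 0.0
            for i in range(k):
                for j in range(i, k):
                    g = (alleles[i], alleles[j])
                    hwe = p[i] ** 2 if i == j else 2 * p[i] * p[j]
                    total += hwe * genotype_pi(g, fmap)[2]
            assert total == pytest.approx(float(np.sum(p ** 2)), abs=1e-12)

    def test_zero_frequency_allele_rejected(self):
        with pytest.raises(ValueError):
            genotype_pi(("A", "B"), {"A": 1.0})


class TestCumulativePi:
    def test_independence_product(self):
        out = cumulative_pi([[0.5, 0.5], [0.5, 0.5]])
        assert out["pi"] == pytest.approx(0.140625, abs=1e-15)

    def test_matches_brute_force_product(self):
        rng = np.random.default_rng(3)
        vecs = [rng.dirichlet([1.0] * rng.integers(2, 6)) for _ in range(21)]
        out = cumulative_pi(vecs)
        want = 1.0
        for p in vecs:
            want *= pi_enumeration(p)
        assert out["pi"] == pytest.approx(want, rel=1e-12)
        assert len(out["neg_log10_pi"]) == 21
        assert out["neg_log10_pi"][-1] == pytest.approx(-math.log10(want))


class TestDiscriminationCapacity:
    def test_query_mode_unit_budget(self):
        assert discrimination_capacity(0.05, mode="query") == 1

    def test_pairwise_published_pi(self):
        n = discrimination_capacity(5.28e-8, mode="pairwise")
        assert n == 1394
        # verify by direct evaluation of the inequality at n and n+1
        assert (1 - 5.28e-8) ** (1394 * 1393 / 2) >= 0.95
        assert (1 - 5.28e-8) ** (1395 * 1394 / 2) < 0.95

    def test_monotone_in_pi(self):
        rng = np.random.default_rng(4)
        pis = sorted(rng.uniform(1e-10, 0.04, size=30))
        caps = [discrimination_capacity(x) for x in pis]
        assert all(a >= b for a, b in zip(caps, caps[1:]))

    def test_query_capacity_zero_warns(self):
        with pytest.warns(UserWarning):
            assert discrimination_capacity(0.2, mode="query") == 0
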