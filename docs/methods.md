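# Methods

This note documents the statistical models behind `pummelid`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Duplicate matching

Two accessions carry the same multilocus genotype when they disagree at
zero co-typed loci and are co-typed at ≥ `min_shared_loci` loci
(default 6).  Missing data is pairwise-complete: a missing cell never
counts as a difference and never fabricates agreement.  Because the
match relation is not transitive under missing data, clusters are
transitive closures (union–find); accessions typed at fewer than
`min_shared_loci` loci overall are reported as unplaceable rather than
silently clustered.  The default floor of 6 keeps the bundled
24-accession segment profiles — two of which miss two or three segments
— placeable while still demanding substantial overlap.

Minimum-difference summaries compare cluster representatives (the first
member in input order); exact-duplicate rows are collapsed before the
pairwise scan, which makes matching O(U²L) in the number of distinct
rows U rather than accessions.

## Identity probabilities

Per locus with allele frequencies pᵢ (HWE assumed):

- PI = 2(Σpᵢ²)² − Σpᵢ⁴
- PI_sibs = ¼ + ½Σpᵢ² + ½(Σpᵢ²)² − ¼Σpᵢ⁴
- PI_par-off = Σpᵢ² (population level)

Genotype-specific values follow the forensic conditional forms: for a
homozygote AᵢAᵢ, PI_g = pᵢ², PI_sibs,g = (1+pᵢ)²/4, PI_par-off,g = pᵢ;
for a heterozygote AᵢAⱼ, PI_g = 2pᵢpⱼ,
PI_sibs,g = (1+pᵢ+pⱼ+2pᵢpⱼ)/4, PI_par-off,g = (pᵢ+pⱼ)/2.  All closed
forms are verified in the test suite against brute-force enumeration
over genotype (and sib/parent) space to 1e-12.

Multi-locus values multiply per-locus values over *effective* loci, so
super-locus recoding must run first; a super locus contributes its EM
haplotype-frequency vector once, not one factor per member SNP.

**Discrimination capacity.**  Two readings of "how many cultivars can
the panel support at 95% confidence" are implemented:

- *pairwise* (default): largest n with (1 − PI)^(n(n−1)/2) ≥ 0.95 —
  no false identical pair anywhere in the collection;
- *query*: largest n with n·PI ≤ 0.05 — a single queried genotype has
  no false match.

Capacity numbers are always reported together with the mode name.  The
pairwise form is the default because it matches the "no false identical
genotypes in a sample of n" phrasing used in germplasm fingerprinting
work and yields capacities in the thousands for panel-level PI ≈ 1e-8.

## Per-locus statistics

He is the uncorrected gene diversity 1 − Σpᵢ², computed over
non-missing gene copies.  PIC is Botstein's
1 − Σpᵢ² − Σ_{i<j} 2pᵢ²pⱼ².  f = (He − Ho)/He and may be negative
(heterozygote excess).  Reported tables round half-up to two decimals;
full precision is kept internally.

The Hardy–Weinberg test is the exact conditional test: given the
allele counts, the p-value sums the probabilities of all heterozygote
counts no more probable than the observed one.  It was chosen over the
chi-square approximation because group sizes in germplasm panels are
routinely far below asymptotic validity; the test matches a
full-enumeration oracle exactly for n ≤ 20 in the suite.

F_ST is multi-locus Weir–Cockerham θ, as a ratio of sums of the a/b/c
variance components across loci (bi-allelic loci; groups contribute per
locus only where typed).

**Panel selection** drops candidates with MAF ≤ 0.10 (the *retained*
set has minor-allele frequency strictly above 10%), ranks the rest by
PIC descending (ties by locus id), and accepts greedily, skipping any
candidate in significant LD (r² > 0.10, p < 0.05) with an accepted one
unless explicitly flagged keep-as-super-locus.

## EM haplotype frequencies, LD and super loci

The EM runs over unphased multilocus genotypes aggregated into genotype
classes.  Compatible unordered haplotype pairs are enumerated per class
(the first heterozygous locus is pinned to break pair symmetry), the
haplotype space is restricted to haplotypes compatible with at least
one observed genotype, initialization is uniform (deterministic), and
convergence is max|Δf| < 1e-8 within 1,000 iterations.  The
log-likelihood is asserted non-decreasing every iteration.  For
two-locus problems the EM maximum matches a 20,001-point grid search of
the one-parameter profile likelihood to 1e-4 in the suite.  Symmetric
double-heterozygote ties (two equal maxima) are resolved toward the
higher coupling-gamete frequency and flagged.

LD between two bi-allelic loci: D = p_AB − p_A p_B,
r² = D²/(p_A(1−p_A) p_B(1−p_B)) from the EM estimate.  Significance is
a permutation test (one genotype column permuted across accessions, the
statistic being r² from a re-run EM; p = (1+exceedances)/(n_perm+1)).
Permutations require ≥ 10 co-typed accessions; with fewer, a pair is
never declared significant.  The permutation EM uses a looser tolerance
(1e-5, 100 iterations) — permutation ranking does not need
convergence to 1e-8 — while observed statistics always use the tight
settings.

Super loci are connected components (≥ 2 members) of the
significant-pair graph (r² > 0.1 AND p < 0.05); components rather than
cliques, because significance is transitive in the intended "cannot be
treated as independent" sense.  Each accession typed at all member loci
is recoded to its posterior-best haplotype pair; below a 0.95 posterior
the recoded genotype is MISSING rather than a fabricated haplotype.
The effective locus count is singletons + number of super loci.

## Segment barcoding

SNP calling uses the clone rule: a column is a variant site only if at
least two alleles each appear in ≥ 2 sequences (default support 2);
columns containing N or gap characters are excluded outright.
Segregating sites count polymorphic columns ignoring N/gap characters.

Nucleotide diversity π is the mean over all C(n,2) sequence pairs of
(differences / comparable columns), columns with N/gap in either
sequence excluded pairwise.  This all-pairs mean equals the
n/(n−1)-corrected frequency form and reduces to diffs/length for a
single pair.

Haplotype diversity uses Nei's unbiased form
Hd = n(1 − Σpᵢ²)/(n − 1).  The correction is deliberate here and
deliberately absent from the SNP-level He: the bundled per-segment
summary is only reproduced at two decimals with the corrected form,
while the SNP panel summary is consistent with the uncorrected one.
One bundled Hd cell (segment Cs1g16760, printed 0.57) is not consistent
with its own haplotype counts (which give 0.60); it is documented here
and excluded from exact assertions.

Phasing is the same EM over per-site genotypes (≤ 12 sites per segment
so the haplotype space stays enumerable); each accession gets its
posterior-best pair plus the posterior itself.  Haplotype ids are dense
positive integers assigned by first occurrence in input order,
namespaced per segment.

Segment-level LD (for merging linked segments before the PI product)
uses a multi-allelic r² analog, Σ_ab D_ab²/(p_a p_b) normalized by
min(k_A−1, k_B−1), with a permutation p-value, the biallelic thresholds
reused.  On small samples (tens of accessions) this all-pairs scan
over-merges by chance — raw α with 66 pairs expects ~3 false edges, and
components chain — so `segment_pi_stats` also accepts an explicit merge
list; the known linked pair Cs9g14320+Cs9g16170 is passed explicitly in
the worked analyses.

## Trees and hybrid screening

Tajima–Nei distance in the equal-input form d = −b ln(1 − p/b),
b = 1 − Σq_i² over the pooled base composition of the two sequences,
sites with N/gap excluded; p ≥ b raises a saturation error.  At uniform
composition this reduces to Jukes–Cantor (b = 0.75).  The simple
equal-input variant suffices because trees here serve classification,
not dating.

Neighbour joining follows Saitou–Nei with the Q criterion, ties broken
deterministically by pair order, negative branch lengths clamped to
zero and counted.  On additive inputs the tree reproduces the
generating metric exactly (verified on random 5–10 taxon trees).

Hybrid screening assigns each segment haplotype the class of its
nearest reference (pummelo / mandarin / optional outgroup) by
Tajima–Nei distance; exact ties (including mutual saturation) are
"ambiguous" and never counted as evidence.  An accession with ≥ 1
non-pummelo haplotype in ≥ 1 segment is flagged.  Nearest-reference
was chosen over clade-membership because monophyly tests are brittle on
a few hundred bp; it approximates the visual tree reading practitioners
use.

## Synthetic collections

`simulate_genotypes` draws ancestral minor-allele frequencies uniformly
in (0.10, 0.50], subpopulation frequencies from the Balding–Nichols
Beta(p(1−F)/F, (1−p)(1−F)/F) at F = 0.16 with K = 4 demes (the
structure and differentiation level the package's intended collections
show), and HWE genotypes within demes (or admixed via a Dirichlet over
demes).  A locus is redrawn when its realized founder-level MAF leaves
the target range, emulating the frequency screen that real panels pass
before deployment.  Clonal groups copy their founder exactly — somatic
mutants are indistinguishable at panel SNPs — and seedlings are
all-unique sexual genotypes.  Genotyping error is random genotype
replacement by default, with a whole-profile swap mode mirroring sample
loading errors; missing data and errors are applied last.  The
study-scale default is 260 accessions carrying 178 genotypes (12
triples, 58 pairs, 53 singletons, 55 unique seedlings).

`simulate_segments` builds per-segment pummelo haplotype pools by
planting 1–10 SNPs on a random base sequence (2–9 distinct haplotypes,
every SNP polymorphic in the pool, symmetric Dirichlet frequency law)
and a mandarin pool diverged at 2% of sites; hybrids carry a mandarin
haplotype in at least one randomly chosen segment.  Segment lengths are
410–631 bp.

What the generator does **not** emulate: real LD within and between
panel SNPs (loci are independent given structure), ascertainment
sharing between the discovery and typed panels, genealogical
(coalescent) correlation among segment haplotypes, indels, and
base-calling error in sequences.  Passing planted-truth tests therefore
demonstrates the estimators' correctness under the stated models, not
robustness to every artifact of real data.

## Numerical conventions and scale choices

- Heterozygotes are canonicalized alphabetically; MISSING is a single
  sentinel; haplotype/barcode strings are deterministic functions of
  the genotype.
- Reported tables round half-up to 2 decimals; comparisons against
  bundled published values use that rounding.
- Permutation counts default to 1,000 in the pipeline (p-resolution
  0.001); tests use 99–199 permutations and simulations of 40–260
  individuals so the whole suite runs in well under five minutes on a
  single core.
- Coordinates are 1-based inclusive; alleles are stored as named
  nucleotides, never strand-flipped.
- HWE and LD p-values are reported raw, with a Bonferroni column
  alongside for transparency; no correction is applied to decisions, to
  match common practice in panel reports.
- Bayesian population-structure clustering is not reimplemented; a
  STRUCTURE-format export is provided for external runs.

## Known limitations

- The exact HWE test is bi-allelic; multi-allelic loci would need a
  network algorithm (out of scope).
- The segment LD scan is honest but high-variance below ~50 accessions;
  prefer explicit merge lists there.
- EM phasing enumerates haplotypes and is limited to 12 variant sites
  per segment; segments with hybrid material can exceed this, so
  hybrids should be screened out (as the intended workflow does) before
  intra-specific phasing.
- Parentage-exclusion power and likelihood-ratio kinship tests are not
  implemented.
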