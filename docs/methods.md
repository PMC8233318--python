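# Methods

This note documents the statistical models, numerical choices and known
limitations of the package, in the spirit of a methods appendix.

## Pooled diversity estimators

### Sampling model

A pool contains *n* chromosomes (2 × diploid count). Sequencing reads at a
site are modelled as draws **with replacement** from those chromosomes:
given a derived-allele count *k*, the alternative read count at coverage
*M* is Binomial(*M*, *k/n*). A variant is only *called* when its minor
allele reaches *b* reads (default *b* = 2, guarding against sequencing
error), which truncates the observable spectrum at both ends.

### Correction denominators

Under the neutral expectation that a site segregates at count *k* with
probability θ/k, the expected contribution of one site to the summed
heterozygosity and to the SNP count are θ·C_pi and θ·C_S, with

- C_pi(n, M, b) = Σ_{k=1}^{n−1} (1/k) Σ_{m=b}^{M−b} Binom(m; M, k/n) · 2m(M−m)/(M(M−1))
- C_S(n, M, b)  = Σ_{k=1}^{n−1} (1/k) Σ_{m=b}^{M−b} Binom(m; M, k/n)

The inner weight in C_pi is exactly the expected sample heterozygosity
(M/(M−1))(1 − Σf²) of a site with *m* alternative reads, so dividing the
summed observed *h* over called SNPs by C_pi (and the called-SNP count by
C_S), then by the number of covered positions, yields per-bp estimators
whose expectation is θ. Both denominators are computed with vectorised
binomial pmfs, memoized per (n, M, b), and are verified in the test suite
against an exact rational-arithmetic enumeration (n ≤ 6, M ≤ 8, agreement
to 12 decimals). They are increasing in M and strictly decreasing in b.

Tri-allelic sites are retained; heterozygosity uses the full frequency
vector, which 1 − Σf² generalises to naturally.

### Tajima's D

The upstream tooling this pipeline mirrors does not publish its variance
formula, so windows use Tajima's classical constants (a1, a2, b1, b2, c1,
c2, e1, e2) evaluated at an effective sample size n_eff:

D = (Σh/C_pi − Σ_SNP 1/C_S) / sqrt(e1·S + e2·S(S−1)),

with S the window's called-SNP count. By default n_eff is the pool
chromosome count *n*; `neff_mode="min_nm"` switches to min(n, mean M).
This is an approximation: the variance normalisation ignores the two-stage
(pool + read) sampling, so |D| is interpretable comparatively, not as an
exactly unit-variance quantity. The neutrality check in the acceptance
suite (mean windowed D within ±0.3 of 0 at θ = 0.005, n = 80, 60× coverage,
1 Mb) bounds the practical consequence. Note c1 = 0 exactly at n_eff = 3;
n_eff < 3 is rejected.

### Filters and subsampling

Defaults mirror a conventional Pool-seq pipeline: base quality ≥ 20
(mapping quality ≥ 20 is a pileup-generation contract, since plain mpileup
text has no per-read MQ), indels and ±5 bp around them removed, per-pool
subsampling without replacement (multivariate hypergeometric) to the 5th
coverage percentile — which doubles as the minimum coverage — and a
maximum-coverage cut at the 99th percentile applied *before* subsampling.
Percentiles are nearest-rank. One genome-wide target per pool is used.
Undefined statistics are emitted as `NA`, never 0. Coordinates: pileup
input is 1-based; all interval outputs are 0-based half-open.

## Differentiation scan

Reads (not estimated frequencies) are summed within groups; the χ²
statistic is the textbook 2×2 form with one degree of freedom and no
continuity correction — the conventional choice at genome scale, where the
Bonferroni line, α divided by the number of SNPs actually tested after
filters, dominates the inference. Sites with a zero marginal are skipped
with a reason code. Every SNP with all marginals positive is tested, and
skips are reported, so thresholds always match what was computed.

The region contrast is a Wilcoxon rank-sum test: for two samples each of
size ≤ 10 the p-value is computed by full enumeration of rank assignments
using midranks (ties exact); larger samples use the normal approximation
with tie correction. The suite checks the two routes agree within 0.05 on
tie-free small samples and that the enumeration reproduces closed-form
cases (e.g. p = 1/C(6,3) for fully separated samples of three).

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical* structure the estimators
assume, with one master seed and per-pool streams keyed by pool index (so
adding a pool never perturbs existing ones); identical config + seed gives
byte-identical output.

- **Neutral pool**: each site independently segregates at count k with
  probability θ/k (θ·a1(n) < 1 enforced); coverage is Poisson(mean depth)
  with zero-depth sites omitted; miscalls are strand-agnostic and uniform
  over the other three bases. Defaults: θ = 0.005, n = 80 chromosomes,
  60× coverage, miscall rate 10⁻³ — typical of a large-population marine
  fish pool.
- **Two-group design**: 7 + 7 pools of 50 diploids. Background sites share
  one population frequency across all pools, so read sampling is the only
  between-pool noise and the χ² null is exactly calibrated — the
  acceptance suite verifies a p < 0.01 fraction of 0.7–1.3% and ≤ 2
  Bonferroni hits at ~10⁵ null SNPs. Planted divergent SNPs (defaults: 20
  SNPs at 0.95 vs 0.05) additionally resample each pool's frequency as
  Binomial(2n, p_group)/(2n), the finite-pool noise that dAF integrates
  over. The sweep analogue thins background segregation inside the region
  by `sweep_theta_factor` (default 0.2). A flag restricts output to
  segregating sites for scan-only runs; diversity analyses use the full
  genome mode.
- **Toy locus**: haplotype S = LTR–internal–LTR element (470 + 4730 + 470
  bp) between printed-offset gaps (1.9 kb to the upstream peak, 2.15 kb to
  the TSS) plus a 66-bp (22-codon) tandem array (3 copies); haplotype A =
  solo LTR equal to a designated origin copy plus extra mismatches, 5
  tandem copies; outgroup = element with identical ancestral LTRs. The S/A
  length difference is internal + one LTR = 5.2 kb, the insertion
  polymorphism. LTR mismatches (default 4) and solo mismatches (default 1)
  are planted at positions disjoint from each other and ≥ 15 bp from the
  copy termini: a substitution at the very end of a repeat is
  unidentifiable to any detector that must also infer the boundary, so the
  generator keeps the planted truth recoverable by construction.

Not emulated: linkage disequilibrium and coalescent correlation between
sites (sites are independent), mapping artefacts, indel/CNV structure,
reference bias, or demography — the 1/k spectrum plus binomial pool
sampling is a minimal stand-in, not a model of any real population. A
passing suite therefore validates the estimators and their corrections
under their own assumptions; it does not certify behaviour under
mis-mapping or structured populations.

## Structural-variant analyses

- **Direct-repeat detection** seeds on exact 15-mer self-matches, chains
  hits on the same diagonal across gaps ≤ one word, and extends ends
  base-by-base, crossing an isolated mismatch when ≥ 8 of the next 10
  aligned positions match. The look-ahead makes interior substitutions
  harmless while keeping the false-crossing probability into random flank
  below ~4·10⁻⁴ per boundary. Pairs need length ≥ 300 bp, identity ≥ 95%,
  copy separation ≥ 100 bp; overlapping reports collapse to maximal pairs.
  Same-strand (direct) repeats only — LTRs are direct repeats; inverted
  repeats are out of scope. Words occurring > 50 times are skipped to keep
  the seed set bounded on low-complexity input.
- **Mismatch counting** is alignment-free Hamming when lengths agree; a
  global-alignment fallback (match 1, mismatch −1, gap −2) handles unequal
  lengths and logs its use. Reported percentages and kb values round
  half-up (0.851% → "1%"; 9.25 kb → 9.3), matching how such figures are
  printed.
- **ORF scan**: six frames, ORF = ATG to first in-frame stop (stop
  included), aa = nt/3 − 1; ties prefer the plus strand, then the lowest
  start. Verified against a brute-force all-substrings oracle.
- **Tandem repeats**: the best Hamming match of the unit anchors the
  array; extension proceeds in unit-length steps while each copy stays
  within the per-copy mismatch tolerance (default 6 of 66 bp).
  Heterozygous copy-number calls are out of scope (sequence level only).
- **Score-track peaks**: "minimum score 0.2 within 500 bp" is read as a
  merge-gap rule — qualifying positions join one peak while consecutive
  gaps are ≤ 500 bp — which is the default; a fixed-bin interpretation is
  available via `mode="bins"` since the phrasing is genuinely ambiguous.
- **Regulatory distances** are plain offset arithmetic (gap + optional
  insertion + gap), reproducing printed distances from printed offsets;
  present-vs-absent differs by exactly the insertion length pre-rounding.

## Haplotype analysis

Classification is unphased: "S/A" means heterozygous at every informative
variant. A variant may be marked non-diagnostic for A (polymorphic among A
haplotypes, e.g. a missense allele of recent origin): hom-A and het calls
there do not break A/A, hom-S still does. `max_missing` defaults to 1,
reflecting occasional dropout when genotypes come from several assay
technologies; the synthetic-cohort check models that noise as 5% per-call
dropout (a miscall model would instead bound recovery near 74% with six
variants, which is a statement about the classifier's strictness, not its
correctness). Polarization calls the haplotype allele matching the
outgroup ancestral and the other derived. Fisher's exact test reports the
two-sided hypergeometric p (cross-checked against a rational enumeration
oracle) and a sample odds ratio with Haldane's 0.5 correction only when a
cell is zero.

## Problem sizes used by the validation suite

Chosen once as the package's standard validation conditions: estimator
recovery at 1 Mb / 60× / n = 80 (θ̂ within 5%, mean windowed D within
±0.3); null scan calibration on a 4.1 Mb genome emitted as segregating
sites only (~10⁵ tested SNPs); power and sweep contrast on a 400 kb genome
with a 100 kb divergent region; structural recovery over 100 seeded locus
instances with copy numbers cycling through (3,5), (4,3), (5,4).

## Known limitations

- The Tajima's D variance is approximate for pooled data (see above).
- The scan's χ² ignores between-pool overdispersion at sites where pool
  frequencies genuinely differ within a group; with few, large pools and
  Bonferroni control this is the conventional, slightly anticonservative
  choice for real data, while the simulator's shared-background null is
  exactly calibrated.
- `genome_scan` assumes one chromosome per call; multi-chromosome inputs
  are scanned per chromosome by the caller.
- The repeat detector reports exact-word-seeded repeats only; highly
  diverged (< 95% identity) or heavily indel-interrupted copies need a
  dedicated aligner.
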