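# Methods

This note documents the models, numerical choices and simulation design
behind `rohdep`, and what the test suite does and does not establish.

## Inbreeding measures

**Pedigree (`F_PED`).** The Meuwissen–Luo algorithm computes
A_jj = Σ_k L²_jk d_k by walking only the ancestors of each animal, where
d_k = ½ − ¼(F_s + F_d) is the Mendelian-sampling variance share (¾ − ¼F
with one known parent, 1 for founders). Unknown parents are unique,
unrelated, non-inbred founders. `truncate_pedigree` measures an ancestor's
depth as its *minimum* path length to the phenotyped cohort, so an animal
reachable both as a parent and a great-grandparent is retained at depth 1;
truncation can only remove inbreeding paths, so it never increases F. The
sparse inverse of the numerator relationship matrix uses Henderson's rules
with exact parental inbreeding in d_j (no approximation — the pedigrees
handled here are small enough).

**GRM diagonal (`F_GRM`).** With the base allele frequency fixed at 0.5 at
every locus, the VanRaden diagonal reduces to
g_ii = Σ_j (x_ij − 1)² / (m/2) and F_GRM = g_ii − 1 =
2·(homozygous fraction) − 1, ranging over [−1, 1]. Because (x − 1)² is
symmetric, F_GRM is invariant to allele re-poling; only the diagonal is
formed (the full GRM is available behind a debug flag). Input SNPs pass a
Hardy–Weinberg exact test (Wigginton-style enumeration, threshold p < 0.001
— the exact test is the robust default at a few hundred samples, where
chi-square misbehaves at low minor-allele counts) and a MAF ≥ 0.01 filter.
The MAF filter applies only to the GRM and HBD inputs, never to the ROH
path.

**ROH classes (`F_ROH2`, `F_ROH2_8`, `F_ROH8`).** The caller reproduces the
PLINK sliding-window semantics: windows of L consecutive SNPs with at most
1 heterozygote (and, by default, 0 missing calls — inputs are assumed
imputed) are homozygous; a SNP is eligible when ≥ 5% of the windows
covering it are homozygous (PLINK's default hit proportion; configurable);
eligible runs are split at inter-SNP gaps > 1 Mb and kept when ≥ 2 Mb long,
≥ L SNPs, and ≤ 100 kb per SNP on average (density taken over the whole
run, PLINK's convention). L = ⌈ln(α/(n_s n_i)) / ln(1 − h̄)⌉ with α = 0.05;
the ceiling is the conservative direction for false-positive control.
Segments shorter than 8,000 kb are class ROH2_8, the rest ROH8 (the
boundary's equality case goes to the long class; configurable). The
heterozygote allowance is enforced per window, not per final segment —
both conventions exist in the field; the per-window one matches
`--homozyg-window-het 1`. F values divide class totals by the autosome
length (2,489,385 kb for the cattle assembly; for simulated genomes the
simulated length must be supplied). F_ROH2 is computed as the sum of the
two class fractions, making the partition identity exact by construction.

**HBD HMM (`F_HBD`).** K = 10 HBD classes with fixed layered rates
R_k = 2^k (Morgans⁻¹) plus one non-HBD class sharing R_K; segment lengths
are exponential, so over a map distance d the chain stays in its class-k
segment with probability e^(−R_k d) and otherwise redraws the class from
the mixing distribution. Emissions are Hardy–Weinberg probabilities
(non-HBD) or {q, 0, p} (HBD), convolved with a symmetric genotyping-error
kernel (ε = 10⁻³ by default; array data after imputation are clean).
Allele frequencies are sample frequencies; map distance is 1 cM/Mb unless
a genetic map is supplied. Decoding is a scaled forward–backward pass whose
transition structure is diagonal-plus-rank-one, so each step is O(K) per
animal; chromosomes restart from the mixing distribution. Mixing
coefficients are re-estimated per animal by EM (expected segment entries;
rates stay fixed), up to 100 iterations or a log-likelihood change below
10⁻⁶. F_HBD is the mean total-HBD posterior over loci, with no class
cutoff.

## Genome-wide depression model

The repeated-records animal model y = Xb + Zu + W·pe + βf + e carries
contemporary group and collection-interval class as fixed factors
(first-level reference dropping; β is invariant to the choice, and that
invariance is tested), bull age as centered linear + quadratic covariates
(centering reduces collinearity and leaves β unchanged; a constant-age
fixture drops the columns), and the inbreeding coefficient(s) as fixed
covariates — the two ROH classes enter jointly as two columns of X.
Random effects: u over *all* pedigree animals with covariance σ²_u A, pe
per phenotyped animal.

Variance components are REML estimates. Rather than average-information
iterations, the residual variance is profiled out in closed form
(σ̂²_e = (y'y − sol'rhs)/(n − p)) and the profiled restricted likelihood

    (n − p)·log σ̂²_e-numerator + log|C_λ| − q_u log λ_u − q_pe log λ_pe

is minimized over the two log variance ratios by Nelder–Mead (function
tolerance 10⁻⁸, ≤ 200 evaluations). Every evaluation is one Cholesky
factorization of the mixed-model coefficient matrix, which at the sizes
this package targets (≤ ~2,000 equations) costs milliseconds; the simplex
search is derivative-free and hence robust to the flat ridges that trip
quasi-Newton REML on small data. A test verifies that the optimum is a
minimum of the textbook dense-V restricted likelihood. Variance components
are re-estimated for every inbreeding-coefficient fit (a config switch can
fix them instead). Standard errors come from the corresponding diagonal of
the inverted coefficient matrix times σ̂²_e; significance uses
z = β̂/se(β̂) against the standard normal (★/★★/★★★ at 0.05/0.01/0.001).

Zero variance components drop the corresponding random effect, so the model
degenerates exactly to (generalized) least squares — tested against OLS.

## ROH-based GWAS

Stage one fits the model above without inbreeding covariates and collapses
each animal to y_adj = û + p̂e + mean(ê). Stage two fits, per SNP k,
y_adj = μ1 + α_k x_k + β_k h_k + Zu + ε with u ~ (0, σ²_u A) over the
phenotyped animals. σ²_u and σ²_ε are estimated once by REML under the
null model μ + u + ε and held fixed across SNPs (GRAMMAR/EMMAX-style; a
`variance_mode` switch allows per-SNP re-estimation), making each SNP a
3-column GLS solve against a single Cholesky factor of V. Dosage enters
uncentered (μ absorbs the offset; β̂_k is invariant, tested). SNPs are
scanned only when more than 20 animals carry ROH state 1 — strictly more
than 20, i.e. ≥ 21 — separately per length class. A SNP whose dosage and
state columns are numerically collinear (condition number ≥ 10¹⁰) is
reported with NA effects and excluded from thresholding. Thresholds are
0.05/n (significant) and 1/n (suggestive) for the n SNPs actually scanned;
suggestive SNPs merge into regions when consecutive passing SNPs lie within
1 Mb (the same scale as the ROH gap rule; the merging radius is
configurable since no canonical rule exists), single-SNP regions allowed.

The two-stage procedure is an approximation: shrinkage in stage one leaks a
fraction of a regional effect into the polygenic term. On a single-group
fixture the two-stage β̂_k agrees with a one-stage joint fit within 10%,
which is the documented (not exact) tolerance.

## Synthetic-data generator

The generator is first-class, tested code and defines the study conditions:

- **Pedigree**: 50 founders, 5 generations of 100 offspring by default;
  the `sib_biased` scheme mates a sire to a full/half sib with probability
  0.3 (raising recent inbreeding the way repeated use of elite sires does
  in closed beef populations); `random` and `circular` schemes exist for
  calibration tests (random mating with selfing reproduces the
  1 − (1 − 1/2N)^t accumulation).
- **Genome**: 29 autosomes × 86 Mb at 1 SNP / 50 kb ≈ 49,880 SNPs — the
  scale of a bovine 50K array; founder allele frequencies uniform on
  [0.05, 0.5]; Haldane recombination (Poisson crossovers, no interference)
  at 1 cM/Mb. Truth is founder-haplotype identity (IBD), deliberately not
  allele sharing (IBS), so estimator accuracy is measurable.
- **Phenotypes**: trait mean 80 (a motility-like percentage), σ²_u = 2,
  σ²_pe = 1, σ²_e = 4, ~30 records per bull in 20 contemporary groups with
  N(0, 1) group effects, small interval-class effects, a centered quadratic
  age curve, and a genome-wide depression slope of −1 trait unit per unit
  *true* autozygous fraction. Planted recessive loci add their effect when
  the animal is truly autozygous across the position — the GWAS must then
  find them through the *detected* ROH state, which is precisely the
  method's inference problem.
- **Determinism**: three PRNG streams (pedigree, gene drop, phenotypes)
  derive from the master seed by fixed spawn keys; the full bundle is
  bit-for-bit reproducible and phenotype settings never perturb genotypes.

What the generator does **not** emulate: genotyping error and missingness
(error exists only inside the HBD emissions), mutation, selection,
assortative mating beyond the sib bias, varying recombination maps, linkage
disequilibrium among founder alleles (founder haplotypes are drawn
site-independently, so baseline LD is weaker than in real cattle), and sex
chromosomes. Passing tests therefore demonstrate correctness of the
estimators under the model's own assumptions, not robustness to array
artifacts or realistic LD decay.

## Simulation-study sizes

Monte-Carlo checks run at sizes chosen to give informative error bars while
keeping the whole suite quick to run:

- REML recovery: 20 replicates of 500 bulls × 30 records (the full study
  scale); mean components must fall within 15% of (2, 1, 4).
- Slope coverage: 50 replicates, 100 bulls × 10 records on a 5 × 60 Mb
  genome; the F_ROH8 estimate must cover −1 within ±2 SE in ≥ 90%.
- Type-I error: 400 null replicates, 80 bulls × 8 records, F_PED covariate;
  empirical rejection at α = 0.05 must lie in [3%, 7%].
- GWAS: 20 replicates, 200 bulls from four generations with strong sib
  bias (so the planted position has ample long-ROH carriers and enough
  recombination breakpoints among them for sharp localization), 5 × 50 Mb
  (~5,000 SNPs), planted recessive effect −5 residual SD; the genome-wide
  minimum p must fall within 1 Mb of the planted position in ≥ 80%, and
  with no planted locus zero Bonferroni-significant regions in ≥ 95%.
- HBD accuracy: 200 animals × 5,000 SNPs; corr(F_HBD, truth) ≥ 0.9.
- ROH caller: exact segment-for-segment agreement with a literal
  brute-force implementation on 100 random instances (≤ 50 animals × ≤ 300
  SNPs).

## Known limitations

- The REML search optimizes two variance ratios; models with more random
  terms would need a different parameterization.
- The HBD model fixes the rates; only mixing coefficients are estimated.
  Populations far from the 2^k ladder may need custom rates.
- The GWAS holds null variance components fixed across SNPs; very large
  regional effects slightly deflate σ²_ε and hence overstate z at the peak
  (conservative for specificity, anticonservative for the top SNP's
  nominal p).
- Region merging at 1 Mb is a pragmatic default; published region tables
  built with unknown merging rules cannot be reproduced exactly.
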