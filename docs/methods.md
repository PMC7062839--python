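# Methods

## Model and procedure

`condfdr` implements a cross-trait pleiotropy analysis on GWAS summary
statistics.  The pipeline runs: read → INFO/MAF filter → allele
harmonization → optional region exclusion → LD pruning → stratified
fold-enrichment and conditional Q–Q curves → conditional FDR in both
directions → conjunction FDR → MR-Egger → nearest-gene locus reports.

### Harmonization

Two tables are inner-joined on rsID (a chrom:pos fallback is available) and
trait B's effects are re-oriented onto trait A's allele coding.  Four cases
are resolved per SNP: identical alleles, swapped alleles (beta negated),
strand complement, and complement-plus-swap (negated).  A/T and C/G SNPs
are strand-ambiguous — orientation is undecidable without allele-frequency
comparison — and are dropped by default.  Odds ratios are converted to
log-odds at load time so all downstream arithmetic is on one scale; SEs of
OR-style inputs are assumed to be on the log-odds scale, the standard GWAS
convention.  p = 0 entries are clamped to the smallest positive double
(needed by the −log₁₀ grids) and counted.  Region exclusion (e.g. the APOE
interval) is inclusive on both ends, 1-based, matching hg19 coordinate
conventions.

### Conditional FDR estimator

Q(A|B)ᵢ = p₁ᵢ / F̂(p₁ᵢ | p₂ ≤ p₂ᵢ) with π₀ ≡ 1.  The implementation is a
lookup table:

* −log₁₀ p₁ nodes: 401 equally spaced points on [0, 20] by default;
* conditioning levels −log₁₀ p₂ ∈ {0, 1, 2, 3}, extended by further integer
  levels while the conditioning subset keeps at least `min_count` SNPs
  (default 100) and coarsened by dropping under-populated levels — an ECDF
  with fewer members is too unstable to condition on;
* cell value p₁/(conditional ECDF), capped at 1;
* monotonization by cumulative minimum along p₁ within each level (the
  step-up convention that makes the estimator reduce exactly to the BH
  q-value when conditioning is uninformative) **and** along the level axis
  from loose to strict, so that tightening the secondary threshold never
  increases the estimate;
* per-SNP assignment by bilinear interpolation on the two −log₁₀ scales,
  clamped at the grid boundary, floored at the SNP's own p₁ (the π₀ = 1
  conservativeness bound Q ≥ p₁).

The two-axis monotonization is a design choice where the published
framework leaves the surface-smoothing details open; it guarantees the
dominance property (conditioning harder never hurts a SNP) that the
stratified enrichment plots visualize, at the cost of a slight liberality
under the null that the calibration suite bounds empirically.  A
`GridSpec(at_data=True)` mode places nodes and levels exactly at the
observed p-values, making the lookup exact; the test suite uses it to match
an O(n²) direct-definition oracle to 1e-9.

Ties at the smallest grid node are clamped, never dropped.  Nothing in this
module is stochastic; input-order dependence is removed by sorting on
(chrom, pos, snp_id) before grid construction.

The conjunction FDR is the elementwise maximum of the two directional Qs.
Tier thresholds (0.05 significant, 1e-5 suggestive, 5e-8 genome-wide)
compare with ≤ at the boundary.

### Fold enrichment and conditional Q–Q

FE_s(t) compares the fraction of primary-significant SNPs inside a
secondary stratum against the all-SNP baseline; the all-SNP stratum is
identically 1, and cells with an empty numerator or baseline are reported
missing rather than extrapolated.  Default strata p₂ ≤ {1, 0.1, 0.01,
0.001} follow the four-curve convention of stratified-enrichment plots.
Q–Q curves plot observed −log₁₀ p₁ order statistics against uniform
quantiles i/(n+1) per stratum; strata under 10 SNPs are flagged low-count.

### LD operations

r² is the squared Pearson correlation of dosage vectors.  D' is |D|
normalized by its frequency-determined bound; for unphased panels the four
two-locus haplotype frequencies are estimated by the classic EM over the
double-heterozygote ambiguity (50 iterations, tolerance 1e-10;
non-convergence yields a flagged missing value), while phased panels use
haplotype counts directly.

Pruning removes, within a window (default 1,000 kb — pruning is windowed
for tractability; LD is local, and the fixed-point oracle in the tests
validates window sufficiency on synthetic panels), the lower-MAF member of
any pair with r² above the threshold (default 0.2).  MAF is taken from the
summary statistics when present, else from the panel; exact ties keep the
SNP with the smaller primary p-value, then the lexicographically smaller
rsID.  The left-to-right single pass reaches the fixed point because every
surviving pair was tested while both members were alive.  SNPs absent from
the panel pass through (counted).

Clumping is greedy by ascending p-value: an index SNP excludes later
candidates within the distance window or above the r² threshold against any
kept SNP.  Panel-absent SNPs skip the LD test but not the distance test —
conservative in both pruning and clumping roles.  Whether the per-SNP
conditional FDR is computed on pruned or unpruned SNPs is configurable
(`prune_for`), defaulting to pruning for the enrichment curves only.

Proxy search returns SNPs with r² above a floor (default 0.9) and D' equal
to 1 within 1e-6, sorted by descending r².

### MR-Egger

Instruments are exposure SNPs at p ≤ 1e-8 after clumping (r² 0.001, 10 kb
by default — the thresholds follow the published analysis even where 5e-8
would be the conventional choice), harmonized with the outcome table and
oriented so every exposure beta is non-negative (without this convention
the intercept is not identifiable).  The fit is WLS with a free intercept
and weights 1/se²_outcome; SEs come from the residual-scaled WLS
covariance, and p-values/CIs use the t distribution with n−2 df (normal
approximation by flag).  No exposure-measurement-error correction is
applied (first-order weights only).

Note on the published clump r² of 0.001: with a finite panel of n
individuals, sample r² between truly independent SNPs has mean ≈ 1/n, so
thresholds below ~3/n are indistinguishable from estimation noise and leave
essentially one instrument.  Synthetic runs therefore use a clump r² above
that floor (0.05 for the 500-individual default panel); the published value
remains the default for real panels of realistic depth, where LD structure,
not noise, dominates.

On the synthetic architecture the shared-effect class is *correlated*
pleiotropy (effects on both traits with correlation ρ), which violates the
Egger InSIDE assumption; with many instruments the intercept test therefore
rejects — detecting exactly the directional pleiotropy that was planted.
The estimator's frequentist calibration is instead verified on simulations
with valid instruments, where the 95% CI covers a planted slope of ln(1.4)
at nominal rate.

### Annotation and reporting

Nearest-gene distance is measured to the closest interval edge (0 inside);
strand is ignored for proximity.  Exact distance ties go to the
alphabetically first gene name and are flagged.  BED input (0-based
half-open) is converted to 1-based inclusive internally.  Locus reports are
sorted by nearest-gene name; printed precision is 3 decimals for betas/ORs
and 2-mantissa-digit scientific notation for p/Q.  Manhattan reference
lines: −log₁₀(5e-8) and −log₁₀(1e-5) for conditional plots, −log₁₀(0.05)
and −log₁₀(0.1) for conjunction plots.

## Synthetic data generator

The generator emulates the structure of two case-control GWAS:

* **Panel.**  Haplotypes are a latent Gaussian AR(1) (coefficient 0.9)
  thresholded at the per-SNP allele-frequency quantile; the process
  restarts at block boundaries (block sizes uniform on [20, 80] SNPs), so
  adjacent-SNP r² decays with distance and blocks are independent.  Dosage
  is the sum of two haplotypes; phase can be retained for D' tests.
* **Architecture.**  Per-SNP class ∈ {null, A-only, B-only, shared} with
  default proportions (0.85, 0.05, 0.05, 0.05); effect SDs σ_A = 0.03,
  σ_B = 0.02 (typical complex-trait log-OR magnitudes); shared effects
  bivariate normal with correlation ρ = 0.8.
* **Summary statistics.**  se = 1/√(2·maf·(1−maf)·n_eff) with
  n_eff = 4/(1/cases + 1/controls); observed beta = true beta + N(0, se);
  two-sided Wald p.  Default sample sizes are those of the two motivating
  consortium studies (21,982/41,944 and 59,851/113,154 cases/controls).
  Trait B is emitted on the OR scale with INFO ~ U(0.6, 1.05), trait A on
  the beta scale without INFO, mirroring the two source dialects.
* **Dominant region.**  An optional 200-SNP window on chromosome 19 whose
  trait-A effect SD is inflated 20-fold, reproducing a locus with p-values
  many orders of magnitude beyond the genome-wide background and the
  masking it causes in conditional analyses.

Statistics are generated at the summary level (true effect + sampling
noise) rather than from individual-level phenotypes: orders of magnitude
faster and sufficient for every statistic the pipeline computes, with the
panel individual-level only where LD matters (pruning, clumping, proxies).
What the generator does **not** emulate: LD-induced correlation between
neighboring SNPs' test statistics (true effects are per-SNP independent
draws), realistic human LD maps and allele-frequency spectra, population
stratification, and sample overlap between the two studies.  Passing tests
therefore demonstrate the estimators' algorithmic correctness and
calibration under idealized sampling, not robustness to those real-data
complications.

All generators are pure functions of (spec, seed).

## Problem sizes and numerical choices

The default test/acceptance scale — 100,000 SNPs over 22 pseudo-chromosomes
(5 kb spacing) and a 500-individual panel — runs the full pipeline in
minutes while leaving thousands of SNPs in the strictest stratum.
Calibration checks use 50,000 independent SNPs × 20 seeds; coverage checks
use 500 replicates of 50 instruments.  Tolerances: grid-vs-oracle 1e-9
(exact-node mode), WLS-vs-normal-equations 1e-10, EM D' vs phased D' 0.05
(phase-uncertainty gap on 2,000 haplotypes).

## Known limitations

* π₀ is fixed at 1 (Storey-style estimation is deliberately out of scope),
  so Q is conservative for strongly non-null mixtures.
* No covariate-adjusted or LD-score-weighted conditional FDR variants; no
  local true-discovery-rate estimation.
* Genome-build liftover, multi-allelic splitting and imputation are out of
  scope; inputs must share a build.
* MR estimators beyond Egger (IVW, weighted median, MR-PRESSO) and Steiger
  filtering are not implemented.
* External annotation services (pathway enrichment, eQTL lookups, tissue
  expression) are interface-level only: the reports emit SNP/gene lists in
  formats those tools accept.
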