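# condfdr

Cross-trait pleiotropy analysis for GWAS summary statistics: conditional and
conjunction false-discovery rates, stratified fold-enrichment and conditional
Q–Q curves, LD pruning and clumping against a reference panel, two-sample
MR-Egger, and nearest-gene locus reporting — plus a synthetic-data generator
so the whole pipeline is testable offline.

## The problem

Two complex diseases that co-occur clinically (the motivating pair is
late-onset Alzheimer's disease and major depressive disorder) may share
genetic risk variants that neither GWAS detects on its own.  Given only the
two studies' summary statistics (per-SNP effect size, standard error,
p-value), `condfdr` asks: does evidence of association with trait B make a
SNP more likely to be associated with trait A, and which SNPs are jointly
implicated?

## The statistics

**Conditional FDR.**  For a SNP with p-values (p₁, p₂) for the primary and
secondary trait, the conditional FDR is

    Q(A|B)ᵢ = p₁ᵢ / F̂(p₁ᵢ | p₂ ≤ p₂ᵢ)

where F̂ is the empirical CDF of p₁ among SNPs whose secondary p-value is at
most p₂ᵢ, with the null proportion π₀ fixed at 1 (a conservative upper
bound).  When the secondary trait is uninformative this reduces exactly to
the Benjamini–Hochberg q-value p·N/rank with step-up monotonization.  The
estimator is a 2-D lookup table over −log₁₀ p₁ nodes × secondary
conditioning thresholds, monotonized in both axes, with per-SNP bilinear
interpolation.

**Conjunction conditional FDR.**  ccFDRᵢ = max(Q(A|B)ᵢ, Q(B|A)ᵢ) — an upper
bound on the probability that the SNP is null for at least one trait; small
values flag jointly associated (pleiotropic) SNPs.

**Fold enrichment.**  FE_s(t) = [#{p₂ ≤ s, p₁ ≤ 10⁻ᵗ}/#{p₂ ≤ s}] ÷
[#{p₁ ≤ 10⁻ᵗ}/N]: the proportion of trait-A-significant SNPs inside a
trait-B stratum relative to all SNPs.  Curves rising with stricter strata
are the graphical signature of pleiotropic enrichment.  SNPs are first
LD-pruned (r² > 0.2 within a window removes the lower-MAF member), and a
single dominant locus (e.g. the APOE region, chr19:45,111,942–45,711,941 on
hg19) can be excluded, since its extreme signal otherwise masks the rest.

**MR-Egger.**  Two-sample Mendelian randomization with the clumped
genome-wide-significant SNPs of the exposure trait as instruments: weighted
least squares of outcome betas on exposure betas with a free intercept
(weights 1/se²_outcome, t-inference on n−2 df).  The slope estimates the
causal log-OR; a non-zero intercept indicates directional horizontal
pleiotropy.

## Worked example

```python
import numpy as np
import condfdr as cf

# two traits, 20k SNPs, 5% shared variants (rho = 0.8), one planted
# extreme-effect region on "chromosome 19"
spec = cf.ArchitectureSpec(n_snps=20_000, seed=42, apoe_like=cf.ApoeLikeSpec())
a, b, truth = cf.simulate_sumstats(spec)
m = cf.merge_traits(a, b)

fe = cf.fold_enrichment(m, direction="A|B")
i5 = int(np.searchsorted(fe.grid, 5.0))
print(np.round(fe.fe[:, i5], 2))
# [1.   2.66 5.42 6.6 ]   <- enrichment grows as the secondary stratum tightens

excl = cf.exclude_region(m, cf.default_apoe_region(spec))
fe2 = cf.fold_enrichment(excl, direction="A|B")
print(np.nanmax(fe.fe), np.nanmax(fe2.fe))
# 6.6  10.2               <- removing the dominant region unmasks enrichment

both = cf.conjunction(cf.cfdr(excl, "A|B"), cf.cfdr(excl, "B|A"))
tiers = cf.call_significant(both, value="q_ab")
print((tiers.q_ab <= 0.05).sum(), (tiers.q_ab <= 5e-8).sum(),
      (tiers.cc <= 0.05).sum())
# 1051 326 416            <- significant / genome-wide / conjunction calls
```

The first line shows fold enrichment at nominal −log₁₀(p) = 5 for secondary
strata p₂ ≤ {1, 0.1, 0.01, 0.001}: the all-SNP stratum is 1 by definition
and enrichment rises to 6.6-fold in the strictest stratum.  The second block
shows the masking effect of the planted dominant locus.  The third block
counts SNPs passing the conditional-FDR significance (Q ≤ 0.05),
genome-wide (Q ≤ 5×10⁻⁸) and conjunction (ccFDR ≤ 0.05) thresholds.

## Command line

```bash
condfdr simulate --outdir data --n-snps 100000 --n-individuals 500 --seed 1
condfdr run --config analysis.yaml        # full pipeline + manifest.json
condfdr cfdr --merged merged.tsv --out cfdr.tsv
condfdr mr --exposure a.tsv --outcome b.tsv --panel panel.tsv --out mr.tsv
condfdr report --cfdr-table cfdr.tsv --merged merged.tsv --genes genes.bed \
    --out loci.tsv
```

The YAML config mirrors `condfdr.RunConfig` (paths, column schemas, INFO/MAF
filters, excluded regions, pruning/clumping parameters, strata, thresholds).
Outputs land in `out/{tables,curves,figures}` with a `manifest.json`
recording input checksums, parameters and per-stage row counts.

## Running on real summary statistics

The pipeline reads any tab-delimited summary statistics through a column
map; both beta-scale and odds-ratio-scale inputs are supported (ORs are
log-transformed on load, SEs taken as log-odds-scale).  A typical real run
uses two consortium files (~10⁷ SNPs each), a 1000 Genomes European panel
for LD, and a gene BED for annotation; filters match the conventional
choices (0.6 ≤ INFO < 1.06, MAF > 0.01), and the APOE region is excluded in
a second pass.  None of these downloads is required to build or test the
package.

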