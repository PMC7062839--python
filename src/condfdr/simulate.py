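"""Synthetic two-trait GWAS data with a controllable pleiotropic
architecture.

The generator emulates the structure of real case-control GWAS summary
statistics so every pipeline stage is testable without downloads:

* a block-structured reference panel — within a block, haplotypes come from
  a thresholded latent AR(1) process, so adjacent-SNP r² decays with
  distance; blocks are independent;
* two traits with a four-class per-SNP effect architecture (null / trait-A
  only / trait-B only / shared), shared effects drawn bivariate-normal with
  correlation ρ;
* Wald-statistic summary stats: the per-SNP standard error follows the
  binary-trait approximation se ≈ 1/√(2·maf·(1−maf)·n_eff) with
  n_eff = 4/(1/cases + 1/controls), the observed beta is the true beta plus
  N(0, se) sampling noise, and p is the two-sided Wald p-value;
* an optional planted extreme-effect region on one chromosome (trait-A
  effect SD inflated by a large factor), reproducing the situation where a
  single dominant locus masks the rest of the conditional signal.

Statistics are generated directly at the summary level (true effect +
sampling noise) rather than via individual-level phenotypes; the panel is
individual-level only where LD actually matters (pruning, clumping, proxy
search).  Every generator is a pure function of (spec, seed).

Default sample sizes follow the two source consortium studies (21,982 /
41,944 and 59,851 / 113,154 cases/controls).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from .ld import ReferencePanel
from .sumstats import (P_FLOOR, GenomicRegion, MergedPair, SumstatsTable,
                       harmonize)

logger = logging.getLogger("condfdr")


@dataclass(frozen=True)
class ApoeLikeSpec:
    """A planted region of extreme trait-A effects on one chromosome.

    When ``start``/``end`` are None the region is an ``n_snps``-wide window
    centered on the chromosome.
    """

    chrom: str = "19"
    start: int | None = None
    end: int | None = None
    n_snps: int = 200
    sigma_factor: float = 20.0


@dataclass(frozen=True)
class ArchitectureSpec:
    """Genome grid, effect architecture, and sample sizes for the generator."""

    n_snps: int = 100_000
    n_chromosomes: int = 22
    snp_spacing_bp: int = 5_000
    block_size_range: tuple = (20, 80)
    ar_rho: float = 0.9                 # latent-haplotype AR(1) correlation
    maf_bounds: tuple = (0.01, 0.5)
    pi_null: float = 0.85
    pi_a_only: float = 0.05
    pi_b_only: float = 0.05
    pi_shared: float = 0.05
    sigma_a: float = 0.03
    sigma_b: float = 0.02
    rho: float = 0.8                    # shared-effect correlation
    n1_cases: int = 21_982
    n1_controls: int = 41_944
    n2_cases: int = 59_851
    n2_controls: int = 113_154
    apoe_like: ApoeLikeSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        pis = (self.pi_null, self.pi_a_only, self.pi_b_only, self.pi_shared)
        if any(p < 0 for p in pis) or abs(sum(pis) - 1.0) > 1e-12:
            raise ValueError(f"mixture proportions must be >= 0 and sum to 1, got {pis}")
        if not (-1.0 <= self.rho <= 1.0):
            raise ValueError(f"rho must be in [-1, 1], got {self.rho}")
        lo, hi = self.maf_bounds
        if not (0 < lo < hi <= 0.5):
            raise ValueError(f"maf_bounds must satisfy 0 < lo < hi <= 0.5, got {self.maf_bounds}")
        if self.n_snps < 1 or self.n_chromosomes < 1:
            raise ValueError("n_snps and n_chromosomes must be positive")

    @property
    def pis(self) -> np.ndarray:
        return np.array([self.pi_null, self.pi_a_only, self.pi_b_only,
                         self.pi_shared])


CLASS_NAMES = np.array(["null", "A", "B", "shared"])


@dataclass
class TruthTable:
    """Ground-truth effect class and effect sizes per SNP."""

    df: pd.DataFrame  # snp_id, true_class, beta_a_true, beta_b_true

    def __len__(self) -> int:
        return len(self.df)


def n_effective(cases: int, controls: int) -> float:
    """Effective sample size of a case-control study: 4/(1/cases + 1/controls)."""
    return 4.0 / (1.0 / cases + 1.0 / controls)


def _coordinates(spec: ArchitectureSpec):
    """Deterministic SNP grid: ids, chromosome labels and positions."""
    per = np.full(spec.n_chromosomes, spec.n_snps // spec.n_chromosomes)
    per[: spec.n_snps % spec.n_chromosomes] += 1
    chrom = np.repeat([str(c + 1) for c in range(spec.n_chromosomes)], per)
    pos = np.concatenate([
        (np.arange(k) + 1) * spec.snp_spacing_bp for k in per
    ]).astype(np.int64)
    ids = np.array([f"rs{i + 1}" for i in range(spec.n_snps)])
    return ids, chrom, pos


def default_apoe_region(spec: ArchitectureSpec) -> GenomicRegion:
    """The planted region as a genomic interval (for exclusion analyses)."""
    apoe = spec.apoe_like or ApoeLikeSpec()
    if apoe.start is not None and apoe.end is not None:
        return GenomicRegion(apoe.chrom, apoe.start, apoe.end)
    _, chrom, pos = _coordinates(spec)
    sel = chrom == str(apoe.chrom)
    if not sel.any():
        raise ValueError(f"chromosome {apoe.chrom} not in simulated grid")
    cpos = pos[sel]
    mid = len(cpos) // 2
    half = apoe.n_snps // 2
    lo = max(0, mid - half)
    hi = min(len(cpos) - 1, lo + apoe.n_snps - 1)
    return GenomicRegion(str(apoe.chrom), int(cpos[lo]), int(cpos[hi]))


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

def simulate_panel(spec: ArchitectureSpec, n_individuals: int,
                   store_haplotypes: bool = False) -> ReferencePanel:
    """Block-structured genotype panel.

    Haplotypes within a block are a latent Gaussian AR(1) (coefficient
    ``spec.ar_rho``) thresholded at the per-SNP allele-frequency quantile, so
    adjacent-SNP r² decays geometrically with distance and blocks are
    mutually independent.  Dosage = sum of the two haplotypes.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    rng = np.random.default_rng(spec.seed)
    ids, chrom, pos = _coordinates(spec)
    maf = rng.uniform(*spec.maf_bounds, size=spec.n_snps)
    thresh = scipy.stats.norm.ppf(maf)

    n_hap = 2 * n_individuals
    lo, hi = spec.block_size_range
    alleles = np.empty((n_hap, spec.n_snps), dtype=np.int8)
    start = 0
    sq = np.sqrt(1.0 - spec.ar_rho ** 2)
    for c in np.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        k = len(idx)
        # block boundaries restart the AR process
        sizes = []
        total = 0
        while total < k:
            s = int(rng.integers(lo, hi + 1))
            sizes.append(min(s, k - total))
            total += sizes[-1]
        z = np.empty((n_hap, k))
        j = 0
        for s in sizes:
            z[:, j] = rng.standard_normal(n_hap)
            for jj in range(j + 1, j + s):
                z[:, jj] = spec.ar_rho * z[:, jj - 1] + sq * rng.standard_normal(n_hap)
            j += s
        alleles[:, idx] = z < thresh[idx]
        start += k
    dosages = (alleles[0::2] + alleles[1::2]).astype(np.float64)
    haps = alleles if store_haplotypes else None
    return ReferencePanel(ids, chrom, pos, dosages, haplotypes=haps)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _wald_table(ids, chrom, pos, beta_true, se, rng) -> tuple[np.ndarray, np.ndarray]:
    beta = beta_true + rng.standard_normal(len(se)) * se
    p = 2.0 * scipy.stats.norm.sf(np.abs(beta / se))
    return beta, np.clip(p, P_FLOOR, 1.0)


def simulate_sumstats(spec: ArchitectureSpec,
                      panel: ReferencePanel | None = None
                      ) -> tuple[SumstatsTable, SumstatsTable, TruthTable]:
    """Two-trait Wald summary statistics plus the ground truth.

    With a panel, per-SNP MAF is the panel allele frequency (keeping the
    emitted MAF and the LD panel consistent); without one, MAF is drawn from
    the spec's bounds and no LD structure exists between summary statistics.
    Trait B is emitted on the odds-ratio scale with INFO ~ U(0.6, 1.05);
    trait A is beta-scale without INFO, mirroring the two source file
    dialects.  ``spec.apoe_like``, when set, is planted before emission.
    """
    rng = np.random.default_rng(spec.seed + 1)
    if panel is not None:
        if len(panel) != spec.n_snps:
            raise ValueError("panel size inconsistent with spec.n_snps")
        ids, chrom, pos = panel.snp_ids, panel.chrom, panel.pos
        freq = panel.dosages.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        maf = np.clip(maf, 1.0 / (2 * panel.n_individuals), 0.5)  # guard monomorphic
    else:
        ids, chrom, pos = _coordinates(spec)
        maf = rng.uniform(*spec.maf_bounds, size=spec.n_snps)

    classes = rng.choice(4, size=spec.n_snps, p=spec.pis)
    beta_a = np.zeros(spec.n_snps)
    beta_b = np.zeros(spec.n_snps)
    is_a = classes == 1
    is_b = classes == 2
    is_s = classes == 3
    beta_a[is_a] = rng.standard_normal(is_a.sum()) * spec.sigma_a
    beta_b[is_b] = rng.standard_normal(is_b.sum()) * spec.sigma_b
    u1 = rng.standard_normal(is_s.sum())
    u2 = rng.standard_normal(is_s.sum())
    beta_a[is_s] = spec.sigma_a * u1
    beta_b[is_s] = spec.sigma_b * (spec.rho * u1
                                   + np.sqrt(1.0 - spec.rho ** 2) * u2)

    if spec.apoe_like is not None:
        region = default_apoe_region(spec)
        in_region = region.contains(chrom, pos)
        beta_a[in_region] = (rng.standard_normal(int(in_region.sum()))
                             * spec.sigma_a * spec.apoe_like.sigma_factor)

    se_a = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf)
                         * n_effective(spec.n1_cases, spec.n1_controls))
    se_b = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf)
                         * n_effective(spec.n2_cases, spec.n2_controls))
    obs_a, p_a = _wald_table(ids, chrom, pos, beta_a, se_a, rng)
    obs_b, p_b = _wald_table(ids, chrom, pos, beta_b, se_b, rng)
    info_b = rng.uniform(0.6, 1.05, size=spec.n_snps)

    base = {"snp_id": ids, "chrom": chrom, "pos": pos,
            "effect_allele": "A", "other_allele": "G"}
    ta = SumstatsTable(pd.DataFrame({**base, "beta": obs_a, "se": se_a,
                                     "p": p_a, "info": np.nan, "maf": maf}),
                       effect_scale="beta", n_cases=spec.n1_cases,
                       n_controls=spec.n1_controls)
    tb = SumstatsTable(pd.DataFrame({**base, "beta": obs_b, "se": se_b,
                                     "p": p_b, "info": info_b, "maf": maf}),
                       effect_scale="or", n_cases=spec.n2_cases,
                       n_controls=spec.n2_controls)
    truth = TruthTable(pd.DataFrame({
        "snp_id": ids, "true_class": CLASS_NAMES[classes],
        "beta_a_true": beta_a, "beta_b_true": beta_b,
    }))
    return ta, tb, truth


def plant_apoe_like(a: SumstatsTable, truth: TruthTable, apoe: ApoeLikeSpec,
                    region: GenomicRegion, seed: int,
                    sigma_a: float = ArchitectureSpec.sigma_a
                    ) -> tuple[SumstatsTable, TruthTable]:
    """Re-draw trait-A effects inside ``region`` with the effect SD inflated
    by ``apoe.sigma_factor`` and re-emit observed beta/p for those SNPs.

    Standalone variant for tables that were generated without
    ``spec.apoe_like``; a factor of 1 is a distributional no-op.
    """
    rng = np.random.default_rng(seed)
    df = a.df.copy()
    tdf = truth.df.copy()
    sel = region.contains(df["chrom"], df["pos"])
    k = int(sel.sum())
    if k == 0:
        raise ValueError("planted region contains no SNPs")
    beta_true = rng.standard_normal(k) * sigma_a * apoe.sigma_factor
    se = df.loc[sel, "se"].to_numpy()
    beta = beta_true + rng.standard_normal(k) * se
    p = np.clip(2.0 * scipy.stats.norm.sf(np.abs(beta / se)), P_FLOOR, 1.0)
    df.loc[sel, "beta"] = beta
    df.loc[sel, "p"] = p
    tdf.loc[sel, "beta_a_true"] = beta_true
    out = SumstatsTable(df, build=a.build, effect_scale=a.effect_scale,
                        n_cases=a.n_cases, n_controls=a.n_controls)
    return out, TruthTable(tdf)


def merge_traits(a: SumstatsTable, b: SumstatsTable,
                 label_a: str = "A", label_b: str = "B") -> MergedPair:
    """Harmonize the two simulated tables (identity orientation by
    construction)."""
    return harmonize(a, b, drop_ambiguous=True, label_a=label_a, label_b=label_b)


# ---------------------------------------------------------------------------
# gene intervals
# ---------------------------------------------------------------------------

def simulate_genes(spec: ArchitectureSpec, genes_per_chrom: int = 30,
                   seed: int | None = None):
    """Random non-overlapping gene intervals covering the simulated grid."""
    from .annotate import GeneIntervals

    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    _, chrom, pos = _coordinates(spec)
    rows = []
    for c in np.unique(chrom):
        cmax = int(pos[chrom == c].max())
        n = min(genes_per_chrom, max(1, cmax // 20_000))
        edges = np.sort(rng.choice(np.arange(1, cmax), size=2 * n, replace=False))
        for g in range(n):
            start, end = int(edges[2 * g]), int(edges[2 * g + 1])
            rows.append((f"GENE{c}_{g + 1}", str(c), start, end))
    df = pd.DataFrame(rows, columns=["name", "chrom", "start", "end"])
    return GeneIntervals(df)


# ---------------------------------------------------------------------------
# file emission (the exact dialects the readers consume)
# ---------------------------------------------------------------------------

def write_dataset(outdir, spec: ArchitectureSpec, panel: ReferencePanel,
                  a: SumstatsTable, b: SumstatsTable, truth: TruthTable,
                  genes=None) -> dict:
    """Write panel matrix, the two summary-statistics dialects, the truth
    table and a gene BED under ``outdir``; returns the path map."""
    import pathlib

    from .ld import write_panel_tsv

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    pa = outdir / "trait_a.tsv"
    da = a.df.rename(columns={"snp_id": "SNP", "chrom": "CHR", "pos": "BP",
                              "effect_allele": "A1", "other_allele": "A2",
                              "beta": "BETA", "se": "SE", "p": "P",
                              "maf": "MAF"}).drop(columns=["info"])
    da.to_csv(pa, sep="\t", index=False)
    paths["sumstats_a"] = str(pa)

    pb = outdir / "trait_b.tsv"
    db = b.df.copy()
    db["beta"] = np.exp(db["beta"])
    db = db.rename(columns={"snp_id": "SNP", "chrom": "CHR", "pos": "BP",
                            "effect_allele": "A1", "other_allele": "A2",
                            "beta": "OR", "se": "SE", "p": "P",
                            "info": "INFO", "maf": "FRQ"})
    db.to_csv(pb, sep="\t", index=False)
    paths["sumstats_b"] = str(pb)

    pp = outdir / "panel.tsv"
    write_panel_tsv(panel, pp)
    paths["panel"] = str(pp)

    pt = outdir / "truth.tsv"
    truth.df.to_csv(pt, sep="\t", index=False)
    paths["truth"] = str(pt)

    if genes is None:
        genes = simulate_genes(spec)
    pg = outdir / "genes.bed"
    bed = genes.df.copy()
    bed["start0"] = bed["start"] - 1
    bed[["chrom", "start0", "end", "name"]].to_csv(pg, sep="\t", index=False,
                                                   header=False)
    paths["genes"] = str(pg)
    return paths


#: column schemas of the two emitted dialects, consumable by read_sumstats
TRAIT_A_SCHEMA = {"snp_id": "SNP", "chrom": "CHR", "pos": "BP",
                  "effect_allele": "A1", "other_allele": "A2",
                  "beta": "BETA", "se": "SE", "p": "P", "maf": "MAF"}
TRAIT_B_SCHEMA = {"snp_id": "SNP", "chrom": "CHR", "pos": "BP",
                  "effect_allele": "A1", "other_allele": "A2",
                  "or": "OR", "se": "SE", "p": "P", "info": "INFO",
                  "maf": "FRQ"}
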