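"""Linkage-disequilibrium operations on a reference genotype panel.

The panel is a SNP-by-individual dosage matrix (0/1/2 or fractional) from
which pairwise r² (squared Pearson correlation of dosages) and D' (|D|
normalized by its bound given the allele frequencies) are computed.  On top
of these sit the three selection procedures the pipeline needs:

* ``prune``   — remove the lower-MAF member of any pair with r² above a
  threshold (used before polygenic-enrichment curves),
* ``clump``   — greedy index-SNP selection by ascending p-value with distance
  and r² exclusion (used for MR instrument selection),
* ``find_proxies`` — LD surrogates of an index SNP (D' = 1, r² above a floor).

For unphased dosages, two-locus haplotype frequencies for D' are estimated by
the classic EM over the double-heterozygote phase ambiguity; phased panels
bypass EM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("condfdr")


class UndefinedLdError(ValueError):
    """LD is undefined (a SNP has zero dosage variance)."""


@dataclass
class ReferencePanel:
    """Genotype dosages for LD computation.

    ``dosages`` is individuals × SNPs with values in [0, 2]; ``haplotypes``
    (2·individuals × SNPs, 0/1), when present, marks the panel as phased.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray
    maf: np.ndarray = field(default=None)
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=str)
        self.chrom = np.asarray(self.chrom, dtype=str)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("dosages must be individuals x SNPs")
        if len(np.unique(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate snp_id in panel")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValueError("dosages outside [0, 2]")
        freq = self.dosages.mean(axis=0) / 2.0
        computed = np.minimum(freq, 1.0 - freq)
        if self.maf is None:
            self.maf = computed
        else:
            self.maf = np.asarray(self.maf, dtype=float)
            if np.max(np.abs(self.maf - computed)) > 1e-12:
                raise ValueError("stored MAF inconsistent with dosages")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def __len__(self) -> int:
        return len(self.snp_ids)

    def __contains__(self, snp_id) -> bool:
        return snp_id in self._index

    def loc(self, snp_id) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in reference panel") from None


@dataclass(frozen=True)
class LdPair:
    """One pairwise LD record; symmetric in (snp_i, snp_j)."""

    snp_i: str
    snp_j: str
    r2: float
    d_prime: float | None = None


# ---------------------------------------------------------------------------
# pairwise statistics
# ---------------------------------------------------------------------------

def compute_r2(panel: ReferencePanel, i, j) -> float:
    """Squared Pearson correlation of the two SNPs' dosage vectors."""
    xi = panel.dosages[:, panel.loc(i)]
    xj = panel.dosages[:, panel.loc(j)]
    return _r2_vec(xi, xj)


def _r2_vec(xi: np.ndarray, xj: np.ndarray) -> float:
    vi, vj = np.var(xi), np.var(xj)
    if vi == 0 or vj == 0:
        raise UndefinedLdError("zero dosage variance: r2 undefined")
    cov = np.mean((xi - xi.mean()) * (xj - xj.mean()))
    return min(float(cov * cov / (vi * vj)), 1.0)


def _em_haplotype_freqs(gi: np.ndarray, gj: np.ndarray, max_iter: int = 50,
                        tol: float = 1e-10) -> np.ndarray | None:
    """Two-locus haplotype frequencies (pAB, pAb, paB, pab) from unphased
    0/1/2 genotypes; 'A'/'B' denote the alt allele at each locus.

    Returns None on non-convergence.
    """
    gi = np.rint(gi).astype(int)
    gj = np.rint(gj).astype(int)
    counts = np.zeros((3, 3))
    for a, b in zip(gi, gj):
        counts[a, b] += 1
    n_hap = 2 * len(gi)
    pA = gi.mean() / 2.0
    pB = gj.mean() / 2.0
    # start from linkage equilibrium
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    n_dh = counts[1, 1]  # double heterozygotes: phase-ambiguous
    for _ in range(max_iter):
        denom = f[0] * f[3] + f[1] * f[2]
        x = n_dh * (f[0] * f[3]) / denom if denom > 0 else 0.0  # E[AB/ab pairs]
        nAB = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + x
        nAb = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0] + (n_dh - x)
        naB = 2 * counts[0, 2] + counts[1, 2] + counts[0, 1] + (n_dh - x)
        nab = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0] + x
        new = np.array([nAB, nAb, naB, nab]) / n_hap
        if np.max(np.abs(new - f)) < tol:
            return new
        f = new
    logger.warning("haplotype EM did not converge in %d iterations", max_iter)
    return None


def _d_prime_from_freqs(f: np.ndarray) -> float:
    pAB, pAb, paB, pab = f
    pA = pAB + pAb
    pB = pAB + paB
    D = pAB - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax == 0:
        return 0.0
    return min(abs(D) / dmax, 1.0)


def compute_d_prime(panel: ReferencePanel, i, j) -> float | None:
    """|D| normalized by its maximum given the allele frequencies, in [0, 1].

    Phased panels use haplotype counts directly; unphased panels estimate the
    four haplotype frequencies by EM (returns None — a flagged missing value —
    if EM fails to converge).
    """
    ii, jj = panel.loc(i), panel.loc(j)
    if panel.haplotypes is not None:
        hi = panel.haplotypes[:, ii].astype(int)
        hj = panel.haplotypes[:, jj].astype(int)
        n = len(hi)
        f = np.array([
            np.sum((hi == 1) & (hj == 1)),
            np.sum((hi == 1) & (hj == 0)),
            np.sum((hi == 0) & (hj == 1)),
            np.sum((hi == 0) & (hj == 0)),
        ]) / n
    else:
        gi = panel.dosages[:, ii]
        gj = panel.dosages[:, jj]
        if np.var(gi) == 0 or np.var(gj) == 0:
            raise UndefinedLdError("zero dosage variance: D' undefined")
        f = _em_haplotype_freqs(gi, gj)
        if f is None:
            return None
    return _d_prime_from_freqs(f)


# ---------------------------------------------------------------------------
# pruning (enrichment analyses)
# ---------------------------------------------------------------------------

def prune(m, panel: ReferencePanel, r2_threshold: float = 0.2,
          window_kb: int = 1000):
    """LD-prune a merged table: within a window, whenever a pair exceeds the
    r² threshold, drop the member with the lower minor allele frequency.

    The scan runs left-to-right in (chrom, pos) order; each SNP is compared
    against every surviving SNP ahead of it within ``window_kb``.  A single
    pass reaches the fixed point: any surviving pair was tested while both
    members were alive.  MAF for the removal rule is the summary-statistics
    MAF when present, else the panel MAF; exact ties keep the SNP with the
    smaller p1, then the lexicographically smaller snp_id.  SNPs absent from
    the panel pass through untouched (counted in the log).
    """
    from .sumstats import MergedPair

    if not (0 < r2_threshold <= 1):
        raise ValueError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    ms = m.sorted()
    df = ms.df
    n = len(df)
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    snp_ids = df["snp_id"].to_numpy()
    p1 = df["p1"].to_numpy()

    col = np.array([panel._index.get(s, -1) for s in snp_ids])
    covered = col >= 0
    n_uncovered = int((~covered).sum())
    if n_uncovered:
        logger.info("prune: %d SNPs absent from panel pass through", n_uncovered)

    maf = df["maf"].to_numpy(dtype=float).copy()
    use_panel_maf = np.isnan(maf) & covered
    maf[use_panel_maf] = panel.maf[col[use_panel_maf]]

    # standardized dosage columns for covered SNPs -> r2 by dot product
    X = panel.dosages[:, col[covered]]
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    nonzero = sd > 0
    Z = np.zeros_like(Xc)
    Z[:, nonzero] = Xc[:, nonzero] / sd[nonzero]
    zcol = np.full(n, -1)
    zcol[covered] = np.arange(int(covered.sum()))

    window = window_kb * 1000
    alive = np.ones(n, dtype=bool)
    n_ind = panel.n_individuals

    for i in range(n):
        if not alive[i] or not covered[i]:
            continue
        j = i + 1
        while j < n and chrom[j] == chrom[i] and pos[j] - pos[i] <= window:
            j += 1
        cand = np.arange(i + 1, j)
        cand = cand[alive[cand] & covered[cand]]
        if len(cand) == 0:
            continue
        r2 = (Z[:, zcol[i]] @ Z[:, zcol[cand]] / n_ind) ** 2
        for k, r2k in zip(cand, r2):
            if r2k <= r2_threshold or not alive[i]:
                continue
            # drop the lower-MAF member; ties by larger p1, then snp_id
            key_i = (maf[i], -p1[i], _desc_key(snp_ids[i]))
            key_k = (maf[k], -p1[k], _desc_key(snp_ids[k]))
            if key_i < key_k:
                alive[i] = False
            else:
                alive[k] = False

    out = MergedPair(df[alive].reset_index(drop=True), ms.label_a, ms.label_b,
                     ms.n_dropped_mismatch, ms.n_dropped_ambiguous)
    logger.info("prune r2>%g window %dkb: %d -> %d SNPs",
                r2_threshold, window_kb, n, len(out))
    return out


class _desc_key(str):
    """Inverts string comparison so that min() on the tuple keeps the
    lexicographically *smaller* snp_id on an exact (maf, p1) tie."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)


# ---------------------------------------------------------------------------
# clumping (MR instrument selection)
# ---------------------------------------------------------------------------

def clump(t, panel: ReferencePanel, p_threshold: float,
          r2_threshold: float, distance_kb: float):
    """Greedy clumping by ascending p-value.

    Only SNPs with p ≤ ``p_threshold`` are considered.  Walking candidates
    from most to least significant, a SNP is kept as an index SNP unless it
    lies within ``distance_kb`` of, or has r² > ``r2_threshold`` with, any
    SNP already kept.  SNPs absent from the panel are excluded by the LD test
    only (the distance test still applies) — conservative, counted in the log.
    Returns a table of index SNPs (same type as the input).
    """
    from .sumstats import SumstatsTable, _copy_with

    if not (0 < r2_threshold <= 1):
        raise ValueError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    df = t.df[t.df["p"] <= p_threshold]
    # deterministic: p, then (chrom, pos, snp_id)
    df = df.sort_values(["p", "chrom", "pos", "snp_id"], kind="mergesort")
    kept_rows = []
    kept_chrom: list[str] = []
    kept_pos: list[int] = []
    kept_col: list[int] = []
    dist = distance_kb * 1000
    n_uncovered = 0
    for row in df.itertuples(index=False):
        ci = panel._index.get(row.snp_id, -1)
        if ci < 0:
            n_uncovered += 1
        excluded = False
        for kc, kp, kcol in zip(kept_chrom, kept_pos, kept_col):
            if kc == row.chrom and abs(int(row.pos) - kp) <= dist:
                excluded = True
                break
            if ci >= 0 and kcol >= 0:
                try:
                    r2 = _r2_vec(panel.dosages[:, ci], panel.dosages[:, kcol])
                except UndefinedLdError:
                    r2 = 0.0
                if r2 > r2_threshold:
                    excluded = True
                    break
        if not excluded:
            kept_rows.append(row)
            kept_chrom.append(row.chrom)
            kept_pos.append(int(row.pos))
            kept_col.append(ci)
    if n_uncovered:
        logger.info("clump: %d candidate SNPs absent from panel (LD test skipped)",
                    n_uncovered)
    out = pd.DataFrame(kept_rows, columns=df.columns)
    return _copy_with(t, out)


# ---------------------------------------------------------------------------
# proxy search
# ---------------------------------------------------------------------------

def find_proxies(panel: ReferencePanel, index, r2_min: float = 0.9,
                 d_prime_eq: float = 1.0, window_kb: int = 500,
                 tol: float = 1e-6) -> list[LdPair]:
    """SNPs within the window with r² > ``r2_min`` and D' equal to
    ``d_prime_eq`` within ``tol``, sorted by descending r².  The index SNP
    itself is never its own proxy."""
    ii = panel.loc(index)
    window = window_kb * 1000
    in_window = (
        (panel.chrom == panel.chrom[ii])
        & (np.abs(panel.pos - panel.pos[ii]) <= window)
    )
    out = []
    for jj in np.nonzero(in_window)[0]:
        if jj == ii:
            continue
        try:
            r2 = _r2_vec(panel.dosages[:, ii], panel.dosages[:, jj])
        except UndefinedLdError:
            continue
        if r2 <= r2_min:
            continue
        dp = compute_d_prime(panel, index, panel.snp_ids[jj])
        if dp is None or abs(dp - d_prime_eq) > tol:
            continue
        out.append(LdPair(str(index), str(panel.snp_ids[jj]), float(r2), float(dp)))
    out.sort(key=lambda pair: (-pair.r2, pair.snp_j))
    return out


# ---------------------------------------------------------------------------
# panel I/O
# ---------------------------------------------------------------------------

def read_panel_tsv(path) -> ReferencePanel:
    """Read the plain-matrix panel format: TSV with columns snp_id, chrom,
    pos, then one dosage column per individual."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    meta = ["snp_id", "chrom", "pos"]
    dosages = df.drop(columns=meta).to_numpy(dtype=float).T
    return ReferencePanel(df["snp_id"].to_numpy(), df["chrom"].to_numpy(),
                          df["pos"].to_numpy(), dosages)


def write_panel_tsv(panel: ReferencePanel, path) -> None:
    df = pd.DataFrame({"snp_id": panel.snp_ids, "chrom": panel.chrom,
                       "pos": panel.pos})
    dos = pd.DataFrame(panel.dosages.T,
                       columns=[f"ind{i}" for i in range(panel.n_individuals)])
    pd.concat([df, dos.set_index(df.index)], axis=1).to_csv(path, sep="\t",
                                                            index=False)


def read_panel_vcf(path) -> ReferencePanel:
    """Read a (plain-text) VCF into a phased reference panel via cyvcf2.

    Genotypes become dosages; phased GTs additionally populate haplotypes so
    D' skips the EM step.
    """
    from cyvcf2 import VCF

    ids, chroms, poss, dos, haps = [], [], [], [], []
    phased = True
    vcf = VCF(str(path))
    for var in vcf:
        gt = np.asarray(var.genotype.array())[:, :2]
        if gt.min() < 0:  # missing genotypes: skip site
            continue
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        dos.append(gt.sum(axis=1))
        haps.append(gt.reshape(-1))
        phased = phased and bool(np.all(var.gt_phases))
    vcf.close()
    dosages = np.asarray(dos, dtype=float).T
    haplotypes = np.asarray(haps, dtype=np.int8).T if phased else None
    return ReferencePanel(np.asarray(ids), np.asarray(chroms), np.asarray(poss),
                          dosages, haplotypes=haplotypes)
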