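"""Nearest-gene mapping, locus report tables, and Manhattan plot data.

Significant SNPs from the conditional-FDR analysis are mapped to the most
proximate gene (distance to the nearest interval edge, 0 inside), assembled
into a per-locus report with the per-trait effect sizes restored to their
native scales, and laid out on a cumulative genome coordinate for Manhattan
plots.  Interfaces with external annotation services are export-only: the
report TSVs carry the SNP and gene lists those tools accept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cfdr import CfdrResult, call_significant
from .sumstats import MergedPair

logger = logging.getLogger("condfdr")


@dataclass
class GeneIntervals:
    """Gene intervals, 1-based inclusive on both ends."""

    df: pd.DataFrame  # columns: name, chrom, start, end[, strand]

    def __post_init__(self) -> None:
        need = ["name", "chrom", "start", "end"]
        missing = [c for c in need if c not in self.df.columns]
        if missing:
            raise ValueError(f"gene table missing columns {missing}")
        if (self.df["start"] > self.df["end"]).any():
            raise ValueError("gene interval with start > end")
        if self.df.duplicated(["name", "chrom"]).any():
            raise ValueError("duplicate (name, chrom) in gene table")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


def read_genes_bed(path) -> GeneIntervals:
    """Read gene intervals from BED (0-based half-open; converted to 1-based
    inclusive) with the gene name in column 4."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "name"],
                     dtype={"chrom": str})
    df["start"] = df["start"].astype(np.int64) + 1
    df["end"] = df["end"].astype(np.int64)
    return GeneIntervals(df[["name", "chrom", "start", "end"]])


def read_genes_tsv(path) -> GeneIntervals:
    """Read the 4-column (name, chrom, start, end) 1-based inclusive TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GeneIntervals(df)


def nearest_gene(chrom: str, pos: int, genes: GeneIntervals,
                 max_distance_kb: float | None = None):
    """Most proximate gene to a position.

    Distance is to the nearest interval edge (0 inside the gene).  Exact
    distance ties go to the alphabetically first gene name and are flagged.
    Returns (name, distance, tied) or (None, None, False) when no gene on the
    chromosome lies within ``max_distance_kb`` (flagged intergenic).
    """
    sub = genes.df[genes.df["chrom"] == str(chrom)]
    if len(sub) == 0:
        logger.warning("nearest_gene: no genes on chromosome %s", chrom)
        return None, None, False
    start = sub["start"].to_numpy()
    end = sub["end"].to_numpy()
    dist = np.maximum.reduce([start - pos, pos - end,
                              np.zeros(len(sub), dtype=np.int64)])
    if max_distance_kb is not None and dist.min() > max_distance_kb * 1000:
        return None, None, False
    best = dist.min()
    hits = sorted(sub["name"].to_numpy()[dist == best])
    tied = len(hits) > 1
    if tied:
        logger.info("nearest_gene %s:%d: distance tie among %s", chrom, pos, hits)
    return hits[0], int(best), tied


#: locus-report column order (the published per-SNP result-table layout)
REPORT_COLUMNS = [
    "snp_id", "chrom", "pos", "nearest_gene", "distance_bp", "minor_allele",
    "maf", "q", "beta1", "se1", "p1", "or2", "se2", "p2", "tier", "gene_tie",
]


def build_locus_report(r: CfdrResult, m: MergedPair, genes: GeneIntervals,
                       tier: float = 0.05, value: str = "q_ab",
                       max_distance_kb: float | None = None) -> pd.DataFrame:
    """One row per SNP with Q ≤ ``tier``: nearest gene, allele/frequency
    info, Q, and the per-trait statistics with the odds-ratio-scale trait
    re-exponentiated.  Rows are sorted by nearest-gene name, then snp_id —
    a deterministic function of (result, gene set)."""
    tiers = call_significant(r, value=value)
    hit = tiers[tiers[value] <= tier]
    md = m.df.set_index("snp_id")
    rows = []
    for row in hit.itertuples(index=False):
        gene, dist, tied = nearest_gene(row.chrom, row.pos, genes,
                                        max_distance_kb=max_distance_kb)
        rec = md.loc[row.snp_id]
        rows.append({
            "snp_id": row.snp_id, "chrom": row.chrom, "pos": row.pos,
            "nearest_gene": gene if gene is not None else "intergenic",
            "distance_bp": dist if dist is not None else -1,
            "minor_allele": rec["ea"], "maf": rec["maf"],
            "q": getattr(row, value),
            "beta1": rec["beta1"], "se1": rec["se1"], "p1": rec["p1"],
            "or2": float(np.exp(rec["beta2"])), "se2": rec["se2"],
            "p2": rec["p2"], "tier": row.tier, "gene_tie": tied,
        })
    out = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return out.sort_values(["nearest_gene", "snp_id"]).reset_index(drop=True)


def format_report(report: pd.DataFrame) -> pd.DataFrame:
    """Printed-precision copy: betas/ORs to 3 decimals, p/Q in scientific
    notation with 2 mantissa digits."""
    out = report.copy()
    for c in ("beta1", "se1", "or2", "se2", "maf"):
        out[c] = out[c].map(lambda v: f"{v:.3f}")
    for c in ("q", "p1", "p2"):
        out[c] = out[c].map(lambda v: f"{v:.2E}")
    return out


#: Manhattan reference lines: conditional plots use the genome-wide and
#: suggestive association thresholds; conjunction plots use 0.05 / 0.1
CONDITIONAL_LINES = (5e-8, 1e-5)
CONJUNCTION_LINES = (0.05, 0.1)


def manhattan_data(r: CfdrResult, value: str = "q_ab",
                   gap: int = 1_000_000) -> tuple[pd.DataFrame, tuple]:
    """Per-SNP cumulative genome coordinate, −log10 of the chosen FDR column
    and a chromosome color index, plus the two reference-line levels
    (−log10) appropriate for the plot type."""
    if value not in r.df.columns:
        raise ValueError(f"column {value!r} not present in result")
    df = r.df.sort_values(["chrom", "pos", "snp_id"],
                          key=_chrom_sort_key).reset_index(drop=True)
    offset = 0
    coords = np.empty(len(df), dtype=np.int64)
    color = np.empty(len(df), dtype=np.int64)
    chroms = list(dict.fromkeys(df["chrom"]))
    for ci, chrom in enumerate(chroms):
        sel = (df["chrom"] == chrom).to_numpy()
        pos = df.loc[sel, "pos"].to_numpy()
        coords[sel] = pos + offset
        color[sel] = ci % 2
        offset = coords[sel].max() + gap
    lines = CONJUNCTION_LINES if value == "cc" else CONDITIONAL_LINES
    out = pd.DataFrame({
        "snp_id": df["snp_id"], "chrom": df["chrom"], "pos": df["pos"],
        "genome_coord": coords,
        "neg_log10_q": -np.log10(df[value].to_numpy(float)),
        "color_index": color,
    })
    return out, tuple(-np.log10(np.asarray(lines)))


def _chrom_sort_key(col: pd.Series) -> pd.Series:
    if col.name != "chrom":
        return col

    def key(c):
        try:
            return (0, int(c))
        except ValueError:
            return (1, str(c))

    return col.map(key)


def plot_manhattan(r: CfdrResult, value: str, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data, lines = manhattan_data(r, value=value)
    fig, ax = plt.subplots(figsize=(10, 3.2))
    for ci, color in ((0, "#1f77b4"), (1, "#7f7f7f")):
        sel = data["color_index"] == ci
        ax.scatter(data.loc[sel, "genome_coord"], data.loc[sel, "neg_log10_q"],
                   s=3, color=color, rasterized=True)
    ax.axhline(lines[0], color="red", lw=0.8)
    ax.axhline(lines[1], color="blue", lw=0.8)
    ax.set_xlabel("genome coordinate")
    ax.set_ylabel(f"-log10 {value}")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_curves(curves, path, title: str = "") -> None:
    """Fold-enrichment or conditional Q–Q figure, one line per stratum."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    if curves.fe is not None:
        for s, stratum in enumerate(curves.strata):
            ax.plot(curves.grid, curves.fe[s], label=f"p2 <= {stratum:g}")
        ax.set_xlabel("nominal -log10(p), primary trait")
        ax.set_ylabel("fold enrichment")
    else:
        top = 0.0
        for s, stratum in enumerate(curves.strata):
            exp, obs = curves.qq[s]
            ax.plot(exp, obs, label=f"p2 <= {stratum:g}")
            if len(exp):
                top = max(top, exp.max(), obs.max())
        ax.plot([0, top], [0, top], "k--", lw=0.8)
        ax.set_xlabel("expected -log10(p)")
        ax.set_ylabel("observed -log10(p)")
    ax.legend(fontsize=7)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
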