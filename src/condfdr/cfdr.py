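"""Conditional and conjunction false-discovery-rate statistics for
cross-trait pleiotropy.

The central quantity is the per-SNP conditional FDR

    Q_i = p1_i / F̂(p1_i | p2 ≤ p2_i),

where F̂ is the empirical CDF of the primary p-value among SNPs whose
secondary p-value is at most the SNP's own.  The null proportion π0 is
treated as 1, which makes Q a conservative upper bound on the local
false-discovery rate and reduces, when the secondary trait is uninformative,
to the classical step-up FDR q-value.

The estimator is a 2-D lookup table: a grid of −log10(p1) nodes crossed with
a small set of secondary conditioning thresholds −log10(p2).  Each cell holds
p1 / (conditional ECDF); the table is made monotone non-decreasing in p1
(cumulative minimum from small to large p1 within each conditioning level)
and monotone non-increasing in the strictness of the conditioning threshold
(cumulative minimum from loose to strict levels, per p1 column), and per-SNP
values are assigned by bilinear interpolation on the −log10 scales.

Stratified fold-enrichment and conditional Q–Q curves — the graphical
evidence for pleiotropic enrichment — are computed from the same merged
table; the conjunction FDR is the elementwise maximum of the two directional
conditional FDRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import MergedPair

logger = logging.getLogger("condfdr")

#: default secondary-trait strata, as p-value thresholds (loose -> strict)
DEFAULT_STRATA = (1.0, 0.1, 0.01, 0.001)

#: default abscissa for enrichment curves, in -log10(p1)
DEFAULT_FE_GRID = np.round(np.arange(0.0, 10.0 + 1e-9, 0.1), 10)


def _primary_secondary(m: MergedPair, direction: str):
    """Map a direction label onto (primary p, secondary p) arrays."""
    if direction in ("A|B", "a|b"):
        return m.df["p1"].to_numpy(float), m.df["p2"].to_numpy(float)
    if direction in ("B|A", "b|a"):
        return m.df["p2"].to_numpy(float), m.df["p1"].to_numpy(float)
    raise ValueError(f"direction must be 'A|B' or 'B|A', got {direction!r}")


# ---------------------------------------------------------------------------
# stratified curves
# ---------------------------------------------------------------------------

@dataclass
class StratifiedCurves:
    """Fold-enrichment or conditional Q–Q curves stratified by secondary
    p-value threshold.

    For fold enrichment, ``fe[s, t]`` holds FE at stratum ``strata[s]`` and
    grid point ``grid[t]`` (NaN where undefined).  For Q–Q, ``qq[s]`` holds
    the (expected, observed) −log10 quantile pairs of stratum ``s``.
    """

    direction: str
    strata: tuple
    counts: np.ndarray
    grid: np.ndarray | None = None
    fe: np.ndarray | None = None
    qq: list | None = None
    low_count: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        if self.fe is not None:
            rows = []
            for s, stratum in enumerate(self.strata):
                for t, g in enumerate(self.grid):
                    rows.append((stratum, g, self.fe[s, t]))
            return pd.DataFrame(rows, columns=["stratum", "neg_log10_p", "fold_enrichment"])
        rows = []
        for s, stratum in enumerate(self.strata):
            exp, obs = self.qq[s]
            for e, o in zip(exp, obs):
                rows.append((stratum, e, o))
        return pd.DataFrame(rows, columns=["stratum", "expected", "observed"])


def fold_enrichment(m: MergedPair, strata=DEFAULT_STRATA, grid=None,
                    direction: str = "A|B") -> StratifiedCurves:
    """Stratified fold-enrichment curves.

    FE_s(t) = [#{p2 ≤ s, p1 ≤ 10^−t} / #{p2 ≤ s}] ÷ [#{p1 ≤ 10^−t} / N]:
    the proportion of primary-significant SNPs inside the stratum relative to
    the same proportion among all SNPs.  Cells with an empty stratum or an
    empty baseline are NaN.  The trivial stratum (s = 1, all SNPs) is
    identically 1 wherever defined.
    """
    if len(m) == 0:
        raise ValueError("fold_enrichment: empty merged table")
    grid = DEFAULT_FE_GRID if grid is None else np.asarray(grid, float)
    strata = tuple(sorted(set(strata), reverse=True))
    p1, p2 = _primary_secondary(m, direction)
    n = len(p1)
    thresholds = 10.0 ** (-grid)
    p1s = np.sort(p1)
    base_num = np.searchsorted(p1s, thresholds, side="right")

    fe = np.full((len(strata), len(grid)), np.nan)
    counts = np.zeros(len(strata), dtype=int)
    for s, stratum in enumerate(strata):
        sel = p2 <= stratum
        counts[s] = sel.sum()
        if counts[s] == 0:
            logger.warning("fold_enrichment: stratum p2<=%g is empty", stratum)
            continue
        sub = np.sort(p1[sel])
        num = np.searchsorted(sub, thresholds, side="right")
        with np.errstate(divide="ignore", invalid="ignore"):
            fe[s] = (num / counts[s]) / (base_num / n)
        fe[s, base_num == 0] = np.nan
    return StratifiedCurves(direction=direction, strata=strata, counts=counts,
                            grid=grid, fe=fe)


def conditional_qq(m: MergedPair, strata=DEFAULT_STRATA,
                   direction: str = "A|B") -> StratifiedCurves:
    """Conditional Q–Q curves: per stratum, the observed −log10 primary
    p-value order statistics against the −log10 uniform quantiles
    i/(n_s + 1).  Leftward deflection (observed above expected in the tail)
    in strict strata is the Q–Q signature of pleiotropic enrichment."""
    if len(m) == 0:
        raise ValueError("conditional_qq: empty merged table")
    strata = tuple(sorted(set(strata), reverse=True))
    p1, p2 = _primary_secondary(m, direction)
    curves, counts, low = [], [], []
    for stratum in strata:
        sel = p2 <= stratum
        ns = int(sel.sum())
        counts.append(ns)
        low.append(ns < 10)
        if ns == 0:
            logger.warning("conditional_qq: stratum p2<=%g is empty", stratum)
            curves.append((np.array([]), np.array([])))
            continue
        obs = -np.log10(np.sort(p1[sel]))                # most significant first
        exp = -np.log10(np.arange(1, ns + 1) / (ns + 1.0))
        curves.append((exp, obs))
    return StratifiedCurves(direction=direction, strata=strata,
                            counts=np.asarray(counts), qq=curves,
                            low_count=np.asarray(low))


# ---------------------------------------------------------------------------
# conditional FDR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Lookup-grid specification for the conditional-FDR estimator.

    ``t1_nodes`` are −log10(p1) evaluation points (default 401 nodes to
    1e-20); ``t2_levels`` are −log10(p2) conditioning thresholds (default
    {0, 1, 2, 3}, extended by further integers while the conditioning subset
    still holds at least ``min_count`` SNPs, and coarsened by dropping
    under-populated levels).  ``at_data`` places nodes and levels exactly at
    the observed p-values instead, which makes the lookup exact.
    """

    t1_nodes: tuple | None = None
    t2_levels: tuple | None = None
    min_count: int = 100
    at_data: bool = False

    def resolve(self, t1_data: np.ndarray, t2_data: np.ndarray):
        if self.at_data:
            t1 = np.unique(t1_data)
            t2 = np.unique(t2_data)
            return t1, t2
        t1 = (np.linspace(0.0, 20.0, 401) if self.t1_nodes is None
              else np.unique(np.asarray(self.t1_nodes, float)))
        if self.t2_levels is not None:
            t2 = np.unique(np.asarray(self.t2_levels, float))
        else:
            t2 = [0.0, 1.0, 2.0, 3.0]
            nxt = 4.0
            while np.sum(t2_data >= nxt) >= self.min_count and nxt <= 10.0:
                t2.append(nxt)
                nxt += 1.0
            t2 = np.asarray(t2)
        # coarsen: drop conditioning levels whose subset is too small
        keep = [True]
        for level in t2[1:]:
            n_sub = int(np.sum(t2_data >= level))
            if n_sub < self.min_count:
                logger.warning(
                    "cfdr: conditioning level -log10(p2)>=%g holds %d < %d SNPs; "
                    "coarsening (level dropped)", level, n_sub, self.min_count)
                keep.append(False)
            else:
                keep.append(True)
        return t1, t2[np.asarray(keep)]


@dataclass
class CfdrResult:
    """Per-SNP conditional (and optionally conjunction) FDR values plus the
    lookup grids used for the assignment.

    ``df`` carries snp_id/chrom/pos/p1/p2 and whichever of q_ab, q_ba, cc
    have been filled; ``grids`` maps a direction label to
    (t1_nodes, t2_levels, grid) with ``grid[level, node]`` the monotonized
    FDR estimate.
    """

    df: pd.DataFrame
    label_a: str = "A"
    label_b: str = "B"
    grids: dict = field(default_factory=dict)


def _build_grid(t1_sorted_per_level, counts, t1_nodes):
    """Monotonized FDR lookup table.

    ``t1_sorted_per_level[l]`` holds the ascending −log10 p1 values of the
    SNPs passing conditioning level l.
    """
    n_levels = len(counts)
    grid = np.ones((n_levels, len(t1_nodes)))
    for l in range(n_levels):
        if counts[l] == 0:
            continue
        # F(node) = P(p1 <= 10^-node | subset) = #(t1 >= node)/n
        n_ge = counts[l] - np.searchsorted(t1_sorted_per_level[l], t1_nodes,
                                           side="left")
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(n_ge > 0, 10.0 ** (-t1_nodes) * counts[l] / n_ge, 1.0)
        grid[l] = np.minimum(raw, 1.0)
    # monotone non-decreasing in p1: cummin from small p1 (large t1) downward
    # equals cummin along ascending t1 index order reversed; nodes ascend in
    # t1, so run cummin from index 0 (p1 = 1 side ... ) -- nodes ascending t1
    # means descending p1; cumulative minimum along ascending t1 makes the
    # value at smaller p1 never exceed the value at larger p1.
    grid = np.minimum.accumulate(grid, axis=1)
    # monotone in conditioning strictness: tightening the secondary threshold
    # never increases the estimate (cummin from loose to strict levels)
    grid = np.minimum.accumulate(grid, axis=0)
    return grid


def cfdr(m: MergedPair, direction: str = "A|B",
         grid_spec: GridSpec | None = None) -> CfdrResult:
    """Per-SNP conditional FDR for one direction.

    Requires p1, p2 ∈ (0, 1].  SNPs are sorted on (chrom, pos, snp_id) before
    grid construction so the result does not depend on input order; −log10
    p-values beyond the grid range are clamped to the extreme node.
    """
    ms = m.sorted()
    p1, p2 = _primary_secondary(ms, direction)
    if np.any(p1 <= 0) or np.any(p1 > 1) or np.any(p2 <= 0) or np.any(p2 > 1):
        raise ValueError("cfdr requires p-values in (0, 1]")
    spec = grid_spec or GridSpec()
    with np.errstate(divide="ignore"):
        t1 = -np.log10(p1)
        t2 = -np.log10(p2)
    t1_nodes, t2_levels = spec.resolve(t1, t2)

    t1_per_level, counts = [], []
    for level in t2_levels:
        sub = np.sort(t1[t2 >= level])
        t1_per_level.append(sub)
        counts.append(len(sub))
    grid = _build_grid(t1_per_level, np.asarray(counts), t1_nodes)

    q = _interp_bilinear(grid, t1_nodes, t2_levels, t1, t2)
    q = np.maximum(q, p1)          # π0 = 1 conservativeness floor
    q = np.minimum(q, 1.0)

    col = "q_ab" if direction.upper().startswith("A") else "q_ba"
    df = ms.df[["snp_id", "chrom", "pos", "p1", "p2"]].copy()
    df[col] = q
    return CfdrResult(df, label_a=ms.label_a, label_b=ms.label_b,
                      grids={direction: (t1_nodes, t2_levels, grid)})


def _interp_bilinear(grid, t1_nodes, t2_levels, t1, t2):
    """Bilinear interpolation on the −log10 × −log10 lookup table, clamped at
    the grid boundary."""
    t1c = np.clip(t1, t1_nodes[0], t1_nodes[-1])
    t2c = np.clip(t2, t2_levels[0], t2_levels[-1])
    if len(t2_levels) == 1:
        return np.interp(t1c, t1_nodes, grid[0])
    hi = np.clip(np.searchsorted(t2_levels, t2c, side="left"), 1,
                 len(t2_levels) - 1)
    lo = hi - 1
    w = (t2c - t2_levels[lo]) / (t2_levels[hi] - t2_levels[lo])
    out = np.empty_like(t1c)
    for l in range(len(t2_levels)):
        m_lo = lo == l
        m_hi = hi == l
        if m_lo.any():
            vals = np.interp(t1c[m_lo], t1_nodes, grid[l])
            out[m_lo] = vals * (1.0 - w[m_lo])
        if m_hi.any():
            vals = np.interp(t1c[m_hi], t1_nodes, grid[l])
            if l == 0:
                out[m_hi] = vals  # degenerate: t2 below first level
            else:
                out[m_hi] += vals * w[m_hi]
    return out


def conjunction(q_ab: CfdrResult, q_ba: CfdrResult) -> CfdrResult:
    """Conjunction conditional FDR: per SNP the maximum of the two
    directional conditional FDRs — an upper bound on the probability the SNP
    is null for at least one of the phenotypes."""
    a, b = q_ab.df, q_ba.df
    if len(a) != len(b) or not np.array_equal(a["snp_id"].to_numpy(),
                                              b["snp_id"].to_numpy()):
        raise ValueError("conjunction: SNP sets of the two directions differ")
    if "q_ab" not in a.columns or "q_ba" not in b.columns:
        raise ValueError("conjunction needs a q_ab result and a q_ba result")
    df = a.copy()
    df["q_ba"] = b["q_ba"].to_numpy()
    df["cc"] = np.maximum(df["q_ab"].to_numpy(), df["q_ba"].to_numpy())
    grids = dict(q_ab.grids)
    grids.update(q_ba.grids)
    return CfdrResult(df, label_a=q_ab.label_a, label_b=q_ab.label_b, grids=grids)


TIER_ORDER = ("ns", "significant", "suggestive", "genome_wide")


def call_significant(r: CfdrResult, q_threshold: float = 0.05,
                     suggestive: float = 1e-5, genome_wide: float = 5e-8,
                     value: str = "q_ab") -> pd.DataFrame:
    """Tier each SNP by the smallest threshold its Q meets (inclusive
    boundaries): genome_wide ≤ suggestive ≤ significant (q_threshold), else
    ns."""
    if not (genome_wide <= suggestive <= q_threshold):
        raise ValueError("thresholds must satisfy genome_wide <= suggestive "
                         f"<= q_threshold, got {genome_wide}, {suggestive}, "
                         f"{q_threshold}")
    if value not in r.df.columns:
        raise ValueError(f"column {value!r} not present in result")
    q = r.df[value].to_numpy(float)
    tier = np.full(len(q), "ns", dtype=object)
    tier[q <= q_threshold] = "significant"
    tier[q <= suggestive] = "suggestive"
    tier[q <= genome_wide] = "genome_wide"
    out = r.df.copy()
    out["tier"] = tier
    return out
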