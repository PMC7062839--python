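"""Reading, validation, filtering and cross-trait harmonization of GWAS
summary statistics.

A :class:`SumstatsTable` holds one phenotype's per-SNP association records
(effect sizes on the log-odds scale, standard errors, p-values, and optional
imputation quality / allele-frequency columns).  Two tables are merged into a
:class:`MergedPair` on a shared allele orientation; every downstream stage of
the pipeline (LD pruning, enrichment curves, conditional FDR, MR) consumes one
of these two containers.

Coordinates are 1-based; the genome build is carried as metadata and defaults
to GRCh37/hg19.  Regions are inclusive on both ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("condfdr")

#: canonical column order of a validated summary-statistics table
SUMSTATS_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "p", "info", "maf",
]

#: canonical column order of a merged two-trait table
MERGED_COLUMNS = [
    "snp_id", "chrom", "pos", "ea", "oa",
    "beta1", "se1", "p1", "beta2", "se2", "p2", "maf",
]

#: default logical->header mapping; identity on canonical names
DEFAULT_SCHEMA = {c: c for c in SUMSTATS_COLUMNS}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: smallest positive double; p = 0 entries are clamped here so that
#: -log10(p) grids downstream stay finite
P_FLOOR = np.nextafter(0.0, 1.0)


class SchemaError(ValueError):
    """A required logical column is missing from the file header."""


class EmptyTableError(ValueError):
    """Validation or merging left no usable rows."""


@dataclass
class SumstatsTable:
    """Validated per-SNP association records for one phenotype.

    ``df`` has the columns in :data:`SUMSTATS_COLUMNS`; ``beta``/``se`` are on
    the log-odds scale (odds ratios are converted at load time).
    """

    df: pd.DataFrame
    build: str = "GRCh37/hg19"
    effect_scale: str = "beta"  # scale of the *source* file
    n_cases: int | None = None
    n_controls: int | None = None
    n_rejected: int = 0
    n_p_clamped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        self.df = self.df[SUMSTATS_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class MergedPair:
    """Two phenotypes' records joined per SNP on a shared allele orientation."""

    df: pd.DataFrame
    label_a: str = "A"
    label_b: str = "B"
    n_dropped_mismatch: int = 0
    n_dropped_ambiguous: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in MERGED_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        self.df = self.df[MERGED_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def sorted(self) -> "MergedPair":
        """Copy sorted by (chrom, pos, snp_id) — the canonical order used
        before any grid construction so results are input-order invariant."""
        out = self.df.sort_values(["chrom", "pos", "snp_id"], kind="mergesort")
        return MergedPair(out.reset_index(drop=True), self.label_a, self.label_b,
                          self.n_dropped_mismatch, self.n_dropped_ambiguous)


@dataclass(frozen=True)
class GenomicRegion:
    """Closed interval [start, end] on one chromosome, 1-based."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def contains(self, chrom, pos) -> np.ndarray:
        chrom = np.asarray(chrom, dtype=str)
        pos = np.asarray(pos)
        return (chrom == str(self.chrom)) & (pos >= self.start) & (pos <= self.end)


#: ± 300 kb around the APOE epsilon coding SNPs, hg19 — the region whose
#: uniquely strong LOAD signal can mask other conditional associations
APOE_REGION = GenomicRegion("19", 45_111_942, 45_711_941)


# ---------------------------------------------------------------------------
# reading & validation
# ---------------------------------------------------------------------------

def read_sumstats(path, schema: dict | None = None, effect_scale: str = "beta",
                  build: str = "GRCh37/hg19", n_cases: int | None = None,
                  n_controls: int | None = None) -> SumstatsTable:
    """Read a tab/whitespace-delimited summary-statistics file.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    schema
        Mapping of logical column names (:data:`SUMSTATS_COLUMNS`, with
        ``"or"`` accepted in place of ``"beta"``) to header names.  Logical
        names absent from the mapping default to themselves; ``info``/``maf``
        may be omitted entirely (filled with NaN).
    effect_scale
        ``"beta"`` if the effect column is already a log-odds coefficient,
        ``"or"`` if it is an odds ratio (converted via the natural log).

    Rows failing validation (p outside (0,1], se ≤ 0, pos < 1, identical
    alleles, duplicate snp_id) are dropped and counted in
    ``SumstatsTable.n_rejected``; p-values equal to 0 are clamped to the
    smallest positive double and counted in ``n_p_clamped``.
    """
    if effect_scale not in ("beta", "or"):
        raise ValueError(f"effect_scale must be 'beta' or 'or', got {effect_scale!r}")
    schema = dict(schema or {})
    if "or" in schema and "beta" not in schema:
        schema["beta"] = schema.pop("or")
        effect_scale = "or"

    try:
        raw = pd.read_csv(path, sep=r"\s+", dtype={0: str})
    except OSError as exc:
        raise OSError(f"cannot read summary statistics from {path}: {exc}") from exc

    required = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                "beta", "se", "p"]
    colmap = {}
    for logical in SUMSTATS_COLUMNS:
        header = schema.get(logical, logical)
        if header in raw.columns:
            colmap[logical] = header
        elif logical in required:
            raise SchemaError(
                f"required column {logical!r} (header {header!r}) not found in {path}; "
                f"available: {list(raw.columns)}")

    df = pd.DataFrame({logical: raw[header] for logical, header in colmap.items()})
    for optional in ("info", "maf"):
        if optional not in df.columns:
            df[optional] = np.nan
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for c in ("beta", "se", "p", "info", "maf"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    if effect_scale == "or":
        with np.errstate(divide="ignore", invalid="ignore"):
            df["beta"] = np.log(df["beta"])

    n_in = len(df)
    clamp = df["p"] == 0.0
    df.loc[clamp, "p"] = P_FLOOR
    n_clamped = int(clamp.sum())
    if n_clamped:
        logger.warning("%s: clamped %d p = 0 entries to %.3e", path, n_clamped, P_FLOOR)

    ok = (
        df["p"].gt(0) & df["p"].le(1)
        & df["se"].gt(0)
        & df["pos"].ge(1)
        & df["beta"].notna()
        & (df["effect_allele"] != df["other_allele"])
    )
    ok &= ~df["snp_id"].duplicated(keep="first")
    df = df[ok].copy()
    df["pos"] = df["pos"].astype(np.int64)
    n_rejected = n_in - len(df)
    if n_rejected:
        logger.info("%s: rejected %d/%d rows failing validation", path, n_rejected, n_in)
    if len(df) == 0:
        raise EmptyTableError(f"{path}: all {n_in} rows failed validation")

    return SumstatsTable(df, build=build, effect_scale=effect_scale,
                         n_cases=n_cases, n_controls=n_controls,
                         n_rejected=n_rejected, n_p_clamped=n_clamped)


def _copy_with(t: SumstatsTable, df: pd.DataFrame) -> SumstatsTable:
    return SumstatsTable(df.reset_index(drop=True), build=t.build,
                         effect_scale=t.effect_scale, n_cases=t.n_cases,
                         n_controls=t.n_controls, n_rejected=t.n_rejected,
                         n_p_clamped=t.n_p_clamped)


def filter_info(t: SumstatsTable, lo: float = 0.6, hi: float = 1.06) -> SumstatsTable:
    """Keep rows with imputation quality lo ≤ INFO < hi (half-open interval).

    Rows with missing INFO pass: the two consortium file formats differ in
    whether they ship an INFO column, and dropping NaNs would silently empty
    one input.
    """
    if lo >= hi:
        raise ValueError(f"filter_info requires lo < hi, got [{lo}, {hi})")
    info = t.df["info"]
    if info.isna().all():
        logger.warning("filter_info: INFO column entirely missing; table unchanged")
        return _copy_with(t, t.df.copy())
    keep = info.isna() | (info.ge(lo) & info.lt(hi))
    n_na = int(info.isna().sum())
    if n_na:
        logger.info("filter_info: %d rows with missing INFO passed through", n_na)
    return _copy_with(t, t.df[keep])


def filter_maf(t: SumstatsTable, min_maf: float = 0.01) -> SumstatsTable:
    """Keep rows with minor allele frequency strictly above ``min_maf``."""
    if not (0 <= min_maf < 0.5):
        raise ValueError(f"min_maf must be in [0, 0.5), got {min_maf}")
    keep = t.df["maf"].gt(min_maf)
    return _copy_with(t, t.df[keep])


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


def _is_ambiguous(ea: str, oa: str) -> bool:
    # A/T and C/G pairs cannot be oriented across strands
    return len(ea) == 1 and len(oa) == 1 and _COMPLEMENT.get(ea) == oa


def harmonize(a: SumstatsTable, b: SumstatsTable, drop_ambiguous: bool = True,
              label_a: str = "A", label_b: str = "B",
              join_on: str = "snp_id") -> MergedPair:
    """Inner-join two tables per SNP and orient trait B's effects onto trait
    A's allele coding.

    Four orientation cases per SNP (after optional strand complementation of
    B's alleles): identical alleles → beta2 kept; swapped alleles → beta2
    negated; complement / complement-swap → same rules on the complemented
    alleles.  SNPs whose alleles match none of the four cases are dropped and
    counted.  Strand-ambiguous (A/T, C/G) SNPs are dropped when
    ``drop_ambiguous`` is set, since orientation is undecidable without
    frequency comparison.

    ``join_on`` is ``"snp_id"`` (rsID-keyed files) or ``"chrom_pos"``.
    """
    da, db = a.df, b.df
    if join_on == "chrom_pos":
        da = da.assign(_key=da["chrom"] + ":" + da["pos"].astype(str))
        db = db.assign(_key=db["chrom"] + ":" + db["pos"].astype(str))
        key = "_key"
    elif join_on == "snp_id":
        key = "snp_id"
    else:
        raise ValueError(f"join_on must be 'snp_id' or 'chrom_pos', got {join_on!r}")

    m = da.merge(db, on=key, suffixes=("_a", "_b"), how="inner")
    if len(m) == 0:
        raise EmptyTableError("harmonize: zero SNPs shared between the two tables")

    ea_a = m["effect_allele_a"].to_numpy()
    oa_a = m["other_allele_a"].to_numpy()
    ea_b = m["effect_allele_b"].to_numpy()
    oa_b = m["other_allele_b"].to_numpy()
    ea_bc = np.array([_complement(x) for x in ea_b])
    oa_bc = np.array([_complement(x) for x in oa_b])

    same = (ea_b == ea_a) & (oa_b == oa_a)
    swap = (ea_b == oa_a) & (oa_b == ea_a)
    comp = (ea_bc == ea_a) & (oa_bc == oa_a) & ~same & ~swap
    comp_swap = (ea_bc == oa_a) & (oa_bc == ea_a) & ~same & ~swap

    flip = (swap | comp_swap) & ~(same | comp)
    matched = same | swap | comp | comp_swap

    ambiguous = np.array([_is_ambiguous(e, o) for e, o in zip(ea_a, oa_a)])
    keep = matched.copy()
    n_ambig = 0
    if drop_ambiguous:
        n_ambig = int((keep & ambiguous).sum())
        keep &= ~ambiguous
    n_mismatch = int((~matched).sum())
    if n_mismatch:
        logger.info("harmonize: dropped %d SNPs with unresolvable alleles", n_mismatch)
    if n_ambig:
        logger.info("harmonize: dropped %d strand-ambiguous SNPs", n_ambig)

    snp_col = "snp_id_a" if "snp_id_a" in m.columns else "snp_id"
    beta2 = np.where(flip, -m["beta_b"].to_numpy(), m["beta_b"].to_numpy())
    maf = m["maf_a"].to_numpy(dtype=float)
    maf = np.where(np.isnan(maf), m["maf_b"].to_numpy(dtype=float), maf)

    out = pd.DataFrame({
        "snp_id": m[snp_col].to_numpy(),
        "chrom": m["chrom_a" if "chrom_a" in m.columns else "chrom"].to_numpy(),
        "pos": m["pos_a" if "pos_a" in m.columns else "pos"].to_numpy(),
        "ea": ea_a, "oa": oa_a,
        "beta1": m["beta_a"].to_numpy(), "se1": m["se_a"].to_numpy(),
        "p1": m["p_a"].to_numpy(),
        "beta2": beta2, "se2": m["se_b"].to_numpy(), "p2": m["p_b"].to_numpy(),
        "maf": maf,
    })[keep]
    if len(out) == 0:
        raise EmptyTableError("harmonize: no SNPs left after allele reconciliation")
    return MergedPair(out.reset_index(drop=True), label_a=label_a, label_b=label_b,
                      n_dropped_mismatch=n_mismatch, n_dropped_ambiguous=n_ambig)


# ---------------------------------------------------------------------------
# region operations
# ---------------------------------------------------------------------------

def exclude_region(m: MergedPair, region: GenomicRegion) -> MergedPair:
    """Remove SNPs inside a closed genomic interval (both ends inclusive)."""
    inside = region.contains(m.df["chrom"], m.df["pos"])
    out = MergedPair(m.df[~inside].reset_index(drop=True), m.label_a, m.label_b,
                     m.n_dropped_mismatch, m.n_dropped_ambiguous)
    logger.info("exclude_region %s:%d-%d removed %d SNPs",
                region.chrom, region.start, region.end, int(inside.sum()))
    return out


def select_region(m: MergedPair, region: GenomicRegion) -> MergedPair:
    """Complement of :func:`exclude_region`: keep only SNPs inside the region."""
    inside = region.contains(m.df["chrom"], m.df["pos"])
    return MergedPair(m.df[inside].reset_index(drop=True), m.label_a, m.label_b,
                      m.n_dropped_mismatch, m.n_dropped_ambiguous)


def write_merged(m: MergedPair, path) -> None:
    """Serialize a merged pair as TSV with the fixed canonical column order."""
    m.df.to_csv(path, sep="\t", index=False)


def read_merged(path, label_a: str = "A", label_b: str = "B") -> MergedPair:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    return MergedPair(df, label_a=label_a, label_b=label_b)
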