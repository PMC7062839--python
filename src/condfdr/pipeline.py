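"""End-to-end orchestration of the pleiotropy analysis from a single config.

Stage order: read → filter → harmonize → exclude_region → prune →
enrichment → conditional_qq → cfdr (both directions) → conjunction → mr →
report.  Each stage logs its row bookkeeping (rows_out + rows_dropped =
rows_in for every filtering stage) into a JSON manifest that, together with
the input checksums and parameters, suffices to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import annotate, ld, sumstats
from .cfdr import (GridSpec, call_significant, cfdr, conditional_qq,
                   conjunction, fold_enrichment)
from .mr import InsufficientInstrumentsError, egger_fit, select_instruments

logger = logging.getLogger("condfdr")

STAGES = ["read", "filter", "harmonize", "exclude_region", "prune",
          "enrichment", "conditional_qq", "cfdr", "conjunction", "mr",
          "report"]


@dataclass
class RunConfig:
    """Everything one analysis run needs; mirrors the YAML layout."""

    sumstats_a: str = ""
    sumstats_b: str = ""
    panel: str = ""
    genes: str = ""
    outdir: str = "out"
    schema_a: dict = field(default_factory=dict)
    schema_b: dict = field(default_factory=dict)
    effect_scale_a: str = "beta"
    effect_scale_b: str = "beta"
    label_a: str = "A"
    label_b: str = "B"
    info_lo: float = 0.6
    info_hi: float = 1.06
    min_maf: float = 0.01
    exclude_regions: list = field(default_factory=list)  # dicts chrom/start/end
    prune_r2: float = 0.2
    prune_window_kb: int = 1000
    prune_for: str = "enrichment_only"   # or "all"
    strata: list = field(default_factory=lambda: [1.0, 0.1, 0.01, 0.001])
    grid_min_count: int = 100
    mr_p_threshold: float = 1e-8
    mr_clump_r2: float = 0.001
    mr_clump_kb: float = 10.0
    mr_snp_list: list | None = None
    q_threshold: float = 0.05
    suggestive: float = 1e-5
    genome_wide: float = 5e-8
    make_figures: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(cfg: RunConfig) -> list[str]:
    """Collect every problem; an empty list means the config is runnable.
    Strata given out of order are auto-sorted descending with a warning."""
    problems = []
    for name in ("sumstats_a", "sumstats_b", "panel", "genes"):
        path = getattr(cfg, name)
        if not path:
            problems.append(f"missing path: {name}")
        elif not pathlib.Path(path).exists():
            problems.append(f"{name}: file not found: {path}")
    if not (cfg.genome_wide <= cfg.suggestive <= cfg.q_threshold):
        problems.append("thresholds not monotone: need genome_wide <= "
                        "suggestive <= q_threshold")
    if not (0 < cfg.prune_r2 <= 1):
        problems.append(f"prune_r2 must be in (0, 1], got {cfg.prune_r2}")
    if cfg.info_lo >= cfg.info_hi:
        problems.append("info filter requires info_lo < info_hi")
    if not (0 <= cfg.min_maf < 0.5):
        problems.append(f"min_maf must be in [0, 0.5), got {cfg.min_maf}")
    if cfg.prune_for not in ("enrichment_only", "all"):
        problems.append(f"prune_for must be enrichment_only|all, got {cfg.prune_for}")
    if sorted(cfg.strata, reverse=True) != list(cfg.strata):
        logger.warning("strata not sorted descending; auto-sorting")
        cfg.strata = sorted(set(cfg.strata), reverse=True)
    for i, reg in enumerate(cfg.exclude_regions):
        if not all(k in reg for k in ("chrom", "start", "end")):
            problems.append(f"exclude_regions[{i}] needs chrom/start/end")
        elif reg["start"] > reg["end"]:
            problems.append(f"exclude_regions[{i}]: start > end")
    return problems


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, cfg: RunConfig):
        self.data = {"config": cfg.to_dict(), "inputs": {}, "stages": [],
                     "outputs": []}

    def stage(self, name, rows_in, rows_out, t0):
        self.data["stages"].append({
            "stage": name, "rows_in": int(rows_in), "rows_out": int(rows_out),
            "rows_dropped": int(rows_in - rows_out),
            "seconds": round(time.perf_counter() - t0, 3),
        })
        logger.info("stage %-14s rows %d -> %d", name, rows_in, rows_out)

    def output(self, path):
        self.data["outputs"].append(str(path))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict (also written to
    outdir/manifest.json).  Any stage error aborts with the stage name after
    writing a partial manifest."""
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = pathlib.Path(cfg.outdir)
    for sub in ("tables", "curves", "figures"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    man = _Manifest(cfg)
    for name in ("sumstats_a", "sumstats_b", "panel", "genes"):
        man.data["inputs"][name] = {"path": getattr(cfg, name),
                                    "sha256": _sha256(getattr(cfg, name))}
    try:
        _run_stages(cfg, out, man)
    except Exception as exc:
        man.data["failed_stage"] = (man.data["stages"][-1]["stage"]
                                    if man.data["stages"] else "read")
        man.data["error"] = str(exc)
        _write_manifest(man, out)
        raise RuntimeError(
            f"pipeline aborted at stage "
            f"{man.data['failed_stage']!r}: {exc}") from exc
    _write_manifest(man, out)
    return man.data


def _write_manifest(man, out):
    with open(out / "manifest.json", "w") as fh:
        json.dump(man.data, fh, indent=2, default=str)


def _run_stages(cfg: RunConfig, out: pathlib.Path, man: _Manifest) -> None:
    t0 = time.perf_counter()
    ta = sumstats.read_sumstats(cfg.sumstats_a, schema=cfg.schema_a,
                                effect_scale=cfg.effect_scale_a)
    tb = sumstats.read_sumstats(cfg.sumstats_b, schema=cfg.schema_b,
                                effect_scale=cfg.effect_scale_b)
    man.stage("read", len(ta) + len(tb) + ta.n_rejected + tb.n_rejected,
              len(ta) + len(tb), t0)

    t0 = time.perf_counter()
    n_in = len(ta) + len(tb)
    ta = sumstats.filter_maf(sumstats.filter_info(ta, cfg.info_lo, cfg.info_hi),
                             cfg.min_maf)
    tb = sumstats.filter_maf(sumstats.filter_info(tb, cfg.info_lo, cfg.info_hi),
                             cfg.min_maf)
    man.stage("filter", n_in, len(ta) + len(tb), t0)

    t0 = time.perf_counter()
    merged = sumstats.harmonize(ta, tb, drop_ambiguous=True,
                                label_a=cfg.label_a, label_b=cfg.label_b)
    n_joined = (len(merged) + merged.n_dropped_mismatch
                + merged.n_dropped_ambiguous)
    man.stage("harmonize", n_joined, len(merged), t0)

    t0 = time.perf_counter()
    n_in = len(merged)
    for reg in cfg.exclude_regions:
        merged = sumstats.exclude_region(
            merged, sumstats.GenomicRegion(str(reg["chrom"]),
                                           int(reg["start"]), int(reg["end"])))
    man.stage("exclude_region", n_in, len(merged), t0)
    sumstats.write_merged(merged, out / "tables" / "merged.tsv")
    man.output(out / "tables" / "merged.tsv")

    t0 = time.perf_counter()
    panel = ld.read_panel_tsv(cfg.panel)
    pruned = ld.prune(merged, panel, r2_threshold=cfg.prune_r2,
                      window_kb=cfg.prune_window_kb)
    man.stage("prune", len(merged), len(pruned), t0)
    sumstats.write_merged(pruned, out / "tables" / "pruned.tsv")
    man.output(out / "tables" / "pruned.tsv")

    t0 = time.perf_counter()
    curves = {}
    for direction in ("A|B", "B|A"):
        fe = fold_enrichment(pruned, strata=cfg.strata,
                                      direction=direction)
        curves[direction] = fe
        tag = direction.replace("|", "_given_").lower()
        fe.to_frame().to_csv(out / "curves" / f"fold_enrichment_{tag}.tsv",
                             sep="\t", index=False)
        man.output(out / "curves" / f"fold_enrichment_{tag}.tsv")
        if cfg.make_figures:
            annotate.plot_curves(fe, out / "figures" / f"fold_enrichment_{tag}.png",
                                 title=f"{cfg.label_a}|{cfg.label_b}"
                                 if direction == "A|B"
                                 else f"{cfg.label_b}|{cfg.label_a}")
    man.stage("enrichment", len(pruned), len(pruned), t0)

    t0 = time.perf_counter()
    for direction in ("A|B", "B|A"):
        qq = conditional_qq(pruned, strata=cfg.strata,
                                     direction=direction)
        tag = direction.replace("|", "_given_").lower()
        qq.to_frame().to_csv(out / "curves" / f"conditional_qq_{tag}.tsv",
                             sep="\t", index=False)
        man.output(out / "curves" / f"conditional_qq_{tag}.tsv")
        if cfg.make_figures:
            annotate.plot_curves(qq, out / "figures" / f"conditional_qq_{tag}.png")
    man.stage("conditional_qq", len(pruned), len(pruned), t0)

    t0 = time.perf_counter()
    cfdr_input = pruned if cfg.prune_for == "all" else merged
    spec = GridSpec(min_count=cfg.grid_min_count)
    r_ab = cfdr(cfdr_input, direction="A|B", grid_spec=spec)
    r_ba = cfdr(cfdr_input, direction="B|A", grid_spec=spec)
    man.stage("cfdr", len(cfdr_input), len(r_ab.df), t0)

    t0 = time.perf_counter()
    both = conjunction(r_ab, r_ba)
    tiers = call_significant(both, cfg.q_threshold, cfg.suggestive,
                                      cfg.genome_wide, value="q_ab")
    tiers["tier_ba"] = call_significant(
        both, cfg.q_threshold, cfg.suggestive, cfg.genome_wide,
        value="q_ba")["tier"]
    tiers.to_csv(out / "tables" / "cfdr.tsv", sep="\t", index=False)
    man.output(out / "tables" / "cfdr.tsv")
    man.stage("conjunction", len(both.df), len(both.df), t0)
    if cfg.make_figures:
        for value in ("q_ab", "q_ba", "cc"):
            annotate.plot_manhattan(both, value,
                                    out / "figures" / f"manhattan_{value}.png")

    t0 = time.perf_counter()
    try:
        inst = select_instruments(
            ta, tb, panel,
            p_threshold=cfg.mr_p_threshold, clump_r2=cfg.mr_clump_r2,
            clump_kb=cfg.mr_clump_kb, snp_list=cfg.mr_snp_list,
            exposure_label=cfg.label_a, outcome_label=cfg.label_b)
        mr_res = egger_fit(inst)
        mr_res.to_frame().to_csv(out / "tables" / "mr_egger.tsv", sep="\t",
                                 index=False)
        man.output(out / "tables" / "mr_egger.tsv")
        n_inst = mr_res.n_instruments
    except InsufficientInstrumentsError as exc:
        logger.warning("MR skipped: %s", exc)
        mr_res = None
        n_inst = 0
    man.stage("mr", n_inst, n_inst, t0)

    t0 = time.perf_counter()
    genes = (annotate.read_genes_bed(cfg.genes)
             if str(cfg.genes).endswith(".bed")
             else annotate.read_genes_tsv(cfg.genes))
    reports = {}
    for value in ("q_ab", "q_ba"):
        rep = annotate.build_locus_report(both, merged, genes,
                                          tier=cfg.q_threshold, value=value)
        reports[value] = rep
        annotate.format_report(rep).to_csv(
            out / "tables" / f"locus_report_{value}.tsv", sep="\t", index=False)
        man.output(out / "tables" / f"locus_report_{value}.tsv")
    man.stage("report", len(both.df),
              sum(len(r) for r in reports.values()), t0)
    man.data["summary"] = _summarize(cfg, curves, both, mr_res, reports)


def _summarize(cfg, curves, both, mr_res, reports) -> dict:
    def max_fe(c):
        ok = np.isfinite(c.fe)
        return float(np.nanmax(c.fe[ok])) if ok.any() else float("nan")

    s = {
        "max_fold_enrichment_ab": max_fe(curves["A|B"]),
        "max_fold_enrichment_ba": max_fe(curves["B|A"]),
        "n_sig_ab": int((both.df["q_ab"] <= cfg.q_threshold).sum()),
        "n_sig_ba": int((both.df["q_ba"] <= cfg.q_threshold).sum()),
        "n_sig_cc": int((both.df["cc"] <= cfg.q_threshold).sum()),
        "n_genes_ab": int(reports["q_ab"]["nearest_gene"].nunique()),
        "n_genes_ba": int(reports["q_ba"]["nearest_gene"].nunique()),
    }
    if mr_res is not None:
        lo, hi = mr_res.or_ci
        s.update({"mr_or": mr_res.or_scale, "mr_or_ci_low": lo,
                  "mr_or_ci_high": hi, "mr_intercept_p": mr_res.intercept_p,
                  "mr_n_instruments": mr_res.n_instruments})
    return s
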