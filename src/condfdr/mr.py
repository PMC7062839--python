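"""Two-sample Mendelian randomization with MR-Egger regression.

Instruments are exposure-associated SNPs surviving p-value thresholding and
LD clumping; the Egger model regresses outcome effects on exposure effects
with a free intercept, weighted by inverse outcome variance.  The slope
estimates the causal effect of the exposure on the outcome (on the log-odds
scale for binary traits); a non-zero intercept indicates directional
horizontal pleiotropy.  Inference uses the t distribution with
(n_instruments − 2) degrees of freedom, with a normal-approximation flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .ld import ReferencePanel, clump
from .sumstats import SumstatsTable, harmonize

logger = logging.getLogger("condfdr")


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the Egger model can be fitted on."""

    def __init__(self, count: int, needed: int = 3):
        self.count = count
        super().__init__(
            f"MR-Egger needs at least {needed} instruments, got {count}")


class SingularFitError(ValueError):
    """Degenerate design: no spread in the exposure effects."""


@dataclass
class InstrumentSet:
    """Harmonized instruments for a two-sample MR fit.

    ``df`` columns: snp_id, beta_exposure, se_exposure, beta_outcome,
    se_outcome, flipped (whether the instrument was re-oriented so that
    beta_exposure ≥ 0 — the convention that identifies the Egger intercept).
    """

    df: pd.DataFrame
    exposure: str = "exposure"
    outcome: str = "outcome"

    def __post_init__(self) -> None:
        need = ["snp_id", "beta_exposure", "se_exposure",
                "beta_outcome", "se_outcome"]
        missing = [c for c in need if c not in self.df.columns]
        if missing:
            raise ValueError(f"instrument table missing columns {missing}")
        if (self.df["se_exposure"].le(0) | self.df["se_outcome"].le(0)).any():
            raise ValueError("instrument standard errors must be positive")

    def __len__(self) -> int:
        return len(self.df)

    def oriented(self) -> "InstrumentSet":
        """Copy with every instrument's alleles coded so the exposure effect
        is non-negative (flipping negates both betas)."""
        df = self.df.copy()
        flip = df["beta_exposure"].to_numpy() < 0
        df["beta_exposure"] = np.abs(df["beta_exposure"])
        df.loc[flip, "beta_outcome"] = -df.loc[flip, "beta_outcome"]
        df["flipped"] = flip
        return InstrumentSet(df, self.exposure, self.outcome)


@dataclass
class MrResult:
    """MR-Egger estimates: causal slope (log-OR per exposure log-OR unit),
    directional-pleiotropy intercept, and their inference."""

    slope: float
    slope_se: float
    slope_ci_low: float
    slope_ci_high: float
    slope_p: float
    intercept: float
    intercept_se: float
    intercept_p: float
    n_instruments: int
    df_resid: int
    exposure: str = "exposure"
    outcome: str = "outcome"

    @property
    def or_scale(self) -> float:
        return float(np.exp(self.slope))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.slope_ci_low)), float(np.exp(self.slope_ci_high))

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.or_ci
        return pd.DataFrame([{
            "exposure": self.exposure, "outcome": self.outcome,
            "n_instruments": self.n_instruments,
            "slope": self.slope, "slope_se": self.slope_se,
            "slope_ci_low": self.slope_ci_low, "slope_ci_high": self.slope_ci_high,
            "slope_p": self.slope_p,
            "or": self.or_scale, "or_ci_low": lo, "or_ci_high": hi,
            "intercept": self.intercept, "intercept_se": self.intercept_se,
            "intercept_p": self.intercept_p,
        }])


def select_instruments(exposure: SumstatsTable, outcome: SumstatsTable,
                       panel: ReferencePanel, p_threshold: float = 1e-8,
                       clump_r2: float = 0.001, clump_kb: float = 10,
                       snp_list=None, exposure_label: str = "exposure",
                       outcome_label: str = "outcome") -> InstrumentSet:
    """Select and harmonize MR instruments.

    Exposure SNPs at p ≤ ``p_threshold`` are LD-clumped (index SNPs by
    ascending p, exclusion by ``clump_kb`` distance or r² > ``clump_r2``) and
    intersected with the outcome table on a shared allele orientation.  An
    explicit ``snp_list`` overrides the threshold route.  Fewer than three
    survivors raises :class:`InsufficientInstrumentsError`.
    """
    if snp_list is not None:
        sel = exposure.df["snp_id"].isin(set(snp_list))
        from .sumstats import _copy_with
        candidates = _copy_with(exposure, exposure.df[sel])
    else:
        candidates = clump(exposure, panel, p_threshold=p_threshold,
                           r2_threshold=clump_r2, distance_kb=clump_kb)
        candidates.df = candidates.df[candidates.df["p"] <= p_threshold]
    if len(candidates.df) == 0:
        raise InsufficientInstrumentsError(0)

    try:
        merged = harmonize(candidates, outcome, drop_ambiguous=True,
                           label_a=exposure_label, label_b=outcome_label)
    except Exception:
        raise InsufficientInstrumentsError(0) from None

    df = pd.DataFrame({
        "snp_id": merged.df["snp_id"],
        "beta_exposure": merged.df["beta1"],
        "se_exposure": merged.df["se1"],
        "beta_outcome": merged.df["beta2"],
        "se_outcome": merged.df["se2"],
    })
    if len(df) < 3:
        raise InsufficientInstrumentsError(len(df))
    return InstrumentSet(df, exposure_label, outcome_label).oriented()


def egger_fit(inst: InstrumentSet, alpha: float = 0.05,
              normal_approx: bool = False) -> MrResult:
    """Fit the MR-Egger regression.

    Weighted least squares of beta_outcome on beta_exposure with a free
    intercept and weights 1/se_outcome²; SEs from the WLS covariance
    (residual-scaled), p-values and the (1 − alpha) CI from the t
    distribution with n − 2 df (or the normal, with ``normal_approx``).
    """
    inst = inst.oriented()
    if len(inst) < 3:
        raise InsufficientInstrumentsError(len(inst))
    bx = inst.df["beta_exposure"].to_numpy(float)
    by = inst.df["beta_outcome"].to_numpy(float)
    w = 1.0 / inst.df["se_outcome"].to_numpy(float) ** 2
    if np.allclose(bx, bx[0]):
        raise SingularFitError("all exposure effects equal: slope unidentifiable")

    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    intercept, slope = fit.params
    int_se, slope_se = fit.bse
    dof = len(inst) - 2
    if normal_approx:
        crit = scipy.stats.norm.ppf(1 - alpha / 2)
        slope_p = 2 * scipy.stats.norm.sf(abs(slope / slope_se)) if slope_se > 0 else (1.0 if slope == 0 else 0.0)
        int_p = 2 * scipy.stats.norm.sf(abs(intercept / int_se)) if int_se > 0 else (1.0 if intercept == 0 else 0.0)
    else:
        crit = scipy.stats.t.ppf(1 - alpha / 2, dof)
        slope_p = 2 * scipy.stats.t.sf(abs(slope / slope_se), dof) if slope_se > 0 else (1.0 if slope == 0 else 0.0)
        int_p = 2 * scipy.stats.t.sf(abs(intercept / int_se), dof) if int_se > 0 else (1.0 if intercept == 0 else 0.0)
    res = MrResult(
        slope=float(slope), slope_se=float(slope_se),
        slope_ci_low=float(slope - crit * slope_se),
        slope_ci_high=float(slope + crit * slope_se),
        slope_p=float(slope_p),
        intercept=float(intercept), intercept_se=float(int_se),
        intercept_p=float(int_p),
        n_instruments=len(inst), df_resid=dof,
        exposure=inst.exposure, outcome=inst.outcome,
    )
    logger.info("MR-Egger %s -> %s: OR %.3f (%.3f-%.3f), intercept p = %.3g",
                res.exposure, res.outcome, res.or_scale, *res.or_ci,
                res.intercept_p)
    return res


@dataclass
class InterceptDecision:
    """Directional horizontal-pleiotropy verdict from the Egger intercept."""

    intercept: float
    intercept_p: float
    alpha: float
    significant: bool

    @property
    def verdict(self) -> str:
        return ("directional pleiotropy detected" if self.significant
                else "no significant directional pleiotropy")


def intercept_test(r: MrResult, alpha: float = 0.05) -> InterceptDecision:
    """Test the Egger intercept against zero at level ``alpha``."""
    return InterceptDecision(intercept=r.intercept, intercept_p=r.intercept_p,
                             alpha=alpha, significant=r.intercept_p < alpha)
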