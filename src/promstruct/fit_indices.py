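"""Global fit indices for covariance-structure models.

Implements the standard battery: chi-square with p-value, CFI and TLI
against the independence baseline, RMSEA with its 90% noncentral-chi-square
confidence interval, and SRMR on the correlation metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .cfa import FactorModelSpec, FittedModel
from .efa import SampleMoments

__all__ = ["FitIndexSet", "baseline_model", "compute_indices", "srmr"]


@dataclass(frozen=True)
class FitIndexSet:
    chisq: float
    df: int
    p_value: float
    cfi: float
    tli: float | None
    rmsea: float | None
    rmsea_ci90: tuple[float, float] | None
    srmr: float
    baseline_chisq: float
    baseline_df: int

    def to_dict(self) -> dict:
        d = {
            "chisq": self.chisq,
            "df": self.df,
            "p_value": self.p_value,
            "cfi": self.cfi,
            "tli": self.tli,
            "rmsea": self.rmsea,
            "rmsea_ci90_low": self.rmsea_ci90[0] if self.rmsea_ci90 else None,
            "rmsea_ci90_high": self.rmsea_ci90[1] if self.rmsea_ci90 else None,
            "srmr": self.srmr,
            "baseline_chisq": self.baseline_chisq,
            "baseline_df": self.baseline_df,
        }
        return d


def baseline_model(moments: SampleMoments, chisq_dialect: str = "wishart") -> FittedModel:
    """Independence model: diagonal implied covariance with free variances.

    Its ML discrepancy has the closed form -ln|R| (R the sample correlation
    matrix) and df = p(p-1)/2.
    """
    p = moments.p
    sign, logdet_R = np.linalg.slogdet(moments.correlation)
    F = max(-logdet_R, 0.0)
    return FittedModel(
        spec=None,
        item_ids=list(moments.item_ids),
        loadings=np.zeros((p, 0)),
        phi=np.zeros((0, 0)),
        theta=np.diag(np.diag(moments.covariance)),
        discrepancy=F,
        df=p * (p - 1) // 2,
        n_free_parameters=p,
        n_obs=moments.n,
        chisq_dialect=chisq_dialect,
    )


def srmr(model: FittedModel, moments: SampleMoments, include_diagonal: bool = True) -> float:
    """Standardized root mean square residual.

    Residuals are standardized by the observed standard deviations (so the
    index is invariant to rescaling any variable); the diagonal is included
    by default, with the off-diagonal-only convention available.
    """
    idx = [moments.item_ids.index(i) for i in model.item_ids]
    S = moments.covariance[np.ix_(idx, idx)]
    sd = np.sqrt(np.diag(S))
    resid = (S - model.implied_covariance) / np.outer(sd, sd)
    p = S.shape[0]
    rows, cols = np.tril_indices(p, k=0 if include_diagonal else -1)
    return float(np.sqrt(np.mean(resid[rows, cols] ** 2)))


def _rmsea_ci(chisq: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Noncentrality-based CI: solve for the noncentral chi-square whose
    (1+level)/2 and (1-level)/2 quantiles sit at the observed statistic."""
    lo_q, hi_q = (1 + level) / 2, (1 - level) / 2

    def cdf(lam: float) -> float:
        if lam <= 0:
            return float(stats.chi2.cdf(chisq, df))
        return float(stats.ncx2.cdf(chisq, df, lam))

    upper = max(10.0 * chisq, 100.0)

    def solve(target: float) -> float:
        if cdf(0.0) < target:
            return 0.0
        if cdf(upper) > target:
            return upper
        return float(optimize.brentq(lambda l: cdf(l) - target, 0.0, upper, xtol=1e-8))

    lam_lo = solve(lo_q)
    lam_hi = solve(hi_q)
    denom = df * (n - 1)
    return (np.sqrt(lam_lo / denom), np.sqrt(lam_hi / denom))


def compute_indices(
    model: FittedModel,
    moments: SampleMoments,
    baseline: FittedModel | None = None,
    *,
    srmr_include_diagonal: bool = True,
) -> FitIndexSet:
    """Assemble the fit battery for a fitted model.

    CFI is clamped to [0, 1] by its max(., 0) definition; TLI is reported
    unclamped (it may exceed 1 or go negative). With df = 0 the RMSEA and
    TLI are undefined and reported as None.
    """
    if baseline is None:
        baseline = baseline_model(moments, model.chisq_dialect)
    chi_m, df_m = model.chisq, model.df
    chi_b, df_b = baseline.chisq, baseline.df
    n = model.n_obs

    d_m = max(chi_m - df_m, 0.0)
    d_b = max(chi_b - df_b, d_m)
    cfi = 1.0 - (d_m / d_b if d_b > 0 else 0.0)

    if df_m > 0:
        rb = chi_b / df_b
        rm = chi_m / df_m
        tli = (rb - rm) / (rb - 1.0) if rb != 1.0 else None
        rmsea = float(np.sqrt(d_m / (df_m * (n - 1))))
        ci = _rmsea_ci(chi_m, df_m, n)
    else:
        tli, rmsea, ci = None, None, None

    return FitIndexSet(
        chisq=chi_m,
        df=df_m,
        p_value=float(stats.chi2.sf(chi_m, df_m)) if df_m > 0 else 1.0,
        cfi=float(np.clip(cfi, 0.0, 1.0)),
        tli=tli,
        rmsea=rmsea,
        rmsea_ci90=ci,
        srmr=srmr(model, moments, srmr_include_diagonal),
        baseline_chisq=chi_b,
        baseline_df=df_b,
    )
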