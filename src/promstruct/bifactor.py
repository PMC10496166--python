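"""Reliability and dimensionality indices for bifactor models.

From a standardized orthogonal bifactor solution (general loadings lambda_g,
specific loadings lambda_k per item group k, residual variances theta):

    omega          = [(sum lambda_g)^2 + sum_k (sum lambda_k)^2] /
                     [(sum lambda_g)^2 + sum_k (sum lambda_k)^2 + sum theta]
    omega_H        = (sum lambda_g)^2 / same denominator
    omega_R        = omega_H / omega
    ECV_general    = sum lambda_g^2 / (sum lambda_g^2 + sum_k sum lambda_k^2)
    PUC            = fraction of item pairs not sharing a specific factor
    FD             = sqrt(diag(Phi Lambda' Sigma^-1 Lambda Phi))

Subscale-level omega / omega_H restrict the sums to one group's items.
These indices quantify whether a total score is defensible despite
multidimensionality ("essential unidimensionality": a strong, determinate
general factor with weak specifics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cfa import FactorModelSpec, FittedModel
from .errors import ConfigurationError

__all__ = [
    "BifactorIndexReport",
    "omega_total",
    "omega_hierarchical",
    "relative_omega",
    "ecv",
    "puc",
    "factor_determinacy",
    "report_table",
    "variance_decomposition",
]


def _check_bifactor(model: FittedModel) -> FactorModelSpec:
    spec = model.spec
    if spec is None or not spec.is_bifactor:
        raise ConfigurationError(
            "bifactor indices require a bifactor model (one general factor, "
            "orthogonal specific factors)"
        )
    return spec


def _parts(model: FittedModel):
    """Standardized general loadings, per-group (indices, specific loadings)
    and standardized residual variances."""
    spec = _check_bifactor(model)
    lam = model.standardized_loadings
    gcol = spec.factor_names.index(spec.general_factor)
    lam_g = lam[:, gcol]
    idx = {i: r for r, i in enumerate(model.item_ids)}
    groups = {}
    for name, items in spec.specific_factors:
        rows = [idx[i] for i in items]
        col = spec.factor_names.index(name)
        groups[name] = (rows, lam[rows, col])
    theta = 1.0 - np.sum(lam**2, axis=1)
    return lam_g, groups, theta


def omega_total(model: FittedModel) -> dict[str, float]:
    """Model-based internal reliability for the total score ("general") and
    for each specific factor's subscale score."""
    lam_g, groups, theta = _parts(model)
    num_g = lam_g.sum() ** 2 + sum(ls.sum() ** 2 for _, ls in groups.values())
    out = {"general": num_g / (num_g + theta.sum())}
    for name, (rows, ls) in groups.items():
        a = lam_g[rows].sum() ** 2
        b = ls.sum() ** 2
        out[name] = (a + b) / (a + b + theta[rows].sum())
    return out


def omega_hierarchical(model: FittedModel) -> dict[str, float]:
    """Proportion of total/subscale score variance due to the general factor
    (for "general") or to the specific factor alone (omega_HS)."""
    lam_g, groups, theta = _parts(model)
    num_g = lam_g.sum() ** 2 + sum(ls.sum() ** 2 for _, ls in groups.values())
    out = {"general": lam_g.sum() ** 2 / (num_g + theta.sum())}
    for name, (rows, ls) in groups.items():
        a = lam_g[rows].sum() ** 2
        b = ls.sum() ** 2
        out[name] = b / (a + b + theta[rows].sum())
    return out


def relative_omega(
    omega: dict[str, float] | float, omega_h: dict[str, float] | float
) -> dict[str, float] | float:
    """omega_R = omega_H / omega, per factor or for a single pair of values."""
    if isinstance(omega, dict):
        out = {}
        for k in omega:
            if omega[k] <= 0:
                out[k] = float("nan")
            else:
                out[k] = omega_h[k] / omega[k]
        return out
    if omega <= 0:
        return float("nan")
    return omega_h / omega


def ecv(model: FittedModel) -> dict[str, float]:
    """Explained common variance: each factor's share of the common variance;
    entries sum to one."""
    lam_g, groups, _ = _parts(model)
    parts = {"general": float(np.sum(lam_g**2))}
    for name, (_, ls) in groups.items():
        parts[name] = float(np.sum(ls**2))
    total = sum(parts.values())
    if total <= 0:
        raise ConfigurationError("zero common variance; ECV undefined")
    return {k: v / total for k, v in parts.items()}


def puc(spec: FactorModelSpec) -> float:
    """Percent uncontaminated correlations: the fraction of item pairs whose
    correlation is driven by the general factor only (the two items belong to
    different specific factors). Structure-only; no estimates needed."""
    if not spec.is_bifactor:
        raise ConfigurationError("PUC is defined for bifactor structures")
    p = len(spec.item_order)
    if p < 2:
        raise ConfigurationError("PUC needs at least two items")
    total = p * (p - 1) / 2
    within = sum(len(items) * (len(items) - 1) / 2 for _, items in spec.specific_factors)
    return (total - within) / total


def factor_determinacy(model: FittedModel) -> dict[str, float]:
    """Correlation between regression factor-score estimates and the factors:
    sqrt(diag(Phi Lambda' Sigma^-1 Lambda Phi)) on the standardized solution."""
    spec = _check_bifactor(model)
    lam = model.standardized_loadings
    phi = model.standardized_phi
    theta = 1.0 - np.sum(lam**2, axis=1)
    sigma = lam @ phi @ lam.T + np.diag(theta)
    try:
        sinv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        raise ConfigurationError("implied covariance is singular; FD undefined") from None
    fd2 = np.diag(phi @ lam.T @ sinv @ lam @ phi)
    fd = np.sqrt(np.clip(fd2, 0.0, 1.0))
    names = spec.factor_names
    out = {"general": float(fd[names.index(spec.general_factor)])}
    for f, _ in spec.specific_factors:
        out[f] = float(fd[names.index(f)])
    return out


def variance_decomposition(omega_general: float, omega_h_general: float) -> dict[str, float]:
    """Split total-score variance (in percent) into general-factor, specific-
    factor and random-error parts: 100*omega_H, 100*(omega - omega_H),
    100*(1 - omega)."""
    return {
        "general_pct": 100.0 * omega_h_general,
        "specific_pct": 100.0 * (omega_general - omega_h_general),
        "error_pct": 100.0 * (1.0 - omega_general),
    }


@dataclass
class BifactorIndexReport:
    """The full index suite, factors ordered general-first."""

    factor_order: list[str]
    omega: dict[str, float]
    omega_hierarchical: dict[str, float]
    relative_omega: dict[str, float]
    factor_determinacy: dict[str, float]
    ecv: dict[str, float]
    puc: float
    essentially_unidimensional: bool

    def to_dataframe(self, decimals: int | None = 3) -> pd.DataFrame:
        rows = []
        for f in self.factor_order:
            rows.append(
                {
                    "factor": f,
                    "omega": self.omega[f],
                    "omega_h": self.omega_hierarchical[f],
                    "omega_r": self.relative_omega[f],
                    "fd": self.factor_determinacy[f],
                    "ecv": self.ecv[f],
                }
            )
        df = pd.DataFrame(rows)
        if decimals is not None:
            num = df.select_dtypes("number").columns
            df[num] = df[num].round(decimals)
        return df

    def to_dict(self) -> dict:
        return {
            "factor_order": self.factor_order,
            "omega": self.omega,
            "omega_hierarchical": self.omega_hierarchical,
            "relative_omega": self.relative_omega,
            "factor_determinacy": self.factor_determinacy,
            "ecv": self.ecv,
            "puc": self.puc,
            "essentially_unidimensional": self.essentially_unidimensional,
        }


def report_table(model: FittedModel) -> BifactorIndexReport:
    """Assemble every index for a converged bifactor fit.

    The "essentially unidimensional" flag is an interpretive heuristic
    (general omega_H > 0.8 and general FD > 0.9), not a statistical test.
    """
    spec = _check_bifactor(model)
    om = omega_total(model)
    om_h = omega_hierarchical(model)
    om_r = relative_omega(om, om_h)
    fd = factor_determinacy(model)
    ev = ecv(model)
    order = ["general"] + [f for f, _ in spec.specific_factors]
    return BifactorIndexReport(
        factor_order=order,
        omega=om,
        omega_hierarchical=om_h,
        relative_omega=om_r,
        factor_determinacy=fd,
        ecv=ev,
        puc=puc(spec),
        essentially_unidimensional=bool(om_h["general"] > 0.8 and fd["general"] > 0.9),
    )
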