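"""Exploratory maximum-likelihood factor analysis.

Extraction follows the classical profile-likelihood algorithm: for fixed
uniquenesses the optimal loadings come from the leading eigenvectors of the
uniqueness-scaled correlation matrix, leaving a concentrated discrepancy

    F(psi) = sum_{j>m} (theta_j - ln theta_j - 1)

over the trailing eigenvalues, which is minimized over log-uniquenesses.
Factor retention uses Horn's parallel analysis; oblique rotation (geomin by
default) is delegated to the gradient-projection algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .errors import ConfigurationError, ConvergenceWarning, HeywoodWarning, PromstructError
from .instrument import InstrumentSpec, ResponseMatrix

__all__ = [
    "SampleMoments",
    "EfaResult",
    "ParallelAnalysisResult",
    "sample_moments",
    "eigenvalues",
    "efa_df",
    "ml_efa",
    "parallel_analysis",
    "rotate",
]


@dataclass(frozen=True)
class SampleMoments:
    """Unbiased sample covariance/correlation of complete-case responses."""

    covariance: np.ndarray
    correlation: np.ndarray
    means: np.ndarray
    n: int
    item_ids: list[str]

    @property
    def p(self) -> int:
        return self.covariance.shape[0]

    @classmethod
    def from_matrix(cls, X: np.ndarray, item_ids: list[str]) -> "SampleMoments":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n <= p:
            raise PromstructError(
                f"N={n} <= p={p}: covariance is singular, ML fitting impossible"
            )
        S = np.cov(X, rowvar=False, ddof=1)
        sd = np.sqrt(np.diag(S))
        if np.any(sd <= 0):
            raise PromstructError("zero-variance item; remove constant columns")
        R = S / np.outer(sd, sd)
        np.fill_diagonal(R, 1.0)
        return cls(S, R, X.mean(axis=0), n, list(item_ids))


def sample_moments(
    data: ResponseMatrix, instrument: InstrumentSpec | None = None
) -> SampleMoments:
    """Moments of the scored items; requires complete cases."""
    if instrument is not None:
        ids = [i for i in instrument.scored_item_ids if i in data.item_ids]
        data = data.subset_items(ids)
    if data.missing_mask.any():
        raise PromstructError(
            "moments require complete cases; run complete_case_filter first"
        )
    return SampleMoments.from_matrix(data.values, data.item_ids)


def eigenvalues(moments: SampleMoments) -> np.ndarray:
    """Descending eigenvalues of the sample correlation matrix (sum = p)."""
    return np.sort(np.linalg.eigvalsh(moments.correlation))[::-1]


def efa_df(p: int, m: int) -> int:
    """Residual df of an m-factor exploratory model:
    p(p+1)/2 - [p*m + p - m(m-1)/2]."""
    return p * (p + 1) // 2 - (p * m + p - m * (m - 1) // 2)


@dataclass
class EfaResult:
    n_factors: int
    unrotated_loadings: np.ndarray
    rotated_loadings: np.ndarray | None
    factor_correlations: np.ndarray
    eigenvalues: np.ndarray
    uniquenesses: np.ndarray
    discrepancy: float
    df: int
    n_obs: int
    item_ids: list[str]
    rotation: str | None = None

    @property
    def chisq(self) -> float:
        return (self.n_obs - 1) * self.discrepancy

    @property
    def loadings(self) -> np.ndarray:
        return self.rotated_loadings if self.rotated_loadings is not None else self.unrotated_loadings


def _concentrated(log_psi: np.ndarray, R: np.ndarray, m: int) -> tuple[float, np.ndarray]:
    psi = np.exp(log_psi)
    d = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(d, d)
    vals, vecs = np.linalg.eigh(Rs)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    tail = vals[m:]
    F = float(np.sum(tail - np.log(tail) - 1.0))
    # envelope gradient: with Lambda at its conditional optimum,
    # dF/dpsi_i = [Sigma^-1 (Sigma - R) Sigma^-1]_ii
    gamma = np.sqrt(np.maximum(vals[:m] - 1.0, 0.0))
    Lam = (vecs[:, :m] * gamma[None, :]) * np.sqrt(psi)[:, None]
    Sigma = Lam @ Lam.T + np.diag(psi)
    Sinv = np.linalg.inv(Sigma)
    A = Sinv - Sinv @ R @ Sinv
    return F, np.diag(A) * psi


def ml_efa(moments: SampleMoments, m: int) -> EfaResult:
    """Canonical ML exploratory factor analysis with m factors.

    Operates on the correlation matrix (ML factor analysis is scale
    invariant, so the discrepancy equals the covariance-metric fit). The
    m = 1 solution coincides with the one-factor confirmatory fit.
    """
    R = moments.correlation
    p = moments.p
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    df = efa_df(p, m)
    if df < 0:
        raise ConfigurationError(f"m={m} factors over-parameterize p={p} items (df={df})")

    # Joreskog's starting uniquenesses
    Rinv = np.linalg.pinv(R)
    psi0 = np.clip((1.0 - m / (2.0 * p)) / np.diag(Rinv), 5e-3, 0.98)
    lb = np.log(1e-4)
    res = optimize.minimize(
        _concentrated,
        np.log(psi0),
        args=(R, m),
        jac=True,
        method="L-BFGS-B",
        bounds=[(lb, np.log(2.0))] * p,
        options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-10},
    )
    F, g = _concentrated(res.x, R, m)
    gnorm = float(np.max(np.abs(g)))
    if gnorm > 5e-6 and not np.any(res.x <= lb + 1e-8):
        warnings.warn(
            f"ML EFA (m={m}): gradient norm {gnorm:.2e} above tolerance",
            ConvergenceWarning,
            stacklevel=2,
        )
    psi = np.exp(res.x)
    if np.any(res.x <= lb + 1e-8):
        warnings.warn(
            f"ML EFA (m={m}): uniqueness at lower bound (Heywood case)",
            HeywoodWarning,
            stacklevel=2,
        )
    d = 1.0 / np.sqrt(psi)
    vals, vecs = np.linalg.eigh(R * np.outer(d, d))
    vals, vecs = vals[::-1], vecs[:, ::-1]
    gamma = np.sqrt(np.maximum(vals[:m] - 1.0, 0.0))
    Lam = (vecs[:, :m] * gamma[None, :]) * np.sqrt(psi)[:, None]
    for c in range(m):
        if Lam[:, c].sum() < 0:
            Lam[:, c] *= -1
    return EfaResult(
        n_factors=m,
        unrotated_loadings=Lam,
        rotated_loadings=None,
        factor_correlations=np.eye(m),
        eigenvalues=eigenvalues(moments),
        uniquenesses=psi,
        discrepancy=max(float(F), 0.0),
        df=df,
        n_obs=moments.n,
        item_ids=list(moments.item_ids),
    )


# ---------------------------------------------------------------------------
# parallel analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParallelAnalysisResult:
    observed_eigenvalues: np.ndarray
    reference_eigenvalues: np.ndarray
    suggested_factors: int
    n_replicates: int
    percentile: float
    method: str


def parallel_analysis(
    data: ResponseMatrix,
    n_replicates: int = 500,
    percentile: float = 99.0,
    seed: int | None = None,
    method: str = "normal",
    instrument: InstrumentSpec | None = None,
) -> ParallelAnalysisResult:
    """Horn's parallel analysis for factor retention.

    Null eigenvalues come from independent standard-normal data of the same
    N x p shape ("normal", classical Horn) or from independently permuted
    columns of the observed data ("permutation"). The suggested number of
    factors is the length of the leading run of observed eigenvalues
    exceeding the per-rank reference percentile. The default reference is
    the 99th percentile (Glorfeld's conservative variant, which keeps the
    pure-noise over-extraction rate near 1%; pass 95 for classical Horn).
    """
    if n_replicates < 100:
        raise ConfigurationError("use at least 100 replicates for stable percentiles")
    if method not in ("normal", "permutation"):
        raise ConfigurationError(f"unknown null method {method!r}")
    moments = sample_moments(data, instrument)
    obs = eigenvalues(moments)
    if instrument is not None:
        ids = [i for i in instrument.scored_item_ids if i in data.item_ids]
        X = data.subset_items(ids).values.astype(float)
    else:
        X = data.values.astype(float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    null_eigs = np.empty((n_replicates, p))
    for r in range(n_replicates):
        if method == "normal":
            Z = rng.standard_normal((n, p))
        else:
            Z = np.column_stack([rng.permutation(X[:, j]) for j in range(p)])
        Rnull = np.corrcoef(Z, rowvar=False)
        null_eigs[r] = np.sort(np.linalg.eigvalsh(Rnull))[::-1]
    ref = np.percentile(null_eigs, percentile, axis=0)
    exceeds = obs > ref
    suggested = int(np.argmin(exceeds)) if not exceeds.all() else p
    if not exceeds[0]:
        suggested = 0
    return ParallelAnalysisResult(obs, ref, suggested, n_replicates, percentile, method)


# ---------------------------------------------------------------------------
# rotation
# ---------------------------------------------------------------------------

def _geomin_vgQ(eps: float):
    def vgQ(L=None, A=None, T=None):
        if L is None:
            L = A @ np.linalg.inv(T.T)
        p, m = L.shape
        L2 = L * L + eps
        pro = np.exp(np.log(L2).sum(axis=1) / m)
        q = float(pro.sum())
        Gq = (2.0 * L / L2) * (pro / m)[:, None]
        return q, Gq

    return vgQ


def _oblimin_vgQ(gamma: float):
    def vgQ(L=None, A=None, T=None):
        if L is None:
            L = A @ np.linalg.inv(T.T)
        p, m = L.shape
        L2 = L * L
        C = np.ones((p, p)) / p
        N = np.ones((m, m)) - np.eye(m)
        X = (np.eye(p) - gamma * C) @ L2 @ N
        q = float(np.sum(L2 * X)) / 4.0
        Gq = L * X
        return q, Gq

    return vgQ


def rotate(result: EfaResult, method: str = "geomin", eps: float = 0.01) -> EfaResult:
    """Oblique rotation of an EFA solution; fit statistics are unchanged.

    ``method`` is "geomin" (default, with fourth-root penalty eps) or
    "oblimin" (gamma = 0, i.e. quartimin). For m = 1 rotation is a no-op.
    """
    A = result.unrotated_loadings
    m = result.n_factors
    if m == 1:
        return replace(result, rotated_loadings=A.copy(), rotation="none")
    if method == "geomin":
        vgQ = _geomin_vgQ(eps)
    elif method == "oblimin":
        vgQ = _oblimin_vgQ(0.0)
    else:
        raise ConfigurationError(f"unknown rotation method {method!r}")
    from statsmodels.multivariate.factor_rotation._gpa_rotation import GPA

    best = None
    # random restarts guard against local optima of the rotation criterion
    rng = np.random.default_rng(0)
    starts = [np.eye(m)] + [
        np.linalg.qr(rng.standard_normal((m, m)))[0] for _ in range(4)
    ]
    for T0 in starts:
        L, Phi_T, T, table = GPA(
            A, vgQ=vgQ, T=T0, rotation_method="oblique", tol=1e-8, max_tries=2000
        )
        crit = table[-1][1]
        if best is None or crit < best[0]:
            best = (crit, L, Phi_T)
    _, L, Phi = best
    Phi = Phi.copy()
    for c in range(m):
        if L[:, c].sum() < 0:
            L[:, c] *= -1
            Phi[c, :] *= -1
            Phi[:, c] *= -1
    return replace(result, rotated_loadings=L, factor_correlations=Phi, rotation=method)
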