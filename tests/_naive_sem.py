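"""Independent brute-force ML covariance-structure fitter used as a test oracle.

Deliberately implemented from the textbook definition only, sharing no code
with the package: the discrepancy F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p
is minimized by scipy's L-BFGS-B with finite-difference gradients over a
direct parameterization (loadings flat, residual variances box-bounded,
factor correlations box-bounded), from several deterministic starts.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def naive_fit(
    pattern: np.ndarray,
    S: np.ndarray,
    orthogonal: bool = True,
    n_starts: int = 3,
    seed: int = 12345,
) -> dict:
    """Minimize F_ML for a loading pattern; returns F, loadings, residual
    variances, factor correlations and the standardized loadings."""
    pattern = np.asarray(pattern, bool)
    p, k = pattern.shape
    pos = [(i, j) for j in range(k) for i in range(p) if pattern[i, j]]
    n_load = len(pos)
    phi_pairs = [] if orthogonal else [(a, b) for a in range(k) for b in range(a + 1, k)]
    var = np.diag(S)
    sign, logdet_S = np.linalg.slogdet(S)
    assert sign > 0

    def build(x):
        Lam = np.zeros((p, k))
        for t, (i, j) in enumerate(pos):
            Lam[i, j] = x[t]
        theta = x[n_load : n_load + p]
        Phi = np.eye(k)
        for t, (a, b) in enumerate(phi_pairs):
            Phi[a, b] = Phi[b, a] = x[n_load + p + t]
        return Lam, theta, Phi

    def objective(x):
        Lam, theta, Phi = build(x)
        Sigma = Lam @ Phi @ Lam.T + np.diag(theta)
        sgn, logdet = np.linalg.slogdet(Sigma)
        if sgn <= 0:
            return 1e8
        try:
            Sinv = np.linalg.inv(Sigma)
        except np.linalg.LinAlgError:
            return 1e8
        return logdet + float(np.sum(Sinv * S)) - logdet_S - p

    bounds = (
        [(None, None)] * n_load
        + [(1e-6 * v, None) for v in var]
        + [(-0.98, 0.98)] * len(phi_pairs)
    )
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        x0 = np.concatenate(
            [
                np.array([0.6 * np.sqrt(var[i]) for i, _ in pos])
                * (1.0 if s == 0 else rng.uniform(0.5, 1.2, n_load)),
                0.5 * var,
                np.full(len(phi_pairs), 0.3),
            ]
        )
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 4000, "maxfun": 400000, "ftol": 1e-15, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    Lam, theta, Phi = build(best.x)
    Sigma = Lam @ Phi @ Lam.T + np.diag(theta)
    std = Lam * np.sqrt(np.diag(Phi))[None, :] / np.sqrt(np.diag(Sigma))[:, None]
    # align signs: each column sums positive
    for j in range(k):
        if std[:, j].sum() < 0:
            std[:, j] *= -1
            Lam[:, j] *= -1
    return {
        "F": float(best.fun),
        "loadings": Lam,
        "theta": theta,
        "phi": Phi,
        "standardized_loadings": std,
    }
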