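"""Confirmatory covariance-structure estimation by maximum likelihood.

Models are declared as loading patterns (items -> factors) with a factor
covariance structure that is either free (correlated factors), orthogonal, or
bifactor (one general factor loaded by every item plus orthogonal specific
factors). The engine minimizes the ML discrepancy

    F_ML = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

over free loadings, residual (co)variances and factor covariances, using an
analytic gradient. chi-square is (N-1) * F_ML by default (Wishart likelihood);
an N * F_ML dialect is available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy import linalg, optimize, stats

from .efa import SampleMoments
from .errors import (
    ConfigurationError,
    ConvergenceWarning,
    HeywoodWarning,
    IdentificationError,
    PromstructError,
)

__all__ = [
    "FactorModelSpec",
    "FittedModel",
    "ModificationIndex",
    "AdequacyCriteria",
    "AdequacyReport",
    "ChisqDifference",
    "model_df",
    "fit_ml",
    "modification_indices",
    "chisq_difference",
    "chisq_difference_test",
    "check_adequacy",
    "ikdc_one_factor",
    "ikdc_two_factor",
    "ikdc_four_factor",
    "ikdc_bifactor",
    "MODEL_FIXTURES",
]

_PENALTY = 1e10  # objective value returned when Sigma leaves the PD cone


@dataclass(frozen=True)
class FactorModelSpec:
    """Declarative factor model: named factors with their item sets.

    ``covariance`` is "free" (all factor correlations estimated) or
    "orthogonal". When ``general_factor`` names one of the factors, the model
    is a bifactor structure: that factor loads every item, all factors are
    orthogonal, and each item belongs to at most one other (specific) factor.
    """

    name: str
    factors: tuple[tuple[str, tuple[str, ...]], ...]
    covariance: str = "free"
    general_factor: str | None = None
    correlated_residuals: tuple[tuple[str, str], ...] = ()
    item_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.covariance not in ("free", "orthogonal"):
            raise ConfigurationError(f"unknown covariance structure {self.covariance!r}")
        names = [f for f, _ in self.factors]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate factor names")
        if self.general_factor is not None:
            if self.general_factor not in names:
                raise ConfigurationError(
                    f"general factor {self.general_factor!r} is not a declared factor"
                )
            if self.covariance != "orthogonal":
                raise ConfigurationError("a bifactor model requires orthogonal factors")
        all_items = [i for _, items in self.factors for i in items]
        if self.general_factor is not None:
            gen_items = set(dict(self.factors)[self.general_factor])
            specifics = [i for f, items in self.factors if f != self.general_factor for i in items]
            if len(specifics) != len(set(specifics)):
                raise ConfigurationError(
                    "bifactor: each item may load at most one specific factor"
                )
            if not set(specifics) <= gen_items:
                raise ConfigurationError("bifactor: general factor must load every item")
        elif len(all_items) != len(set(all_items)):
            # cross-loadings are allowed for non-bifactor models, but warn on
            # accidental duplicates within one factor
            for f, items in self.factors:
                if len(items) != len(set(items)):
                    raise ConfigurationError(f"factor {f!r} lists an item twice")
        if not self.item_order:
            seen: dict[str, None] = {}
            for _, items in self.factors:
                for i in items:
                    seen.setdefault(i)
            object.__setattr__(self, "item_order", tuple(seen))
        covered = {i for _, items in self.factors for i in items}
        if set(self.item_order) != covered:
            raise ConfigurationError("item_order must list exactly the items in the model")
        for a, b in self.correlated_residuals:
            if a not in covered or b not in covered or a == b:
                raise ConfigurationError(f"bad correlated-residual pair ({a!r}, {b!r})")

    # -- structure queries --------------------------------------------------

    @property
    def factor_names(self) -> list[str]:
        return [f for f, _ in self.factors]

    @property
    def item_ids(self) -> list[str]:
        return list(self.item_order)

    @property
    def is_bifactor(self) -> bool:
        return self.general_factor is not None

    @property
    def specific_factors(self) -> list[tuple[str, tuple[str, ...]]]:
        return [(f, items) for f, items in self.factors if f != self.general_factor]

    def pattern(self) -> np.ndarray:
        """Boolean p x k matrix of which loadings are free."""
        p, k = len(self.item_order), len(self.factors)
        idx = {i: r for r, i in enumerate(self.item_order)}
        P = np.zeros((p, k), dtype=bool)
        for c, (_, items) in enumerate(self.factors):
            for i in items:
                P[idx[i], c] = True
        return P

    def free_phi_pairs(self) -> list[tuple[int, int]]:
        if self.covariance == "orthogonal":
            return []
        k = len(self.factors)
        return [(a, b) for a in range(k) for b in range(a + 1, k)]

    def residual_pairs(self) -> list[tuple[int, int]]:
        idx = {i: r for r, i in enumerate(self.item_order)}
        out = []
        for a, b in self.correlated_residuals:
            ia, ib = idx[a], idx[b]
            out.append((min(ia, ib), max(ia, ib)))
        return out

    def n_free_parameters(self) -> int:
        return (
            int(self.pattern().sum())
            + len(self.item_order)
            + len(self.free_phi_pairs())
            + len(self.residual_pairs())
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "factors": {f: list(items) for f, items in self.factors},
            "covariance": self.covariance,
            "general_factor": self.general_factor,
            "correlated_residuals": [list(p) for p in self.correlated_residuals],
            "item_order": list(self.item_order),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FactorModelSpec":
        return cls(
            name=d["name"],
            factors=tuple((f, tuple(items)) for f, items in dict(d["factors"]).items()),
            covariance=d.get("covariance", "free"),
            general_factor=d.get("general_factor"),
            correlated_residuals=tuple(tuple(p) for p in d.get("correlated_residuals", [])),
            item_order=tuple(d.get("item_order", ())),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "FactorModelSpec":
        path = Path(path)
        raw = path.read_text()
        return cls.from_dict(json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw))


# ---------------------------------------------------------------------------
# IKDC model fixtures
# ---------------------------------------------------------------------------

_ALL_18 = (
    "1", "2", "3", "4", "5", "6", "7", "8",
    "9a", "9b", "9c", "9d", "9e", "9f", "9g", "9h", "9i", "10b",
)

_GROUPS = {
    "symptoms": ("2", "3", "4", "6"),
    "activity": ("1", "5", "7", "8", "10b"),
    "adls": ("9a", "9b", "9c", "9d", "9e", "9f"),
    "sport": ("9g", "9h", "9i"),
}


def ikdc_one_factor() -> FactorModelSpec:
    """All 18 scored items on a single factor (the intended IKDC structure)."""
    return FactorModelSpec(
        name="one_factor",
        factors=(("general", _ALL_18),),
        covariance="orthogonal",
        item_order=_ALL_18,
    )


def ikdc_two_factor() -> FactorModelSpec:
    """Two correlated factors in the Higgins style: "symptoms" (items 2, 3, 4,
    6, 9a-i) and "activity" (items 1, 5, 7, 8, 10b). Item 3 (pain severity) is
    placed with the symptom items."""
    return FactorModelSpec(
        name="two_factor",
        factors=(
            ("symptoms", ("2", "3", "4", "6", "9a", "9b", "9c", "9d", "9e", "9f", "9g", "9h", "9i")),
            ("activity", ("1", "5", "7", "8", "10b")),
        ),
        covariance="free",
        item_order=_ALL_18,
    )


def ikdc_four_factor() -> FactorModelSpec:
    """Four correlated content factors: symptoms / activity level / ADLs / sport."""
    return FactorModelSpec(
        name="four_factor",
        factors=tuple(_GROUPS.items()),
        covariance="free",
        item_order=_ALL_18,
    )


def ikdc_bifactor() -> FactorModelSpec:
    """General factor over all 18 items plus the four orthogonal specific factors."""
    return FactorModelSpec(
        name="bifactor",
        factors=(("general", _ALL_18),) + tuple(_GROUPS.items()),
        covariance="orthogonal",
        general_factor="general",
        item_order=_ALL_18,
    )


MODEL_FIXTURES = {
    "one_factor": ikdc_one_factor,
    "two_factor": ikdc_two_factor,
    "four_factor": ikdc_four_factor,
    "bifactor": ikdc_bifactor,
}


# ---------------------------------------------------------------------------
# degrees of freedom
# ---------------------------------------------------------------------------

def model_df(spec: FactorModelSpec, p: int | None = None) -> int:
    """p(p+1)/2 minus the number of free parameters (factor variances fixed)."""
    if p is None:
        p = len(spec.item_order)
    if p != len(spec.item_order):
        raise ConfigurationError(
            f"spec covers {len(spec.item_order)} items but p={p} was requested"
        )
    df = p * (p + 1) // 2 - spec.n_free_parameters()
    if df < 0:
        raise IdentificationError(f"model {spec.name!r} is under-identified (df={df})")
    return df


# ---------------------------------------------------------------------------
# fitted model container
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """Result of an ML covariance-structure fit.

    Loading and covariance matrices are on the input (raw) scale; the
    standardized solution rescales loadings by sqrt(Phi_kk)/sqrt(Sigma_ii)
    and factor covariances to correlations.
    """

    spec: FactorModelSpec | None
    item_ids: list[str]
    loadings: np.ndarray
    phi: np.ndarray
    theta: np.ndarray  # full p x p residual covariance (diagonal + freed pairs)
    discrepancy: float
    df: int
    n_free_parameters: int
    n_obs: int
    chisq_dialect: str = "wishart"
    converged: bool = True
    gradient_norm: float = 0.0
    heywood: bool = False
    identification: str = "unit_variance"

    @property
    def implied_covariance(self) -> np.ndarray:
        return self.loadings @ self.phi @ self.loadings.T + self.theta

    @property
    def chisq(self) -> float:
        mult = self.n_obs - 1 if self.chisq_dialect == "wishart" else self.n_obs
        return mult * self.discrepancy

    @property
    def standardized_loadings(self) -> np.ndarray:
        s = np.sqrt(np.diag(self.implied_covariance))
        f = np.sqrt(np.diag(self.phi))
        return self.loadings * f[None, :] / s[:, None]

    @property
    def standardized_phi(self) -> np.ndarray:
        f = np.sqrt(np.diag(self.phi))
        return self.phi / np.outer(f, f)

    @property
    def standardized_residual_variances(self) -> np.ndarray:
        return np.diag(self.theta) / np.diag(self.implied_covariance)

    def factor_index(self, name: str) -> int:
        assert self.spec is not None
        return self.spec.factor_names.index(name)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict() if self.spec is not None else None,
            "item_ids": self.item_ids,
            "loadings": self.loadings.tolist(),
            "phi": self.phi.tolist(),
            "theta": self.theta.tolist(),
            "discrepancy": self.discrepancy,
            "df": self.df,
            "n_free_parameters": self.n_free_parameters,
            "n_obs": self.n_obs,
            "chisq_dialect": self.chisq_dialect,
            "converged": self.converged,
            "gradient_norm": self.gradient_norm,
            "heywood": self.heywood,
            "identification": self.identification,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FittedModel":
        return cls(
            spec=FactorModelSpec.from_dict(d["spec"]) if d.get("spec") else None,
            item_ids=list(d["item_ids"]),
            loadings=np.asarray(d["loadings"], dtype=float),
            phi=np.asarray(d["phi"], dtype=float),
            theta=np.asarray(d["theta"], dtype=float),
            discrepancy=float(d["discrepancy"]),
            df=int(d["df"]),
            n_free_parameters=int(d["n_free_parameters"]),
            n_obs=int(d["n_obs"]),
            chisq_dialect=d.get("chisq_dialect", "wishart"),
            converged=bool(d.get("converged", True)),
            gradient_norm=float(d.get("gradient_norm", 0.0)),
            heywood=bool(d.get("heywood", False)),
            identification=d.get("identification", "unit_variance"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FittedModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# parameterization
# ---------------------------------------------------------------------------

class _Parameterization:
    """Maps the unconstrained optimizer vector to (Lambda, Phi, Theta).

    Layout: free loadings (column-major over the pattern), log residual
    variances, residual covariances, free factor covariances, and (marker
    identification only) log factor variances. Residual variances are
    log-transformed to stay positive; factor correlations are bounded in
    (-0.99, 0.99) by box constraints.
    """

    def __init__(self, spec: FactorModelSpec, S: np.ndarray, identification: str):
        self.spec = spec
        self.p, self.k = len(spec.item_order), len(spec.factors)
        self.identification = identification
        self.pattern = spec.pattern()
        self.phi_pairs = spec.free_phi_pairs()
        self.res_pairs = spec.residual_pairs()
        self.var = np.diag(S).copy()

        load_pos = [(i, c) for c in range(self.k) for i in range(self.p) if self.pattern[i, c]]
        self.fixed_markers: list[tuple[int, int]] = []
        if identification == "marker":
            for c in range(self.k):
                first = next(i for i in range(self.p) if self.pattern[i, c])
                self.fixed_markers.append((first, c))
            load_pos = [pos for pos in load_pos if pos not in self.fixed_markers]
        elif identification != "unit_variance":
            raise ConfigurationError(f"unknown identification {identification!r}")
        self.load_pos = load_pos

        self.n_load = len(load_pos)
        self.n_theta = self.p
        self.n_res = len(self.res_pairs)
        self.n_phi = len(self.phi_pairs)
        self.n_fvar = self.k if identification == "marker" else 0
        self.n_params = self.n_load + self.n_theta + self.n_res + self.n_phi + self.n_fvar

        self.sl = {}
        ofs = 0
        for name, n in [
            ("load", self.n_load), ("theta", self.n_theta), ("res", self.n_res),
            ("phi", self.n_phi), ("fvar", self.n_fvar),
        ]:
            self.sl[name] = slice(ofs, ofs + n)
            ofs += n

    def start(self) -> np.ndarray:
        x = np.zeros(self.n_params)
        sd = np.sqrt(self.var)
        lam0 = np.zeros(self.n_load)
        for t, (i, c) in enumerate(self.load_pos):
            scale = 0.7
            if self.spec.is_bifactor:
                # split communality between general and specific columns
                scale = 0.6 if self.spec.factor_names[c] == self.spec.general_factor else 0.3
            lam0[t] = scale * sd[i]
        x[self.sl["load"]] = lam0
        x[self.sl["theta"]] = np.log(0.5 * self.var)
        if self.n_fvar:
            x[self.sl["fvar"]] = 0.0
        return x

    def bounds(self) -> list[tuple[float | None, float | None]]:
        b: list[tuple[float | None, float | None]] = [(None, None)] * self.n_load
        b += [(np.log(1e-4 * v), np.log(1e3 * v)) for v in self.var]
        b += [(None, None)] * self.n_res
        b += [(-0.99, 0.99)] * self.n_phi
        b += [(np.log(1e-4), np.log(1e4))] * self.n_fvar
        return b

    def unpack(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        Lam = np.zeros((self.p, self.k))
        for (i, c) in self.fixed_markers:
            Lam[i, c] = 1.0
        for t, (i, c) in enumerate(self.load_pos):
            Lam[i, c] = x[self.sl["load"]][t]
        Phi = np.eye(self.k)
        if self.n_fvar:
            np.fill_diagonal(Phi, np.exp(x[self.sl["fvar"]]))
        fsd = np.sqrt(np.diag(Phi))
        for t, (a, b) in enumerate(self.phi_pairs):
            Phi[a, b] = Phi[b, a] = x[self.sl["phi"]][t] * fsd[a] * fsd[b]
        Theta = np.diag(np.exp(x[self.sl["theta"]]))
        for t, (i, j) in enumerate(self.res_pairs):
            Theta[i, j] = Theta[j, i] = x[self.sl["res"]][t]
        return Lam, Phi, Theta


def _fml_and_grad(
    x: np.ndarray, par: _Parameterization, S: np.ndarray, logdet_S: float
) -> tuple[float, np.ndarray]:
    Lam, Phi, Theta = par.unpack(x)
    p = par.p
    Sigma = Lam @ Phi @ Lam.T + Theta
    try:
        c, low = linalg.cho_factor(Sigma, check_finite=False)
    except linalg.LinAlgError:
        return _PENALTY + float(np.sum(x * x)), 2.0 * x
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    Sinv = linalg.cho_solve((c, low), np.eye(p), check_finite=False)
    F = logdet + float(np.sum(Sinv * S)) - logdet_S - p
    # A = Sigma^-1 (Sigma - S) Sigma^-1
    A = Sinv - Sinv @ S @ Sinv
    A = 0.5 * (A + A.T)

    g = np.zeros_like(x)
    ALP = A @ Lam @ Phi
    gl = np.empty(par.n_load)
    for t, (i, cidx) in enumerate(par.load_pos):
        gl[t] = 2.0 * ALP[i, cidx]
    g[par.sl["load"]] = gl
    theta_diag = np.exp(x[par.sl["theta"]])
    g[par.sl["theta"]] = np.diag(A) * theta_diag
    for t, (i, j) in enumerate(par.res_pairs):
        g[par.sl["res"]][t] = 2.0 * A[i, j]
    if par.n_phi or par.n_fvar:
        LAL = Lam.T @ A @ Lam
        fvar = np.diag(Phi)
        fsd = np.sqrt(fvar)
        for t, (a, b) in enumerate(par.phi_pairs):
            g[par.sl["phi"]][t] = 2.0 * LAL[a, b] * fsd[a] * fsd[b]
        if par.n_fvar:
            # d Sigma / d ln(phi_ff): direct variance term plus the part of each
            # covariance phi_ab = r_ab * sd_a * sd_b that moves with sd_f
            gf = LAL.diagonal() * fvar
            for a, b in par.phi_pairs:
                gf_ab = 2.0 * LAL[a, b] * Phi[a, b]
                gf[a] += 0.5 * gf_ab
                gf[b] += 0.5 * gf_ab
            g[par.sl["fvar"]] += gf
    return F, g


def _sign_fix(model: FittedModel) -> FittedModel:
    """Flip factor columns so each column of loadings sums positive."""
    Lam, Phi = model.loadings.copy(), model.phi.copy()
    for c in range(Lam.shape[1]):
        if Lam[:, c].sum() < 0:
            Lam[:, c] *= -1
            Phi[c, :] *= -1
            Phi[:, c] *= -1
    model.loadings, model.phi = Lam, Phi
    return model


def fit_ml(
    spec: FactorModelSpec,
    moments: SampleMoments,
    *,
    identification: str = "unit_variance",
    chisq_dialect: str = "wishart",
    max_iter: int = 5000,
    gtol: float = 5e-7,
) -> FittedModel:
    """Fit a factor model to sample moments by maximum likelihood.

    Raises :class:`IdentificationError` if df < 0; warns (never silently) on
    non-convergence or Heywood cases (residual variances at their lower
    bound).
    """
    item_ids = spec.item_ids
    missing = [i for i in item_ids if i not in moments.item_ids]
    if missing:
        raise ConfigurationError(f"moments lack model item(s) {missing!r}")
    idx = [moments.item_ids.index(i) for i in item_ids]
    S = moments.covariance[np.ix_(idx, idx)]
    p = len(item_ids)
    df = model_df(spec, p)

    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ConfigurationError("sample covariance is not positive definite")

    par = _Parameterization(spec, S, identification)
    x0 = par.start()
    res = optimize.minimize(
        _fml_and_grad,
        x0,
        args=(par, S, logdet_S),
        jac=True,
        method="L-BFGS-B",
        bounds=par.bounds(),
        options={"maxiter": max_iter, "maxfun": 10 * max_iter, "ftol": 1e-15, "gtol": 1e-10},
    )
    F, g = _fml_and_grad(res.x, par, S, logdet_S)
    # projected gradient: at an active box bound only feasible descent counts
    pg = g.copy()
    for t, (lo, hi) in enumerate(par.bounds()):
        if lo is not None and res.x[t] <= lo + 1e-10:
            pg[t] = min(g[t], 0.0)
        elif hi is not None and res.x[t] >= hi - 1e-10:
            pg[t] = max(g[t], 0.0)
    gnorm = float(np.max(np.abs(pg)))
    converged = bool(gnorm < max(gtol, gtol * max(abs(F), 1.0)))
    if not converged:
        warnings.warn(
            f"model {spec.name!r}: gradient norm {gnorm:.2e} above tolerance after "
            f"{res.nit} iterations",
            ConvergenceWarning,
            stacklevel=2,
        )

    Lam, Phi, Theta = par.unpack(res.x)
    theta_diag = np.diag(Theta)
    heywood = bool(np.any(theta_diag <= 1.01e-4 * par.var))
    if heywood:
        warnings.warn(
            f"model {spec.name!r}: residual variance at lower bound (Heywood case); "
            "estimate is boundary-constrained",
            HeywoodWarning,
            stacklevel=2,
        )

    model = FittedModel(
        spec=spec,
        item_ids=list(item_ids),
        loadings=Lam,
        phi=Phi,
        theta=Theta,
        discrepancy=max(float(F), 0.0),
        df=df,
        n_free_parameters=par.n_params,
        n_obs=moments.n,
        chisq_dialect=chisq_dialect,
        converged=converged,
        gradient_norm=gnorm,
        heywood=heywood,
        identification=identification,
    )
    return _sign_fix(model)


# ---------------------------------------------------------------------------
# modification indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModificationIndex:
    kind: str  # "residual_covariance" or "loading"
    parameter: str
    expected_chisq_drop: float


def _dsigma_free(par: _Parameterization, Lam: np.ndarray, Phi: np.ndarray) -> list[np.ndarray]:
    """dSigma for every free parameter, in natural (untransformed) coordinates."""
    p, k = par.p, par.k
    out: list[np.ndarray] = []
    LP = Lam @ Phi
    for (i, c) in par.load_pos:
        D = np.zeros((p, p))
        D[i, :] += LP[:, c]
        D[:, i] += LP[:, c]
        out.append(D)
    for i in range(p):
        D = np.zeros((p, p))
        D[i, i] = 1.0
        out.append(D)
    for (i, j) in par.res_pairs:
        D = np.zeros((p, p))
        D[i, j] = D[j, i] = 1.0
        out.append(D)
    for (a, b) in par.phi_pairs:
        D = np.outer(Lam[:, a], Lam[:, b])
        out.append(D + D.T)
    for f in range(par.n_fvar):
        out.append(np.outer(Lam[:, f], Lam[:, f]))
    return out


def modification_indices(
    model: FittedModel,
    moments: SampleMoments,
    *,
    include_loadings: bool = True,
    include_residuals: bool = True,
) -> list[ModificationIndex]:
    """Univariate score-test estimates of the chi-square drop from freeing each
    fixed residual covariance or cross-loading, sorted descending."""
    if model.spec is None:
        raise ConfigurationError("modification indices need a model spec")
    spec = model.spec
    idx = [moments.item_ids.index(i) for i in model.item_ids]
    S = moments.covariance[np.ix_(idx, idx)]
    p = len(model.item_ids)
    Sigma = model.implied_covariance
    Sinv = np.linalg.inv(Sigma)
    A = Sinv - Sinv @ S @ Sinv
    A = 0.5 * (A + A.T)

    par = _Parameterization(spec, S, model.identification)
    frees = _dsigma_free(par, model.loadings, model.phi)
    if model.df == 0 or not frees:
        return []

    pattern = spec.pattern()
    res_set = set(spec.residual_pairs())
    candidates: list[tuple[str, str, np.ndarray]] = []
    if include_residuals:
        for i in range(p):
            for j in range(i + 1, p):
                if (i, j) in res_set:
                    continue
                D = np.zeros((p, p))
                D[i, j] = D[j, i] = 1.0
                candidates.append(
                    ("residual_covariance", f"{model.item_ids[i]}~~{model.item_ids[j]}", D)
                )
    if include_loadings:
        LP = model.loadings @ model.phi
        for c, fname in enumerate(spec.factor_names):
            for i in range(p):
                if pattern[i, c]:
                    continue
                D = np.zeros((p, p))
                D[i, :] += LP[:, c]
                D[:, i] += LP[:, c]
                candidates.append(("loading", f"{model.item_ids[i]}=~{fname}", D))

    mats = frees + [D for *_, D in candidates]
    M = np.stack([Sinv @ D for D in mats])  # (q, p, p)
    H = np.einsum("aij,bji->ab", M, M)
    nf = len(frees)
    Hff = H[:nf, :nf]
    out: list[ModificationIndex] = []
    mult = model.n_obs - 1 if model.chisq_dialect == "wishart" else model.n_obs
    try:
        Hff_inv = np.linalg.pinv(Hff)
    except np.linalg.LinAlgError:
        warnings.warn("singular information matrix; no modification indices", stacklevel=2)
        return []
    for t, (kind, label, D) in enumerate(candidates):
        row = H[nf + t, :nf]
        c_tt = H[nf + t, nf + t] - row @ Hff_inv @ row
        if c_tt <= 1e-10:
            continue
        gt = float(np.sum(A * D))
        mi = mult * gt * gt / (2.0 * c_tt)
        out.append(ModificationIndex(kind, label, max(mi, 0.0)))
    out.sort(key=lambda m: -m.expected_chisq_drop)
    return out


# ---------------------------------------------------------------------------
# nested comparison and adequacy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChisqDifference:
    delta_chisq: float
    delta_df: int
    p_value: float


def chisq_difference(
    chisq_nested: float, df_nested: int, chisq_parent: float, df_parent: int
) -> ChisqDifference:
    """Likelihood-ratio comparison from two chi-square statistics.

    The nested (more restricted) model has the larger df; its chi-square
    cannot be smaller than the parent's beyond convergence noise.
    """
    ddf = df_nested - df_parent
    if ddf < 0:
        raise PromstructError("nested model must have more degrees of freedom than parent")
    dchi = chisq_nested - chisq_parent
    if dchi < -1e-6:
        raise PromstructError(
            f"nested chi-square smaller than parent ({dchi:.3g}); models are not nested "
            "or the parent fit did not converge"
        )
    dchi = max(dchi, 0.0)
    p = 1.0 if ddf == 0 and dchi <= 1e-12 else float(stats.chi2.sf(dchi, max(ddf, 1)))
    if ddf == 0:
        p = 1.0 if dchi <= 1e-12 else 0.0
    return ChisqDifference(dchi, ddf, p)


def chisq_difference_test(nested: FittedModel, parent: FittedModel) -> ChisqDifference:
    """Delta-chi-square test between two fits of the same data."""
    if nested.n_obs != parent.n_obs or nested.item_ids != parent.item_ids:
        raise PromstructError("nested comparison requires fits to the same moments")
    if nested.chisq_dialect != parent.chisq_dialect:
        raise PromstructError("nested comparison requires the same chi-square dialect")
    return chisq_difference(nested.chisq, nested.df, parent.chisq, parent.df)


@dataclass(frozen=True)
class AdequacyCriteria:
    """Published adequacy thresholds for this instrument's validation:
    CFI and TLI > 0.9, RMSEA and SRMR < 0.08, standardized loadings > 0.3,
    factor correlations < 0.85."""

    min_loading: float = 0.3
    max_factor_covariance: float = 0.85
    min_cfi: float = 0.9
    min_tli: float = 0.9
    max_rmsea: float = 0.08
    max_srmr: float = 0.08


@dataclass
class AdequacyReport:
    passed: dict[str, bool]
    offending_loadings: list[tuple[str, str, float]]
    offending_covariances: list[tuple[str, str, float]]

    @property
    def all_passed(self) -> bool:
        return all(self.passed.values())


def check_adequacy(
    model: FittedModel,
    indices: "object" = None,
    criteria: AdequacyCriteria | None = None,
) -> AdequacyReport:
    """Evaluate a fitted model against published adequacy thresholds.

    ``indices`` is a FitIndexSet (or None to check only loadings/covariances).
    For bifactor models the loading check applies to the general factor only,
    matching how such models are reported.
    """
    crit = criteria or AdequacyCriteria()
    spec = model.spec
    lam = model.standardized_loadings
    passed: dict[str, bool] = {}
    bad_load: list[tuple[str, str, float]] = []
    bad_cov: list[tuple[str, str, float]] = []

    if spec is not None:
        pattern = spec.pattern()
        cols = range(lam.shape[1])
        if spec.is_bifactor:
            cols = [spec.factor_names.index(spec.general_factor)]
        for c in cols:
            for i in range(lam.shape[0]):
                if pattern[i, c] and abs(lam[i, c]) <= crit.min_loading:
                    bad_load.append((model.item_ids[i], spec.factor_names[c], float(lam[i, c])))
        phi = model.standardized_phi
        for a in range(phi.shape[0]):
            for b in range(a + 1, phi.shape[1]):
                if abs(phi[a, b]) >= crit.max_factor_covariance:
                    bad_cov.append((spec.factor_names[a], spec.factor_names[b], float(phi[a, b])))
    passed["loadings"] = not bad_load
    passed["factor_covariances"] = not bad_cov

    if indices is not None:
        passed["cfi"] = indices.cfi > crit.min_cfi
        tli = indices.tli
        passed["tli"] = tli is not None and tli > crit.min_tli
        rmsea = indices.rmsea
        passed["rmsea"] = rmsea is not None and rmsea < crit.max_rmsea
        passed["srmr"] = indices.srmr < crit.max_srmr
    return AdequacyReport(passed, bad_load, bad_cov)
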