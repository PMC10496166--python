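"""Synthetic ordinal questionnaire cohorts from latent factor models.

Respondents are drawn from a continuous latent factor model: factor scores
eta ~ N(0, Phi), residuals eps ~ N(0, Theta), continuous responses
y* = Lambda eta + eps, each discretized through its item's ordered thresholds
into 0-based category codes. The default population is a standardized
bifactor structure over the 18 scored IKDC items (general factor plus four
orthogonal content factors: symptoms, activity level, ADLs, sport) with
equal-probability thresholds, so the generator reproduces the coarse 2/5/11
category scales of the instrument and the attenuation they induce in
product-moment correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cfa import FactorModelSpec, ikdc_bifactor
from .errors import ConfigurationError
from .instrument import ResponseMatrix, builtin_ikdc

__all__ = [
    "BifactorPopulation",
    "SimulationConfig",
    "default_population",
    "symptomatic_population",
    "simulate",
    "simulate_from_model",
    "simulate_latent",
]

# default specific-loading magnitude per content factor; sport is the most
# coherent cluster in this instrument, symptoms the loosest
_DEFAULT_SPECIFIC = {"symptoms": 0.35, "activity": 0.40, "adls": 0.45, "sport": 0.55}
_DEFAULT_GENERAL = 0.6


@dataclass(frozen=True)
class BifactorPopulation:
    """Standardized bifactor generating model for ordinal items.

    Per item i: lambda_g[i]^2 + lambda_s[i]^2 + theta[i] = 1, so the latent
    response scale is a standard normal and thresholds are z-values.
    """

    item_ids: tuple[str, ...]
    general_loadings: np.ndarray
    specific_loadings: np.ndarray
    group_of: tuple[str, ...]  # specific-factor name per item
    group_order: tuple[str, ...]
    thresholds: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        p = len(self.item_ids)
        object.__setattr__(self, "general_loadings", np.asarray(self.general_loadings, float))
        object.__setattr__(self, "specific_loadings", np.asarray(self.specific_loadings, float))
        if not (
            len(self.general_loadings) == len(self.specific_loadings)
            == len(self.group_of) == len(self.thresholds) == p
        ):
            raise ConfigurationError("population field lengths disagree")
        if set(self.group_of) != set(self.group_order):
            raise ConfigurationError("group_order must cover exactly the groups used")
        if np.any(self.residual_variances <= 0):
            raise ConfigurationError("loadings imply non-positive residual variance")
        for i, tau in enumerate(self.thresholds):
            if np.any(np.diff(tau) <= 0):
                raise ConfigurationError(
                    f"item {self.item_ids[i]!r}: thresholds must be strictly increasing"
                )

    @property
    def p(self) -> int:
        return len(self.item_ids)

    @property
    def residual_variances(self) -> np.ndarray:
        return 1.0 - self.general_loadings**2 - self.specific_loadings**2

    @property
    def groups(self) -> dict[str, list[str]]:
        return {
            g: [i for i, gi in zip(self.item_ids, self.group_of) if gi == g]
            for g in self.group_order
        }

    def lambda_matrix(self) -> np.ndarray:
        """p x (1 + n_groups) loading matrix, general factor first."""
        k = 1 + len(self.group_order)
        Lam = np.zeros((self.p, k))
        Lam[:, 0] = self.general_loadings
        col = {g: 1 + j for j, g in enumerate(self.group_order)}
        for i, g in enumerate(self.group_of):
            Lam[i, col[g]] = self.specific_loadings[i]
        return Lam

    def implied_covariance(self) -> np.ndarray:
        """Population covariance of the continuous latents: Lam Lam' + Theta
        (orthogonal factors), a correlation matrix by standardization."""
        Lam = self.lambda_matrix()
        return Lam @ Lam.T + np.diag(self.residual_variances)

    def model_spec(self) -> FactorModelSpec:
        """The confirmatory bifactor spec matching this population."""
        return FactorModelSpec(
            name="bifactor",
            factors=(("general", tuple(self.item_ids)),)
            + tuple((g, tuple(items)) for g, items in self.groups.items()),
            covariance="orthogonal",
            general_factor="general",
            item_order=tuple(self.item_ids),
        )

    def to_dict(self) -> dict:
        return {
            "item_ids": list(self.item_ids),
            "general_loadings": [float(v) for v in self.general_loadings],
            "specific_loadings": [float(v) for v in self.specific_loadings],
            "group_of": list(self.group_of),
            "group_order": list(self.group_order),
            "thresholds": [[float(t) for t in tau] for tau in self.thresholds],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BifactorPopulation":
        return cls(
            item_ids=tuple(d["item_ids"]),
            general_loadings=np.asarray(d["general_loadings"], float),
            specific_loadings=np.asarray(d["specific_loadings"], float),
            group_of=tuple(d["group_of"]),
            group_order=tuple(d["group_order"]),
            thresholds=tuple(tuple(tau) for tau in d["thresholds"]),
        )


@dataclass(frozen=True)
class SimulationConfig:
    n_respondents: int
    seed: int
    population: BifactorPopulation

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ConfigurationError("n_respondents must be >= 1")

    def to_dict(self) -> dict:
        return {
            "n_respondents": self.n_respondents,
            "seed": self.seed,
            "population": self.population.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(
            n_respondents=int(d["n_respondents"]),
            seed=int(d["seed"]),
            population=BifactorPopulation.from_dict(d["population"]),
        )

    def save(self, path) -> None:
        from pathlib import Path

        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "SimulationConfig":
        from pathlib import Path

        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def equal_probability_thresholds(n_categories: int, shift: float = 0.0) -> tuple[float, ...]:
    """z-value cut points giving equal category probabilities (optionally
    shifted upward, which piles respondents into the low categories)."""
    qs = np.arange(1, n_categories) / n_categories
    return tuple(stats.norm.ppf(qs) + shift)


def default_population(
    general_loading: float = _DEFAULT_GENERAL,
    specific_loadings: dict[str, float] | None = None,
    threshold_shift: float = 0.0,
) -> BifactorPopulation:
    """The reference generating model: 18 scored IKDC items, general loading
    0.6 throughout, specific loadings 0.35/0.40/0.45/0.55 for the symptoms /
    activity / ADLs / sport clusters, equal-probability thresholds."""
    spec_mag = dict(_DEFAULT_SPECIFIC)
    if specific_loadings:
        spec_mag.update(specific_loadings)
    instrument = builtin_ikdc()
    bifactor = ikdc_bifactor()
    groups = dict(bifactor.specific_factors)
    item_ids = bifactor.item_ids
    group_of = []
    for i in item_ids:
        group_of.append(next(g for g, items in groups.items() if i in items))
    lam_s = np.array([spec_mag[g] for g in group_of])
    thresholds = tuple(
        equal_probability_thresholds(instrument.item(i).n_categories, threshold_shift)
        for i in item_ids
    )
    return BifactorPopulation(
        item_ids=tuple(item_ids),
        general_loadings=np.full(len(item_ids), general_loading),
        specific_loadings=lam_s,
        group_of=tuple(group_of),
        group_order=tuple(groups),
        thresholds=thresholds,
    )


def symptomatic_population(shift: float = 0.8) -> BifactorPopulation:
    """Post-injury preset: thresholds shifted up so scores skew low, as in
    ACL-deficient baseline cohorts."""
    return default_population(threshold_shift=shift)


def simulate_latent(
    Lam: np.ndarray,
    Phi: np.ndarray,
    Theta_diag: np.ndarray,
    thresholds: tuple[tuple[float, ...], ...],
    item_ids: list[str],
    n: int,
    seed: int,
) -> ResponseMatrix:
    """Draw n respondents from y* = Lam eta + eps and discretize.

    One generator per call; factor scores are drawn before residuals, items
    in declared order, so a fixed seed yields a bit-identical matrix.
    """
    p, k = Lam.shape
    try:
        C = np.linalg.cholesky(Phi)
    except np.linalg.LinAlgError:
        raise ConfigurationError("factor covariance matrix is not positive definite") from None
    if np.any(Theta_diag < 0):
        raise ConfigurationError("negative residual variance")
    rng = np.random.default_rng(seed)
    eta = rng.standard_normal((n, k)) @ C.T
    eps = rng.standard_normal((n, p)) * np.sqrt(Theta_diag)[None, :]
    ystar = eta @ Lam.T + eps
    codes = np.empty((n, p), dtype=np.int64)
    for j in range(p):
        tau = np.asarray(thresholds[j])
        if np.any(np.diff(tau) <= 0):
            raise ConfigurationError(f"item {item_ids[j]!r}: non-increasing thresholds")
        codes[:, j] = np.searchsorted(tau, ystar[:, j])
    return ResponseMatrix(
        values=codes,
        missing_mask=np.zeros_like(codes, dtype=bool),
        item_ids=list(item_ids),
        respondent_ids=[str(i) for i in range(n)],
    )


def simulate(config: SimulationConfig) -> ResponseMatrix:
    """Draw a cohort from a bifactor population (orthogonal factors)."""
    pop = config.population
    Lam = pop.lambda_matrix()
    return simulate_latent(
        Lam,
        np.eye(Lam.shape[1]),
        pop.residual_variances,
        pop.thresholds,
        list(pop.item_ids),
        config.n_respondents,
        config.seed,
    )


def simulate_from_model(
    spec: FactorModelSpec,
    loadings: np.ndarray,
    thresholds: tuple[tuple[float, ...], ...],
    n: int,
    seed: int,
    phi: np.ndarray | None = None,
    residual_variances: np.ndarray | None = None,
) -> ResponseMatrix:
    """Draw a cohort from any confirmatory model, including correlated
    factors (phi not identity). With residual_variances omitted, items are
    standardized: theta = 1 - diag(Lam Phi Lam')."""
    Lam = np.asarray(loadings, float)
    p, k = Lam.shape
    if p != len(spec.item_order) or k != len(spec.factors):
        raise ConfigurationError("loading matrix shape does not match the spec")
    if np.any(Lam[~spec.pattern()] != 0):
        raise ConfigurationError("nonzero loading outside the spec's pattern")
    Phi = np.eye(k) if phi is None else np.asarray(phi, float)
    common = np.einsum("if,fg,ig->i", Lam, Phi, Lam)
    if residual_variances is None:
        theta = 1.0 - common
        if np.any(theta <= 0):
            raise ConfigurationError("loadings imply non-positive residual variance")
    else:
        theta = np.asarray(residual_variances, float)
    return simulate_latent(Lam, Phi, theta, thresholds, list(spec.item_order), n, seed)
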