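"""End-to-end structural-validity pipeline.

Runs the full analysis sequence on a respondent CSV or a simulated cohort:
complete-case filtering, sample moments, eigenvalues and parallel analysis,
ML EFA (one factor, then the parallel-suggested number with oblique
rotation), the confirmatory model suite (one-factor / two-factor /
four-factor / bifactor by default), the nested four-factor-vs-bifactor
likelihood-ratio comparison, bifactor reliability indices, and adequacy
verdicts. All artifacts (JSON report, fit and index tables, loading tables,
run log) are deterministic given the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .bifactor import BifactorIndexReport, report_table
from .cfa import (
    MODEL_FIXTURES,
    AdequacyCriteria,
    ChisqDifference,
    FactorModelSpec,
    FittedModel,
    check_adequacy,
    chisq_difference_test,
    fit_ml,
)
from .cohort import SimulationConfig, default_population, simulate
from .efa import (
    EfaResult,
    ParallelAnalysisResult,
    eigenvalues,
    ml_efa,
    parallel_analysis,
    rotate,
    sample_moments,
)
from .errors import ConfigurationError, PromstructError
from .fit_indices import FitIndexSet, baseline_model, compute_indices
from .instrument import (
    CompletenessSummary,
    InstrumentSpec,
    builtin_ikdc,
    complete_case_filter,
    read_responses,
)

__all__ = ["PipelineConfig", "StudyReport", "run_structural_validity"]


@dataclass
class PipelineConfig:
    data_path: str | None = None
    simulate_n: int | None = None
    seed: int = 0
    models: tuple[str, ...] = ("one_factor", "two_factor", "four_factor", "bifactor")
    nested_pair: tuple[str, str] = ("four_factor", "bifactor")  # (nested, parent)
    out_dir: str | None = None
    chisq_dialect: str = "wishart"
    parallel_replicates: int = 500
    parallel_percentile: float = 99.0
    rotation: str = "geomin"
    one_based: bool = False
    adequacy: AdequacyCriteria = field(default_factory=AdequacyCriteria)

    def __post_init__(self) -> None:
        if not self.models:
            raise ConfigurationError("at least one model must be requested")
        if (self.data_path is None) == (self.simulate_n is None):
            raise ConfigurationError("provide exactly one of data_path or simulate_n")
        unknown = [m for m in self.models if m not in MODEL_FIXTURES]
        if unknown:
            raise ConfigurationError(f"unknown model fixture(s) {unknown!r}")


@dataclass
class StudyReport:
    completeness: CompletenessSummary
    eigenvalues: np.ndarray
    parallel: ParallelAnalysisResult
    efa_one: EfaResult
    efa_m: EfaResult
    models: dict[str, FittedModel]
    indices: dict[str, FitIndexSet]
    adequacy: dict[str, Any]
    nested_test: ChisqDifference | None
    bifactor_report: BifactorIndexReport | None
    seed: int
    settings: dict[str, Any]

    def fit_table(self) -> pd.DataFrame:
        rows = []
        for name, m in self.models.items():
            ix = self.indices[name]
            rows.append(
                {
                    "model": name,
                    "chisq": ix.chisq,
                    "df": ix.df,
                    "p_value": ix.p_value,
                    "cfi": ix.cfi,
                    "tli": ix.tli,
                    "rmsea": ix.rmsea,
                    "rmsea_ci90_low": ix.rmsea_ci90[0] if ix.rmsea_ci90 else None,
                    "rmsea_ci90_high": ix.rmsea_ci90[1] if ix.rmsea_ci90 else None,
                    "srmr": ix.srmr,
                    "converged": m.converged,
                    "adequate": self.adequacy[name].all_passed,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        d: dict[str, Any] = {
            "promstruct_version": __version__,
            "seed": self.seed,
            "settings": self.settings,
            "completeness": {
                "n_total": self.completeness.n_total,
                "n_complete": self.completeness.n_complete,
                "pct_complete": self.completeness.pct_complete,
            },
            "eigenvalues": [round(float(v), 12) for v in self.eigenvalues],
            "parallel_analysis": {
                "suggested_factors": self.parallel.suggested_factors,
                "reference_eigenvalues": [
                    round(float(v), 12) for v in self.parallel.reference_eigenvalues
                ],
            },
            "efa": {
                "one_factor": {
                    "chisq": round(self.efa_one.chisq, 10),
                    "df": self.efa_one.df,
                },
                "retained": {
                    "n_factors": self.efa_m.n_factors,
                    "chisq": round(self.efa_m.chisq, 10),
                    "df": self.efa_m.df,
                    "rotation": self.efa_m.rotation,
                },
            },
            "models": {},
            "nested_test": None,
            "bifactor_indices": None,
        }
        for name, m in self.models.items():
            ix = self.indices[name].to_dict()
            d["models"][name] = {
                "df": m.df,
                "converged": m.converged,
                "heywood": m.heywood,
                "fit": {k: (round(v, 10) if isinstance(v, float) else v) for k, v in ix.items()},
                "adequate": self.adequacy[name].all_passed,
                "adequacy": self.adequacy[name].passed,
            }
        if self.nested_test is not None:
            d["nested_test"] = {
                "nested": self.settings["nested_pair"][0],
                "parent": self.settings["nested_pair"][1],
                "delta_chisq": round(self.nested_test.delta_chisq, 10),
                "delta_df": self.nested_test.delta_df,
                "p_value": float(self.nested_test.p_value),
            }
        if self.bifactor_report is not None:
            br = self.bifactor_report.to_dict()
            d["bifactor_indices"] = json.loads(
                json.dumps(br, default=lambda o: round(float(o), 10))
            )
        return d

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.bool_, np.integer, np.floating)):
                return o.item()
            raise TypeError(f"not JSON serializable: {type(o)}")

        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=default)


def _load_data(config: PipelineConfig, instrument: InstrumentSpec):
    if config.data_path is not None:
        return read_responses(config.data_path, instrument, one_based=config.one_based)
    cohort = simulate(
        SimulationConfig(
            n_respondents=config.simulate_n,
            seed=config.seed,
            population=default_population(),
        )
    )
    return cohort


def run_structural_validity(
    config: PipelineConfig, instrument: InstrumentSpec | None = None
) -> StudyReport:
    """Execute the full structural-validity sequence and (optionally) write
    artifacts to ``config.out_dir``."""
    instrument = instrument or builtin_ikdc()
    data = _load_data(config, instrument)
    data, completeness = complete_case_filter(data, instrument)
    moments = sample_moments(data, instrument)
    eig = eigenvalues(moments)
    pa = parallel_analysis(
        data,
        n_replicates=config.parallel_replicates,
        percentile=config.parallel_percentile,
        seed=config.seed,
        instrument=instrument,
    )
    efa_one = ml_efa(moments, 1)
    m_retained = max(pa.suggested_factors, 2)
    efa_m = rotate(ml_efa(moments, m_retained), method=config.rotation)

    base = baseline_model(moments, config.chisq_dialect)
    models: dict[str, FittedModel] = {}
    indices: dict[str, FitIndexSet] = {}
    adequacy: dict[str, Any] = {}
    for name in config.models:
        spec = MODEL_FIXTURES[name]()
        fitted = fit_ml(spec, moments, chisq_dialect=config.chisq_dialect)
        ix = compute_indices(fitted, moments, base)
        models[name] = fitted
        indices[name] = ix
        adequacy[name] = check_adequacy(fitted, ix, config.adequacy)

    nested_test = None
    nst, par = config.nested_pair
    if nst in models and par in models:
        nested_test = chisq_difference_test(models[nst], models[par])

    bif_report = None
    for name, m in models.items():
        if m.spec is not None and m.spec.is_bifactor and m.converged:
            bif_report = report_table(m)
            break

    settings = {
        "chisq_dialect": config.chisq_dialect,
        "rotation": config.rotation,
        "parallel_replicates": config.parallel_replicates,
        "parallel_percentile": config.parallel_percentile,
        "models": list(config.models),
        "nested_pair": list(config.nested_pair),
        "data_source": config.data_path or f"simulated(n={config.simulate_n})",
    }
    report = StudyReport(
        completeness=completeness,
        eigenvalues=eig,
        parallel=pa,
        efa_one=efa_one,
        efa_m=efa_m,
        models=models,
        indices=indices,
        adequacy=adequacy,
        nested_test=nested_test,
        bifactor_report=bif_report,
        seed=config.seed,
        settings=settings,
    )
    if config.out_dir is not None:
        _write_artifacts(report, config)
    return report


def _write_artifacts(report: StudyReport, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json() + "\n")
    report.fit_table().to_csv(out / "fit_table.csv", index=False)
    if report.bifactor_report is not None:
        report.bifactor_report.to_dataframe(decimals=3).to_csv(
            out / "indices_table.csv", index=False
        )
    for name, m in report.models.items():
        lam = pd.DataFrame(
            m.standardized_loadings, index=m.item_ids, columns=m.spec.factor_names
        )
        lam.to_csv(out / f"loadings_{name}.csv", index_label="item")
    log_lines = [
        f"promstruct {__version__}",
        f"seed: {report.seed}",
        *(f"{k}: {v}" for k, v in report.settings.items()),
        f"n_complete: {report.completeness.n_complete} / {report.completeness.n_total}",
        f"parallel suggested factors: {report.parallel.suggested_factors}",
    ]
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
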