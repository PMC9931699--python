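"""End-to-end drivers: curation -> model -> decisions (+ rank test) -> report.

`run_comparison` executes one two-group analysis for each configured period
(optionally JIF-normalized); `run_multi_comparison` fits one joint
shared-shape model over every (period x group) dataset and returns the
pairwise credibility matrix behind the multi-period heat map. `write_report`
emits the summary tables (rank-test table and Bayesian difference-of-means
table), diagnostics JSON and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curation import (
    CitationRecord,
    CurationConfig,
    Group,
    curate,
    read_citations_table,
)
from .decisions import ComparisonSummary, DecisionConfig, summarize_comparison, \
    pairwise_credibility_matrix
from .model import (
    ModelSpec,
    PosteriorTrace,
    PriorMode,
    convergence_diagnostics,
    pooled_prior_spec,
    predictive_check,
    sample_posterior,
)
from .ranktests import FrequentistResult, mwu_pvalue, normality_gate

logger = logging.getLogger("citebest")

__all__ = ["RunConfig", "ComparisonResult", "run_comparison", "run_multi_comparison",
           "write_report", "load_run_config"]


@dataclass(frozen=True)
class RunConfig:
    """One analysis campaign: input table, periods, groups, sampler settings."""

    input_table: str
    periods: tuple[tuple[int, int], ...] = ((1985, 2020),)
    group1: Group = Group.REPRODUCIBLE
    group2: Group = Group.NON_REPRODUCIBLE
    normalize_by_jif: bool = False
    prior_mode: PriorMode = PriorMode.DEFAULT
    draws: int = 100_000
    chains: int = 4
    tune: int = 500
    seed: int = 0
    hdi_mass: float = 0.95
    rope: tuple[float, float] = (-0.2, 0.2)
    imputation_factor: float = 0.6287
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.periods:
            raise ValueError("need at least one period")
        if self.group1 is self.group2:
            raise ValueError("group1 and group2 must differ")

    def decision_config(self) -> DecisionConfig:
        return DecisionConfig(hdi_mass=self.hdi_mass, rope=self.rope)

    def curation_config(self, period: tuple[int, int]) -> CurationConfig:
        return CurationConfig(
            imputation_factor=self.imputation_factor,
            period=tuple(period),
            normalize_by_jif=self.normalize_by_jif,
        )


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from a YAML or JSON mapping."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if "periods" in raw:
        raw["periods"] = tuple(tuple(p) for p in raw["periods"])
    if "rope" in raw:
        raw["rope"] = tuple(raw["rope"])
    for key in ("group1", "group2"):
        if key in raw:
            raw[key] = Group(raw[key])
    if "prior_mode" in raw:
        raw["prior_mode"] = PriorMode(raw["prior_mode"])
    return RunConfig(**raw)


@dataclass(frozen=True)
class ComparisonResult:
    """Everything one period's comparison produced."""

    period: tuple[int, int]
    summary: ComparisonSummary
    frequentist: FrequentistResult
    normality: dict
    diagnostics: dict
    predictive: dict
    trace: PosteriorTrace = field(repr=False, compare=False)


def _analyze_pair(
    groups, cfg: RunConfig, period, seed: int
) -> ComparisonResult:
    prior = pooled_prior_spec(groups, cfg.prior_mode)
    spec = ModelSpec(groups=tuple(groups), prior=prior)
    trace = sample_posterior(spec, draws=cfg.draws, chains=cfg.chains,
                             seed=seed, tune=cfg.tune)
    summary = summarize_comparison(trace, 0, 1, cfg.decision_config())
    diag = convergence_diagnostics(trace)
    ppc = predictive_check(spec, trace, reps=500, seed=seed + 1)
    freq = mwu_pvalue(groups[0].values, groups[1].values)
    norm = {
        g.label: normality_gate(g.values).to_dict() if g.n >= 3 else None
        for g in groups
    }
    return ComparisonResult(
        period=tuple(period),
        summary=summary,
        frequentist=freq,
        normality=norm,
        diagnostics=diag.to_dict(),
        predictive=ppc.to_dict(),
        trace=trace,
    )


def run_comparison(cfg: RunConfig,
                   records: list[CitationRecord] | None = None) -> list[ComparisonResult]:
    """Curate and compare group1 vs group2 for every configured period."""
    if records is None:
        records = read_citations_table(cfg.input_table)
    results = []
    for k, period in enumerate(cfg.periods):
        ccfg = cfg.curation_config(period)
        datasets, log = curate(records, [cfg.group1, cfg.group2], ccfg,
                               labels=[f"{cfg.group1.value} {period[0]}-{period[1]}",
                                       f"{cfg.group2.value} {period[0]}-{period[1]}"])
        for entry in log:
            logger.info("excluded %s: %s", entry["paper_id"], entry["reason"])
        results.append(_analyze_pair(datasets, cfg, period, cfg.seed + k))
    return results


def run_multi_comparison(
    cfg: RunConfig, records: list[CitationRecord] | None = None
) -> tuple[list[ComparisonResult], pd.DataFrame]:
    """Per-period two-group summaries plus one joint pairwise matrix.

    The matrix comes from a single shared-shape model over all
    (period x group) datasets, so every pairwise credibility is computed
    from draws of one coherent posterior.
    """
    if records is None:
        records = read_citations_table(cfg.input_table)
    summaries = run_comparison(cfg, records)
    all_groups = []
    for period in cfg.periods:
        ccfg = cfg.curation_config(period)
        datasets, _ = curate(records, [cfg.group1, cfg.group2], ccfg,
                             labels=[f"{cfg.group1.value} {period[0]}-{period[1]}",
                                     f"{cfg.group2.value} {period[0]}-{period[1]}"])
        all_groups.extend(datasets)
    prior = pooled_prior_spec(all_groups, cfg.prior_mode)
    spec = ModelSpec(groups=tuple(all_groups), prior=prior)
    trace = sample_posterior(spec, draws=cfg.draws, chains=cfg.chains,
                             seed=cfg.seed + 1000, tune=cfg.tune)
    matrix = pairwise_credibility_matrix(trace)
    return summaries, matrix


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(results: list[ComparisonResult], outdir,
                 cfg: RunConfig | None = None,
                 matrix: pd.DataFrame | None = None) -> dict[str, Path]:
    """Emit the rank-test table, Bayesian summary table, diagnostics, manifest."""
    if not results:
        raise ValueError("no results to report")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    freq_rows, bayes_rows = [], []
    for r in results:
        pair = f"{r.summary.group1} versus {r.summary.group2}"
        freq_rows.append({
            "groups": pair, "n1": r.frequentist.n1, "n2": r.frequentist.n2,
            "U": r.frequentist.u_statistic, "p_value": r.frequentist.p_value,
            "method": r.frequentist.method.value,
        })
        bayes_rows.append({
            "groups": pair, "n1": r.summary.n1, "n2": r.summary.n2,
            "mean_diff": r.summary.mean_diff.mean,
            "hdi_low": r.summary.mean_diff.hdi_low,
            "hdi_high": r.summary.mean_diff.hdi_high,
            "credibility_above_zero": r.summary.mean_diff.credibility_above_zero,
            "effect_size": r.summary.effect_size.mean,
            "decision": r.summary.decision.value,
        })
    paths["rank_tests"] = out / "rank_tests.csv"
    pd.DataFrame(freq_rows).to_csv(paths["rank_tests"], index=False)
    paths["bayes_summaries"] = out / "bayes_summaries.csv"
    pd.DataFrame(bayes_rows).to_csv(paths["bayes_summaries"], index=False)

    paths["diagnostics"] = out / "diagnostics.json"
    with open(paths["diagnostics"], "w") as fh:
        json.dump(
            {
                f"{r.period[0]}-{r.period[1]}": {
                    "convergence": r.diagnostics,
                    "predictive": r.predictive,
                    "normality": r.normality,
                    "summary": r.summary.to_dict(),
                }
                for r in results
            },
            fh, indent=2,
        )

    if matrix is not None:
        paths["credibility_matrix"] = out / "credibility_matrix.csv"
        matrix.to_csv(paths["credibility_matrix"])

    manifest = {"n_comparisons": len(results)}
    if cfg is not None:
        manifest |= {"seed": cfg.seed, "config": asdict(cfg),
                     "config_hash": _config_hash(cfg)}
    import citebest

    manifest["version"] = citebest.__version__
    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return paths
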