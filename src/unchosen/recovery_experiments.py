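"""Validation experiments: parameter recovery, model recovery, and the
signature-reproduction check, as seeded, reproducible recipes.

Scales default to desk size (tens of agents, short chains) so the whole
battery runs on one CPU in minutes; the study-scale settings (175
agents, 20 chains x 1000 warmup x 50 draws) are available as the
``paper`` preset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hierarchical_inference import (
    DEFAULT_INDIVIDUAL_SD,
    PopulationParams,
    PosteriorDraws,
    SamplerConfig,
    fit,
    sample_cohort_params,
    summarize,
)
from .model_comparison import ElpdMatrix, compare, leave_one_block_out
from .rl_models import MODEL_IDS, PARAM_NAMES, simulate_cohort
from .sequential_analysis import (
    build_lagged_dataset,
    fit_lagged_regression,
    raw_rates,
)
from .synthetic_task import CohortDataset, TaskConfig

__all__ = [
    "TRUE_POPULATIONS",
    "RecoveryConfig",
    "RecoveryReport",
    "ModelRecoveryTable",
    "simulate_recovery_cohort",
    "run_parameter_recovery",
    "run_model_recovery",
    "run_signature_reproduction",
    "run_full_study",
]

#: natural-scale population truths used in the recovery experiments
TRUE_POPULATIONS: Mapping[str, Mapping[str, float]] = {
    "baseline": {"alpha_chosen": 0.3, "beta": 4.0},
    "double_two_pe": {"alpha_chosen": 0.3, "alpha_unchosen": 0.1, "beta": 4.0},
    "double_one_pe": {"alpha_chosen": 0.3, "alpha_unchosen": 0.1, "beta": 4.0},
    "select_reject": {"alpha_chosen": 0.3, "omega": 0.7, "beta": 4.0},
}

RECOVERY_MODELS = ("double_two_pe", "double_one_pe", "select_reject")


@dataclass(frozen=True)
class RecoveryConfig:
    n_agents: int = 40
    sampler_preset: str = "desk"
    seed: int = 0
    task: TaskConfig = field(default_factory=TaskConfig)
    individual_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INDIVIDUAL_SD)
    )
    scale_factor: float = 1.0
    max_treedepth: int = 10

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2")
        if any(s < 0 for s in self.individual_sd.values()):
            raise ValueError("individual SDs must be >= 0")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    @property
    def effective_agents(self) -> int:
        return max(2, int(round(self.n_agents * self.scale_factor)))

    def sampler(self, seed: int) -> SamplerConfig:
        cfg = SamplerConfig.preset(self.sampler_preset, seed=seed)
        if self.max_treedepth != cfg.max_treedepth:
            cfg = replace(cfg, max_treedepth=self.max_treedepth)
        if self.scale_factor != 1.0:
            cfg = replace(
                cfg,
                warmup=max(100, int(round(cfg.warmup * self.scale_factor))),
                draws=max(50, int(round(cfg.draws * self.scale_factor))),
            )
        return cfg


@dataclass
class RecoveryReport:
    model: str
    population: pd.DataFrame  # parameter, truth, median, hdi_low, hdi_high, covered
    individual_r: dict[str, float | None]  # Pearson r per parameter (None if undefined)
    converged: bool
    n_agents: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def all_covered(self) -> bool:
        return bool(self.population["covered"].all())

    @property
    def min_individual_r(self) -> float:
        vals = [v for v in self.individual_r.values() if v is not None]
        return float(min(vals)) if vals else float("nan")


@dataclass
class ModelRecoveryTable:
    """Delta-elpd grid: rows = fitted models, columns = generating models.

    Entries are elpd(fitted) - elpd(generating) on the generating model's
    cohort; the diagonal is zero by construction.
    """

    delta: pd.DataFrame
    se: pd.DataFrame
    totals: pd.DataFrame  # raw elpd totals, fitted x generating

    def top_model(self, generating: str) -> str:
        return str(self.totals[generating].idxmax())

    def beats_baseline_substantially(self, generating: str) -> bool:
        d = float(self.delta.loc["baseline", generating])
        se = float(self.se.loc["baseline", generating])
        return d < 0 and abs(d) > 2.0 * se


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


def simulate_recovery_cohort(
    model: str, cfg: RecoveryConfig, seed: int
) -> tuple[CohortDataset, pd.DataFrame]:
    """Cohort simulated hierarchically at the stated population truths.

    Returns the cohort and a frame of the true per-agent parameters.
    """
    sds = {n: cfg.individual_sd[n] for n in PARAM_NAMES[model]}
    population = PopulationParams.from_natural(model, TRUE_POPULATIONS[model], sds)
    s_params, s_cohort = _spawn_seeds(seed, 2)
    agent_params = sample_cohort_params(model, population, cfg.effective_agents, s_params)
    cohort = simulate_cohort(model, agent_params, cfg.task, s_cohort)
    truths = pd.DataFrame(
        [p.to_dict() for p in agent_params], index=cohort.participant_ids
    )
    return cohort, truths


def run_parameter_recovery(model: str, cfg: RecoveryConfig) -> RecoveryReport:
    """Simulate at known truths, refit, and score coverage and correlation."""
    if model not in MODEL_IDS:
        raise ValueError(f"unknown model {model!r}")
    s_sim, s_fit = _spawn_seeds(cfg.seed, 2)
    cohort, truths = simulate_recovery_cohort(model, cfg, s_sim)
    posterior = fit(model, cohort, cfg.sampler(s_fit))

    pop_nat = posterior.population_natural()
    rows = []
    for name in PARAM_NAMES[model]:
        summ = summarize(pop_nat[name].to_numpy())
        truth = TRUE_POPULATIONS[model][name]
        rows.append(
            {
                "parameter": name,
                "truth": truth,
                "median": summ.median,
                "hdi_low": summ.hdi_low,
                "hdi_high": summ.hdi_high,
                "covered": bool(summ.hdi_low <= truth <= summ.hdi_high),
            }
        )
    population = pd.DataFrame(rows)

    indiv_medians = posterior.individual_medians()
    individual_r: dict[str, float | None] = {}
    for name in PARAM_NAMES[model]:
        true_vals = truths[name].to_numpy()
        if np.std(true_vals) == 0:
            individual_r[name] = None  # degenerate point hierarchy
            continue
        est = indiv_medians[name].reindex(truths.index).to_numpy()
        individual_r[name] = float(np.corrcoef(true_vals, est)[0, 1])

    return RecoveryReport(
        model=model,
        population=population,
        individual_r=individual_r,
        converged=posterior.converged,
        n_agents=cfg.effective_agents,
        diagnostics=posterior.diagnostics,
    )


def run_model_recovery(
    cfg: RecoveryConfig,
    generating_models: Sequence[str] = RECOVERY_MODELS,
    fitted_models: Sequence[str] = MODEL_IDS,
) -> ModelRecoveryTable:
    """Simulate from each generating model and cross-fit all candidates."""
    if len(fitted_models) < 2:
        raise ValueError("need at least 2 candidate models")
    gen_seeds = _spawn_seeds(cfg.seed, len(generating_models))
    delta = pd.DataFrame(index=list(fitted_models), columns=list(generating_models), dtype=float)
    se = pd.DataFrame(index=list(fitted_models), columns=list(generating_models), dtype=float)
    totals = pd.DataFrame(index=list(fitted_models), columns=list(generating_models), dtype=float)

    for gen, gseed in zip(generating_models, gen_seeds):
        s_sim, s_fit = _spawn_seeds(gseed, 2)
        cohort, _ = simulate_recovery_cohort(gen, cfg, s_sim)
        matrices: dict[str, ElpdMatrix] = {}
        for k, fitted in enumerate(fitted_models):
            matrices[fitted] = leave_one_block_out(
                fitted, cohort, cfg.sampler(s_fit + k)
            )
        gen_vals = matrices[gen].pointwise["elpd"].to_numpy()
        for fitted in fitted_models:
            vals = matrices[fitted].pointwise["elpd"].to_numpy()
            diff = vals - gen_vals
            delta.loc[fitted, gen] = float(diff.sum())
            se.loc[fitted, gen] = (
                0.0 if fitted == gen else float(np.sqrt(len(diff)) * diff.std(ddof=1))
            )
            totals.loc[fitted, gen] = float(vals.sum())
    return ModelRecoveryTable(delta=delta, se=se, totals=totals)


def run_signature_reproduction(
    model: str,
    population: PopulationParams | PosteriorDraws | None,
    n_agents: int,
    seed: int,
    lags: Sequence[int] = (1,),
    moderators: Sequence[str] = ("prev_difficulty",),
    task: TaskConfig | None = None,
    regression_config: SamplerConfig | None = None,
) -> dict:
    """Simulate a cohort and test whether it shows the lagged-outcome effect.

    ``population=None`` uses the stated recovery truths for the model.
    Returns, per lag, the raw selection rates and the regression
    coefficient summaries (log-odds scale).
    """
    if population is None:
        sds = {n: DEFAULT_INDIVIDUAL_SD[n] for n in PARAM_NAMES[model]}
        population = PopulationParams.from_natural(model, TRUE_POPULATIONS[model], sds)
    task = task or TaskConfig()
    s_params, s_cohort = _spawn_seeds(seed, 2)
    agent_params = sample_cohort_params(model, population, n_agents, s_params)
    cohort = simulate_cohort(model, agent_params, task, s_cohort)

    report: dict = {"model": model, "n_agents": n_agents, "lags": {}}
    for lag in lags:
        rows = build_lagged_dataset(cohort, lag=lag)
        rates = raw_rates(rows)
        reg = fit_lagged_regression(rows, moderators=moderators, config=regression_config)
        report["lags"][lag] = {
            "n_rows": len(rows),
            "rates": rates.pooled,
            "coefficients": reg.to_json_dict(),
            "diagnostics": reg.diagnostics,
        }
    return report


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_full_study(
    cfg: RecoveryConfig,
    out_dir: str | Path,
    data: CohortDataset | None = None,
    signature_agents: int | None = None,
    recovery_models: Sequence[str] = RECOVERY_MODELS,
    fitted_models: Sequence[str] = MODEL_IDS,
    signature_models: Sequence[str] = MODEL_IDS,
) -> dict:
    """Run the whole validation battery and write artifacts + manifest.

    Stages: parameter recovery (three 3-parameter models), model
    recovery, signature reproduction (all four models), and — only when
    an empirical-format cohort is supplied — fitting, comparison and
    lagged regression on it. Failures are recorded per stage and do not
    abort later independent stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "n_agents": cfg.effective_agents,
        "sampler_preset": cfg.sampler_preset,
        "scale_factor": cfg.scale_factor,
        "stages": {},
    }
    stage_seeds = _spawn_seeds(cfg.seed, 4)

    def run_stage(name: str, fn):
        try:
            result = fn()
            manifest["stages"][name] = {"status": "ok"}
            return result
        except Exception as exc:  # recorded, not raised
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            return None

    for model in recovery_models:
        def _param_stage(model=model):
            report = run_parameter_recovery(model, replace(cfg, seed=stage_seeds[0]))
            report.population.to_csv(out / f"param_recovery_{model}.csv", index=False)
            return _jsonable(
                {
                    "individual_r": report.individual_r,
                    "all_covered": report.all_covered,
                    "converged": report.converged,
                }
            )
        res = run_stage(f"param_recovery/{model}", _param_stage)
        if res is not None:
            manifest["stages"][f"param_recovery/{model}"].update(res)

    def _model_stage():
        table = run_model_recovery(
            replace(cfg, seed=stage_seeds[1]),
            generating_models=recovery_models,
            fitted_models=fitted_models,
        )
        table.delta.to_csv(out / "model_recovery_delta.csv")
        table.se.to_csv(out / "model_recovery_se.csv")
        return {
            "top_models": {g: table.top_model(g) for g in table.delta.columns},
        }
    res = run_stage("model_recovery", _model_stage)
    if res is not None:
        manifest["stages"]["model_recovery"].update(res)

    for model in signature_models:
        def _sig_stage(model=model):
            report = run_signature_reproduction(
                model,
                None,
                signature_agents or cfg.effective_agents,
                stage_seeds[2],
                regression_config=cfg.sampler(stage_seeds[2]),
            )
            (out / f"signature_{model}.json").write_text(
                json.dumps(_jsonable(report), indent=2, sort_keys=True)
            )
            coef = report["lags"][1]["coefficients"]["prev_outcome"]
            return {"prev_outcome_median": coef["median"], "pd": coef["pd"]}
        res = run_stage(f"signature/{model}", _sig_stage)
        if res is not None:
            manifest["stages"][f"signature/{model}"].update(res)

    if data is None:
        manifest["stages"]["empirical"] = {"status": "skipped", "reason": "no data supplied"}
    else:
        def _empirical_stage():
            sampler = cfg.sampler(stage_seeds[3])
            matrices = {
                m: leave_one_block_out(m, data, sampler) for m in MODEL_IDS
            }
            comparison = compare(matrices)
            comparison.table.to_csv(out / "empirical_comparison.csv", index=False)
            rows = build_lagged_dataset(data, lag=1)
            reg = fit_lagged_regression(rows)
            (out / "empirical_regression.json").write_text(
                json.dumps(_jsonable(reg.to_json_dict()), indent=2, sort_keys=True)
            )
            return {"best_model": comparison.best_model}
        res = run_stage("empirical", _empirical_stage)
        if res is not None:
            manifest["stages"]["empirical"].update(res)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
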