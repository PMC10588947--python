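"""Leave-one-block-out cross-validated predictive density and the
pairwise 2-standard-error model comparison rule.

For each fold, one task block is held out, the model is refit
hierarchically on the remaining blocks, and every held-out trial is
scored with the log posterior-mean probability of the observed choice
(states reset at the block start and are advanced within the block on
the observed choices and outcomes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._likelihoods import cohort_mean_choice_prob, pack_cohort
from .hierarchical_inference import PosteriorDraws, SamplerConfig, fit
from .rl_models import MODEL_IDS
from .synthetic_task import CohortDataset

__all__ = ["ElpdMatrix", "ElpdComparison", "pointwise_elpd", "leave_one_block_out", "compare"]


@dataclass
class ElpdMatrix:
    """Pointwise held-out log predictive densities for one model."""

    model: str
    pointwise: pd.DataFrame  # participant_id, block, trial, elpd

    @property
    def total(self) -> float:
        return float(self.pointwise["elpd"].sum())

    @property
    def se_total(self) -> float:
        vals = self.pointwise["elpd"].to_numpy()
        return float(np.sqrt(len(vals)) * vals.std(ddof=1))

    @property
    def n_points(self) -> int:
        return len(self.pointwise)


@dataclass
class ElpdComparison:
    """Pairwise deltas against the best model, CSV-ready."""

    table: pd.DataFrame  # model, elpd, se_elpd, delta_vs_best, se_delta, substantial

    @property
    def best_model(self) -> str:
        return str(self.table.iloc[0]["model"])


def pointwise_elpd(
    draws: PosteriorDraws, model: str, held_out: CohortDataset
) -> pd.DataFrame:
    """Per-trial elpd of held-out records under a fitted posterior.

    ``elpd_i = log( mean_s p(choice_i | theta_s) )`` with the probability
    obtained by running the model forward through the held-out block,
    teacher-forced on the observed choices and outcomes.
    """
    if model != draws.model:
        raise ValueError(f"draws are for {draws.model!r}, not {model!r}")
    trained = set(draws.diagnostics.get("trained_blocks", ()))
    overlap = trained & {int(b) for b in held_out.blocks()}
    if overlap:
        raise ValueError(
            f"draws were trained on held-out block(s) {sorted(overlap)}; "
            "refit excluding them"
        )
    packed = pack_cohort(held_out, participant_ids=draws.participant_ids)
    thetas = draws.individual_natural()  # (S, P, K)
    mean_p = cohort_mean_choice_prob(model, packed, thetas)
    out = packed.index.copy()
    out["elpd"] = np.log(mean_p)
    return out


def leave_one_block_out(
    model: str,
    data: CohortDataset,
    config: SamplerConfig = SamplerConfig(),
) -> ElpdMatrix:
    """Cross-validated elpd: each block held out once, scored pointwise."""
    if model not in MODEL_IDS:
        raise ValueError(f"unknown model {model!r}")
    blocks = data.blocks()
    if len(blocks) < 2:
        raise ValueError("leave-one-block-out needs at least 2 blocks")
    participant_ids = tuple(data.participant_ids)
    pieces = []
    for i, b in enumerate(blocks):
        train = data.drop_blocks([b])
        test = data.keep_blocks([b])
        fold_config = SamplerConfig(
            chains=config.chains,
            warmup=config.warmup,
            draws=config.draws,
            seed=config.seed + i,
            target_accept=config.target_accept,
            max_treedepth=config.max_treedepth,
            rhat_threshold=config.rhat_threshold,
        )
        posterior = fit(model, train, fold_config)
        if tuple(posterior.participant_ids) != participant_ids:
            raise ValueError("training fold lost participants; check block coverage")
        pieces.append(pointwise_elpd(posterior, model, test))
    pointwise = pd.concat(pieces, ignore_index=True)
    pointwise = pointwise.sort_values(
        ["participant_id", "block", "trial"], kind="stable"
    ).reset_index(drop=True)
    return ElpdMatrix(model=model, pointwise=pointwise)


def compare(matrices: dict[str, ElpdMatrix] | list[ElpdMatrix]) -> ElpdComparison:
    """Rank models by total elpd and apply the 2xSE substantiality rule.

    Deltas are each model minus the best model; the SE of a delta comes
    from the pointwise differences (sqrt(N) * SD).
    """
    if isinstance(matrices, dict):
        matrices = list(matrices.values())
    if len(matrices) < 2:
        raise ValueError("need at least two models to compare")

    key_cols = ["participant_id", "block", "trial"]
    ref_idx = matrices[0].pointwise[key_cols]
    for m in matrices[1:]:
        idx = m.pointwise[key_cols]
        if len(idx) != len(ref_idx) or not idx.reset_index(drop=True).equals(
            ref_idx.reset_index(drop=True)
        ):
            raise ValueError(
                f"pointwise trial sets differ between {matrices[0].model!r} "
                f"and {m.model!r}"
            )

    best = max(matrices, key=lambda m: m.total)
    best_vals = best.pointwise["elpd"].to_numpy()
    rows = []
    for m in sorted(matrices, key=lambda m: -m.total):
        diff = m.pointwise["elpd"].to_numpy() - best_vals
        delta = float(diff.sum())
        se_delta = 0.0 if m is best else float(np.sqrt(len(diff)) * diff.std(ddof=1))
        rows.append(
            {
                "model": m.model,
                "elpd": m.total,
                "se_elpd": m.se_total,
                "delta_vs_best": delta,
                "se_delta": se_delta,
                "substantial": bool(abs(delta) > 2.0 * se_delta) if m is not best else False,
            }
        )
    return ElpdComparison(table=pd.DataFrame(rows))
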