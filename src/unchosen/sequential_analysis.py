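"""Model-independent analyses of lagged choice behaviour.

The core object is the lagged-trial filter: a pair of trials ``(n, n+lag)``
within a block qualifies when the card left unchosen at ``n`` is offered
again at ``n + lag`` together with a fresh third card (the card chosen at
``n`` must not be reoffered, and the companion card must not have been
offered at ``n``). The outcome at ``n`` then predicts whether the
previously unchosen card is selected, via hierarchical Bayesian logistic
regression with optional deliberation moderators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from ._nuts import sample_nuts
from .hierarchical_inference import PosteriorSummary, SamplerConfig, summarize
from .synthetic_task import CohortDataset, RewardSchedule

__all__ = [
    "ExclusionConfig",
    "ExclusionReport",
    "RegressionResult",
    "apply_exclusions",
    "build_lagged_dataset",
    "raw_rates",
    "fit_lagged_regression",
    "accuracy_score",
    "individual_correlations",
]

MODERATORS = ("block_type", "prev_rt", "prev_difficulty", "curr_difficulty")

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ExclusionConfig:
    rt_min: float = 200.0
    rt_max: float = 4000.0
    max_excluded_fraction: float = 0.10
    max_no_response_fraction: float = 0.05
    use_rt: bool = True

    def __post_init__(self) -> None:
        if self.rt_min >= self.rt_max:
            raise ValueError("rt_min must be below rt_max")
        for f in (self.max_excluded_fraction, self.max_no_response_fraction):
            if not 0.0 < f < 1.0:
                raise ValueError("exclusion fractions must lie in (0, 1)")


@dataclass
class ExclusionReport:
    n_trials_total: int
    n_trials_dropped: int
    excluded_participants: dict[str, str]  # pid -> reason

    @property
    def n_participants_excluded(self) -> int:
        return len(self.excluded_participants)


def apply_exclusions(
    data: CohortDataset, cfg: ExclusionConfig = ExclusionConfig()
) -> tuple[CohortDataset, ExclusionReport]:
    """Drop implausible-RT trials, then participants over either threshold."""
    df = data.records
    if cfg.use_rt:
        if df["rt_ms"].isna().all():
            raise ValueError(
                "RT rules are active but the rt_ms column is empty; for "
                "simulated cohorts use ExclusionConfig(use_rt=False)"
            )
        rt = df["rt_ms"].astype(float)
        bad_rt = rt.notna() & ((rt < cfg.rt_min) | (rt > cfg.rt_max))
    else:
        bad_rt = pd.Series(False, index=df.index)

    no_resp = df["choice"].isna()
    excluded: dict[str, str] = {}
    for pid, grp in df.groupby("participant_id", sort=False):
        frac_bad = bad_rt.loc[grp.index].mean()
        frac_nr = no_resp.loc[grp.index].mean()
        if frac_bad > cfg.max_excluded_fraction:
            excluded[pid] = f"{frac_bad:.1%} trials outside RT bounds"
        elif frac_nr > cfg.max_no_response_fraction:
            excluded[pid] = f"{frac_nr:.1%} no-response trials"

    keep = ~bad_rt & ~df["participant_id"].isin(excluded)
    kept = df[keep].reset_index(drop=True)
    report = ExclusionReport(
        n_trials_total=len(df),
        n_trials_dropped=int(bad_rt.sum()),
        excluded_participants=excluded,
    )
    schedules = {p: s for p, s in data.schedules.items() if p not in excluded}
    return CohortDataset(kept, schedules, data.provenance), report


def _difficulty(schedule: RewardSchedule | None, block: int, trial: int, a: int, b: int):
    if schedule is None:
        return np.nan
    p = schedule.p[block - 1, trial - 1]
    return abs(float(p[a] - p[b]))


def build_lagged_dataset(data: CohortDataset, lag: int = 1) -> pd.DataFrame:
    """Emit one row per qualifying ``(n, n + lag)`` trial pair.

    Columns: participant_id, lag, prev_outcome, chose_prev_unchosen,
    block_type, prev_rt, prev_difficulty, curr_difficulty.
    """
    if lag not in (1, 2):
        raise ValueError(f"lag must be 1 or 2, got {lag}")
    rows = []
    for pid, grp in data.records.groupby("participant_id", sort=False):
        schedule = data.schedules.get(pid)
        for block, bgrp in grp.groupby("block", sort=True):
            bgrp = bgrp.sort_values("trial")
            by_trial = {int(r.trial): r for r in bgrp.itertuples(index=False)}
            for t, r1 in by_trial.items():
                if pd.isna(r1.choice):
                    continue
                r2 = by_trial.get(t + lag)
                if r2 is None or pd.isna(r2.choice):
                    continue
                chosen = int(r1.choice)
                unchosen = int(r1.offer_b if chosen == r1.offer_a else r1.offer_a)
                offered_next = (int(r2.offer_a), int(r2.offer_b))
                if unchosen not in offered_next:
                    continue
                if chosen in offered_next:
                    continue
                third = offered_next[1] if offered_next[0] == unchosen else offered_next[0]
                if third in (int(r1.offer_a), int(r1.offer_b)):
                    continue
                rows.append(
                    {
                        "participant_id": pid,
                        "lag": lag,
                        "prev_outcome": int(r1.reward01),
                        "chose_prev_unchosen": int(int(r2.choice) == unchosen),
                        "block_type": r1.block_type,
                        "prev_rt": float(r1.rt_ms) if pd.notna(r1.rt_ms) else np.nan,
                        "prev_difficulty": _difficulty(
                            schedule, int(block), t, int(r1.offer_a), int(r1.offer_b)
                        ),
                        "curr_difficulty": _difficulty(
                            schedule, int(block), t + lag, *offered_next
                        ),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "lag",
            "prev_outcome",
            "chose_prev_unchosen",
            "block_type",
            "prev_rt",
            "prev_difficulty",
            "curr_difficulty",
        ],
    )


@dataclass
class RawRates:
    """Selection rates of the previously unchosen card by previous outcome."""

    pooled: dict[str, float | None]  # rewarded / unrewarded, overall
    by_block_type: pd.DataFrame  # block_type x {rewarded, unrewarded}
    per_participant: pd.DataFrame  # participant_id x {rewarded, unrewarded}


def raw_rates(rows: pd.DataFrame) -> RawRates:
    """Pooled and per-participant P(chose previously unchosen | outcome)."""
    if rows.empty:
        raise ValueError("no qualifying lagged rows")

    def _rate(sub: pd.DataFrame) -> float | None:
        return float(sub["chose_prev_unchosen"].mean()) if len(sub) else None

    pooled = {
        "rewarded": _rate(rows[rows["prev_outcome"] == 1]),
        "unrewarded": _rate(rows[rows["prev_outcome"] == 0]),
    }
    by_bt = (
        rows.pivot_table(
            index="block_type",
            columns="prev_outcome",
            values="chose_prev_unchosen",
            aggfunc="mean",
        )
        .rename(columns={0: "unrewarded", 1: "rewarded"})
        .rename_axis(columns=None)
    )
    per_p = (
        rows.pivot_table(
            index="participant_id",
            columns="prev_outcome",
            values="chose_prev_unchosen",
            aggfunc="mean",
        )
        .rename(columns={0: "unrewarded", 1: "rewarded"})
        .rename_axis(columns=None)
    )
    return RawRates(pooled=pooled, by_block_type=by_bt, per_participant=per_p)


@dataclass
class RegressionResult:
    coefficients: dict[str, PosteriorSummary]
    per_participant: pd.DataFrame  # per-participant coefficient medians
    draws: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {k: v.to_dict() for k, v in self.coefficients.items()}


def _standardize_within(series: pd.Series, pid: pd.Series) -> np.ndarray:
    vals = series.astype(float)
    grp = vals.groupby(pid)
    mean = grp.transform("mean")
    sd = grp.transform("std").fillna(0.0)
    sd = sd.where(sd > 0, 1.0)
    return ((vals - mean) / sd).to_numpy()


def fit_lagged_regression(
    rows: pd.DataFrame,
    moderators: Sequence[str] = (),
    config: SamplerConfig | None = None,
    center_outcome: bool = False,
) -> RegressionResult:
    """Hierarchical Bayesian logistic regression of the lagged choice.

    Population coefficients get Normal(0, 2) priors; per-participant
    random intercepts and slopes (for the previous outcome and every
    moderator interaction) get half-Normal(0, 1) scale priors,
    non-centered. Continuous moderators are standardized within
    participant; block type is coded win = +0.5 / loss = -0.5.
    Coefficients are reported on the log-odds scale.
    """
    if rows.empty:
        raise ValueError("no rows to fit")
    for m in moderators:
        if m not in MODERATORS:
            raise ValueError(f"unknown moderator {m!r}; expected one of {MODERATORS}")
    rows = rows.reset_index(drop=True)
    if config is None:
        config = SamplerConfig(chains=2, warmup=500, draws=500)

    pid_series = rows["participant_id"]
    pids = tuple(dict.fromkeys(pid_series))
    pid_idx = pid_series.map({p: i for i, p in enumerate(pids)}).to_numpy()
    y = rows["chose_prev_unchosen"].to_numpy(dtype=float)

    outcome = rows["prev_outcome"].to_numpy(dtype=float)
    if center_outcome:
        outcome = outcome - 0.5
    cols = {"intercept": np.ones(len(rows)), "prev_outcome": outcome}
    for m in moderators:
        if m == "block_type":
            vals = rows["block_type"].map({"win": 0.5, "loss": -0.5}).to_numpy(dtype=float)
        else:
            raw = rows[m]
            if raw.isna().any():
                raise ValueError(
                    f"moderator {m!r} has missing values; cannot be used "
                    "(simulated cohorts without RTs or schedules)"
                )
            vals = _standardize_within(raw, pid_series)
        if np.allclose(vals.std(), 0.0):
            raise ValueError(f"moderator {m!r} has zero variance")
        cols[m] = vals
        cols[f"prev_outcome:{m}"] = cols["prev_outcome"] * vals

    coef_names = list(cols)
    X = np.column_stack([cols[c] for c in coef_names])
    random_names = ["intercept", "prev_outcome"] + [
        c for c in coef_names if c.startswith("prev_outcome:")
    ]
    Z = np.column_stack([cols[c] for c in random_names])

    F, R, P = X.shape[1], Z.shape[1], len(pids)
    dim = F + R + P * R

    def logp_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        b = x[:F]
        log_tau = x[F : F + R]
        z = x[F + R :].reshape(P, R)
        tau = np.exp(log_tau)
        u = tau[None, :] * z
        eta = X @ b + np.einsum("nr,nr->n", Z, u[pid_idx])
        p = expit(eta)
        # Bernoulli log-likelihood, stable around extreme eta
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        resid = y - p
        g_b = X.T @ resid
        g_u = np.zeros((P, R))
        np.add.at(g_u, pid_idx, Z * resid[:, None])
        g_z = g_u * tau[None, :]
        g_logtau = (g_u * z).sum(axis=0) * tau
        # priors: b ~ N(0, 2); tau ~ halfN(0, 1) via log tau; z ~ N(0, 1)
        lp = ll
        lp += float(np.sum(-0.125 * b**2 - np.log(2.0) - 0.5 * _LOG_2PI))
        g_b = g_b - b / 4.0
        lp += float(np.sum(np.log(2.0) - 0.5 * _LOG_2PI - 0.5 * tau**2 + log_tau))
        g_logtau = g_logtau - tau**2 + 1.0
        lp += float(np.sum(-0.5 * z**2 - 0.5 * _LOG_2PI))
        g_z = g_z - z
        return lp, np.concatenate([g_b, g_logtau, g_z.ravel()])

    result = sample_nuts(logp_grad, dim, config.to_nuts())
    flat = result.draws.reshape(-1, dim)
    b_draws = flat[:, :F]
    tau_draws = np.exp(flat[:, F : F + R])
    z_draws = flat[:, F + R :].reshape(-1, P, R)

    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = float(np.nanmax(np.asarray(az.rhat(az.from_dict(posterior={"x": result.draws}))["x"])))

    coefficients = {
        name: summarize(b_draws[:, i]) for i, name in enumerate(coef_names)
    }
    # per-participant coefficient = population + random offset
    per_p = {}
    for r, name in enumerate(random_names):
        f_idx = coef_names.index(name)
        indiv = b_draws[:, f_idx, None] + tau_draws[:, r, None] * z_draws[:, :, r]
        per_p[name] = np.median(indiv, axis=0)
    per_participant = pd.DataFrame(per_p, index=list(pids))

    return RegressionResult(
        coefficients=coefficients,
        per_participant=per_participant,
        draws={name: b_draws[:, i] for i, name in enumerate(coef_names)},
        diagnostics={
            "max_rhat": rhat,
            "divergences": int(result.divergences.sum()),
            "n_rows": len(rows),
            "n_participants": P,
        },
    )


def accuracy_score(data: CohortDataset) -> pd.Series:
    """Per-participant rate of choosing the offered card with the higher
    true reward probability (ties count one half)."""
    scores = {}
    for pid, grp in data.records.groupby("participant_id", sort=False):
        schedule = data.schedules.get(pid)
        if schedule is None:
            raise ValueError(f"no schedule available for participant {pid!r}")
        answered = grp[grp["choice"].notna()]
        vals = []
        for r in answered.itertuples(index=False):
            p = schedule.p[int(r.block) - 1, int(r.trial) - 1]
            chosen = int(r.choice)
            other = int(r.offer_b if chosen == r.offer_a else r.offer_a)
            if p[chosen] > p[other]:
                vals.append(1.0)
            elif p[chosen] < p[other]:
                vals.append(0.0)
            else:
                vals.append(0.5)
        scores[pid] = float(np.mean(vals)) if vals else np.nan
    return pd.Series(scores, name="accuracy")


def individual_correlations(x, y) -> tuple[float, PosteriorSummary]:
    """Pearson correlation with a Fisher-z posterior summary.

    The posterior is the standard large-sample approximation:
    ``atanh(r) ~ Normal(atanh(rho), 1 / (n - 3))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the inputs")
    r = float(stats.pearsonr(x, y)[0])
    n = len(x)
    if n > 3 and abs(r) < 1.0:
        zr = np.arctanh(r)
        sd = 1.0 / np.sqrt(n - 3)
        crit = stats.norm.ppf(0.975)
        lo, hi = np.tanh(zr - crit * sd), np.tanh(zr + crit * sd)
        p_pos = float(stats.norm.cdf(zr / sd))
        pd_ = max(p_pos, 1.0 - p_pos)
    else:
        lo = hi = r
        pd_ = 1.0
    return r, PosteriorSummary(median=r, hdi_low=float(lo), hdi_high=float(hi), pd=pd_)
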