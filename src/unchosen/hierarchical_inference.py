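"""Hierarchical Bayesian estimation of the learning models.

Each model parameter gets an independent population location and scale;
individuals are non-centered offsets: ``natural = T(loc + scale * z)``
with ``T`` the inverse-logit for learning rates and the decision weight,
and softplus for the inverse-noise parameter. Priors: locations
Normal(0, 2), scales half-Cauchy(0, 2), offsets Normal(0, 1).

Sampling uses the package's own No-U-Turn sampler over analytic
gradients (see :mod:`unchosen._likelihoods` and :mod:`unchosen._nuts`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._likelihoods import PackedCohort, cohort_loglik_grad, pack_cohort
from ._nuts import NutsConfig, sample_nuts
from .rl_models import MODEL_IDS, PARAM_NAMES, ModelParams
from .synthetic_task import CohortDataset

__all__ = [
    "TRANSFORMS",
    "DEFAULT_INDIVIDUAL_SD",
    "to_natural",
    "to_unconstrained",
    "PopulationPrior",
    "PopulationParams",
    "SamplerConfig",
    "PosteriorDraws",
    "PosteriorSummary",
    "log_posterior",
    "fit",
    "summarize",
    "sample_cohort_params",
]

#: unconstrained-to-natural transform per parameter
TRANSFORMS = {
    "alpha_chosen": "logit",
    "alpha_unchosen": "logit",
    "omega": "logit",
    "beta": "softplus",
}

#: individual-level SDs on the unconstrained scale used when simulating
#: cohorts from fixed population values (1 for rates/weights, 1.5 for beta)
DEFAULT_INDIVIDUAL_SD = {
    "alpha_chosen": 1.0,
    "alpha_unchosen": 1.0,
    "omega": 1.0,
    "beta": 1.5,
}

_LOG_2PI = np.log(2.0 * np.pi)


def _softplus(x):
    return np.logaddexp(0.0, x)


def _inv_softplus(v):
    v = np.asarray(v, dtype=float)
    with np.errstate(divide="ignore"):
        out = v + np.log(-np.expm1(-v))
    return out


def to_natural(name: str, x):
    """Map an unconstrained value to the parameter's natural scale."""
    kind = TRANSFORMS[name]
    return expit(x) if kind == "logit" else _softplus(x)


def to_unconstrained(name: str, v):
    """Inverse of :func:`to_natural`; boundary values are rejected."""
    kind = TRANSFORMS[name]
    v = np.asarray(v, dtype=float)
    if kind == "logit":
        if np.any(v <= 0.0) or np.any(v >= 1.0):
            raise ValueError(f"{name} must lie strictly inside (0, 1)")
        return logit(v)
    if np.any(v <= 0.0):
        raise ValueError(f"{name} must be strictly positive")
    return _inv_softplus(v)


def _dnatural_dx(name: str, x):
    kind = TRANSFORMS[name]
    s = expit(x)
    return s * (1.0 - s) if kind == "logit" else s


@dataclass(frozen=True)
class PopulationPrior:
    """Weakly informative hyperpriors."""

    location_sd: float = 2.0
    scale_gamma: float = 2.0  # half-Cauchy scale
    offset_sd: float = 1.0

    def __post_init__(self) -> None:
        if min(self.location_sd, self.scale_gamma, self.offset_sd) <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class PopulationParams:
    """Fixed population values: unconstrained locations and positive scales."""

    model: str
    loc: Mapping[str, float]
    scale: Mapping[str, float]

    def __post_init__(self) -> None:
        names = PARAM_NAMES[self.model]
        if set(self.loc) != set(names) or set(self.scale) != set(names):
            raise ValueError(f"expected parameters {names}")
        if any(s < 0 for s in self.scale.values()):
            raise ValueError("population scales must be non-negative")

    @classmethod
    def from_natural(
        cls,
        model: str,
        natural: Mapping[str, float],
        scale: Mapping[str, float] | None = None,
    ) -> "PopulationParams":
        """Build from natural-scale population values (e.g. alpha = 0.3)."""
        names = PARAM_NAMES[model]
        loc = {n: float(to_unconstrained(n, natural[n])) for n in names}
        if scale is None:
            scale = {n: DEFAULT_INDIVIDUAL_SD[n] for n in names}
        return cls(model, loc, dict(scale))

    def natural(self) -> dict[str, float]:
        return {n: float(to_natural(n, v)) for n, v in self.loc.items()}


_PRESETS = {
    "default": (4, 1000, 500),
    "paper": (20, 1000, 50),
    "desk": (2, 400, 250),
    "fast": (2, 250, 150),
}


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 500
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 10
    rhat_threshold: float = 1.01

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains for R-hat")

    @classmethod
    def preset(cls, name: str, seed: int = 0, **kwargs) -> "SamplerConfig":
        chains, warmup, draws = _PRESETS[name]
        return cls(chains=chains, warmup=warmup, draws=draws, seed=seed, **kwargs)

    def to_nuts(self) -> NutsConfig:
        return NutsConfig(
            chains=self.chains,
            warmup=self.warmup,
            draws=self.draws,
            seed=self.seed,
            target_accept=self.target_accept,
            max_treedepth=self.max_treedepth,
        )


def _make_logp_grad(model: str, packed: PackedCohort, prior: PopulationPrior):
    names = PARAM_NAMES[model]
    K = len(names)
    P = packed.n_participants
    kinds = np.array([TRANSFORMS[n] == "logit" for n in names])

    def logp_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        loc = x[:K]
        log_sig = x[K : 2 * K]
        z = x[2 * K :].reshape(P, K)
        sig = np.exp(log_sig)
        eta = loc[None, :] + sig[None, :] * z

        s = expit(eta)
        theta = np.where(kinds[None, :], s, _softplus(eta))
        dtheta = np.where(kinds[None, :], s * (1.0 - s), s)

        ll, g_theta = cohort_loglik_grad(model, packed, theta)
        g_eta = g_theta * dtheta

        g_loc = g_eta.sum(axis=0)
        g_z = g_eta * sig[None, :]
        g_logsig = (g_eta * z).sum(axis=0) * sig

        # hyperpriors
        lsd, gam = prior.location_sd, prior.scale_gamma
        lp = ll
        lp += float(np.sum(-0.5 * (loc / lsd) ** 2 - np.log(lsd) - 0.5 * _LOG_2PI))
        g_loc = g_loc - loc / lsd**2
        # half-Cauchy on sig, sampled as log sig (Jacobian = log sig)
        ratio2 = (sig / gam) ** 2
        lp += float(np.sum(np.log(2.0 / (np.pi * gam)) - np.log1p(ratio2) + log_sig))
        g_logsig = g_logsig + 1.0 - 2.0 * ratio2 / (1.0 + ratio2)
        # standard-normal offsets
        lp += float(np.sum(-0.5 * z**2 - 0.5 * _LOG_2PI))
        g_z = g_z - z

        grad = np.concatenate([g_loc, g_logsig, g_z.ravel()])
        return lp, grad

    return logp_grad


def log_posterior(
    model: str,
    data: CohortDataset,
    loc: np.ndarray,
    log_scale: np.ndarray,
    z: np.ndarray,
    prior: PopulationPrior = PopulationPrior(),
) -> float:
    """Joint log density (priors + likelihood) at one unconstrained point."""
    if model not in MODEL_IDS:
        raise ValueError(f"unknown model {model!r}")
    loc = np.asarray(loc, dtype=float)
    log_scale = np.asarray(log_scale, dtype=float)
    z = np.asarray(z, dtype=float)
    K = len(PARAM_NAMES[model])
    packed = pack_cohort(data)
    if loc.shape != (K,) or log_scale.shape != (K,):
        raise ValueError(f"population parameters must have shape ({K},)")
    if z.shape != (packed.n_participants, K):
        raise ValueError(
            f"offsets must have shape ({packed.n_participants}, {K}), got {z.shape}"
        )
    x = np.concatenate([loc, log_scale, z.ravel()])
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite parameter values")
    lp, _ = _make_logp_grad(model, packed, prior)(x)
    return float(lp)


@dataclass
class PosteriorDraws:
    """MCMC draws from a hierarchical fit, plus diagnostics."""

    model: str
    param_names: tuple[str, ...]
    participant_ids: tuple[str, ...]
    loc: np.ndarray  # (chains, draws, K) unconstrained
    log_scale: np.ndarray  # (chains, draws, K)
    z: np.ndarray  # (chains, draws, P, K)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.loc.shape[0]

    @property
    def n_draws_total(self) -> int:
        return self.loc.shape[0] * self.loc.shape[1]

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", True))

    def population_natural(self) -> pd.DataFrame:
        """Population-level parameters on the natural scale, one column each."""
        flat = self.loc.reshape(-1, self.loc.shape[-1])
        cols = {
            n: to_natural(n, flat[:, k]) for k, n in enumerate(self.param_names)
        }
        return pd.DataFrame(cols)

    def individual_natural(self) -> np.ndarray:
        """Natural-scale individual parameters, shape (S, P, K)."""
        C, D, P, K = self.z.shape
        eta = self.loc[:, :, None, :] + np.exp(self.log_scale)[:, :, None, :] * self.z
        eta = eta.reshape(C * D, P, K)
        out = np.empty_like(eta)
        for k, n in enumerate(self.param_names):
            out[:, :, k] = to_natural(n, eta[:, :, k])
        return out

    def individual_medians(self) -> pd.DataFrame:
        med = np.median(self.individual_natural(), axis=0)
        return pd.DataFrame(
            med, columns=list(self.param_names), index=list(self.participant_ids)
        )

    def population_params(self) -> PopulationParams:
        """Posterior-median population values (for simulation hand-off)."""
        loc_med = np.median(self.loc.reshape(-1, self.loc.shape[-1]), axis=0)
        sig_med = np.median(
            np.exp(self.log_scale).reshape(-1, self.log_scale.shape[-1]), axis=0
        )
        return PopulationParams(
            self.model,
            {n: float(loc_med[k]) for k, n in enumerate(self.param_names)},
            {n: float(sig_med[k]) for k, n in enumerate(self.param_names)},
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: chain, draw, parameter, value."""
        C, D, K = self.loc.shape
        rows = []
        chain = np.repeat(np.arange(C), D)
        draw = np.tile(np.arange(D), C)
        for k, n in enumerate(self.param_names):
            for label, arr in (
                (f"mu_{n}", self.loc[:, :, k].ravel()),
                (f"sigma_{n}", np.exp(self.log_scale[:, :, k]).ravel()),
            ):
                rows.append(
                    pd.DataFrame(
                        {"chain": chain, "draw": draw, "parameter": label, "value": arr}
                    )
                )
        return pd.concat(rows, ignore_index=True)


def fit(
    model: str,
    data: CohortDataset,
    config: SamplerConfig = SamplerConfig(),
    prior: PopulationPrior = PopulationPrior(),
) -> PosteriorDraws:
    """Hierarchical NUTS fit of one model to a cohort.

    Returns draws with R-hat and divergence diagnostics; a fit whose worst
    R-hat exceeds the threshold is flagged (``converged = False``) but
    still returned.
    """
    if model not in MODEL_IDS:
        raise ValueError(f"unknown model {model!r}")
    packed = pack_cohort(data)
    if packed.n_rows == 0:
        raise ValueError("no answered trials to fit")
    names = PARAM_NAMES[model]
    K = len(names)
    P = packed.n_participants
    dim = 2 * K + P * K

    logp_grad = _make_logp_grad(model, packed, prior)
    result = sample_nuts(logp_grad, dim, config.to_nuts())

    C, D = config.chains, config.draws
    x = result.draws
    loc = x[:, :, :K]
    log_scale = x[:, :, K : 2 * K]
    z = x[:, :, 2 * K :].reshape(C, D, P, K)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(az.from_dict(posterior={"x": x}))
    rhat = np.asarray(rhat_ds["x"])
    max_rhat = float(np.nanmax(rhat))
    converged = max_rhat <= config.rhat_threshold
    if not converged:
        warnings.warn(
            f"fit of {model} flagged non-converged: max R-hat {max_rhat:.3f}",
            stacklevel=2,
        )
    diagnostics = {
        "max_rhat": max_rhat,
        "rhat_population": {
            f"mu_{n}": float(rhat[k]) for k, n in enumerate(names)
        },
        "divergences": int(result.divergences.sum()),
        "step_sizes": result.step_sizes.tolist(),
        "mean_accept": result.mean_accept.tolist(),
        "converged": converged,
        "trained_blocks": [int(b) for b in data.blocks()],
        "chains": C,
        "draws": D,
        "warmup": config.warmup,
        "seed": config.seed,
    }
    return PosteriorDraws(
        model=model,
        param_names=tuple(names),
        participant_ids=packed.participant_ids,
        loc=loc,
        log_scale=log_scale,
        z=z,
        diagnostics=diagnostics,
    )


@dataclass(frozen=True)
class PosteriorSummary:
    median: float
    hdi_low: float
    hdi_high: float
    pd: float

    def to_dict(self) -> dict[str, float]:
        return {
            "median": self.median,
            "hdi_low": self.hdi_low,
            "hdi_high": self.hdi_high,
            "pd": self.pd,
        }


def summarize(
    draws: np.ndarray, hdi_prob: float = 0.95, interval: str = "hdi"
) -> PosteriorSummary:
    """Median, 95% interval and probability of direction for one quantity.

    ``interval`` selects highest-density (default) or equal-tailed bounds.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 100:
        raise ValueError(f"need at least 100 draws, got {draws.size}")
    if interval == "hdi":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lo, hi = az.hdi(draws, hdi_prob=hdi_prob)
    elif interval == "eti":
        tail = (1.0 - hdi_prob) / 2.0
        lo, hi = np.quantile(draws, [tail, 1.0 - tail])
    else:
        raise ValueError(f"unknown interval kind {interval!r}")
    p_pos = float(np.mean(draws > 0))
    return PosteriorSummary(
        median=float(np.median(draws)),
        hdi_low=float(lo),
        hdi_high=float(hi),
        pd=max(p_pos, 1.0 - p_pos),
    )


def sample_cohort_params(
    model: str,
    population: PopulationParams | PosteriorDraws,
    n_agents: int,
    seed: int,
) -> list[ModelParams]:
    """Draw per-agent natural-scale parameters from a population.

    With fixed :class:`PopulationParams`, agents are Normal draws around
    the location on the unconstrained scale. With :class:`PosteriorDraws`,
    each agent first draws a population (location, scale) sample from the
    marginal posterior, then its own offset.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    rng = np.random.default_rng(seed)
    names = PARAM_NAMES[model]
    out = []
    if isinstance(population, PopulationParams):
        if population.model != model:
            raise ValueError("population was built for a different model")
        loc = np.array([population.loc[n] for n in names])
        scale = np.array([population.scale[n] for n in names])
        eta = loc[None, :] + scale[None, :] * rng.standard_normal((n_agents, len(names)))
    else:
        if population.model != model:
            raise ValueError("draws come from a different model")
        flat_loc = population.loc.reshape(-1, len(names))
        flat_sig = np.exp(population.log_scale.reshape(-1, len(names)))
        idx = rng.integers(0, len(flat_loc), size=n_agents)
        eta = flat_loc[idx] + flat_sig[idx] * rng.standard_normal((n_agents, len(names)))
    for row in eta:
        natural = {n: float(to_natural(n, row[k])) for k, n in enumerate(names)}
        out.append(ModelParams(model=model, **natural))
    return out
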